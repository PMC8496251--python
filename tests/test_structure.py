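"""Population-structure metrics: communities, F_ST, PC1 screen, LD summary."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from kinscan.datatypes import GenotypeMatrix, MarkerMap, PhenotypeTable
from kinscan.kinship import KinshipMatrix, overall_kinship
from kinscan import simpop
from kinscan.structure import (
    SubpopulationAssignment,
    detect_subpopulations,
    fst,
    kinship_pc1,
    kinship_to_network,
    ld_summary,
    trait_kinship_pc1_correlation,
)


def _K(values, ids=None):
    n = len(values)
    return KinshipMatrix(np.asarray(values, float),
                        ids or [f"i{k}" for k in range(n)], "overall")


class TestNetwork:
    def test_uniform_offdiagonal_gives_triangle(self):
        K = _K([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1]])
        G = kinship_to_network(K)
        assert G.number_of_edges() == 3
        assert all(d["weight"] == 0.5 for _, _, d in G.edges(data=True))

    def test_diagonal_only_gives_edgeless_graph(self):
        G = kinship_to_network(_K(np.eye(4)))
        assert G.number_of_edges() == 0
        assert G.number_of_nodes() == 4

    def test_negative_entry_clipped_to_absent_edge(self):
        vals = np.full((5, 5), 0.3)
        np.fill_diagonal(vals, 1.0)
        vals[1, 3] = vals[3, 1] = -0.2
        G = kinship_to_network(_K(vals))
        assert not G.has_edge("i1", "i3")
        assert G.number_of_edges() == 9  # 10 pairs minus the clipped one


class TestCommunities:
    def test_two_cliques_split(self):
        G = nx.Graph()
        for block, nodes in enumerate([range(5), range(5, 10)]):
            for a, b in itertools.combinations(nodes, 2):
                G.add_edge(a, b, weight=1.0)
        G.add_edge(0, 5, weight=0.01)
        out = detect_subpopulations(G)
        assert out.n_communities == 2
        assert {out.membership[i] for i in range(5)} != {
            out.membership[i] for i in range(5, 10)
        }

    def test_edgeless_graph_flagged_singletons(self):
        G = nx.Graph()
        G.add_nodes_from(range(4))
        out = detect_subpopulations(G)
        assert out.degenerate and out.n_communities == 4

    def test_matches_exhaustive_modularity_oracle(self):
        # planted 3-block toy small enough for exhaustive search
        rng = np.random.default_rng(0)
        n, blocks = 9, [range(0, 3), range(3, 6), range(6, 9)]
        G = nx.Graph()
        for blk in blocks:
            for a, b in itertools.combinations(blk, 2):
                G.add_edge(a, b, weight=1.0)
        for a, b in [(0, 3), (1, 6), (4, 7)]:
            G.add_edge(a, b, weight=0.05)
        found = detect_subpopulations(G)

        def partitions(collection):
            if len(collection) == 1:
                yield [collection]
                return
            first, rest = collection[0], collection[1:]
            for smaller in partitions(rest):
                for i, subset in enumerate(smaller):
                    yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
                yield [[first]] + smaller

        best_q = max(
            nx.community.modularity(G, [set(p) for p in part], weight="weight")
            for part in partitions(list(range(n)))
            if len(part) <= 3
        )
        assert found.modularity == pytest.approx(best_q, abs=1e-12)


class TestFst:
    def _assignment(self, labels):
        mem = {f"i{k}": lab for k, lab in enumerate(labels)}
        return SubpopulationAssignment(mem, len(set(labels)), 0.0)

    def test_hand_computed_two_subpopulations(self):
        # one locus, equal sizes, p1=0.2, p2=0.8
        g = np.array([[0.2]] * 5 + [[0.8]] * 5)
        gm = GenotypeMatrix(g, [f"i{k}" for k in range(10)], ["m"])
        out = fst(gm, self._assignment([0] * 5 + [1] * 5))
        assert out.pi_total == pytest.approx(0.5)
        assert out.pi_sub_mean == pytest.approx(0.32)
        assert out.fst == pytest.approx(0.36)

    def test_single_community_gives_zero(self):
        rng = np.random.default_rng(1)
        g = rng.choice([0, 0.5, 1.0], size=(8, 5))
        gm = GenotypeMatrix(g, [f"i{k}" for k in range(8)], list("abcde"))
        out = fst(gm, self._assignment([0] * 8))
        assert out.fst == pytest.approx(0.0, abs=1e-12)

    def test_opposite_fixation_gives_one(self):
        g = np.array([[0.0, 0.0]] * 4 + [[1.0, 1.0]] * 4)
        gm = GenotypeMatrix(g, [f"i{k}" for k in range(8)], ["a", "b"])
        out = fst(gm, self._assignment([0] * 4 + [1] * 4))
        assert out.fst == pytest.approx(1.0)

    def test_invariant_to_relabeling_and_order(self):
        rng = np.random.default_rng(2)
        g = rng.choice([0, 0.5, 1.0], size=(10, 6))
        ids = [f"i{k}" for k in range(10)]
        gm = GenotypeMatrix(g, ids, [f"m{k}" for k in range(6)])
        labels = [0, 1, 0, 2, 1, 0, 2, 1, 0, 2]
        a = fst(gm, self._assignment(labels))
        b = fst(gm, self._assignment([{0: 7, 1: 3, 2: 5}[l] for l in labels]))
        perm = rng.permutation(10)
        gm_p = gm.subset_individuals(perm)
        mem = {f"i{k}": labels[k] for k in range(10)}
        c = fst(gm_p, SubpopulationAssignment(mem, 3, 0.0))
        assert a.fst == pytest.approx(b.fst) == pytest.approx(c.fst)

    def test_ril_replicates_raise_fst_over_averaged(self, small_ril):
        K = overall_kinship(small_ril.genotypes)
        assign = detect_subpopulations(kinship_to_network(K))
        f_rep = fst(small_ril.genotypes, assign).fst
        nr = simpop.average_over_lines(small_ril)
        Knr = overall_kinship(nr.genotypes)
        assign_nr = detect_subpopulations(kinship_to_network(Knr))
        f_nr = fst(nr.genotypes, assign_nr).fst
        assert f_rep > f_nr


class TestPC1:
    def test_trait_equal_to_pc1_has_unit_correlation(self, small_f2):
        K = overall_kinship(small_f2.genotypes)
        pc1 = kinship_pc1(K)
        ph = PhenotypeTable(
            pc1[:, None], list(K.individual_ids), ["pc"]
        )
        out = trait_kinship_pc1_correlation(K, ph)
        assert out["pc"] == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_trait_has_zero_correlation(self, small_f2):
        K = overall_kinship(small_f2.genotypes)
        pc1 = kinship_pc1(K)
        rng = np.random.default_rng(0)
        y = rng.standard_normal(K.n)
        y = y - y.mean()
        y -= (y @ (pc1 - pc1.mean())) / ((pc1 - pc1.mean()) @ (pc1 - pc1.mean())) * (
            pc1 - pc1.mean()
        )
        ph = PhenotypeTable(y[:, None], list(K.individual_ids), ["orth"])
        out = trait_kinship_pc1_correlation(K, ph)
        assert out["orth"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_independent_eigen_oracle(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((8, 5))
        K = _K(A @ A.T / 5)
        y = rng.standard_normal(8)
        ph = PhenotypeTable(y[:, None], K.individual_ids, ["t"])
        # oracle: direct eigen of centered matrix + pearson correlation
        C = np.eye(8) - np.ones((8, 8)) / 8
        vals, vecs = np.linalg.eigh(C @ K.values @ C)
        v = vecs[:, np.argmax(vals)]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        expect = np.corrcoef(y, v)[0, 1]
        out = trait_kinship_pc1_correlation(K, ph)
        assert out["t"] == pytest.approx(expect, abs=1e-10)

    def test_constant_trait_reported_missing(self, small_f2):
        K = overall_kinship(small_f2.genotypes)
        ph = PhenotypeTable(
            np.ones((K.n, 1)), list(K.individual_ids), ["const"]
        )
        assert np.isnan(trait_kinship_pc1_correlation(K, ph)["const"])


class TestLD:
    def test_duplicated_marker_columns_have_unit_r(self):
        rng = np.random.default_rng(5)
        x = rng.choice([0, 0.5, 1.0], size=20)
        gm = GenotypeMatrix(
            np.column_stack([x, x]), [f"i{k}" for k in range(20)], ["a", "b"]
        )
        mm = MarkerMap(pd.DataFrame({"marker": ["a", "b"],
                                     "chromosome": ["1", "1"],
                                     "position_cM": [0.0, 1.0]}))
        pooled, qs, _ = ld_summary(gm, mm)
        assert pooled == pytest.approx([1.0])

    def test_independent_markers_have_near_zero_mean_r(self):
        rng = np.random.default_rng(6)
        g = rng.choice([0, 0.5, 1.0], size=(1000, 10), p=[0.25, 0.5, 0.25])
        gm = GenotypeMatrix(g, [f"i{k}" for k in range(1000)],
                            [f"m{k}" for k in range(10)])
        mm = MarkerMap(pd.DataFrame({"marker": gm.marker_ids,
                                     "chromosome": ["1"] * 10,
                                     "position_cM": np.arange(10.0)}))
        pooled, _, _ = ld_summary(gm, mm)
        se = 1 / np.sqrt(1000)
        assert abs(pooled.mean()) < 3 * se / np.sqrt(len(pooled))

    def test_f2_has_higher_ld_than_ail(self, small_f2):
        spec = simpop.GeneticMapSpec([("1", 100.0, 20), ("2", 100.0, 20)])
        ail = simpop.simulate_population(
            simpop.BreedingDesign(scheme="AIL", n_individuals=200,
                                  n_intercross_generations=50),
            spec, seed=11,
        )
        _, q_f2, _ = ld_summary(small_f2.genotypes, small_f2.marker_map)
        _, q_ail, _ = ld_summary(ail.genotypes, ail.marker_map)
        assert q_f2["q0.5"] > q_ail["q0.5"]

    def test_monomorphic_pairs_skipped_and_counted(self):
        g = np.column_stack([np.full(10, 0.5), np.linspace(0, 1, 10)])
        gm = GenotypeMatrix(g, [f"i{k}" for k in range(10)], ["mono", "poly"])
        mm = MarkerMap(pd.DataFrame({"marker": ["mono", "poly"],
                                     "chromosome": ["1", "1"],
                                     "position_cM": [0.0, 1.0]}))
        pooled, _, skipped = ld_summary(gm, mm)
        assert pooled.size == 0 and skipped == 1
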