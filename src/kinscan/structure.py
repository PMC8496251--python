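"""Population-structure diagnostics.

Subpopulations are found by greedy modularity maximization on the kinship
matrix viewed as a weighted network; differentiation between them is
summarized by the fixation index F_ST = (π_T − π_S)/π_T built from expected
heterozygosity.  Trait screening uses the Pearson correlation of each trait
with the first principal component of the (centered) kinship matrix, and
linkage disequilibrium is summarized as the distribution of within-chromosome
pairwise marker correlations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, MarkerMap, PhenotypeTable
from .kinship import KinshipMatrix

__all__ = [
    "SubpopulationAssignment",
    "StructureMetrics",
    "kinship_to_network",
    "detect_subpopulations",
    "fst",
    "trait_kinship_pc1_correlation",
    "ld_summary",
    "structure_report",
]


@dataclass
class SubpopulationAssignment:
    membership: dict  # individual id -> community label (int)
    n_communities: int
    modularity: float
    degenerate: bool = False  # edgeless graph: singleton communities

    def sizes(self) -> dict:
        out: dict = {}
        for lab in self.membership.values():
            out[lab] = out.get(lab, 0) + 1
        return out


@dataclass
class StructureMetrics:
    fst: float
    pi_total: float
    pi_sub_mean: float
    fst_clipped: bool = False
    pc1_correlations: dict = field(default_factory=dict)
    ld_quantiles: dict = field(default_factory=dict)
    n_ld_pairs: int = 0
    n_monomorphic_skipped: int = 0


def kinship_to_network(K: KinshipMatrix) -> nx.Graph:
    """Kinship matrix → weighted undirected graph.

    Nodes are individuals; each off-diagonal entry becomes an edge weight.
    Self-loops are removed; negative weights are clipped to zero and the
    resulting zero-weight edges dropped (modularity clustering assumes
    nonnegative weights).
    """
    A = np.clip(K.values, 0.0, None).copy()
    np.fill_diagonal(A, 0.0)
    G = nx.Graph()
    G.add_nodes_from(K.individual_ids)
    n = K.n
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j] > 0:
                G.add_edge(
                    K.individual_ids[i], K.individual_ids[j], weight=A[i, j]
                )
    return G


def detect_subpopulations(graph: nx.Graph) -> SubpopulationAssignment:
    """Greedy modularity-maximization communities (fast-greedy clustering).

    Deterministic for a fixed node insertion order.  An edgeless graph gets
    one singleton community per node, flagged degenerate.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.number_of_edges() == 0:
        membership = {node: i for i, node in enumerate(graph.nodes)}
        return SubpopulationAssignment(
            membership, len(membership), 0.0, degenerate=True
        )
    communities = nx.community.greedy_modularity_communities(
        graph, weight="weight"
    )
    # stable labels: communities ordered by their smallest node (node order)
    order = {node: i for i, node in enumerate(graph.nodes)}
    communities = sorted(
        (sorted(c, key=order.get) for c in communities),
        key=lambda c: order[c[0]],
    )
    membership = {
        node: lab for lab, comm in enumerate(communities) for node in comm
    }
    q = nx.community.modularity(
        graph, [set(c) for c in communities], weight="weight"
    )
    return SubpopulationAssignment(membership, len(communities), float(q))


def fst(
    genotypes: GenotypeMatrix,
    assignment: SubpopulationAssignment,
    weighted: bool = True,
    heterozygosity: str = "expected",
) -> StructureMetrics:
    """F_ST = (π_T − π_S)/π_T from heterozygosity summed over loci.

    π_T sums expected heterozygosity 2p(1−p) over loci at pooled allele
    frequencies; π_S averages the per-subpopulation sums (weighted by
    subpopulation size by default).  ``heterozygosity="observed"`` uses the
    observed heterozygote fraction (dosage exactly 0.5) instead; expected is
    the default because inbred-line individuals have near-zero observed
    heterozygosity.  F_ST is clipped at 0 (and flagged) if π_S > π_T.
    """
    G = genotypes.values
    labels = np.array(
        [assignment.membership[i] for i in genotypes.individual_ids]
    )

    def pi(block: np.ndarray) -> float:
        if heterozygosity == "expected":
            p = block.mean(axis=0)
            return float(np.sum(2 * p * (1 - p)))
        return float(np.sum((np.abs(block - 0.5) < 1e-9).mean(axis=0)))

    pi_total = pi(G)
    groups = [np.flatnonzero(labels == lab) for lab in np.unique(labels)]
    pis = np.array([pi(G[idx]) for idx in groups])
    sizes = np.array([len(idx) for idx in groups], dtype=float)
    pi_sub = float(
        np.average(pis, weights=sizes if weighted else None)
    )
    if pi_total <= 0:
        warnings.warn("monomorphic genotypes: F_ST undefined", stacklevel=2)
        return StructureMetrics(np.nan, pi_total, pi_sub)
    value = (pi_total - pi_sub) / pi_total
    clipped = value < 0
    return StructureMetrics(max(value, 0.0), pi_total, pi_sub, clipped)


def kinship_pc1(K: KinshipMatrix) -> np.ndarray:
    """Leading eigenvector of the row/column-centered kinship matrix, sign
    fixed so its largest-magnitude loading is positive."""
    n = K.n
    if n < 3:
        raise ValueError("PC1 requires at least 3 individuals")
    C = np.eye(n) - np.ones((n, n)) / n
    Kc = C @ K.values @ C
    vals, vecs = np.linalg.eigh((Kc + Kc.T) / 2)
    pc1 = vecs[:, -1]
    top = np.argmax(np.abs(pc1))
    if pc1[top] < 0:
        pc1 = -pc1
    return pc1


def trait_kinship_pc1_correlation(
    K: KinshipMatrix, phenotypes: PhenotypeTable
) -> dict[str, float]:
    """Pearson correlation of each trait with kinship PC1.

    Used to screen traits whose variance is dominated by population
    structure; constant traits are reported as NaN.
    """
    pc1 = kinship_pc1(K)
    out = {}
    for t, name in enumerate(phenotypes.trait_names):
        y = phenotypes.values[:, t]
        keep = np.isfinite(y)
        yk, pk = y[keep], pc1[keep]
        if yk.size < 3 or np.std(yk) == 0:
            out[name] = np.nan
            continue
        out[name] = float(np.corrcoef(yk, pk)[0, 1])
    return out


def ld_summary(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    quantiles: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> tuple[np.ndarray, dict[str, float], int]:
    """Pooled within-chromosome pairwise Pearson r between markers.

    Returns (all r values, summary quantiles, number of pairs skipped
    because a member was monomorphic).
    """
    chrom_of = marker_map.chromosome_of()
    values: list[np.ndarray] = []
    skipped = 0
    cols = {m: i for i, m in enumerate(genotypes.marker_ids)}
    for chrom in marker_map.chromosomes:
        markers = [m for m in marker_map.markers_on(chrom) if m in cols]
        if len(markers) < 2:
            continue
        X = genotypes.values[:, [cols[m] for m in markers]]
        sd = X.std(axis=0)
        poly = sd > 0
        n_poly = int(poly.sum())
        n_all = len(markers)
        skipped += n_all * (n_all - 1) // 2 - n_poly * (n_poly - 1) // 2
        if n_poly < 2:
            continue
        R = np.corrcoef(X[:, poly], rowvar=False)
        iu = np.triu_indices(n_poly, k=1)
        values.append(R[iu])
    pooled = np.concatenate(values) if values else np.array([])
    qs = {
        f"q{q:g}": (float(np.quantile(pooled, q)) if pooled.size else np.nan)
        for q in quantiles
    }
    return pooled, qs, skipped


def structure_report(
    K: KinshipMatrix,
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    phenotypes: PhenotypeTable | None = None,
) -> StructureMetrics:
    """One-stop structure metrics: communities, F_ST, PC1 screens, LD."""
    assignment = detect_subpopulations(kinship_to_network(K))
    metrics = fst(genotypes, assignment)
    if phenotypes is not None:
        metrics.pc1_correlations = trait_kinship_pc1_correlation(K, phenotypes)
    pooled, qs, skipped = ld_summary(genotypes, marker_map)
    metrics.ld_quantiles = qs
    metrics.n_ld_pairs = pooled.size
    metrics.n_monomorphic_skipped = skipped
    return metrics
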