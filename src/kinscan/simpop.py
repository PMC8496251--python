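"""Breeding-scheme population simulator.

Generates genotype matrices with the linkage and relatedness structure of the
standard mouse mapping designs — F2 intercross, backcross, recombinant inbred
lines (RIL, with genomic replicates or averaged over them), advanced
intercross lines (AIL), and an 8-founder outbred stock — together with traits
of configurable genetic architecture (additive QTL, epistatic pairs,
kinship-structured polygenic background, strain random effects, residual
noise).

Meiosis follows the Haldane model: crossover counts per chromosome are
Poisson with mean ``length_cM / 100``, crossover positions are uniform in cM,
and there is no interference.  Haplotypes are sequences of founder labels;
dosages are produced at the end by mapping founder labels to biallelic
alternate-allele counts (for two-founder designs, founder 1 simply carries
the alternate allele everywhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, MarkerMap, PhenotypeTable
from .kinship import overall_kinship

__all__ = [
    "GeneticMapSpec",
    "BreedingDesign",
    "TraitModel",
    "SimulatedPopulation",
    "simulate_meiosis",
    "simulate_population",
    "simulate_traits",
    "simulate_bundle",
]

SCHEMES = ("F2", "backcross", "RIL", "RIL_NR", "AIL", "outbred8")


@dataclass
class GeneticMapSpec:
    """Equally spaced markers on chromosomes of given genetic length."""

    chromosomes: list[tuple[str, float, int]]  # (label, length_cM, n_markers)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        for label, length, n in self.chromosomes:
            if length < 0:
                raise ValueError(f"chromosome {label}: length_cM must be >= 0")
            if n < 1:
                raise ValueError(f"chromosome {label}: n_markers must be >= 1")

    @property
    def n_markers(self) -> int:
        return sum(n for _, _, n in self.chromosomes)

    def positions(self, label: str) -> np.ndarray:
        for lab, length, n in self.chromosomes:
            if lab == label:
                if n == 1:
                    return np.array([length / 2.0])
                return np.linspace(0.0, length, n)
        raise KeyError(label)

    def chrom_slices(self) -> list[tuple[str, float, slice]]:
        out, start = [], 0
        for label, length, n in self.chromosomes:
            out.append((label, length, slice(start, start + n)))
            start += n
        return out

    def to_marker_map(self) -> MarkerMap:
        rows = []
        for label, _, _ in self.chromosomes:
            for k, pos in enumerate(self.positions(label)):
                rows.append((f"chr{label}_m{k}", label, pos))
        return MarkerMap(
            pd.DataFrame(rows, columns=["marker", "chromosome", "position_cM"])
        )


@dataclass
class BreedingDesign:
    """Which cross to simulate and at what scale.

    ``n_individuals`` is the number of rows in the output genotype matrix;
    for RIL it defaults to ``n_lines * replicates_per_line`` and for RIL_NR
    to ``n_lines``.
    """

    scheme: str
    n_individuals: int = 0
    n_founders: int = 2
    n_intercross_generations: int = 50  # AIL filial generation / outbred rounds
    n_inbreeding_generations: int = 20  # RIL sib-mating generations
    n_lines: int = 0
    replicates_per_line: int = 1
    force_homozygous: bool = False  # RIL: collapse residual hets to 0/1
    n_sampled_generations: int = 1  # outbred8: draw from this many final gens

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.scheme == "outbred8":
            self.n_founders = 8
        elif self.n_founders != 2:
            raise ValueError("only outbred8 uses more than 2 founders")
        if self.scheme in ("RIL", "RIL_NR"):
            if self.n_lines <= 0:
                raise ValueError("RIL designs require n_lines > 0")
            if self.replicates_per_line < 1:
                raise ValueError("replicates_per_line must be >= 1")
            if not self.n_individuals:
                self.n_individuals = self.n_lines * (
                    1 if self.scheme == "RIL_NR" else self.replicates_per_line
                )
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.scheme in ("AIL", "outbred8") and self.n_intercross_generations < 2:
            raise ValueError("intercross designs need at least 2 generations")


@dataclass
class TraitModel:
    """Genetic architecture of simulated traits.

    Effects are on the dosage scale: an additive QTL of effect a contributes
    ``a * dosage``; an epistatic pair ``w * dosage_i * dosage_j``.  The
    polygenic term is drawn with covariance proportional to the realized
    overall kinship matrix (normalized to unit mean diagonal) scaled to
    ``polygenic_variance``, i.e. exactly the random effect the mixed model
    fits.  ``line_variance`` adds a strain-level effect shared by genomic
    replicates (RIL only).
    """

    additive_qtl: list[tuple[int, float]] = field(default_factory=list)
    epistatic_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    polygenic_variance: float = 0.0
    line_variance: float = 0.0
    residual_variance: float = 1.0
    n_traits: int = 2
    trait_scaling: list[float] | None = None  # per-trait fixed-effect multiplier
    #: optional (n_qtl, n_traits) per-trait multipliers on the additive QTL
    #: effects; partial pleiotropy (distinct columns) is what gives the CAPE
    #: trait matrix full rank — identical columns make every pair degenerate
    qtl_trait_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        for v, name in [
            (self.polygenic_variance, "polygenic_variance"),
            (self.line_variance, "line_variance"),
            (self.residual_variance, "residual_variance"),
        ]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_traits < 1:
            raise ValueError("n_traits must be >= 1")
        if self.trait_scaling is None:
            self.trait_scaling = [1.0] * self.n_traits
        if len(self.trait_scaling) != self.n_traits:
            raise ValueError("trait_scaling length must equal n_traits")
        if self.qtl_trait_weights is not None:
            self.qtl_trait_weights = np.asarray(self.qtl_trait_weights, float)
            if self.qtl_trait_weights.shape != (
                len(self.additive_qtl), self.n_traits
            ):
                raise ValueError(
                    "qtl_trait_weights must be (n_qtl, n_traits)"
                )


@dataclass
class SimulatedPopulation:
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    phenotypes: PhenotypeTable | None = None
    line_labels: list[str] | None = None
    generation_labels: list[int] | None = None
    founder_haplotypes: np.ndarray | None = None  # (n, 2, M) founder labels
    truth: dict = field(default_factory=dict)

    def to_bundle(self):
        """View as a population bundle for the analysis pipeline."""
        from .io import PopulationBundle

        if self.phenotypes is None:
            raise ValueError("simulate traits before building a bundle")
        return PopulationBundle(
            self.genotypes, self.marker_map, self.phenotypes, None
        )


# --------------------------------------------------------------------------
# meiosis

def _gamete_one_chrom(
    hap_pair: np.ndarray, positions: np.ndarray, length_cM: float, rng
) -> np.ndarray:
    """One recombined chromosome from a (2, m) founder-label haplotype pair."""
    n_co = rng.poisson(length_cM / 100.0)
    strand = int(rng.integers(2))
    if n_co == 0:
        return hap_pair[strand].copy()
    breaks = np.sort(rng.uniform(0.0, length_cM, size=n_co))
    # strand index at each marker = start strand + #crossovers before it, mod 2
    n_before = np.searchsorted(breaks, positions, side="left")
    idx = (strand + n_before) % 2
    return hap_pair[idx, np.arange(len(positions))]


def simulate_meiosis(
    parent_haplotype_pair: np.ndarray, map_spec: GeneticMapSpec, rng
) -> np.ndarray:
    """Produce one gamete (founder-label sequence) from a haplotype pair.

    ``parent_haplotype_pair`` has shape (2, n_markers) over the full map;
    chromosomes recombine independently.
    """
    pair = np.asarray(parent_haplotype_pair)
    if pair.shape != (2, map_spec.n_markers):
        raise ValueError("haplotype pair shape must be (2, n_markers)")
    gamete = np.empty(map_spec.n_markers, dtype=pair.dtype)
    for label, length, sl in map_spec.chrom_slices():
        gamete[sl] = _gamete_one_chrom(
            pair[:, sl], map_spec.positions(label), length, rng
        )
    return gamete


def _offspring(mother: np.ndarray, father: np.ndarray, spec, rng) -> np.ndarray:
    return np.stack(
        [simulate_meiosis(mother, spec, rng), simulate_meiosis(father, spec, rng)]
    )


# --------------------------------------------------------------------------
# breeding schemes (all on founder-label haplotypes, shape (n, 2, M))

def _f1(spec: GeneticMapSpec) -> np.ndarray:
    M = spec.n_markers
    return np.stack([np.zeros(M, dtype=np.int8), np.ones(M, dtype=np.int8)])


def _sim_f2(n: int, spec: GeneticMapSpec, rng) -> np.ndarray:
    f1 = _f1(spec)
    return np.stack([_offspring(f1, f1, spec, rng) for _ in range(n)])


def _sim_backcross(n: int, spec: GeneticMapSpec, rng) -> np.ndarray:
    f1 = _f1(spec)
    a = np.zeros(spec.n_markers, dtype=np.int8)  # recurrent parent haplotype
    return np.stack(
        [np.stack([a.copy(), simulate_meiosis(f1, spec, rng)]) for _ in range(n)]
    )


def _sim_ril_lines(
    n_lines: int, k_gens: int, spec: GeneticMapSpec, rng
) -> np.ndarray:
    """One inbred genome per line: F1 × F1, then k generations of sib mating."""
    f1 = _f1(spec)
    lines = []
    for _ in range(n_lines):
        pair = (_offspring(f1, f1, spec, rng), _offspring(f1, f1, spec, rng))
        for _ in range(k_gens):
            pair = (
                _offspring(pair[0], pair[1], spec, rng),
                _offspring(pair[0], pair[1], spec, rng),
            )
        lines.append(_offspring(pair[0], pair[1], spec, rng))
    return np.stack(lines)


def _random_mating_round(pop: np.ndarray, n_out: int, spec, rng) -> np.ndarray:
    """Each offspring from a random pair of distinct parents."""
    n = pop.shape[0]
    out = []
    for _ in range(n_out):
        i, j = rng.choice(n, size=2, replace=False)
        out.append(_offspring(pop[i], pop[j], spec, rng))
    return np.stack(out)


def _sim_ail(n: int, g: int, spec: GeneticMapSpec, rng) -> np.ndarray:
    """AIL at filial generation g: F2, then g-2 rounds of random-pair mating."""
    pop = _sim_f2(max(n, 20), spec, rng)
    for _ in range(g - 2):
        pop = _random_mating_round(pop, pop.shape[0], spec, rng)
    return pop[:n]


def _sim_outbred8(
    n: int, g: int, n_sampled_gens: int, spec: GeneticMapSpec, rng
) -> tuple[np.ndarray, np.ndarray]:
    """8-founder outbred: round-robin funnel per individual, then g rounds of
    random mating; individuals may be drawn from the last few generations."""
    M = spec.n_markers

    def funnel() -> np.ndarray:
        order = rng.permutation(8).astype(np.int8)
        two_way = [
            np.stack([np.full(M, order[2 * i], dtype=np.int8),
                      np.full(M, order[2 * i + 1], dtype=np.int8)])
            for i in range(4)
        ]
        four_way = [
            _offspring(two_way[0], two_way[1], spec, rng),
            _offspring(two_way[2], two_way[3], spec, rng),
        ]
        return _offspring(four_way[0], four_way[1], spec, rng)

    pop_size = max(n, 20)
    pop = np.stack([funnel() for _ in range(pop_size)])
    sampled, gens = [], []
    for gen in range(g):
        pop = _random_mating_round(pop, pop_size, spec, rng)
        if gen >= g - n_sampled_gens:
            sampled.append(pop)
            gens.append(gen + 1)
    pools = np.concatenate(sampled, axis=0)
    gen_of = np.repeat(gens, pop_size)
    pick = rng.choice(pools.shape[0], size=n, replace=False)
    return pools[pick], gen_of[pick]


# --------------------------------------------------------------------------
# dosage conversion and the public entry points

def _haplos_to_dosage(
    haplos: np.ndarray, founder_alleles: np.ndarray
) -> np.ndarray:
    """(n, 2, M) founder labels + (n_founders, M) 0/1 alleles → (n, M) dosage."""
    M = haplos.shape[2]
    cols = np.arange(M)
    a = founder_alleles[haplos[:, 0, :], cols]
    b = founder_alleles[haplos[:, 1, :], cols]
    return (a + b) / 2.0


def simulate_population(
    design: BreedingDesign, map_spec: GeneticMapSpec, seed: int
) -> SimulatedPopulation:
    """Simulate genotypes under a breeding design; deterministic given seed."""
    rng = np.random.default_rng(seed)
    mm = map_spec.to_marker_map()
    M = map_spec.n_markers
    line_labels = generation_labels = None

    if design.scheme == "F2":
        haplos = _sim_f2(design.n_individuals, map_spec, rng)
    elif design.scheme == "backcross":
        haplos = _sim_backcross(design.n_individuals, map_spec, rng)
    elif design.scheme in ("RIL", "RIL_NR"):
        line_genomes = _sim_ril_lines(
            design.n_lines, design.n_inbreeding_generations, map_spec, rng
        )
        if design.force_homozygous:
            # collapse residual heterozygous sites to a random homozygote
            het = line_genomes[:, 0, :] != line_genomes[:, 1, :]
            pick = rng.integers(2, size=het.shape).astype(bool)
            chosen = np.where(pick, line_genomes[:, 0, :], line_genomes[:, 1, :])
            line_genomes[:, 0, :] = np.where(het, chosen, line_genomes[:, 0, :])
            line_genomes[:, 1, :] = np.where(het, chosen, line_genomes[:, 1, :])
        reps = 1 if design.scheme == "RIL_NR" else design.replicates_per_line
        haplos = np.repeat(line_genomes, reps, axis=0)
        line_labels = [
            f"line{l}" for l in np.repeat(np.arange(design.n_lines), reps)
        ]
    elif design.scheme == "AIL":
        haplos = _sim_ail(
            design.n_individuals, design.n_intercross_generations, map_spec, rng
        )
    elif design.scheme == "outbred8":
        haplos, gen_of = _sim_outbred8(
            design.n_individuals,
            design.n_intercross_generations,
            design.n_sampled_generations,
            map_spec,
            rng,
        )
        generation_labels = [int(g) for g in gen_of]
    else:  # pragma: no cover
        raise ValueError(design.scheme)

    if design.n_founders == 2:
        founder_alleles = np.array([np.zeros(M), np.ones(M)])
    else:
        # each founder carries a random biallelic genotype per marker
        founder_alleles = rng.integers(
            2, size=(design.n_founders, M)
        ).astype(float)
    dosages = _haplos_to_dosage(haplos, founder_alleles)

    ids = [f"ind{i}" for i in range(haplos.shape[0])]
    if design.scheme == "RIL_NR":
        ids = [f"line{l}" for l in range(design.n_lines)]
    elif line_labels is not None:
        reps = design.replicates_per_line
        ids = [f"{lab}_r{i % reps}" for i, lab in enumerate(line_labels)]

    gm = GenotypeMatrix(dosages, ids, mm.marker_ids)
    truth = {
        "scheme": design.scheme,
        "seed": seed,
        "founder_alleles": founder_alleles,
    }
    return SimulatedPopulation(
        genotypes=gm,
        marker_map=mm,
        line_labels=line_labels,
        generation_labels=generation_labels,
        founder_haplotypes=haplos,
        truth=truth,
    )


def average_over_lines(pop: SimulatedPopulation) -> SimulatedPopulation:
    """Average genotype (and phenotype) rows within line: the RIL → RIL-NR
    reduction, one row per line."""
    if pop.line_labels is None:
        raise ValueError("population has no line labels")
    labels = np.asarray(pop.line_labels)
    uniq = list(dict.fromkeys(pop.line_labels))
    G = np.stack(
        [pop.genotypes.values[labels == lab].mean(axis=0) for lab in uniq]
    )
    gm = GenotypeMatrix(G, uniq, list(pop.genotypes.marker_ids))
    ph = None
    if pop.phenotypes is not None:
        P = np.stack(
            [pop.phenotypes.values[labels == lab].mean(axis=0) for lab in uniq]
        )
        ph = PhenotypeTable(P, uniq, list(pop.phenotypes.trait_names))
    return SimulatedPopulation(
        genotypes=gm, marker_map=pop.marker_map, phenotypes=ph,
        truth=dict(pop.truth, averaged_over_lines=True),
    )


def simulate_traits(
    pop: SimulatedPopulation, model: TraitModel, seed: int
) -> SimulatedPopulation:
    """Draw phenotypes under a trait model; returns a new population with
    ``phenotypes`` set and a truth record holding every component drawn.

    y = Σ a·dosage + Σ w·dosage_i·dosage_j + polygenic + line + residual,
    with the polygenic term multivariate normal with covariance
    ``polygenic_variance × K/mean(diag K)`` for the realized overall kinship K.
    """
    rng = np.random.default_rng(seed)
    G = pop.genotypes.values
    n, M = G.shape
    for idx, _ in model.additive_qtl:
        if not 0 <= idx < M:
            raise ValueError(f"additive QTL marker index {idx} out of range")
    for i, j, _ in model.epistatic_pairs:
        if not (0 <= i < M and 0 <= j < M):
            raise ValueError(f"epistatic pair ({i},{j}) out of range")

    genetic_per_trait = np.zeros((n, model.n_traits))
    for q, (idx, a) in enumerate(model.additive_qtl):
        w_t = (
            model.qtl_trait_weights[q]
            if model.qtl_trait_weights is not None
            else np.ones(model.n_traits)
        )
        genetic_per_trait += a * G[:, idx][:, None] * w_t[None, :]
    epi = np.zeros(n)
    for i, j, w in model.epistatic_pairs:
        epi += w * G[:, i] * G[:, j]
    genetic_per_trait += epi[:, None]

    L = None
    if model.polygenic_variance > 0:
        K = overall_kinship(pop.genotypes).normalized().values
        vals, vecs = np.linalg.eigh(K)
        vals = np.clip(vals, 0.0, None)
        L = vecs * np.sqrt(vals)[None, :]

    line_index = None
    if model.line_variance > 0:
        if pop.line_labels is None:
            raise ValueError("line_variance > 0 requires line labels")
        uniq = list(dict.fromkeys(pop.line_labels))
        line_index = np.array([uniq.index(lab) for lab in pop.line_labels])

    Y = np.empty((n, model.n_traits))
    truth_components = []
    for t in range(model.n_traits):
        y = model.trait_scaling[t] * genetic_per_trait[:, t]
        comp = {"genetic": y.copy()}
        if L is not None:
            u = np.sqrt(model.polygenic_variance) * (L @ rng.standard_normal(n))
            y = y + u
            comp["polygenic"] = u
        if line_index is not None:
            e_line = np.sqrt(model.line_variance) * rng.standard_normal(
                line_index.max() + 1
            )
            y = y + e_line[line_index]
            comp["line"] = e_line[line_index]
        eps = np.sqrt(model.residual_variance) * rng.standard_normal(n)
        y = y + eps
        comp["residual"] = eps
        Y[:, t] = y
        truth_components.append(comp)

    ph = PhenotypeTable(
        Y,
        list(pop.genotypes.individual_ids),
        [f"trait{t}" for t in range(model.n_traits)],
    )
    denom = (
        model.polygenic_variance + model.line_variance + model.residual_variance
    )
    truth = dict(
        pop.truth,
        additive_qtl=list(model.additive_qtl),
        epistatic_pairs=list(model.epistatic_pairs),
        polygenic_variance=model.polygenic_variance,
        line_variance=model.line_variance,
        residual_variance=model.residual_variance,
        h2=(model.polygenic_variance / denom) if denom > 0 else 0.0,
        components=truth_components,
        trait_seed=seed,
    )
    return SimulatedPopulation(
        genotypes=pop.genotypes,
        marker_map=pop.marker_map,
        phenotypes=ph,
        line_labels=pop.line_labels,
        generation_labels=pop.generation_labels,
        founder_haplotypes=pop.founder_haplotypes,
        truth=truth,
    )


def simulate_bundle(
    design: BreedingDesign,
    map_spec: GeneticMapSpec,
    model: TraitModel,
    seed: int,
) -> SimulatedPopulation:
    """Genotypes + traits in one call (trait seed derived from the design seed)."""
    pop = simulate_population(design, map_spec, seed)
    return simulate_traits(pop, model, seed=(seed * 100003 + 7) % (2**31 - 1))
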