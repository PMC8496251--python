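"""Single-locus and pairwise marker regressions with optional kinship rotation.

The single-locus model per trait j and marker is

    U_ij = β0j + Σ_c x_c,i β_cj + x_1,i β_1j + ε_ij

and the pairwise model adds a second marker and their product

    U_ij = β0j + Σ_c x_c,i β_cj + x_1,i β_1j + x_2,i β_2j
           + x_1,i x_2,i β_12j + ε_ij.

With ``correction="reduced"`` the phenotype and design are first rotated into
the whitened basis of the leave-one-chromosome-out (single-locus) or
leave-two-chromosomes-out (pairwise) mixed-model fit; ``"overall"`` uses the
all-marker kinship matrix; ``"none"`` runs plain OLS.  P-values default to a
t distribution with n−1 degrees of freedom (``df_rule="n_minus_1"``); the
conventional residual degrees of freedom are available via
``df_rule="residual"``.

Empirical p-values for the interaction (and CAPE) statistics come from a
pooled permutation null: phenotype rows are permuted jointly across traits,
preserving trait–trait correlation, and statistics from successive
permutations are pooled until a target null size is reached.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CovariateTable, GenotypeMatrix, MarkerMap, PhenotypeTable
from .kinship import loco_kinship, ltco_kinship, overall_kinship
from .lmm import LMMFit, eigen_kinship, fit_mixing_parameter, rotate

__all__ = [
    "ScanResult",
    "PairScanResult",
    "PermutationNull",
    "marker_scan",
    "select_markers_for_pairs",
    "pair_scan",
    "permutation_null",
    "empirical_p",
]

CORRECTIONS = ("none", "reduced", "overall")


@dataclass
class ScanResult:
    """Long-format single-locus scan results: one row per (marker, trait)."""

    table: pd.DataFrame  # trait, marker, beta, se, t, p, beta0, n_used
    correction: str
    df_rule: str
    n_monomorphic: int = 0

    def best_p_per_marker(self, traits: list[str] | None = None) -> pd.Series:
        t = self.table
        if traits is not None:
            t = t[t["trait"].isin(traits)]
        return t.groupby("marker", sort=False)["p"].min()


@dataclass
class PairScanResult:
    """Pairwise scan results with retained coefficient covariance blocks.

    ``coef_cov[(m1, m2)][trait]`` is the symmetric 3×3 covariance of
    (β̂₁, β̂₂, β̂₁₂) from that trait's regression.
    """

    table: pd.DataFrame  # trait, marker1, marker2, beta1, beta2, beta12,
    #                      se1, se2, se12, t12, p12, flagged
    coef_cov: dict = field(default_factory=dict)
    correction: str = "none"
    df_rule: str = "n_minus_1"

    def attach_empirical_p(self, null: "PermutationNull") -> None:
        """Add empirical interaction p-values from a pooled permutation null."""
        stats_ = self.table["t12"].to_numpy()
        self.table["p12_empirical"] = empirical_p(stats_, null)


@dataclass
class PermutationNull:
    """Pooled null distribution of absolute scan statistics."""

    values: np.ndarray
    target_size: int
    kind: str  # main | interaction | cape
    n_permutations: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.size and not np.isfinite(self.values).all():
            raise ValueError("permutation null contains non-finite values")

    @property
    def size(self) -> int:
        return self.values.size


def empirical_p(statistic, null: PermutationNull) -> np.ndarray | float:
    """p = (1 + #{null ≥ |statistic|}) / (1 + N); never exactly zero."""
    if null.size == 0:
        raise ValueError("empty permutation null")
    stat = np.abs(np.atleast_1d(np.asarray(statistic, float)))
    sorted_null = np.sort(null.values)
    n_ge = null.size - np.searchsorted(sorted_null, stat, side="left")
    p = (1.0 + n_ge) / (1.0 + null.size)
    return p if np.ndim(statistic) else float(p[0])


# --------------------------------------------------------------------------
# rotation plumbing

class _RotationCache:
    """Caches kinship eigendecompositions and per-trait mixing fits keyed by
    the omitted chromosome set, so LOCO/LTCO scans reuse work."""

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        marker_map: MarkerMap | None,
        covariates: np.ndarray | None,
        denominator: str = "used",
    ):
        self.genotypes = genotypes
        self.marker_map = marker_map
        self.covariates = covariates
        self.denominator = denominator
        self._eigen: dict = {}
        self._fit: dict = {}

    def clone_for_new_phenotypes(self) -> "_RotationCache":
        """Share the (phenotype-independent) eigendecompositions but start
        with a fresh mixing-parameter fit cache."""
        new = _RotationCache(
            self.genotypes, self.marker_map, self.covariates, self.denominator
        )
        new._eigen = self._eigen
        return new

    def eigen(self, omit: tuple[str, ...]):
        key = tuple(sorted(omit))
        if key not in self._eigen:
            if not key:
                K = overall_kinship(self.genotypes)
            elif len(key) == 1:
                K = loco_kinship(
                    self.genotypes, self.marker_map, key[0], self.denominator
                )
            else:
                K = ltco_kinship(
                    self.genotypes, self.marker_map, key[0], key[1],
                    self.denominator,
                )
            self._eigen[key] = eigen_kinship(K.normalized())
        return self._eigen[key]

    def fit(self, trait_key, y: np.ndarray, omit: tuple[str, ...]) -> LMMFit:
        key = (trait_key, tuple(sorted(omit)))
        if key not in self._fit:
            self._fit[key] = fit_mixing_parameter(
                y, self.covariates, self.eigen(omit)
            )
        return self._fit[key]


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None or np.size(covariates) == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), covariates])


def _cov_values(covariates) -> np.ndarray | None:
    if covariates is None:
        return None
    if isinstance(covariates, CovariateTable):
        return covariates.values
    return np.asarray(covariates, float)


def _pvalue(t: np.ndarray, n: int, p_full: int, df_rule: str) -> np.ndarray:
    df = n - 1 if df_rule == "n_minus_1" else n - p_full
    return 2.0 * stats.t.sf(np.abs(t), df)


# --------------------------------------------------------------------------
# single-locus scan

def marker_scan(
    phenotypes: PhenotypeTable,
    genotypes: GenotypeMatrix,
    covariates: CovariateTable | np.ndarray | None = None,
    correction: str = "none",
    marker_map: MarkerMap | None = None,
    df_rule: str = "n_minus_1",
    kinship_denominator: str = "used",
) -> ScanResult:
    """Regress every trait on every marker, optionally after kinship rotation.

    ``correction="reduced"`` rotates with the LOCO kinship of each marker's
    chromosome (requires ``marker_map``); ``"overall"`` rotates once per trait
    with the all-marker kinship; ``"none"`` is plain OLS.  Individuals with a
    missing value of a trait are dropped for that trait only.  Monomorphic
    markers yield missing statistics and are counted.
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"correction must be one of {CORRECTIONS}")
    if correction == "reduced" and marker_map is None:
        raise ValueError("reduced correction requires a marker map")
    if genotypes.has_missing:
        raise ValueError("impute missing genotypes before scanning")
    G = genotypes.values
    n_all, n_markers = G.shape
    cov = _cov_values(covariates)

    if correction == "reduced":
        chrom_of = marker_map.chromosome_of()
        groups: dict[tuple[str, ...], np.ndarray] = {}
        for j, m in enumerate(genotypes.marker_ids):
            groups.setdefault((chrom_of[m],), []).append(j)
        groups = {k: np.asarray(v) for k, v in groups.items()}
    elif correction == "overall":
        groups = {(): np.arange(n_markers)}
    else:
        groups = {None: np.arange(n_markers)}

    rows = []
    n_monomorphic = 0
    for t_idx, trait in enumerate(phenotypes.trait_names):
        y_full = phenotypes.values[:, t_idx]
        keep = np.flatnonzero(np.isfinite(y_full))
        if keep.size < 3:
            raise ValueError(f"trait {trait}: fewer than 3 observed values")
        sub_geno = genotypes.subset_individuals(keep) if keep.size < n_all else genotypes
        y = y_full[keep]
        cov_k = cov[keep] if cov is not None else None
        cache = _RotationCache(
            sub_geno, marker_map, cov_k, kinship_denominator
        ) if correction != "none" else None

        for omit, marker_idx in groups.items():
            if correction == "none":
                ys, Xs = y, _design(cov_k, keep.size)
                Ms = sub_geno.values[:, marker_idx]
            else:
                fit = cache.fit(trait, y, omit)
                design = _design(cov_k, keep.size)
                ys, Xs = rotate(y, design, fit)
                _, Ms = rotate(y, sub_geno.values[:, marker_idx], fit)
            n = ys.shape[0]
            p0 = Xs.shape[1]
            # Frisch–Waugh: residualize on the base design
            Q, _ = np.linalg.qr(Xs)
            y_res = ys - Q @ (Q.T @ ys)
            M_res = Ms - Q @ (Q.T @ Ms)
            ss_x = np.einsum("ij,ij->j", M_res, M_res)
            poly = ss_x > 1e-12 * max(1.0, float(np.max(ss_x, initial=0.0)))
            beta = np.full(len(marker_idx), np.nan)
            se = np.full(len(marker_idx), np.nan)
            with np.errstate(divide="ignore", invalid="ignore"):
                beta[poly] = (M_res[:, poly].T @ y_res) / ss_x[poly]
                rss0 = float(y_res @ y_res)
                rss = rss0 - beta[poly] ** 2 * ss_x[poly]
                rss = np.clip(rss, 0.0, None)
                sigma2 = rss / max(n - p0 - 1, 1)
                se[poly] = np.sqrt(sigma2 / ss_x[poly])
            tstat = beta / se
            pval = _pvalue(tstat, n, p0 + 1, df_rule)
            n_monomorphic += int((~poly).sum())
            for k, j in enumerate(marker_idx):
                rows.append(
                    (
                        trait,
                        genotypes.marker_ids[j],
                        beta[k],
                        se[k],
                        tstat[k],
                        pval[k] if np.isfinite(tstat[k]) else np.nan,
                        n,
                    )
                )

    table = pd.DataFrame(
        rows, columns=["trait", "marker", "beta", "se", "t", "p", "n_used"]
    )
    # preserve marker order within trait
    order = {m: i for i, m in enumerate(genotypes.marker_ids)}
    table = table.sort_values(
        ["trait", "marker"], key=lambda s: s.map(order) if s.name == "marker" else s
    ).reset_index(drop=True)
    return ScanResult(table, correction, df_rule, n_monomorphic)


# --------------------------------------------------------------------------
# marker selection and pair scan

@dataclass
class MarkerSelection:
    markers: list[str]
    pairs: list[tuple[str, str]]
    excluded_pairs: list[tuple[str, str]]


def select_markers_for_pairs(
    scan: ScanResult,
    genotypes: GenotypeMatrix,
    n_keep: int,
    collinearity_r_max: float = 0.5,
    traits: list[str] | None = None,
) -> MarkerSelection:
    """Pick the markers with the strongest main effects for pairwise testing.

    Markers are ranked by their minimum main-effect p across the (two)
    traits and taken greedily from the top, skipping any marker whose
    genotype Pearson correlation with an already selected marker exceeds
    ``collinearity_r_max`` in magnitude (in high-LD designs the strongest
    markers cluster on one linkage block, so without this pruning no
    testable pair would survive).  Any remaining pair above the threshold
    is still excluded from the downstream pair list.
    """
    if n_keep < 2:
        raise ValueError("n_keep must be at least 2")
    best = scan.best_p_per_marker(traits).dropna()
    ranked = best.sort_values(kind="stable").index.tolist()
    midx = {m: i for i, m in enumerate(genotypes.marker_ids)}
    G = genotypes.values
    selected: list[str] = []
    with np.errstate(invalid="ignore"):
        for m in ranked:
            if len(selected) >= n_keep:
                break
            x = G[:, midx[m]]
            if x.std() == 0:
                continue
            ok = True
            for s in selected:
                r = np.corrcoef(x, G[:, midx[s]])[0, 1]
                if np.isfinite(r) and abs(r) > collinearity_r_max:
                    ok = False
                    break
            if ok:
                selected.append(m)
        X = G[:, [midx[m] for m in selected]]
        R = np.corrcoef(X, rowvar=False)
    pairs, excluded = [], []
    for a, b in itertools.combinations(range(len(selected)), 2):
        pair = (selected[a], selected[b])
        r = R[a, b]
        if np.isfinite(r) and abs(r) > collinearity_r_max:
            excluded.append(pair)
        else:
            pairs.append(pair)
    return MarkerSelection(selected, pairs, excluded)


def pair_scan(
    phenotypes: PhenotypeTable,
    genotypes: GenotypeMatrix,
    pairs: list[tuple[str, str]],
    covariates: CovariateTable | np.ndarray | None = None,
    correction: str = "none",
    marker_map: MarkerMap | None = None,
    df_rule: str = "n_minus_1",
    kinship_denominator: str = "used",
    rotation_cache: "_RotationCache | None" = None,
) -> PairScanResult:
    """Fit the two-marker interaction model for every pair and trait.

    With ``correction="reduced"`` the kinship matrix leaves out the two
    chromosomes carrying the pair (one, if they coincide).  The 3×3
    coefficient covariance of (β̂₁, β̂₂, β̂₁₂) is retained per (pair, trait)
    for the CAPE reparametrization.  Pairs whose design is numerically
    collinear are flagged, not fatal.
    """
    if not pairs:
        raise ValueError("pair list is empty")
    if correction not in CORRECTIONS:
        raise ValueError(f"correction must be one of {CORRECTIONS}")
    if correction == "reduced" and marker_map is None:
        raise ValueError("reduced correction requires a marker map")
    if phenotypes.has_missing:
        keep = np.flatnonzero(np.isfinite(phenotypes.values).all(axis=1))
        phenotypes = phenotypes.subset_individuals(keep)
        genotypes = genotypes.subset_individuals(keep)
        if covariates is not None and isinstance(covariates, CovariateTable):
            covariates = covariates.subset_individuals(keep)
        elif covariates is not None:
            covariates = np.asarray(covariates, float)[keep]
    cov = _cov_values(covariates)
    midx = {m: i for i, m in enumerate(genotypes.marker_ids)}
    chrom_of = marker_map.chromosome_of() if marker_map is not None else None

    cache = rotation_cache
    if cache is None and correction != "none":
        cache = _RotationCache(genotypes, marker_map, cov, kinship_denominator)

    rows = []
    coef_cov: dict = {}
    n = genotypes.n_individuals
    base = _design(cov, n)
    for trait_i, trait in enumerate(phenotypes.trait_names):
        y = phenotypes.values[:, trait_i]
        for m1, m2 in pairs:
            x1 = genotypes.values[:, midx[m1]]
            x2 = genotypes.values[:, midx[m2]]
            X = np.column_stack([base, x1, x2, x1 * x2])
            if correction == "none":
                ys, Xs = y, X
            else:
                omit = ()
                if correction == "reduced":
                    ca, cb = chrom_of[m1], chrom_of[m2]
                    omit = (ca,) if ca == cb else (ca, cb)
                fit = cache.fit(trait, y, omit)
                ys, Xs = rotate(y, X, fit)
            p_full = Xs.shape[1]
            XtX = Xs.T @ Xs
            flagged = False
            try:
                cond = np.linalg.cond(XtX)
                if not np.isfinite(cond) or cond > 1e12:
                    raise np.linalg.LinAlgError
                coef = np.linalg.solve(XtX, Xs.T @ ys)
                resid = ys - Xs @ coef
                sigma2 = float(resid @ resid) / max(n - p_full, 1)
                C = np.linalg.inv(XtX) * sigma2
            except np.linalg.LinAlgError:
                flagged = True
                coef = np.full(p_full, np.nan)
                C = np.full((p_full, p_full), np.nan)
            b1, b2, b12 = coef[-3], coef[-2], coef[-1]
            se = np.sqrt(np.diag(C)[-3:]) if not flagged else np.full(3, np.nan)
            t12 = b12 / se[2] if se[2] > 0 else np.nan
            p12 = (
                _pvalue(np.array([t12]), n, p_full, df_rule)[0]
                if np.isfinite(t12)
                else np.nan
            )
            rows.append(
                (trait, m1, m2, b1, b2, b12, se[0], se[1], se[2], t12, p12,
                 flagged)
            )
            block = C[-3:, -3:] if not flagged else None
            coef_cov.setdefault((m1, m2), {})[trait] = block

    table = pd.DataFrame(
        rows,
        columns=[
            "trait", "marker1", "marker2", "beta1", "beta2", "beta12",
            "se1", "se2", "se12", "t12", "p12", "flagged",
        ],
    )
    return PairScanResult(table, coef_cov, correction, df_rule)


# --------------------------------------------------------------------------
# permutation null

def permutation_null(
    phenotypes: PhenotypeTable,
    genotypes: GenotypeMatrix,
    covariates: CovariateTable | np.ndarray | None,
    statistic: str,
    target_size: int,
    seed: int,
    pairs: list[tuple[str, str]] | None = None,
    correction: str = "none",
    marker_map: MarkerMap | None = None,
    df_rule: str = "n_minus_1",
) -> PermutationNull:
    """Pool absolute scan statistics over permutations into a null.

    Phenotype rows are permuted jointly across traits while genotypes and
    covariates stay fixed; each permutation contributes all of its scan
    statistics, and permutations are run until ``target_size`` values have
    been pooled.  ``statistic`` selects what is pooled: ``"main"`` pools
    single-locus |t|, ``"interaction"`` pools pairwise |t₁₂| (requires
    ``pairs``), ``"cape"`` pools standardized |m| influence statistics.
    """
    if target_size < 1:
        raise ValueError("target_size must be positive")
    if statistic in ("interaction", "cape") and not pairs:
        raise ValueError(f"statistic={statistic!r} requires a pair list")
    n = phenotypes.n_individuals
    if n < 4:
        warnings.warn("very few individuals: permutations largely overlap",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    base_cache = None
    if correction != "none" and statistic in ("interaction", "cape"):
        base_cache = _RotationCache(
            genotypes, marker_map, _cov_values(covariates)
        )
    pooled: list[np.ndarray] = []
    total = 0
    n_perm = 0
    while total < target_size:
        perm = rng.permutation(n)
        ph = PhenotypeTable(
            phenotypes.values[perm],
            list(phenotypes.individual_ids),
            list(phenotypes.trait_names),
        )
        cache = (
            base_cache.clone_for_new_phenotypes() if base_cache else None
        )
        if statistic == "main":
            res = marker_scan(
                ph, genotypes, covariates, correction, marker_map, df_rule
            )
            vals = np.abs(res.table["t"].to_numpy())
        elif statistic == "interaction":
            res = pair_scan(
                ph, genotypes, pairs, covariates, correction, marker_map,
                df_rule, rotation_cache=cache,
            )
            vals = np.abs(res.table["t12"].to_numpy())
        elif statistic == "cape":
            from .cape import cape_statistics_from_pair_scan

            res = pair_scan(
                ph, genotypes, pairs, covariates, correction, marker_map,
                df_rule, rotation_cache=cache,
            )
            vals = np.abs(cape_statistics_from_pair_scan(res))
        else:
            raise ValueError(f"unknown statistic kind {statistic!r}")
        vals = vals[np.isfinite(vals)]
        pooled.append(vals)
        total += vals.size
        n_perm += 1
        if n_perm > 100000:  # pragma: no cover - guard against empty scans
            raise RuntimeError("permutation null failed to accumulate values")
    values = np.concatenate(pooled)[:target_size]
    return PermutationNull(values, target_size, statistic, n_perm)
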