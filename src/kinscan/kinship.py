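"""Realized genomic relationship matrices: overall, LOCO and LTCO.

The kinship matrix is K = G·Gᵀ/n for the dosage matrix G.  For scans the
chromosome(s) carrying the tested marker(s) are left out of the calculation
(leave-one-chromosome-out for single-locus tests, leave-two-chromosomes-out
for pair tests) so that the random polygenic term does not absorb the signal
at the tested loci.

Dosages enter as-is, with no column centering or standardization, so K is
guaranteed positive semidefinite.  By default the denominator is the number
of markers actually used in each matrix; ``denominator="total"`` divides
every matrix by the full genotyped-marker count instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import GenotypeMatrix, MarkerMap

__all__ = ["KinshipMatrix", "overall_kinship", "loco_kinship", "ltco_kinship"]

#: eigenvalues in (-PSD_TOL, 0) are clipped to zero; more negative is fatal
PSD_TOL = 1e-8


@dataclass
class KinshipMatrix:
    """Symmetric n×n relatedness matrix with provenance of omitted chromosomes."""

    values: np.ndarray
    individual_ids: list[str]
    kind: str  # overall | loco | ltco
    omitted_chromosomes: tuple[str, ...] = ()
    n_markers_used: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match individual ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")
        if self.kind not in {"overall", "loco", "ltco"}:
            raise ValueError(f"unknown kinship kind {self.kind!r}")
        expected = {"overall": 0, "loco": 1, "ltco": 2}[self.kind]
        if len(self.omitted_chromosomes) > expected:
            raise ValueError(
                f"kind={self.kind} admits at most {expected} omitted chromosomes"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def normalized(self) -> "KinshipMatrix":
        """Scale to unit deviation variance: divide by the mean diagonal of
        the row/column-centered matrix, so that a polygenic effect drawn
        with this covariance has unit between-individual variance.  The
        mixed model's mixing parameter h is then on the
        h² = Vg/(Vg+Ve) scale.  (Dosage kinship is uncentered and carries a
        large shared component along the all-ones direction; that component
        is absorbed by the intercept and does not contribute to deviation
        variance, so the plain mean diagonal would be the wrong scale.)"""
        d = float(np.mean(np.diag(self.values)) - np.mean(self.values))
        if d <= 0:
            raise ValueError(
                "centered kinship diagonal mean must be positive to normalize"
            )
        return KinshipMatrix(
            self.values / d,
            list(self.individual_ids),
            self.kind,
            self.omitted_chromosomes,
            self.n_markers_used,
        )

    def subset_individuals(self, index: np.ndarray) -> "KinshipMatrix":
        index = np.asarray(index)
        return KinshipMatrix(
            self.values[np.ix_(index, index)],
            [self.individual_ids[i] for i in index],
            self.kind,
            self.omitted_chromosomes,
            self.n_markers_used,
        )


def _gram(G: np.ndarray, denom: int) -> np.ndarray:
    K = G @ G.T / denom
    return (K + K.T) / 2.0


def _resolve_denominator(n_used: int, n_total: int, denominator: str) -> int:
    if denominator == "used":
        return n_used
    if denominator == "total":
        return n_total
    raise ValueError("denominator must be 'used' or 'total'")


def overall_kinship(genotypes: GenotypeMatrix) -> KinshipMatrix:
    """K = G·Gᵀ/n over all genotyped markers."""
    if genotypes.n_markers == 0:
        raise ValueError("cannot compute kinship with zero markers")
    if genotypes.has_missing:
        raise ValueError("impute missing genotypes before kinship calculation")
    K = _gram(genotypes.values, genotypes.n_markers)
    return KinshipMatrix(
        K, list(genotypes.individual_ids), "overall",
        n_markers_used=genotypes.n_markers,
    )


def _reduced(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    omit: tuple[str, ...],
    kind: str,
    denominator: str,
) -> KinshipMatrix:
    chrom = marker_map.chromosome_of()
    known = set(marker_map.marker_ids)
    unknown = [m for m in genotypes.marker_ids if m not in known]
    if unknown:
        raise ValueError(f"markers absent from map: {unknown[:10]}")
    omit_set = set(omit)
    missing_chrom = omit_set - set(marker_map.chromosomes)
    if missing_chrom:
        raise ValueError(f"chromosome(s) not in map: {sorted(missing_chrom)}")
    keep = np.array(
        [chrom[m] not in omit_set for m in genotypes.marker_ids], dtype=bool
    )
    n_used = int(keep.sum())
    if n_used == 0:
        raise ValueError(
            f"omitting chromosome(s) {sorted(omit_set)} leaves no markers"
        )
    if genotypes.has_missing:
        raise ValueError("impute missing genotypes before kinship calculation")
    denom = _resolve_denominator(n_used, genotypes.n_markers, denominator)
    K = _gram(genotypes.values[:, keep], denom)
    return KinshipMatrix(
        K, list(genotypes.individual_ids), kind,
        omitted_chromosomes=omit, n_markers_used=n_used,
    )


def loco_kinship(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    chromosome: str,
    denominator: str = "used",
) -> KinshipMatrix:
    """Leave-one-chromosome-out kinship: K_C from all markers off chromosome C."""
    return _reduced(genotypes, marker_map, (str(chromosome),), "loco", denominator)


def ltco_kinship(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    chrom_a: str,
    chrom_b: str,
    denominator: str = "used",
) -> KinshipMatrix:
    """Leave-two-chromosomes-out kinship for a pair test.

    When both tested markers sit on the same chromosome only that one
    chromosome is left out, and the result is bit-identical to
    :func:`loco_kinship` on it.
    """
    chrom_a, chrom_b = str(chrom_a), str(chrom_b)
    if chrom_a == chrom_b:
        K = loco_kinship(genotypes, marker_map, chrom_a, denominator)
        return KinshipMatrix(
            K.values, K.individual_ids, "ltco", (chrom_a,), K.n_markers_used
        )
    return _reduced(
        genotypes, marker_map, (chrom_a, chrom_b), "ltco", denominator
    )
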