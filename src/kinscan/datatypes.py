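"""Shared containers for genotype, map, phenotype and covariate data.

All containers are thin, validated wrappers around numpy arrays / pandas
objects with individuals as rows.  Genotypes are stored as alternate-allele
dosages in [0, 1]: 0 = homozygous reference, 0.5 = heterozygous,
1 = homozygous alternate.  Multi-founder populations are encoded as
alternate-allele dosage at biallelic markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "MarkerMap",
    "PhenotypeTable",
    "CovariateTable",
]


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicated {what}: {dupes[:10]}")


@dataclass
class GenotypeMatrix:
    """Individuals × markers dosage matrix.

    ``values[i, j]`` is the expected alternate-allele fraction of individual
    ``i`` at marker ``j``.  NaN marks a missing call; every analysis entry
    point requires missing calls to be imputed first
    (:func:`kinscan.io.impute_missing_genotypes`).
    """

    values: np.ndarray
    individual_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (individuals × markers)")
        self.individual_ids = [str(x) for x in self.individual_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        if self.values.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError(
                f"genotype shape {self.values.shape} does not match "
                f"{len(self.individual_ids)} ids × {len(self.marker_ids)} markers"
            )
        _check_unique(self.individual_ids, "individual ids")
        _check_unique(self.marker_ids, "marker ids")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("dosages must lie in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.values[index],
            [self.individual_ids[i] for i in index],
            list(self.marker_ids),
        )

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.values[:, index],
            list(self.individual_ids),
            [self.marker_ids[i] for i in index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.marker_ids
        )


@dataclass
class MarkerMap:
    """Genetic map: marker → (chromosome, position in cM).

    Positions must be nondecreasing within each chromosome; chromosome labels
    are arbitrary strings (autosome names and "X" both allowed).
    """

    table: pd.DataFrame  # columns: marker, chromosome, position_cM

    def __post_init__(self) -> None:
        required = ["marker", "chromosome", "position_cM"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"marker map missing columns {missing}")
        t = self.table[required].copy()
        t["marker"] = t["marker"].astype(str)
        t["chromosome"] = t["chromosome"].astype(str)
        t["position_cM"] = t["position_cM"].astype(float)
        _check_unique(t["marker"].tolist(), "marker ids")
        if (t["position_cM"] < 0).any():
            raise ValueError("map positions must be nonnegative")
        for chrom, grp in t.groupby("chromosome", sort=False):
            if not grp["position_cM"].is_monotonic_increasing:
                raise ValueError(
                    f"positions on chromosome {chrom} are not nondecreasing"
                )
        self.table = t.reset_index(drop=True)

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker"].tolist()

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chromosome"]))

    def chromosome_of(self) -> pd.Series:
        return self.table.set_index("marker")["chromosome"]

    def markers_on(self, chromosome: str) -> list[str]:
        t = self.table
        return t.loc[t["chromosome"] == str(chromosome), "marker"].tolist()

    def subset(self, marker_ids: list[str]) -> "MarkerMap":
        keep = self.table[self.table["marker"].isin(set(marker_ids))]
        return MarkerMap(keep.reset_index(drop=True))


@dataclass
class PhenotypeTable:
    """Individuals × traits matrix of continuous trait values."""

    values: np.ndarray
    individual_ids: list[str]
    trait_names: list[str]
    has_missing: bool = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        self.individual_ids = [str(x) for x in self.individual_ids]
        self.trait_names = [str(x) for x in self.trait_names]
        if self.values.shape != (len(self.individual_ids), len(self.trait_names)):
            raise ValueError("phenotype shape does not match ids × trait names")
        _check_unique(self.individual_ids, "individual ids")
        _check_unique(self.trait_names, "trait names")
        self.has_missing = bool(np.isnan(self.values).any())

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def trait(self, name: str) -> np.ndarray:
        return self.values[:, self.trait_names.index(name)]

    def subset_individuals(self, index: np.ndarray) -> "PhenotypeTable":
        index = np.asarray(index)
        return PhenotypeTable(
            self.values[index],
            [self.individual_ids[i] for i in index],
            list(self.trait_names),
        )

    def select_traits(self, names: list[str]) -> "PhenotypeTable":
        idx = [self.trait_names.index(n) for n in names]
        return PhenotypeTable(self.values[:, idx], list(self.individual_ids), names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.trait_names
        )


@dataclass
class CovariateTable:
    """Individuals × covariates matrix (e.g. sex, cross direction "pgm").

    Covariates may not contain missing values, and together with an intercept
    must have full column rank — the scan design matrices prepend a constant.
    """

    values: np.ndarray
    individual_ids: list[str]
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        self.individual_ids = [str(x) for x in self.individual_ids]
        self.names = [str(x) for x in self.names]
        if self.values.shape != (len(self.individual_ids), len(self.names)):
            raise ValueError("covariate shape does not match ids × names")
        _check_unique(self.individual_ids, "individual ids")
        _check_unique(self.names, "covariate names")
        if np.isnan(self.values).any():
            raise ValueError("covariates may not contain missing values")
        n = self.values.shape[0]
        design = np.column_stack([np.ones(n), self.values])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("covariates are collinear with the intercept")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    def subset_individuals(self, index: np.ndarray) -> "CovariateTable":
        index = np.asarray(index)
        return CovariateTable(
            self.values[index],
            [self.individual_ids[i] for i in index],
            list(self.names),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individual_ids, columns=self.names)
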