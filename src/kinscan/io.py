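"""Read, write and align delimited population bundles.

A bundle is a set of comma-delimited text files sharing an individual-id
first column: a genotype dosage matrix, a marker map
(``marker,chromosome,position_cM``), a phenotype table and an optional
covariate table.  Reading aligns all tables on the intersection of
individual ids, preserving the genotype file's row order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CovariateTable, GenotypeMatrix, MarkerMap, PhenotypeTable

log = logging.getLogger(__name__)

__all__ = [
    "PopulationBundle",
    "read_population_bundle",
    "write_population_bundle",
    "impute_missing_genotypes",
]


@dataclass
class PopulationBundle:
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    phenotypes: PhenotypeTable
    covariates: CovariateTable | None = None
    dropped_ids: list[str] | None = None

    def subset_individuals(self, index: np.ndarray) -> "PopulationBundle":
        return PopulationBundle(
            self.genotypes.subset_individuals(index),
            self.marker_map,
            self.phenotypes.subset_individuals(index),
            self.covariates.subset_individuals(index) if self.covariates else None,
        )


def _read_matrix_csv(path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{what} file {path}: duplicated individual ids {dupes[:10]}")
    bad = df.apply(pd.to_numeric, errors="coerce")
    nonnum = bad.isna() & df.notna()
    if nonnum.any().any():
        r, c = np.argwhere(nonnum.values)[0]
        raise ValueError(
            f"{what} file {path}: non-numeric value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return bad.astype(float)


def read_population_bundle(
    genotype_path,
    map_path,
    phenotype_path,
    covariate_path=None,
) -> PopulationBundle:
    """Read and align a population bundle from delimited text files.

    Tables are aligned on the intersection of individual ids, in the order
    they appear in the genotype file; ids missing from any table are dropped
    with a warning listing them.

    Raises
    ------
    ValueError
        On an empty id intersection, duplicated ids, or non-numeric dosages.
    """
    geno_df = _read_matrix_csv(genotype_path, "genotype")
    pheno_df = _read_matrix_csv(phenotype_path, "phenotype")
    cov_df = _read_matrix_csv(covariate_path, "covariate") if covariate_path else None

    mm = MarkerMap(pd.read_csv(map_path))
    if list(geno_df.columns) != mm.marker_ids:
        # accept maps covering a superset, but the genotype columns define order
        missing = set(geno_df.columns) - set(mm.marker_ids)
        if missing:
            raise ValueError(f"markers absent from map: {sorted(missing)[:10]}")
        mm = MarkerMap(
            mm.table.set_index("marker").loc[list(geno_df.columns)].reset_index()
        )

    shared = set(geno_df.index.astype(str)) & set(pheno_df.index.astype(str))
    if cov_df is not None:
        shared &= set(cov_df.index.astype(str))
    keep = [i for i in geno_df.index.astype(str) if i in shared]
    if not keep:
        raise ValueError("no individual ids shared across bundle files")
    dropped = sorted(
        (set(geno_df.index.astype(str)) | set(pheno_df.index.astype(str)))
        - set(keep)
    )
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} individuals absent from some bundle file: "
            f"{dropped[:20]}",
            stacklevel=2,
        )

    geno_df.index = geno_df.index.astype(str)
    pheno_df.index = pheno_df.index.astype(str)
    gm = GenotypeMatrix(
        geno_df.loc[keep].values, keep, [str(c) for c in geno_df.columns]
    )
    pt = PhenotypeTable(
        pheno_df.loc[keep].values, keep, [str(c) for c in pheno_df.columns]
    )
    ct = None
    if cov_df is not None:
        cov_df.index = cov_df.index.astype(str)
        ct = CovariateTable(
            cov_df.loc[keep].values, keep, [str(c) for c in cov_df.columns]
        )
    return PopulationBundle(gm, mm, pt, ct, dropped_ids=dropped)


def write_population_bundle(bundle: PopulationBundle, prefix) -> dict[str, Path]:
    """Write a bundle as delimited text next to ``prefix``; returns the paths.

    Values are written with 12 significant digits so a write → read round
    trip is lossless at that precision.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": prefix.with_name(prefix.name + "_genotypes.csv"),
        "map": prefix.with_name(prefix.name + "_map.csv"),
        "phenotypes": prefix.with_name(prefix.name + "_phenotypes.csv"),
    }
    fmt = "%.12g"
    bundle.genotypes.to_frame().to_csv(paths["genotypes"], float_format=fmt)
    bundle.marker_map.table.to_csv(paths["map"], index=False, float_format=fmt)
    bundle.phenotypes.to_frame().to_csv(paths["phenotypes"], float_format=fmt)
    if bundle.covariates is not None:
        paths["covariates"] = prefix.with_name(prefix.name + "_covariates.csv")
        bundle.covariates.to_frame().to_csv(paths["covariates"], float_format=fmt)
    return paths


def impute_missing_genotypes(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by their marker's observed mean.

    Markers with no observed calls at all are dropped with a warning.
    Returns the input unchanged when nothing is missing.
    """
    if not genotypes.has_missing:
        return genotypes
    values = genotypes.values.copy()
    observed = np.isfinite(values)
    n_obs = observed.sum(axis=0)
    all_missing = n_obs == 0
    if all_missing.any():
        dropped = [m for m, bad in zip(genotypes.marker_ids, all_missing) if bad]
        warnings.warn(
            f"dropping {len(dropped)} all-missing markers: {dropped[:20]}",
            stacklevel=2,
        )
        keep = np.flatnonzero(~all_missing)
        values = values[:, keep]
        observed = observed[:, keep]
        n_obs = n_obs[keep]
        marker_ids = [genotypes.marker_ids[i] for i in keep]
    else:
        marker_ids = list(genotypes.marker_ids)
    col_mean = np.where(observed, values, 0.0).sum(axis=0) / n_obs
    values = np.where(observed, values, col_mean[None, :])
    return GenotypeMatrix(values, list(genotypes.individual_ids), marker_ids)
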