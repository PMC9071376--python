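"""CSV readers and writers for graft populations.

Long format (``graft_id, replicate, feature, value``) is the canonical
interchange; wide format (one row per graft x replicate, one column per
feature) is accepted on read. All files are RFC-4180 CSV, UTF-8, '.'
decimal separator. Empty cells in wide format are missing values and are
dropped on conversion to long format.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import (DEFAULT_REFERENCE_ID, DEFAULT_TRAIT_NAMES,
                        GraftPopulation)

log = logging.getLogger(__name__)

LONG_COLUMNS = ("graft_id", "replicate", "feature", "value")


def _read_feature_table(path: str, what: str) -> pd.DataFrame:
    """Read a long- or wide-format feature CSV into long format."""
    df = pd.read_csv(path, dtype={"graft_id": str},
                     float_precision="round_trip")
    if "graft_id" not in df.columns:
        raise ValueError(f"{what} file {path!r} lacks a 'graft_id' column")
    if "replicate" not in df.columns:
        raise ValueError(f"{what} file {path!r} lacks a 'replicate' column")
    if set(LONG_COLUMNS).issubset(df.columns):
        long = df.loc[:, list(LONG_COLUMNS)].copy()
    else:
        feature_cols = [c for c in df.columns
                        if c not in ("graft_id", "replicate")]
        if not feature_cols:
            raise ValueError(f"{what} file {path!r} has no feature columns")
        long = df.melt(id_vars=["graft_id", "replicate"],
                       value_vars=feature_cols,
                       var_name="feature", value_name="value")
        long = long.dropna(subset=["value"])
    numeric = pd.to_numeric(long["value"], errors="coerce")
    bad = long.index[numeric.isna() & long["value"].notna()]
    if len(bad):
        raise ValueError(
            f"non-numeric value in {what} file {path!r} at row "
            f"{int(bad[0]) + 2} (1-based, counting the header)")
    long = long.assign(value=numeric).dropna(subset=["value"])
    long["replicate"] = long["replicate"].astype(str)
    return long.reset_index(drop=True)


def read_population(
    trait_csv_path: str,
    metabolite_csv_path: str,
    metadata_csv_path: str,
    *,
    reference_id: str = DEFAULT_REFERENCE_ID,
    trait_names: Iterable[str] | None = None,
    metabolite_names: Iterable[str] | None = None,
    mda_is_fold_change: bool = True,
) -> GraftPopulation:
    """Read and validate a graft population from three CSV tables.

    ``trait_names`` defaults to the canonical 14-feature panel;
    ``metabolite_names`` defaults to the features present in the metabolite
    file, in order of appearance. Features are matched case-sensitively
    against the registries.
    """
    traits = _read_feature_table(trait_csv_path, "trait")
    metabs = _read_feature_table(metabolite_csv_path, "metabolite")
    meta = pd.read_csv(metadata_csv_path, dtype=str)
    for col in ("graft_id", "accession", "origin"):
        if col not in meta.columns:
            raise ValueError(
                f"metadata file {metadata_csv_path!r} lacks column {col!r}")
    meta = meta.set_index("graft_id")[["accession", "origin"]]

    if trait_names is None:
        trait_names = list(DEFAULT_TRAIT_NAMES)
    if metabolite_names is None:
        metabolite_names = list(dict.fromkeys(metabs["feature"]))

    measurements = pd.concat([traits, metabs], ignore_index=True)
    pop = GraftPopulation(
        measurements=measurements,
        meta=meta,
        trait_names=list(trait_names),
        metabolite_names=list(metabolite_names),
        reference_id=reference_id,
        mda_is_fold_change=mda_is_fold_change,
    )
    reps = pop.replicate_counts()
    log.info("read %d grafts (%d-%d replicates), %d traits, %d metabolites",
             pop.n_grafts, reps.min(), reps.max(),
             len(pop.trait_names), len(pop.metabolite_names))
    return pop


def write_population(pop: GraftPopulation, out_dir: str) -> dict[str, str]:
    """Write a population to ``traits.csv``, ``metabolites.csv`` and
    ``metadata.csv`` under ``out_dir`` (long format, full float precision).

    Returns the mapping of table name to file path.
    """
    os.makedirs(out_dir, exist_ok=True)
    trait_set = set(pop.trait_names)
    is_trait = pop.measurements["feature"].isin(trait_set)
    paths = {
        "traits": os.path.join(out_dir, "traits.csv"),
        "metabolites": os.path.join(out_dir, "metabolites.csv"),
        "metadata": os.path.join(out_dir, "metadata.csv"),
    }
    pop.measurements[is_trait].to_csv(paths["traits"], index=False)
    pop.measurements[~is_trait].to_csv(paths["metabolites"], index=False)
    pop.meta.reset_index().to_csv(paths["metadata"], index=False)
    return paths


def write_matrix(df: pd.DataFrame, path: str, index_label: str = "graft_id") -> None:
    """Write a grafts x features (or similar) matrix as CSV."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, index_label=index_label)
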