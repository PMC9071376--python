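"""Domain types for graft-population phenomics.

A *graft population* is a collection of composite plants sharing one scion
genotype, each grafted onto a different rootstock, measured at replicate
level for a set of morphological traits and relative metabolite abundances.
One member — the self-graft, where scion and rootstock are the same
genotype — acts as the reference against which all fold-changes are taken.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

ORIGIN_LEVELS = ("SLL", "SLC", "SP", "Wild", "Other")

#: The eight primary morphological measurements (MDA is the oxidative-stress
#: marker malondialdehyde; all others are classical yield/architecture traits).
PRIMARY_TRAITS = ("PH", "BN", "FN", "FFW", "PFW", "FDW", "PDW", "MDA")

#: Traits derived arithmetically from the primaries.
DERIVED_TRAITS = ("TFW", "TDW", "HI", "FFW_over_TFW", "MIL", "MFW")

#: Canonical 14-feature morphology panel (13 growth/yield traits + MDA).
DEFAULT_TRAIT_NAMES = (
    "PH", "BN", "FN", "MIL",
    "FFW", "MFW", "PFW", "TFW", "FFW_over_TFW",
    "FDW", "PDW", "TDW", "HI",
    "MDA",
)

DEFAULT_REFERENCE_ID = "SG-M82"


def derive_traits(raw: Mapping[str, float]) -> dict[str, float]:
    """Fill the six derived traits from the eight primary measurements.

    TFW = FFW + PFW, TDW = FDW + PDW, HI = FDW/TDW,
    FFW_over_TFW = FFW/TFW, MIL = PH/BN, MFW = FFW/FN.

    Divisions by zero yield NaN (recorded as missing), never infinity.
    Missing (NaN) primaries propagate to the derived traits that use them.

    Raises
    ------
    ValueError
        If a primary measurement is absent or negative.
    """
    missing = [t for t in PRIMARY_TRAITS if t not in raw]
    if missing:
        raise ValueError(f"primary trait(s) missing: {missing}")
    vals = {t: float(raw[t]) for t in PRIMARY_TRAITS}
    bad = [t for t, v in vals.items() if not math.isnan(v) and v < 0]
    if bad:
        raise ValueError(f"negative primary trait value(s): {bad}")

    def _ratio(num: float, den: float) -> float:
        if math.isnan(num) or math.isnan(den) or den == 0.0:
            return float("nan")
        return num / den

    out = dict(vals)
    out["TFW"] = vals["FFW"] + vals["PFW"]
    out["TDW"] = vals["FDW"] + vals["PDW"]
    out["HI"] = _ratio(vals["FDW"], out["TDW"])
    out["FFW_over_TFW"] = _ratio(vals["FFW"], out["TFW"])
    out["MIL"] = _ratio(vals["PH"], vals["BN"])
    out["MFW"] = _ratio(vals["FFW"], vals["FN"])
    return out


@dataclass
class AnalysisConfig:
    """Tunable constants of the analysis pipeline.

    Defaults encode the study conventions: a fold-change CV below 0.3 marks
    a feature as stable; network edges require q < 0.05 and |r| > 0.3;
    prediction uses 10x10 repeated outer cross-validation with an inner
    10-fold lambda search over a 100-point glmnet-style grid, 100
    permutations per prediction, and a selection-frequency cutoff of 95
    (out of 100 fits).
    """

    cv_low_variability_threshold: float = 0.3
    edge_r_threshold: float = 0.3
    edge_q_threshold: float = 0.05
    fdr_method: str = "BH"  # or "Holm"
    outer_folds: int = 10
    outer_repeats: int = 10
    inner_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    permutations_per_prediction: int = 100
    selection_frequency_threshold: int = 95
    lambda_rule: str = "min"  # or "1se"
    group_test: str = "t"  # or "ranksum", for origin-group comparisons
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("outer_folds", "inner_folds", "n_lambda",
                     "permutations_per_prediction"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.outer_repeats < 1:
            raise ValueError("outer_repeats must be >= 1")
        for name in ("cv_low_variability_threshold", "edge_r_threshold",
                     "edge_q_threshold", "lambda_min_ratio"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.fdr_method not in ("BH", "Holm"):
            raise ValueError("fdr_method must be 'BH' or 'Holm'")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")
        if self.group_test not in ("t", "ranksum"):
            raise ValueError("group_test must be 't' or 'ranksum'")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**mapping)  # type: ignore[arg-type]

    @classmethod
    def from_file(cls, path: str) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            if str(path).endswith(".json"):
                data = json.load(fh)
            else:
                data = yaml.safe_load(fh)
        return cls.from_mapping(data or {})

    def to_dict(self) -> dict[str, object]:
        return dataclasses.asdict(self)

    def to_file(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if str(path).endswith(".json"):
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class GraftPopulation:
    """Replicate-level trait and metabolite measurements for a graft panel.

    Parameters
    ----------
    measurements:
        Long-format table with columns ``graft_id, replicate, feature,
        value``; one row per measured value. Missing values are simply
        absent rows.
    meta:
        Indexed by ``graft_id`` with columns ``accession`` and ``origin``
        (one of :data:`ORIGIN_LEVELS`).
    trait_names, metabolite_names:
        Ordered feature registries; measurement features must come from
        their union.
    reference_id:
        The self-graft control all fold-changes are taken against.
    mda_is_fold_change:
        When True, MDA values are already fold-changes over the reference
        (batch-wise normalization at measurement time) and are passed
        through the fold-change computation unchanged.
    """

    measurements: pd.DataFrame
    meta: pd.DataFrame
    trait_names: list[str] = field(default_factory=lambda: list(DEFAULT_TRAIT_NAMES))
    metabolite_names: list[str] = field(default_factory=list)
    reference_id: str = DEFAULT_REFERENCE_ID
    mda_is_fold_change: bool = True

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        required = {"graft_id", "replicate", "feature", "value"}
        if not required.issubset(self.measurements.columns):
            raise ValueError(
                f"measurements must have columns {sorted(required)}")
        if not self.meta.index.is_unique:
            dup = self.meta.index[self.meta.index.duplicated()].tolist()
            raise ValueError(f"duplicate graft_id in metadata: {dup}")
        if self.reference_id not in self.meta.index:
            raise ValueError(
                f"reference graft {self.reference_id!r} not in population")
        known = set(self.trait_names) | set(self.metabolite_names)
        seen = set(self.measurements["feature"].unique())
        unknown = sorted(seen - known)
        if unknown:
            raise ValueError(f"unknown feature name(s): {unknown}")
        values = self.measurements["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite measurement values present")
        if np.any(values < 0):
            raise ValueError("negative raw measurement values present")
        reps = self.replicate_counts()
        few = reps[reps < 2]
        if len(few):
            raise ValueError(
                f"graft(s) with fewer than 2 replicates: {few.index.tolist()}")
        missing_meta = sorted(
            set(self.measurements["graft_id"].unique()) - set(self.meta.index))
        if missing_meta:
            raise ValueError(f"graft(s) without metadata: {missing_meta}")
        bad_origin = sorted(set(self.meta["origin"]) - set(ORIGIN_LEVELS))
        if bad_origin:
            raise ValueError(f"unknown origin group(s): {bad_origin}")

    # -- accessors --------------------------------------------------------

    @property
    def graft_ids(self) -> list[str]:
        return list(self.meta.index)

    @property
    def n_grafts(self) -> int:
        return len(self.meta)

    def feature_kind(self, feature: str) -> str:
        if feature in self.trait_names:
            return "morphology"
        if feature in self.metabolite_names:
            return "metabolite"
        raise KeyError(feature)

    def replicate_counts(self) -> pd.Series:
        """Number of distinct replicates observed per graft."""
        return (self.measurements.groupby("graft_id", sort=False)["replicate"]
                .nunique())

    def graft_means(self, features: Iterable[str] | None = None) -> pd.DataFrame:
        """Mean over biological replicates, grafts x features.

        A graft missing a feature in all replicates gets NaN there.
        """
        df = self.measurements
        if features is not None:
            df = df[df["feature"].isin(set(features))]
        wide = (df.pivot_table(index="graft_id", columns="feature",
                               values="value", aggfunc="mean"))
        order = [f for f in (self.trait_names + self.metabolite_names)
                 if f in wide.columns]
        return wide.reindex(index=self.graft_ids, columns=order)

    def origins(self) -> pd.Series:
        return self.meta["origin"]
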