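"""Fold-change profiling against the self-graft reference.

The fold-change of graft g for feature f is the mean over g's biological
replicates divided by the mean over the reference graft's replicates —
means are taken before the ratio, not ratios of paired replicates. All
downstream statistics (CV, outlier calls, dispersion, correlations,
prediction) operate on this matrix or its log2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import GraftPopulation

log = logging.getLogger(__name__)


@dataclass
class ResponseProfile:
    """Per-graft, per-feature fold-changes vs the reference graft."""

    fc: pd.DataFrame          # grafts x features, > 0 where defined
    feature_kind: dict[str, str]   # feature -> "morphology" | "metabolite"
    reference_id: str

    @property
    def log2fc(self) -> pd.DataFrame:
        return np.log2(self.fc)

    def features(self, kind: str | None = None) -> list[str]:
        if kind is None:
            return list(self.fc.columns)
        return [f for f in self.fc.columns if self.feature_kind[f] == kind]


@dataclass
class CVProfile:
    """Coefficient of variation of the fold-change across the population."""

    cv: pd.Series       # feature -> sd/mean of the FC column
    n_used: pd.Series   # feature -> grafts contributing

    def stable_features(self, threshold: float = 0.3) -> list[str]:
        """Features whose FC-scale CV falls below the stability threshold."""
        return list(self.cv.index[self.cv < threshold])


def compute_response(pop: GraftPopulation, *,
                     include_reference: bool = True) -> ResponseProfile:
    """Fold-change matrix of all grafts vs the reference graft.

    Features whose reference mean is zero or missing are dropped with a
    warning. When the population flags MDA as already fold-change scale,
    the MDA column is the replicate mean itself, not re-normalized.
    The reference graft's own row is 1 by construction and is kept unless
    ``include_reference`` is False.
    """
    means = pop.graft_means()
    ref = means.loc[pop.reference_id]
    bad = ref.index[(ref.isna()) | (ref == 0.0)].tolist()
    if pop.mda_is_fold_change and "MDA" in bad:
        bad.remove("MDA")
    if bad:
        log.warning("dropping feature(s) with zero/missing reference mean: %s",
                    bad)
    keep = [f for f in means.columns if f not in bad]
    fc = means[keep] / ref[keep]
    if pop.mda_is_fold_change and "MDA" in fc.columns:
        fc["MDA"] = means["MDA"]
    if not include_reference:
        fc = fc.drop(index=pop.reference_id)
    kind = {f: pop.feature_kind(f) for f in fc.columns}
    return ResponseProfile(fc=fc, feature_kind=kind,
                           reference_id=pop.reference_id)


def compute_cv(profile: ResponseProfile, *, min_grafts: int = 3,
               scale: str = "fc") -> CVProfile:
    """Population CV (sample sd / mean, n-1 denominator) per feature.

    Computed on the fold-change scale by default; ``scale="log2"`` uses the
    log2 fold-changes instead (for comparison only). Features observed in
    fewer than ``min_grafts`` grafts get a missing CV.
    """
    mat = profile.fc if scale == "fc" else profile.log2fc
    n = mat.notna().sum()
    mean = mat.mean()
    sd = mat.std(ddof=1)
    cv = sd / mean
    cv[n < min_grafts] = np.nan
    return CVProfile(cv=cv, n_used=n)


def tukey_fences(values: np.ndarray, k: float = 1.5) -> tuple[float, float]:
    """Boxplot whisker fences: Q1 - k*IQR, Q3 + k*IQR (type-7 quartiles)."""
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def flag_outliers(profile: ResponseProfile, feature: str, *,
                  whisker: float = 1.5) -> set[str]:
    """Grafts outside the boxplot whiskers of a feature's log2FC column."""
    col = profile.log2fc[feature].dropna()
    if len(col) < 5:
        raise ValueError(
            f"need >= 5 defined values for {feature}, have {len(col)}")
    lo, hi = tukey_fences(col.to_numpy(), whisker)
    mask = (col < lo) | (col > hi)
    return set(col.index[mask])


def outlier_signature(profile: ResponseProfile, min_features: int = 6, *,
                      whisker: float = 1.5
                      ) -> tuple[dict[str, set[str]], set[str]]:
    """Grafts that are outliers in at least ``min_features`` metabolites.

    Returns (graft -> set of metabolites it is an outlier for, restricted
    to grafts reaching the threshold; intersection of those sets across
    the reported grafts). The intersection is the candidate shared
    metabolic signature.
    """
    per_graft: dict[str, set[str]] = {}
    for met in profile.features("metabolite"):
        for g in flag_outliers(profile, met, whisker=whisker):
            per_graft.setdefault(g, set()).add(met)
    reported = {g: mets for g, mets in per_graft.items()
                if len(mets) >= min_features}
    if reported:
        signature = set.intersection(*reported.values())
    else:
        signature = set()
    return reported, signature


def improvement_counts(profile: ResponseProfile,
                       scored_features: list[str] | None = None,
                       *, lower_is_better: tuple[str, ...] = ("MDA",)
                       ) -> pd.Series:
    """Per graft, the number of features improved over the reference.

    Improvement is a strict FC > 1 for growth/yield traits and a strict
    FC < 1 for features where lower is better (MDA). Ties (FC exactly 1)
    and missing values count as not improved; missing values are logged.
    """
    if scored_features is None:
        scored_features = profile.features("morphology")
    fc = profile.fc[scored_features]
    n_missing = int(fc.isna().to_numpy().sum())
    if n_missing:
        log.warning("%d missing fold-changes counted as not improved",
                    n_missing)
    better = pd.DataFrame(index=fc.index, columns=fc.columns, dtype=bool)
    for f in scored_features:
        if f in lower_is_better:
            better[f] = fc[f] < 1.0
        else:
            better[f] = fc[f] > 1.0
    return better.fillna(False).sum(axis=1).astype(int)


def improvement_histogram(counts: pd.Series, n_features: int) -> pd.Series:
    """Number of grafts per improvement count, binned 0..n_features."""
    bins = counts.value_counts().reindex(range(n_features + 1), fill_value=0)
    bins.index.name = "n_improved"
    return bins.rename("n_grafts")


def compare_origin_groups(values: pd.Series, origins: pd.Series, *,
                          test: str = "t", min_group: int = 3
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-origin summary and BH-adjusted pairwise two-sample tests.

    ``values`` is any per-graft statistic (e.g. a metabolite's log2FC or a
    graft-level CV); groups with fewer than ``min_group`` members are
    excluded with a warning. ``test`` is "t" (Welch) or "ranksum"
    (Mann-Whitney U). Thin convenience wrapper around scipy/statsmodels.
    """
    df = pd.DataFrame({"value": values, "origin": origins}).dropna()
    sizes = df.groupby("origin")["value"].size()
    small = sizes.index[sizes < min_group].tolist()
    if small:
        log.warning("excluding origin group(s) with < %d members: %s",
                    min_group, small)
        df = df[~df["origin"].isin(small)]
    summary = (df.groupby("origin")["value"]
               .agg(n="size", mean="mean", median="median", sd="std"))
    groups = list(summary.index)
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            xa = df.loc[df["origin"] == a, "value"]
            xb = df.loc[df["origin"] == b, "value"]
            if test == "t":
                stat, p = stats.ttest_ind(xa, xb, equal_var=False)
            elif test == "ranksum":
                stat, p = stats.mannwhitneyu(xa, xb,
                                             alternative="two-sided")
            else:
                raise ValueError("test must be 't' or 'ranksum'")
            rows.append({"group_a": a, "group_b": b,
                         "mean_diff": xa.mean() - xb.mean(),
                         "statistic": float(stat), "p": float(p)})
    pairwise = pd.DataFrame(
        rows, columns=["group_a", "group_b", "mean_diff", "statistic", "p"])
    if len(pairwise):
        pairwise["p_adj"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    else:
        pairwise["p_adj"] = pd.Series(dtype=float)
    return summary, pairwise
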