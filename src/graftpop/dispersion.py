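"""Per-graft dispersion around the reference and its cluster structure.

The dispersion statistic is a variance taken about the *control* value
rather than about the graft's own mean: since the reference graft's log2
fold-change is identically zero, the statistic is

    Var(X) = (1/(n-1)) * sum_i (log2FC_i)^2

over a feature set of size n. It differs from the sample variance
whenever the graft's mean log2FC is nonzero — e.g. log2FC = (1, 1, 1)
gives 1.5 here but sample variance 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .response import ResponseProfile

log = logging.getLogger(__name__)

CLUSTER_LABELS = ("A", "B", "C")


def control_variance(log2fc: np.ndarray) -> float:
    """Dispersion of a log2FC vector about the control (zero).

    Requires at least 2 defined values; returns NaN (with a warning)
    otherwise.
    """
    x = np.asarray(log2fc, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        log.warning("control_variance needs >= 2 values, have %d", n)
        return float("nan")
    return float(np.sum(x * x) / (n - 1))


def compute_dispersion(profile: ResponseProfile, graft_id: str,
                       feature_set: list[str]) -> float:
    """Dispersion of one graft over a feature set (see module docstring)."""
    return control_variance(profile.log2fc.loc[graft_id, feature_set]
                            .to_numpy())


def dispersion_table(profile: ResponseProfile,
                     morph_features: list[str] | None = None,
                     metab_features: list[str] | None = None) -> pd.DataFrame:
    """Per-graft dispersion over the morphology and metabolite panels.

    Returns a frame indexed by graft with columns var_morph, var_metab,
    n_morph, n_metab.
    """
    if morph_features is None:
        morph_features = profile.features("morphology")
    if metab_features is None:
        metab_features = profile.features("metabolite")
    l2 = profile.log2fc
    rows = {}
    for g in l2.index:
        xm = l2.loc[g, morph_features].to_numpy(dtype=float)
        xk = l2.loc[g, metab_features].to_numpy(dtype=float)
        rows[g] = {
            "var_morph": control_variance(xm),
            "var_metab": control_variance(xk),
            "n_morph": int(np.isfinite(xm).sum()),
            "n_metab": int(np.isfinite(xk).sum()),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "graft_id"
    return out


def classify_dispersion(records: pd.DataFrame, *, method: str = "kmeans",
                        k: int = 3, seed: int = 0,
                        thresholds: dict[str, float] | None = None
                        ) -> pd.DataFrame:
    """Partition grafts in (var_morph, var_metab) space.

    Default: seeded k-means with k=3 on standardized coordinates. Labels
    are assigned from centroid geometry so they are comparable across
    runs: B = highest var_morph centroid; among the rest A = highest
    var_metab (phenotype buffered by metabolic adjustment) and C = both
    low (homogeneous response); further centroids are labeled "other".
    Alternatively ``method="thresholds"`` splits on user rectangles
    ``{"var_morph": x, "var_metab": y}``.
    """
    df = records.dropna(subset=["var_morph", "var_metab"]).copy()
    if method == "thresholds":
        if thresholds is None:
            raise ValueError("thresholds required for method='thresholds'")
        tm, tk = thresholds["var_morph"], thresholds["var_metab"]
        hi_m = df["var_morph"] >= tm
        hi_k = df["var_metab"] >= tk
        label = np.where(hi_m, "B", np.where(hi_k, "A", "C"))
        df["cluster_label"] = label
        return df
    if method != "kmeans":
        raise ValueError("method must be 'kmeans' or 'thresholds'")
    if k > len(df):
        raise ValueError(f"k={k} exceeds the {len(df)} labelable grafts")
    coords = df[["var_morph", "var_metab"]].to_numpy(dtype=float)
    sd = coords.std(axis=0, ddof=0)
    sd[sd == 0.0] = 1.0
    z = (coords - coords.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(z)
    centers = km.cluster_centers_  # standardized (var_morph, var_metab)
    order = {}
    remaining = list(range(k))
    b = max(remaining, key=lambda c: centers[c, 0])
    order[b] = "B"
    remaining.remove(b)
    if remaining:
        a = max(remaining, key=lambda c: centers[c, 1])
        order[a] = "A"
        remaining.remove(a)
    if remaining:
        c = min(remaining, key=lambda c: centers[c].sum())
        order[c] = "C"
        remaining.remove(c)
    for extra in remaining:
        order[extra] = "other"
    df["cluster_label"] = [order[c] for c in assign]
    return df
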