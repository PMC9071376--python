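"""Pearson correlation networks on log2 fold-changes with FDR control.

Correlations are computed pairwise-complete; two-sided p-values come from
the exact t transform t = r * sqrt((n-2)/(1-r^2)) with n-2 degrees of
freedom, and q-values from Benjamini-Hochberg (or Holm) across all pairs
of a family. Edges are retained under strict inequalities q < q_thresh
and |r| > r_thresh.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

_ADJUST = {"BH": "fdr_bh", "Holm": "holm"}


@dataclass
class CorrelationNetwork:
    """Feature-pair correlation table for one family of comparisons."""

    pairs: pd.DataFrame        # feature_a, feature_b, r, p, q, n
    family: str                # e.g. "metab-metab", "metab-morph"
    adjust_method: str = "BH"  # recorded so results are traceable
    skipped: list[tuple[str, str]] = field(default_factory=list)


def median_center(fc: pd.DataFrame) -> pd.DataFrame:
    """log2 of fold-changes renormalized to the population median.

    Used for graft-graft correlation analyses, where each feature is
    first scaled to the median across grafts so that features become
    comparable rows.
    """
    med = fc.median()
    if (med <= 0).any():
        bad = med.index[med <= 0].tolist()
        raise ValueError(f"non-positive median for feature(s): {bad}")
    return np.log2(fc / med)


def _pearson_pvalue(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p from the t transform with n-2 df (p -> 0 as |r| -> 1)."""
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return p


def correlate(log2fc: pd.DataFrame, features_a: list[str],
              features_b: list[str] | None = None, *,
              family: str | None = None, adjust: str = "BH",
              min_n: int = 4) -> CorrelationNetwork:
    """Pearson correlations between (or within) feature sets.

    Within-family mode (``features_b`` omitted or equal to ``features_a``)
    uses the upper triangle only; self-pairs are always excluded. Pairs
    with fewer than ``min_n`` pairwise-complete grafts are skipped; a
    zero-variance feature yields missing r with a warning.
    """
    if adjust not in _ADJUST:
        raise ValueError("adjust must be 'BH' or 'Holm'")
    within = features_b is None or list(features_b) == list(features_a)
    if features_b is None:
        features_b = features_a
    if family is None:
        family = "within" if within else "between"

    mat = log2fc
    pairs: list[tuple[str, str]] = []
    if within:
        for i, a in enumerate(features_a):
            for b in features_a[i + 1:]:
                pairs.append((a, b))
    else:
        pairs = [(a, b) for a in features_a for b in features_b if a != b]

    rows = []
    skipped: list[tuple[str, str]] = []
    for a, b in pairs:
        x = mat[a].to_numpy(dtype=float)
        y = mat[b].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < min_n:
            skipped.append((a, b))
            continue
        xs, ys = x[ok], y[ok]
        sx, sy = xs.std(ddof=0), ys.std(ddof=0)
        if sx == 0.0 or sy == 0.0:
            log.warning("zero-variance feature in pair (%s, %s); r missing",
                        a, b)
            rows.append({"feature_a": a, "feature_b": b, "r": np.nan,
                         "p": np.nan, "n": n})
            continue
        r = float(np.dot(xs - xs.mean(), ys - ys.mean()) / (n * sx * sy))
        rows.append({"feature_a": a, "feature_b": b, "r": r,
                     "p": float(_pearson_pvalue(np.array([r]),
                                                np.array([n]))[0]),
                     "n": n})
    table = pd.DataFrame(rows,
                         columns=["feature_a", "feature_b", "r", "p", "n"])
    table["q"] = np.nan
    valid = table["p"].notna()
    if valid.any():
        table.loc[valid, "q"] = multipletests(
            table.loc[valid, "p"], method=_ADJUST[adjust])[1]
    if skipped:
        log.warning("skipped %d pair(s) with < %d complete observations",
                    len(skipped), min_n)
    table = table[["feature_a", "feature_b", "r", "p", "q", "n"]]
    return CorrelationNetwork(pairs=table, family=family,
                              adjust_method=adjust, skipped=skipped)


def extract_edges(net: CorrelationNetwork, r_thresh: float = 0.3,
                  q_thresh: float = 0.05
                  ) -> tuple[pd.DataFrame, int, int]:
    """Signed edges passing q < q_thresh and |r| > r_thresh (strict).

    ``r_thresh=0`` gives significance-only counting. Returns the edge
    table sorted by |r| descending plus (n_positive, n_negative).
    """
    t = net.pairs.dropna(subset=["r", "q"])
    keep = (t["q"] < q_thresh) & (t["r"].abs() > r_thresh)
    edges = t[keep].copy()
    edges["sign"] = np.where(edges["r"] > 0, "positive", "negative")
    edges = edges.sort_values("r", key=lambda s: s.abs(),
                              ascending=False).reset_index(drop=True)
    n_pos = int((edges["sign"] == "positive").sum())
    n_neg = int((edges["sign"] == "negative").sum())
    return edges, n_pos, n_neg
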