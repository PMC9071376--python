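"""Metabolome-based trait prediction with L1-penalized regression.

The engine mirrors the glmnet-style workflow: for each outer
cross-validation fold the model is trained on the remaining folds with
the penalty weight chosen by an inner 10-fold search over a log-spaced
lambda grid, and the held-out fold's *predictability* — the Pearson
correlation between predicted and observed trait values — is recorded.
Ten random re-partitions of ten folds yield 100 predictabilities per
trait. Significance comes from a permutation null (the response shuffled
afresh for every re-fit), and variable importance from the selection
frequency: the number of the 100 fits in which a metabolite receives a
nonzero coefficient.

The objective is (1/2n)*sum(y_i - b0 - x_i'b)^2 + lambda*sum|b_j| with
predictors standardized internally on the training rows only;
coefficients are reported back on the original scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, lasso_path

from .datamodel import AnalysisConfig

log = logging.getLogger(__name__)

#: coefficients with absolute (standardized-scale) value above this count
#: as selected; coordinate descent produces exact zeros, the tolerance
#: guards against solver substitution
SUPPORT_TOL = 1e-10


# ---------------------------------------------------------------------------
# standardization helpers

def _train_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    return mu, sd


def _apply_stats(X: np.ndarray, mu: np.ndarray,
                 sd: np.ndarray) -> np.ndarray:
    safe = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / safe


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the L1 solution is the zero vector.

    glmnet-compatible: max_j |x_j'(y - ybar)| / n on standardized columns.
    """
    mu, sd = _train_stats(X)
    Xs = _apply_stats(X, mu, sd)
    Xs[:, sd == 0.0] = 0.0
    n = len(y)
    return float(np.max(np.abs(Xs.T @ (y - y.mean()))) / n)


def lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 100,
                min_ratio: float = 1e-4) -> np.ndarray:
    """Descending log-spaced grid from lambda_max to lambda_max*min_ratio."""
    lmax = lambda_max(X, y)
    if lmax == 0.0:
        raise ValueError("lambda_max is 0: response or predictors are "
                         "degenerate")
    return lmax * np.logspace(0.0, np.log10(min_ratio), n_lambda)


# ---------------------------------------------------------------------------
# single fit

@dataclass
class LassoFit:
    """One penalized fit, with coefficients on the original scale."""

    intercept: float
    beta: pd.Series                 # metabolite -> coefficient
    lambda_selected: float
    lambda_path: np.ndarray | None
    nonzero_support: frozenset[str]
    training_ids: frozenset

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.intercept
                + X[self.beta.index].to_numpy(dtype=float)
                @ self.beta.to_numpy())


def fit_lasso(X: pd.DataFrame, y: pd.Series, lam: float, *,
              lambda_path_used: np.ndarray | None = None,
              stats_rows: np.ndarray | None = None,
              tol: float = 1e-8, max_iter: int = 100_000) -> LassoFit:
    """Solve the L1-penalized least-squares problem at one penalty.

    Predictors are z-scored internally (zero-variance columns excluded,
    coefficient 0) and coefficients returned on the original scale.
    ``lam=0`` is the ordinary least-squares limit. ``stats_rows``
    optionally restricts the rows used for standardization statistics
    (diagnostic hook; defaults to all training rows).
    """
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    if not (np.all(np.isfinite(Xv)) and np.all(np.isfinite(yv))):
        raise ValueError("non-finite values in X or y")
    ref = Xv if stats_rows is None else stats_rows
    mu, sd = _train_stats(ref)
    Xs = _apply_stats(Xv, mu, sd)
    Xs[:, sd == 0.0] = 0.0

    if lam == 0.0:
        A = np.column_stack([np.ones(len(yv)), Xs])
        coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
        b_std = coef[1:]
        b_std[sd == 0.0] = 0.0
        intercept_std = float(coef[0])
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = Lasso(alpha=lam, fit_intercept=True, tol=tol,
                          max_iter=max_iter)
            model.fit(Xs, yv)
        b_std = model.coef_.copy()
        intercept_std = float(model.intercept_)

    support = np.abs(b_std) > SUPPORT_TOL
    b_std[~support] = 0.0
    safe = np.where(sd == 0.0, 1.0, sd)
    beta = b_std / safe
    intercept = intercept_std - float(np.dot(beta, mu))
    names = list(X.columns)
    return LassoFit(
        intercept=intercept,
        beta=pd.Series(beta, index=names),
        lambda_selected=lam,
        lambda_path=lambda_path_used,
        nonzero_support=frozenset(np.asarray(names)[support]),
        training_ids=frozenset(X.index),
    )


# ---------------------------------------------------------------------------
# inner-CV lambda selection

def select_lambda(X: pd.DataFrame, y: pd.Series, inner_folds: int,
                  grid: np.ndarray | None = None, seed: int = 0, *,
                  n_lambda: int = 100, min_ratio: float = 1e-4,
                  rule: str = "min") -> tuple[float, np.ndarray]:
    """Choose the penalty by inner cross-validation.

    The grid is computed from the full training data (glmnet semantics)
    unless supplied. Returns (lambda, grid). ``rule="min"`` takes the
    grid member minimizing the mean validation MSE, ties going to the
    larger penalty; ``rule="1se"`` the largest penalty within one
    standard error of that minimum.
    """
    yv = y.to_numpy(dtype=float)
    if yv.std(ddof=0) == 0.0:
        raise ValueError("response has zero variance")
    Xv = X.to_numpy(dtype=float)
    n = len(yv)
    if inner_folds > n:
        raise ValueError("more inner folds than training rows")
    if grid is None:
        grid = lambda_grid(Xv, yv, n_lambda, min_ratio)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, inner_folds)
    sq_err = np.zeros((n, len(grid)))
    for val_idx in folds:
        tr_idx = np.setdiff1d(perm, val_idx, assume_unique=True)
        Xtr, ytr = Xv[tr_idx], yv[tr_idx]
        mu, sd = _train_stats(Xtr)
        Xtr_s = _apply_stats(Xtr, mu, sd)
        Xtr_s[:, sd == 0.0] = 0.0
        Xval_s = _apply_stats(Xv[val_idx], mu, sd)
        Xval_s[:, sd == 0.0] = 0.0
        ybar = ytr.mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, coefs, _ = lasso_path(Xtr_s, ytr - ybar, alphas=grid)
        preds = Xval_s @ coefs + ybar           # n_val x n_lambda
        sq_err[val_idx] = (preds - yv[val_idx, None]) ** 2
    mean_mse = sq_err.mean(axis=0)
    best = int(np.argmin(mean_mse))  # grid descends: first min = larger lam
    if rule == "1se":
        se = sq_err.std(axis=0, ddof=1)[best] / np.sqrt(n)
        within = np.flatnonzero(mean_mse <= mean_mse[best] + se)
        best = int(within[0])
    elif rule != "min":
        raise ValueError("rule must be 'min' or '1se'")
    return float(grid[best]), grid


# ---------------------------------------------------------------------------
# repeated outer CV

@dataclass
class PredictionReport:
    """Predictability and selection-stability summary for one trait."""

    trait: str
    predictabilities: np.ndarray        # one Pearson r per outer test fold
    per_fold_p: np.ndarray
    mean_predictability: float
    selection_frequency: pd.Series      # metabolite -> count of fits
    n_fits: int
    outer_repeats: int
    outer_folds: int
    folds: list[tuple[np.ndarray, np.ndarray]] = field(repr=False,
                                                       default_factory=list)
    row_index: pd.Index | None = field(repr=False, default=None)
    null_distribution: np.ndarray | None = None
    empirical_p: float | None = None

    def frequently_selected(self, threshold: int = 95) -> list[str]:
        return frequently_selected(self.selection_frequency, threshold,
                                   self.n_fits)


def _fold_predictability(pred: np.ndarray, obs: np.ndarray
                         ) -> tuple[float, float]:
    """Pearson r and its p on one held-out fold.

    A zero-variance prediction vector (the all-shrunk null model) carries
    no information; its predictability is defined as 0 with p = 1.
    """
    if np.ptp(pred) == 0.0 or np.ptp(obs) == 0.0:
        return 0.0, 1.0
    r, p = stats.pearsonr(pred, obs)
    return float(r), float(p)


def _make_folds(n: int, n_folds: int, seed: int,
                min_test: int = 4) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [f for f in np.array_split(perm, n_folds)]
    merged: list[np.ndarray] = []
    for f in folds:
        if merged and len(f) < min_test:
            log.warning("merging fold with %d grafts into its neighbor",
                        len(f))
            merged[-1] = np.concatenate([merged[-1], f])
        else:
            merged.append(f)
    return merged


def repeated_cv_predict(X: pd.DataFrame, y: pd.Series, cfg: AnalysisConfig,
                        *, trait: str = "trait",
                        leak_standardization: bool = False
                        ) -> PredictionReport:
    """Repeated outer cross-validation predictability for one trait.

    For repeat r the grafts are randomly partitioned into near-equal
    folds (partition seed ``cfg.rng_seed + r``); each fold is predicted
    by a model trained on the others with the penalty chosen by inner
    cross-validation, giving ``outer_repeats * outer_folds``
    predictabilities and per-metabolite selection counts.

    ``leak_standardization=True`` is a deliberate-leakage diagnostic that
    computes standardization statistics on all rows including the test
    fold; it exists only to demonstrate that the train-only guard is
    load-bearing and must stay off for real analyses.
    """
    keep = y.notna() & X.notna().all(axis=1)
    X, y = X.loc[keep], y.loc[keep]
    n = len(y)
    if n < 3 * cfg.outer_folds:
        log.warning("only %d complete grafts for %d outer folds", n,
                    cfg.outer_folds)
    Xv_all = X.to_numpy(dtype=float)

    preds_r: list[float] = []
    preds_p: list[float] = []
    counts = pd.Series(0, index=X.columns, dtype=int)
    folds_used: list[tuple[np.ndarray, np.ndarray]] = []
    for rep in range(cfg.outer_repeats):
        folds = _make_folds(n, cfg.outer_folds, cfg.rng_seed + rep)
        for j, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx,
                                     assume_unique=False)
            Xtr, ytr = X.iloc[train_idx], y.iloc[train_idx]
            inner_seed = cfg.rng_seed + 1000 * (rep + 1) + j
            lam, grid = select_lambda(
                Xtr, ytr, cfg.inner_folds, seed=inner_seed,
                n_lambda=cfg.n_lambda, min_ratio=cfg.lambda_min_ratio,
                rule=cfg.lambda_rule)
            stats_rows = Xv_all if leak_standardization else None
            fit = fit_lasso(Xtr, ytr, lam, lambda_path_used=grid,
                            stats_rows=stats_rows)
            pred = fit.predict(X.iloc[test_idx])
            r, p = _fold_predictability(pred,
                                        y.iloc[test_idx].to_numpy(float))
            preds_r.append(r)
            preds_p.append(p)
            for m in fit.nonzero_support:
                counts[m] += 1
            folds_used.append((train_idx, test_idx))
    preds = np.array(preds_r)
    return PredictionReport(
        trait=trait,
        predictabilities=preds,
        per_fold_p=np.array(preds_p),
        mean_predictability=float(preds.mean()),
        selection_frequency=counts,
        n_fits=len(preds),
        outer_repeats=cfg.outer_repeats,
        outer_folds=cfg.outer_folds,
        folds=folds_used,
        row_index=X.index,
    )


# ---------------------------------------------------------------------------
# permutation null

def permutation_test(X: pd.DataFrame, y: pd.Series, cfg: AnalysisConfig,
                     report: PredictionReport) -> PredictionReport:
    """Permutation null distribution and empirical p for a report.

    Each of the report's outer predictions is re-run
    ``cfg.permutations_per_prediction`` times with the response freshly
    permuted across all grafts (the fold partition is reused), recording
    the held-out-fold predictability. The empirical p compares the
    observed mean predictability against the pooled null with the
    +1/(N+1) estimator.
    """
    keep = y.notna() & X.notna().all(axis=1)
    X, y = X.loc[keep], y.loc[keep]
    if report.row_index is not None and not X.index.equals(report.row_index):
        raise ValueError("X/y rows do not match the report's rows")
    n = len(y)
    yv = y.to_numpy(dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 797]))
    nulls: list[float] = []
    for train_idx, test_idx in report.folds:
        for _ in range(cfg.permutations_per_prediction):
            yp = pd.Series(yv[rng.permutation(n)], index=y.index)
            inner_seed = int(rng.integers(0, 2**31 - 1))
            lam, grid = select_lambda(
                X.iloc[train_idx], yp.iloc[train_idx], cfg.inner_folds,
                seed=inner_seed, n_lambda=cfg.n_lambda,
                min_ratio=cfg.lambda_min_ratio, rule=cfg.lambda_rule)
            fit = fit_lasso(X.iloc[train_idx], yp.iloc[train_idx], lam,
                            lambda_path_used=grid)
            pred = fit.predict(X.iloc[test_idx])
            r, _ = _fold_predictability(pred,
                                        yp.iloc[test_idx].to_numpy(float))
            nulls.append(r)
    null = np.array(nulls)
    obs = report.mean_predictability
    p = (1.0 + float((null >= obs).sum())) / (1.0 + len(null))
    report.null_distribution = null
    report.empirical_p = p
    return report


# ---------------------------------------------------------------------------
# selection-frequency summaries

def frequently_selected(freq: Mapping[str, int] | pd.Series,
                        threshold: int = 95, n_fits: int = 100) -> list[str]:
    """Metabolites selected in at least threshold% of 100-equivalent fits.

    The threshold is stated on the 100-fit scale (>= 95 of 100); for runs
    with a different number of fits the same fraction applies. Returned
    sorted by frequency descending, ties by name.
    """
    freq = pd.Series(dict(freq)) if not isinstance(freq, pd.Series) else freq
    cutoff = threshold / 100.0 * n_fits
    hits = freq[freq >= cutoff]
    return list(hits.sort_index()
                .sort_values(ascending=False, kind="stable").index)


def overlap_analysis(selected: Mapping[str, Sequence[str]]
                     ) -> dict[tuple[str, ...], list[str]]:
    """Partition metabolites by the exact set of traits selecting them.

    Input maps trait -> frequently-selected metabolites; output maps each
    realized trait combination (sorted tuple) to its metabolites. Empty
    cells are omitted.
    """
    if len(selected) < 2:
        raise ValueError("need at least two traits to overlap")
    membership: dict[str, list[str]] = {}
    for trait, mets in selected.items():
        for m in mets:
            membership.setdefault(m, []).append(trait)
    cells: dict[tuple[str, ...], list[str]] = {}
    for m, traits in membership.items():
        cells.setdefault(tuple(sorted(traits)), []).append(m)
    return {combo: sorted(ms) for combo, ms in sorted(cells.items())}
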