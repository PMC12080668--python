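"""Prediction-performance metrics, bootstrap confidence intervals, permutation test.

The coefficient of determination used here is the cross-validation form

    R^2 = 1 - sum (y - yhat)^2 / sum (y - ybar)^2,

which compares the model's squared prediction error against the error of
predicting the observed mean.  Out of sample it is unbounded below: a model
worse than the mean yields a negative value, and it is *not* the square of
the correlation between observed and predicted values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MetricSet",
    "mae",
    "pearson_r",
    "r2_cv",
    "compute_metrics",
    "bootstrap_ci",
    "perm_test",
]


@dataclass(frozen=True)
class MetricSet:
    """Point estimates of the three prediction metrics."""

    mae: float
    r: float
    r2: float


def _check_pairs(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(observed, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError(
            f"observed and predicted have different lengths ({y.size} vs {yhat.size})"
        )
    if y.size == 0:
        raise ValueError("empty input")
    return y, yhat


def mae(observed, predicted) -> float:
    """Mean absolute error, in the units of the outcome."""
    y, yhat = _check_pairs(observed, predicted)
    return float(np.mean(np.abs(y - yhat)))


def pearson_r(observed, predicted) -> float:
    """Pearson correlation between observed and predicted values."""
    y, yhat = _check_pairs(observed, predicted)
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(y, yhat)[0, 1])


def r2_cv(observed, predicted) -> float:
    """Cross-validation coefficient of determination.

    ``1 - SS_res / SS_tot`` with the total sum of squares taken around the
    mean of the *observed* values.  May be negative when predictions are
    worse than predicting the mean.
    """
    y, yhat = _check_pairs(observed, predicted)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: observed values are constant")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def compute_metrics(observed, predicted) -> MetricSet:
    return MetricSet(
        mae=mae(observed, predicted),
        r=pearson_r(observed, predicted),
        r2=r2_cv(observed, predicted),
    )


def bootstrap_ci(
    observed,
    predicted,
    metric: Callable[[np.ndarray, np.ndarray], float] | str,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for a prediction metric.

    Observed-predicted *pairs* are resampled with replacement ``n_boot``
    times and the metric recomputed on each resample; the interval is the
    pair of symmetric percentiles at the requested ``level``.  Resamples on
    which the metric is undefined (e.g. a constant resample for a
    correlation) are redrawn, with the count logged; if more than 10% of
    draws are degenerate the distribution is considered pathological and an
    error is raised.
    """
    y, yhat = _check_pairs(observed, predicted)
    if y.size < 3:
        raise ValueError("bootstrap needs at least 3 observed-predicted pairs")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if isinstance(metric, str):
        metric = {"mae": mae, "r": pearson_r, "r2": r2_cv}[metric]
    rng = np.random.default_rng(seed)
    n = y.size
    values = np.empty(n_boot)
    n_degenerate = 0
    max_degenerate = int(np.ceil(0.1 * n_boot))
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            values[i] = metric(y[idx], yhat[idx])
        except ValueError:
            n_degenerate += 1
            if n_degenerate > max_degenerate:
                raise ValueError(
                    "metric undefined on more than 10% of bootstrap resamples"
                )
            continue
        i += 1
    if n_degenerate:
        logger.info("bootstrap: redrew %d degenerate resamples", n_degenerate)
    alpha = 1.0 - level
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def perm_test(
    x,
    y,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation test of the Pearson correlation between ``x`` and ``y``.

    Returns ``(r, p)`` where ``p`` is the two-tailed add-one permutation
    p-value: the fraction of permutations of ``y`` (the observed pairing
    included) whose ``|r|`` meets or exceeds the observed ``|r|``.  The
    smallest attainable p is ``1 / (n_perm + 1)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal lengths")
    if x.size < 5:
        raise ValueError("permutation test needs at least 5 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rng = np.random.default_rng(seed)
    # standardize once; |r| of permuted y is then a plain dot product
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    n = x.size
    r_obs = float(xs @ ys) / n
    n_hits = 0
    for _ in range(n_perm):
        r_perm = float(xs @ rng.permutation(ys)) / n
        if abs(r_perm) >= abs(r_obs) - 1e-14:
            n_hits += 1
    p = (n_hits + 1) / (n_perm + 1)
    return r_obs, p


def motion_check(
    mean_fd,
    outcome,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Pre-check that head motion does not predict the outcome.

    Thin wrapper of :func:`perm_test` applied to mean framewise displacement
    versus the post-treatment score.
    """
    return perm_test(mean_fd, outcome, n_perm=n_perm, seed=seed)
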