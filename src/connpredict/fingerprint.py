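"""Cross-session fingerprinting and the differential-power statistic.

Subjects are identified by correlating each subject's baseline feature
vector with every subject's follow-up vector and taking the most similar
(with replacement).  The number of correct identifications is tested
against a Binomial(N, 1/N) null in log space, so p-values far below the
smallest normal float are reported accurately.

Per-feature analysis decomposes each baseline-follow-up correlation into
per-feature contributions (products of standardized values, summing exactly
to Pearson r).  For each subject and feature, the within-subject
cross-session product is compared against the between-subject products; the
add-one-smoothed fraction of between products that meet or exceed it is a
chance probability estimate p-hat, strictly inside (0, 1].  The
differential power of a feature aggregates these over subjects as
-2 * sum(log p-hat), which under the null of uniform p-hat follows a
chi-squared distribution with 2N degrees of freedom (Fisher's method); its
upper tail gives a per-feature p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "DPResult",
    "similarity",
    "identify",
    "identification_pvalue",
    "contributions",
    "phat",
    "differential_power",
    "dp_select",
    "fingerprint_report",
]


@dataclass
class SimilarityMatrix:
    """Entry (s, t): Pearson r between subject s's baseline and t's follow-up."""

    values: np.ndarray
    subject_ids: list | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if np.any(np.abs(v) > 1 + 1e-9):
            raise ValueError("similarity entries must lie in [-1, 1]")
        self.values = v

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class DPResult:
    """Per-feature differential power with its chi-squared(2N) p-values."""

    phat: np.ndarray       # n_subjects x n_features, in (0, 1]
    dp: np.ndarray         # per-feature, >= 0
    dp_pvalue: np.ndarray  # per-feature upper tail, in (0, 1]
    dp_logp: np.ndarray    # natural log of the p-value (no underflow)

    @property
    def n_subjects(self) -> int:
        return self.phat.shape[0]

    @property
    def n_features(self) -> int:
        return self.phat.shape[1]


def _standardize(m: np.ndarray) -> np.ndarray:
    """Row-standardize to mean 0 and population variance 1."""
    m = np.asarray(m, dtype=float)
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = int(np.argmax(sd.ravel() == 0))
        raise ValueError(f"subject {bad} has a zero-variance feature vector")
    return (m - mu) / sd


def _as_matrix(fs) -> np.ndarray:
    return fs.matrix if hasattr(fs, "matrix") else np.asarray(fs, dtype=float)


def similarity(baseline, followup) -> SimilarityMatrix:
    """Full N x N Pearson-correlation matrix between sessions.

    Rows index baseline subjects, columns follow-up subjects; the diagonal
    (a subject against itself) is included, not excluded.
    """
    bm, fm = _as_matrix(baseline), _as_matrix(followup)
    if bm.shape != fm.shape:
        raise ValueError(
            f"sessions have different shapes: {bm.shape} vs {fm.shape}"
        )
    b_ids = getattr(baseline, "feature_ids", None)
    f_ids = getattr(followup, "feature_ids", None)
    if b_ids and f_ids and b_ids != f_ids:
        first = next(i for i, (a, b) in enumerate(zip(b_ids, f_ids)) if a != b)
        raise ValueError(
            f"feature identity mismatch between sessions at position {first}: "
            f"{b_ids[first]!r} vs {f_ids[first]!r}"
        )
    n_feat = bm.shape[1]
    sim = _standardize(bm) @ _standardize(fm).T / n_feat
    sim = np.clip(sim, -1.0, 1.0)
    ids = getattr(baseline, "subject_ids", None)
    return SimilarityMatrix(sim, subject_ids=ids)


def identify(
    sim: SimilarityMatrix | np.ndarray,
    direction: str = "baseline_to_followup",
    tie_break: str = "lowest",
    seed: int | np.random.Generator | None = None,
) -> tuple[int, np.ndarray]:
    """Identification with replacement: argmax similarity per subject.

    ``baseline_to_followup``: for each baseline (row), the most similar
    follow-up is picked; a hit is an argmax on the diagonal.  The reverse
    direction scans columns.  Exact ties at the maximum are broken toward
    the lowest index (logged), or uniformly at random with
    ``tie_break="random"`` and a seed.

    Returns ``(n_correct, per-subject hit flags)``.
    """
    v = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("similarity matrix must be square")
    if direction in ("baseline_to_followup", "rows"):
        m = v
    elif direction in ("followup_to_baseline", "cols"):
        m = v.T
    else:
        raise ValueError(f"unknown direction {direction!r}")
    n = m.shape[0]
    rng = np.random.default_rng(seed)
    hits = np.zeros(n, dtype=bool)
    n_ties = 0
    for s in range(n):
        row = m[s]
        top = row.max()
        winners = np.flatnonzero(row == top)
        if winners.size > 1:
            n_ties += 1
            if tie_break == "random":
                pick = int(rng.choice(winners))
            else:
                pick = int(winners[0])
        else:
            pick = int(winners[0])
        hits[s] = pick == s
    if n_ties:
        logger.warning(
            "identify: %d subject(s) had ties at the maximum similarity "
            "(tie_break=%s)", n_ties, tie_break,
        )
    return int(hits.sum()), hits


def identification_pvalue(k: int, n_subjects: int) -> float:
    """Upper-tail binomial probability of >= k correct identifications.

    ``P(X >= k)`` for ``X ~ Binomial(N, 1/N)``: because the most similar
    scan is chosen with replacement, each of the N subjects is a chance-1/N
    trial.  Computed in log space so values far below 1e-300 do not
    underflow to 0.
    """
    if not 0 <= k <= n_subjects:
        raise ValueError(f"k={k} must lie in [0, {n_subjects}]")
    if k == 0:
        return 1.0
    p = float(np.exp(identification_log_pvalue(k, n_subjects)))
    # below the float range the log form (identification_log_pvalue) is the
    # faithful report; keep this one strictly positive per contract
    return max(p, np.nextafter(0, 1))


def identification_log_pvalue(k: int, n_subjects: int) -> float:
    """Natural log of :func:`identification_pvalue`, exact even when the
    probability falls below the smallest representable float."""
    if not 0 <= k <= n_subjects:
        raise ValueError(f"k={k} must lie in [0, {n_subjects}]")
    if k == 0:
        return 0.0
    js = np.arange(k, n_subjects + 1)
    return float(logsumexp(stats.binom.logpmf(js, n_subjects, 1.0 / n_subjects)))


def contributions(baseline_vec, followup_vec) -> np.ndarray:
    """Per-feature contribution of each entry to the Pearson correlation.

    With both vectors standardized to mean 0, variance 1, the correlation is
    the scaled dot product ``r = (1/n) sum x_i y_i``; each term
    ``c_i = x_i y_i / n`` is that feature's contribution, and the
    contributions sum exactly to r.
    """
    x = np.asarray(baseline_vec, dtype=float).ravel()
    y = np.asarray(followup_vec, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance vector: contributions undefined")
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    return xs * ys / x.size


def phat(baseline, followup) -> np.ndarray:
    """Smoothed per-subject, per-feature chance-contribution probability.

    For subject s and feature i, the within-subject product
    ``w = x_i(s) y_i(s)`` of standardized session values is compared to the
    2(N-1) between-subject products ``x_i(s) y_i(t)`` and ``y_i(s) x_i(t)``
    for t != s (both cross directions enter symmetrically).  p-hat is the
    add-one-smoothed fraction of between products that are >= w:

        phat = (count + 1) / (2 (N - 1) + 1)

    so it lies in ``[1 / (2N - 1), 1]`` and is never exactly 0.  Ties count
    against discriminability (>= rather than >).
    """
    bm, fm = _as_matrix(baseline), _as_matrix(followup)
    if bm.shape != fm.shape:
        raise ValueError("sessions have different shapes")
    n, _ = bm.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    x = _standardize(bm)
    y = _standardize(fm)
    within = x * y  # n x f, per-subject own-pair products
    total = 2 * (n - 1)
    counts = np.zeros_like(within)
    for t in range(n):
        # feature-wise cross products of every subject s with subject t
        cross_xy = x * y[t]   # x_i(s) * y_i(t)
        cross_yx = y * x[t]   # y_i(s) * x_i(t)
        counts += (cross_xy >= within) & (np.arange(n) != t)[:, None]
        counts += (cross_yx >= within) & (np.arange(n) != t)[:, None]
    return (counts + 1.0) / (total + 1.0)


def differential_power(phat_matrix: np.ndarray) -> DPResult:
    """Combine per-subject chance probabilities into per-feature DP.

    ``dp_i = sum_s -2 log phat_{s,i}``.  If the true chance probability is
    uniform, ``-log phat`` is Exponential(1), so ``-2 log phat`` is
    chi-squared(2) and the sum over N subjects is chi-squared(2N); the
    upper tail at dp gives the feature's p-value.  The survival function is
    evaluated in log space so extreme DP does not underflow.
    """
    p = np.asarray(phat_matrix, dtype=float)
    if p.ndim != 2:
        raise ValueError("phat must be 2-D (subjects x features)")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("phat entries must lie in (0, 1]")
    n = p.shape[0]
    dp = -2.0 * np.log(p).sum(axis=0)
    logp = _chi2_even_df_logsf(dp, 2 * n)
    pval = np.exp(logp)
    # the estimator never reaches 0; keep the reported tail strictly positive
    pval = np.maximum(pval, np.nextafter(0, 1))
    return DPResult(phat=p, dp=dp, dp_pvalue=pval, dp_logp=logp)


def _chi2_even_df_logsf(x: np.ndarray, df: int) -> np.ndarray:
    """Log upper tail of chi-squared with even df, exact in log space.

    For df = 2m the tail is the Erlang survival function
    ``exp(-x/2) * sum_{j<m} (x/2)^j / j!``; evaluating the sum with
    log-sum-exp avoids the underflow of the direct survival function at
    large x.
    """
    if df % 2 != 0 or df < 2:
        raise ValueError("closed-form tail needs positive even df")
    from scipy.special import gammaln

    x = np.atleast_1d(np.asarray(x, dtype=float))
    m = df // 2
    half = x / 2.0
    j = np.arange(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        # terms j*log(x/2) - log(j!); x = 0 handled by the j = 0 term
        log_terms = np.where(
            half[:, None] > 0, j * np.log(half[:, None]), np.where(j == 0, 0.0, -np.inf)
        ) - gammaln(j + 1)
    out = -half + logsumexp(log_terms, axis=1)
    return np.minimum(out, 0.0)


def dp_select(dp_result: DPResult, alpha: float) -> np.ndarray:
    """Feature indices with DP p-value below alpha, sorted by DP descending."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if alpha == 1.0:
        idx = np.arange(dp_result.n_features)
    else:
        idx = np.flatnonzero(dp_result.dp_pvalue < alpha)
    return idx[np.argsort(-dp_result.dp[idx], kind="stable")]


def fingerprint_report(baseline, followup, compute_dp: bool = True) -> dict:
    """End-to-end fingerprinting: identification both ways, binomial p, DP."""
    sim = similarity(baseline, followup)
    n = sim.n_subjects
    out: dict = {"n_subjects": n, "similarity": sim}
    for key, direction in [
        ("baseline_to_followup", "baseline_to_followup"),
        ("followup_to_baseline", "followup_to_baseline"),
    ]:
        k, hits = identify(sim, direction=direction)
        out[key] = {
            "n_correct": k,
            "accuracy": k / n,
            "pvalue": identification_pvalue(k, n),
            "hits": hits,
        }
    if compute_dp:
        out["dp"] = differential_power(phat(baseline, followup))
    return out
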