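"""Connectome / anatomical predictive modeling core.

Two-stage procedure: (1) per-feature association screening of the outcome
against every edge or vertex, keeping features whose coefficient is
significant at ``alpha_select`` (split by sign into positive and negative
sets); (2) the Fisher-z values (or morphometric values) of selected
features are summed into one strength score per subject and the outcome is
regressed on it.  The model is evaluated out of sample by leave-one-out
cross-validation and by external validation on an independent dataset.

Covariates (age, sex, baseline severity, scanner) are handled in one of
three schemes:

* ``none`` — ignored everywhere;
* ``predictors`` — included as regressors of interest in both stages;
* ``nuisance`` — included in the first stage, while in the second stage
  both outcome and strengths are residualized against them using
  training-set coefficients; predictions are made on the residual scale and
  the nuisance effects added back, so outputs stay on the outcome scale.
  Leave-one-out test subjects are residualized with training coefficients
  (a single subject cannot support its own estimate); an external test set
  large enough can be residualized with its own coefficients, reducing the
  risk of covariate shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from connpredict import metrics as _metrics
from connpredict.fingerprint import DPResult, dp_select

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "PredictiveModelFit",
    "PredictionReport",
    "build_covariates",
    "select_features",
    "strength",
    "fit_second_stage",
    "fit_model",
    "predict",
    "loo_cv",
    "external_validation",
]


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of one CPM/APM model."""

    feature_kind: str = "edges"           # edges | vertices
    selection: str = "positive"           # positive | negative | both | dp
    alpha_select: float = 0.01
    weighting: str = "none"               # none | correlation
    covariate_mode: str = "none"          # none | predictors | nuisance
    covariates: tuple[str, ...] = ()      # e.g. ("age_years", "sex", "pars_baseline")
    outcome: str = "post_score"           # post_score | change_score
    both_as_difference: bool = False      # use pos-sum minus neg-sum as one regressor
    dp_alpha: float = 0.01                # threshold when selection == "dp"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha_select < 1:
            raise ValueError("alpha_select must be in (0, 1)")
        if self.selection not in ("positive", "negative", "both", "dp"):
            raise ValueError(f"unknown selection mode {self.selection!r}")
        if self.weighting not in ("none", "correlation"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.covariate_mode not in ("none", "predictors", "nuisance"):
            raise ValueError(f"unknown covariate_mode {self.covariate_mode!r}")
        if self.outcome not in ("post_score", "change_score"):
            raise ValueError(f"unknown outcome {self.outcome!r}")


@dataclass
class PredictiveModelFit:
    """Everything needed to predict a new subject."""

    positive_idx: np.ndarray
    negative_idx: np.ndarray
    weights: np.ndarray | None            # per-feature weights (correlation mode)
    second_stage_coefs: np.ndarray        # on the design described by coef_names
    coef_names: list[str]
    nuisance_coefs_y: np.ndarray | None   # outcome ~ [1, covariates] (nuisance mode)
    nuisance_coefs_s: np.ndarray | None   # strengths ~ [1, covariates]
    config: ModelConfig
    empty_selection: bool = False

    def __post_init__(self):
        if np.intersect1d(self.positive_idx, self.negative_idx).size:
            raise ValueError("positive and negative index sets must be disjoint")


@dataclass
class PredictionReport:
    """Out-of-sample predictions with metrics, CIs and selection frequencies."""

    observed: np.ndarray
    predicted: np.ndarray
    mae: float
    r: float
    r2: float
    ci_mae: tuple[float, float]
    ci_r: tuple[float, float]
    ci_r2: tuple[float, float]
    selection_frequency: np.ndarray | None = None
    frequency_positive: np.ndarray | None = None
    frequency_negative: np.ndarray | None = None
    flagged_folds: list[int] = field(default_factory=list)
    config: ModelConfig | None = None

    def frequent_features(self, threshold: float = 0.5) -> np.ndarray:
        """Features selected in at least ``threshold`` of the CV folds."""
        if self.selection_frequency is None:
            raise ValueError("no per-fold selection frequencies available")
        return np.flatnonzero(self.selection_frequency >= threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"observed": self.observed, "predicted": self.predicted})


def outcome_vector(cohort: pd.DataFrame, config: ModelConfig) -> np.ndarray:
    y = cohort["pars_post"].to_numpy(dtype=float)
    if config.outcome == "change_score":
        y = y - cohort["pars_baseline"].to_numpy(dtype=float)
    return y


def build_covariates(cohort: pd.DataFrame, config: ModelConfig):
    """Covariate design matrix (no intercept) and its column names.

    Scanner is expanded into indicator variables (first level dropped);
    everything else enters as the numeric column of the phenotype table.
    """
    if config.covariate_mode == "none" or not config.covariates:
        return None, []
    cols, names = [], []
    for name in config.covariates:
        if name not in cohort.columns:
            raise ValueError(f"covariate {name!r} not in cohort table")
        if name == "scanner":
            levels = np.sort(cohort["scanner"].unique())
            for lev in levels[1:]:
                cols.append((cohort["scanner"] == lev).to_numpy(dtype=float))
                names.append(f"scanner[{lev}]")
        else:
            cols.append(cohort[name].to_numpy(dtype=float))
            names.append(name)
    if not cols:
        return None, []
    return np.column_stack(cols), names


def _with_intercept(C: np.ndarray | None, n: int) -> np.ndarray:
    ones = np.ones((n, 1))
    return ones if C is None else np.hstack([ones, C])


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the columns that lie in the span of the others
        collinear = []
        for j in range(design.shape[1]):
            others = np.delete(design, j, axis=1)
            proj, *_ = np.linalg.lstsq(others, design[:, j], rcond=None)
            resid = design[:, j] - others @ proj
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(design[:, j])):
                collinear.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")


def select_features(
    train_features: np.ndarray,
    train_outcome: np.ndarray,
    train_covariates: np.ndarray | None,
    config: ModelConfig,
    dp_result: DPResult | None = None,
):
    """First-stage screening.

    Per feature, the outcome is regressed on the feature (plus covariates
    when a covariate scheme is active) and the feature coefficient's exact
    two-tailed t-test p-value is computed; features with p < ``alpha_select``
    are assigned to the positive or negative set by coefficient sign.  In
    ``dp`` mode the candidate set comes from the differential-power
    threshold instead, then split by sign.

    Returns ``(positive_idx, negative_idx, feature_correlations)`` where the
    correlations are the (partial) correlations used for weighting.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_outcome, dtype=float).ravel()
    n = y.size
    if n < 10:
        raise ValueError(f"need at least 10 training subjects, got {n}")
    Z = _with_intercept(train_covariates, n)
    k_z = Z.shape[1]
    # residualize outcome and every feature against [1, covariates]; the
    # correlation of the residuals carries the same t statistic as the
    # feature coefficient in the full multiple regression
    beta_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
    yr = y - Z @ beta_y
    beta_x, *_ = np.linalg.lstsq(Z, X, rcond=None)
    Xr = X - Z @ beta_x
    x_norm = np.linalg.norm(Xr, axis=0)
    y_norm = np.linalg.norm(yr)
    zero_var = x_norm <= 1e-12 * np.sqrt(n)
    if zero_var.any():
        logger.info("select_features: %d zero-variance feature(s) excluded",
                    int(zero_var.sum()))
    safe_norm = np.where(zero_var, 1.0, x_norm)
    r = (Xr.T @ yr) / (safe_norm * max(y_norm, 1e-300))
    r = np.clip(r, -1.0, 1.0)
    df = n - k_z - 1
    if df < 1:
        raise ValueError("not enough degrees of freedom for first-stage test")
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals[zero_var] = 1.0

    if config.selection == "dp":
        if dp_result is None:
            raise ValueError("selection='dp' requires a DPResult")
        candidates = dp_select(dp_result, config.dp_alpha)
        cand_mask = np.zeros(X.shape[1], dtype=bool)
        cand_mask[candidates] = True
        sig = cand_mask & ~zero_var
    else:
        sig = (pvals < config.alpha_select) & ~zero_var
    positive_idx = np.flatnonzero(sig & (r > 0))
    negative_idx = np.flatnonzero(sig & (r < 0))
    return positive_idx, negative_idx, r


def strength(
    features: np.ndarray,
    positive_idx: np.ndarray,
    negative_idx: np.ndarray,
    config: ModelConfig,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Summarize selected features into per-subject strength regressors.

    ``positive`` / ``negative`` modes sum the feature values over the
    corresponding set (one column); ``both`` produces two columns (or their
    difference with ``both_as_difference``); ``dp`` behaves like ``both``
    over the DP-selected sets.  In correlation weighting each value is
    multiplied by its training-fold correlation with the outcome.  An empty
    selected set yields a zero column.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    n_feat = X.shape[1]
    for idx in (positive_idx, negative_idx):
        if idx.size and (idx.min() < 0 or idx.max() >= n_feat):
            raise IndexError("selected feature index out of range")
    if config.weighting == "correlation":
        if weights is None:
            raise ValueError("correlation weighting requires the training weights")
        W = np.asarray(weights, dtype=float)
        vals = X * W
    else:
        vals = X

    def _sum(idx):
        if idx.size == 0:
            return np.zeros(X.shape[0])
        return vals[:, idx].sum(axis=1)

    if config.selection == "positive":
        return _sum(positive_idx)[:, None]
    if config.selection == "negative":
        return _sum(negative_idx)[:, None]
    # both / dp
    pos, neg = _sum(positive_idx), _sum(negative_idx)
    if config.both_as_difference:
        return (pos - neg)[:, None]
    return np.column_stack([pos, neg])


def _strength_names(config: ModelConfig) -> list[str]:
    if config.selection == "positive":
        return ["strength_pos"]
    if config.selection == "negative":
        return ["strength_neg"]
    if config.both_as_difference:
        return ["strength_pos_minus_neg"]
    return ["strength_pos", "strength_neg"]


def fit_second_stage(
    strengths: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None,
    config: ModelConfig,
    covariate_names: list[str] | None = None,
    positive_idx: np.ndarray | None = None,
    negative_idx: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> PredictiveModelFit:
    """Second-stage regression of the outcome on the strength score(s).

    ``predictors`` mode appends the covariates to the design; ``nuisance``
    mode estimates outcome~covariates and strength~covariates on the
    training data, residualizes both, and fits the residual regression.
    """
    S = np.atleast_2d(np.asarray(strengths, dtype=float))
    if S.shape[0] == 1 and S.shape[1] != len(_strength_names(config)):
        S = S.T
    y = np.asarray(outcome, dtype=float).ravel()
    n = y.size
    s_names = _strength_names(config)
    cov_names = covariate_names or (
        [f"cov{i}" for i in range(covariates.shape[1])] if covariates is not None else []
    )
    # drop strength columns that are identically zero (empty selection)
    live = np.linalg.norm(S - S.mean(axis=0), axis=0) > 1e-12
    empty = not live.all()
    if empty:
        logger.warning("fit_second_stage: empty/degenerate strength column(s) "
                       "%s dropped; fold reduces to intercept(+covariates)",
                       [s_names[j] for j in range(S.shape[1]) if not live[j]])
    S_live = S[:, live]
    live_names = [nm for nm, keep in zip(s_names, live) if keep]

    nuis_y = nuis_s = None
    if config.covariate_mode == "nuisance" and covariates is not None:
        Z = _with_intercept(covariates, n)
        _check_full_rank(Z, ["intercept"] + cov_names)
        nuis_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
        nuis_s, *_ = np.linalg.lstsq(Z, S, rcond=None)
        y_fit = y - Z @ nuis_y
        S_fit = (S - Z @ nuis_s)[:, live]
        design = _with_intercept(S_fit, n)
        names = ["intercept"] + live_names
    elif config.covariate_mode == "predictors" and covariates is not None:
        design = np.hstack([_with_intercept(S_live, n), covariates])
        names = ["intercept"] + live_names + cov_names
        y_fit = y
    else:
        design = _with_intercept(S_live, n)
        names = ["intercept"] + live_names
        y_fit = y
    _check_full_rank(design, names)
    coefs, *_ = np.linalg.lstsq(design, y_fit, rcond=None)
    # re-inflate dropped strength coefficients as exact zeros
    full_names = (["intercept"] + s_names
                  + (cov_names if config.covariate_mode == "predictors" else []))
    full = np.zeros(len(full_names))
    pos = {nm: j for j, nm in enumerate(names)}
    for j, nm in enumerate(full_names):
        if nm in pos:
            full[j] = coefs[pos[nm]]
    return PredictiveModelFit(
        positive_idx=np.asarray(positive_idx if positive_idx is not None else [], int),
        negative_idx=np.asarray(negative_idx if negative_idx is not None else [], int),
        weights=weights,
        second_stage_coefs=full,
        coef_names=full_names,
        nuisance_coefs_y=nuis_y,
        nuisance_coefs_s=nuis_s,
        config=config,
        empty_selection=empty,
    )


def fit_model(
    train_features: np.ndarray,
    train_cohort: pd.DataFrame,
    config: ModelConfig,
    dp_result: DPResult | None = None,
) -> PredictiveModelFit:
    """First stage + strength + second stage on one training set."""
    y = outcome_vector(train_cohort, config)
    C, cov_names = build_covariates(train_cohort, config)
    pos, neg, r = select_features(train_features, y, C, config, dp_result=dp_result)
    w = r if config.weighting == "correlation" else None
    S = strength(train_features, pos, neg, config, weights=w)
    return fit_second_stage(
        S, y, C, config, covariate_names=cov_names,
        positive_idx=pos, negative_idx=neg, weights=w,
    )


def predict(
    fit: PredictiveModelFit,
    test_features: np.ndarray,
    test_cohort: pd.DataFrame | None = None,
    nuisance_source: str = "train",
    test_outcome: np.ndarray | None = None,
) -> np.ndarray:
    """Predict outcomes for test subjects from a fitted model.

    In nuisance mode, ``nuisance_source="train"`` residualizes the test
    strengths with the training coefficients and adds the training-estimated
    nuisance effects back; ``"test"`` estimates nuisance effects on the test
    set itself (requires more than one test subject and the observed test
    outcomes, as in external validation).
    """
    config = fit.config
    X = np.atleast_2d(np.asarray(test_features, dtype=float))
    S = strength(X, fit.positive_idx, fit.negative_idx, config, weights=fit.weights)
    n = S.shape[0]
    s_names = _strength_names(config)
    coef = dict(zip(fit.coef_names, fit.second_stage_coefs))

    if config.covariate_mode == "none" or not config.covariates:
        design = _with_intercept(S, n)
        return design @ np.array([coef["intercept"]] + [coef[nm] for nm in s_names])

    if test_cohort is None:
        raise ValueError("covariate scheme active but no test covariates given")
    C, cov_names = build_covariates(test_cohort, config)

    if config.covariate_mode == "predictors":
        design = np.hstack([_with_intercept(S, n), C])
        order = ["intercept"] + s_names + cov_names
        return design @ np.array([coef[nm] for nm in order])

    # nuisance mode
    Z = _with_intercept(C, n)
    if nuisance_source == "train":
        nuis_y, nuis_s = fit.nuisance_coefs_y, fit.nuisance_coefs_s
    elif nuisance_source == "test":
        if n < 2:
            raise ValueError(
                "cannot estimate nuisance effects from a single test subject; "
                "use nuisance_source='train'"
            )
        if test_outcome is None:
            raise ValueError(
                "nuisance_source='test' needs the observed test outcomes to "
                "estimate the test-set nuisance effects"
            )
        y_test = np.asarray(test_outcome, dtype=float).ravel()
        nuis_y, *_ = np.linalg.lstsq(Z, y_test, rcond=None)
        nuis_s, *_ = np.linalg.lstsq(Z, S, rcond=None)
    else:
        raise ValueError(f"unknown nuisance_source {nuisance_source!r}")
    S_resid = S - Z @ nuis_s
    beta = np.array([coef["intercept"]] + [coef[nm] for nm in s_names])
    yhat_resid = _with_intercept(S_resid, n) @ beta
    return yhat_resid + Z @ nuis_y  # add nuisance effects back


def _report(
    observed: np.ndarray,
    predicted: np.ndarray,
    config: ModelConfig,
    n_boot: int,
    seed,
    **kwargs,
) -> PredictionReport:
    ms = _metrics.compute_metrics(observed, predicted)
    rng = np.random.default_rng(seed)
    ci_mae = _metrics.bootstrap_ci(observed, predicted, "mae", n_boot=n_boot, seed=rng)
    ci_r = _metrics.bootstrap_ci(observed, predicted, "r", n_boot=n_boot, seed=rng)
    ci_r2 = _metrics.bootstrap_ci(observed, predicted, "r2", n_boot=n_boot, seed=rng)
    return PredictionReport(
        observed=observed, predicted=predicted,
        mae=ms.mae, r=ms.r, r2=ms.r2,
        ci_mae=ci_mae, ci_r=ci_r, ci_r2=ci_r2,
        config=config, **kwargs,
    )


def loo_cv(
    dataset_features: np.ndarray,
    cohort: pd.DataFrame,
    config: ModelConfig,
    dp_result: DPResult | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> PredictionReport:
    """Leave-one-out cross-validation.

    For every subject, selection, strength summarization and the second
    stage are re-fit on the remaining n-1 subjects and the held-out subject
    is predicted (training-set nuisance coefficients).  Selection
    frequencies across folds support the >= 50%-of-folds reporting rule.
    """
    X = np.asarray(dataset_features, dtype=float)
    n, n_feat = X.shape
    if n < 10:
        raise ValueError("leave-one-out needs at least 10 subjects")
    y_all = outcome_vector(cohort, config)
    predicted = np.empty(n)
    count_pos = np.zeros(n_feat)
    count_neg = np.zeros(n_feat)
    count_used = np.zeros(n_feat)
    flagged = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fit = fit_model(X[mask], cohort.iloc[mask], config, dp_result=dp_result)
        predicted[i] = predict(
            fit, X[i: i + 1], cohort.iloc[[i]], nuisance_source="train"
        )[0]
        count_pos[fit.positive_idx] += 1
        count_neg[fit.negative_idx] += 1
        if config.selection == "positive":
            count_used[fit.positive_idx] += 1
        elif config.selection == "negative":
            count_used[fit.negative_idx] += 1
        else:
            count_used[fit.positive_idx] += 1
            count_used[fit.negative_idx] += 1
        if fit.empty_selection:
            flagged.append(i)
    if flagged:
        logger.warning("loo_cv: %d fold(s) had an empty selected set: %s",
                       len(flagged), flagged)
    seed = config.seed if seed is None else seed
    return _report(
        y_all, predicted, config, n_boot, seed,
        selection_frequency=count_used / n,
        frequency_positive=count_pos / n,
        frequency_negative=count_neg / n,
        flagged_folds=flagged,
    )


def external_validation(
    train_features: np.ndarray,
    train_cohort: pd.DataFrame,
    test_features: np.ndarray,
    test_cohort: pd.DataFrame,
    config: ModelConfig,
    dp_result: DPResult | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    nuisance_source: str = "test",
) -> PredictionReport:
    """Train on one dataset, predict every subject of the other.

    Feature spaces must match (same parcellation or vertex mask).  With the
    nuisance covariate scheme, test-set nuisance effects are by default
    estimated from the test set itself; pass ``nuisance_source="train"`` to
    carry the training coefficients over instead.  Either direction (A->B
    or B->A) is supported symmetrically.
    """
    Xtr = np.asarray(train_features, dtype=float)
    Xte = np.atleast_2d(np.asarray(test_features, dtype=float))
    if Xtr.shape[1] != Xte.shape[1]:
        raise ValueError(
            f"feature-space mismatch: train has {Xtr.shape[1]} features, "
            f"test has {Xte.shape[1]}"
        )
    fit = fit_model(Xtr, train_cohort, config, dp_result=dp_result)
    y_test = outcome_vector(test_cohort, config)
    predicted = predict(
        fit, Xte, test_cohort,
        nuisance_source=nuisance_source if config.covariate_mode == "nuisance" else "train",
        test_outcome=y_test,
    )
    seed = config.seed if seed is None else seed
    sel = np.zeros(Xtr.shape[1])
    if config.selection == "positive":
        sel[fit.positive_idx] = 1.0
    elif config.selection == "negative":
        sel[fit.negative_idx] = 1.0
    else:
        sel[fit.positive_idx] = 1.0
        sel[fit.negative_idx] = 1.0
    return _report(
        y_test, predicted, config, n_boot, seed,
        selection_frequency=sel,
        flagged_folds=[0] if fit.empty_selection else [],
    )
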