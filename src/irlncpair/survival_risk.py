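"""Cox modelling, riskscore construction, stratification and evaluation.

The model-selection flow mirrors the signature-building recipe: univariate
Cox on each pair indicator (keep p < 0.05), LASSO-penalized Cox to narrow
the candidates (lambda by 10-fold cross-validated partial-likelihood
deviance), a joint multivariate Cox fit, and a final model of the
multivariate-significant pairs. The riskscore of a sample is

    riskscore = sum_i coef_i * indicator_i,

with coef_i the multivariate Cox coefficients; samples are split into
high/low risk at the median score (or at the Youden-optimal cutoff of a
time-dependent ROC). Separation is tested by the two-group log-rank test,
and discrimination at 1/2/3 years by cumulative-case/dynamic-control
time-dependent ROC curves with Kaplan-Meier-based censoring weights.

Partial-likelihood fits use Efron tie handling (lifelines) by default; a
Breslow Newton-Raphson solver is provided both as a switchable alternative
and as an independent check in the tests.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats

from .errors import (
    DegeneratePredictorError,
    DegenerateStratificationError,
    SingularInformationError,
    ValidationError,
)
from .expression_io import ClinicalTable
from .pair_encoding import PairMatrix

#: z for 95% CIs, fixed so printed-table arithmetic reproduces to 3 dp.
Z95 = 1.959964

HIGH, LOW = "high", "low"


@dataclass(frozen=True)
class CoxFit:
    """One fitted Cox coefficient with Wald statistics."""

    variable: str
    beta: float
    se: float
    hr: float
    hr_lo: float
    hr_hi: float
    p: float

    def __post_init__(self):
        if self.se <= 0:
            raise ValidationError(f"{self.variable}: se must be > 0")


def _safe_exp(v: float) -> float:
    try:
        return math.exp(v)
    except OverflowError:  # divergent fit (e.g. a separated predictor)
        return math.inf


def hazard_ratio_from_fit(beta: float, se: float = 1.0) -> tuple[float, float, float]:
    """exp-transform (beta, se) -> (HR, HR 95% lower, HR 95% upper)."""
    return (
        _safe_exp(beta),
        _safe_exp(beta - Z95 * se),
        _safe_exp(beta + Z95 * se),
    )


def _coxfit(variable: str, beta: float, se: float) -> CoxFit:
    hr, lo, hi = hazard_ratio_from_fit(beta, se)
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return CoxFit(variable, beta, se, hr, lo, hi, p)


def coxfits_to_frame(fits: list[CoxFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(f.variable, f.beta, f.se, f.hr, f.hr_lo, f.hr_hi, f.p) for f in fits],
        columns=["variable", "beta", "se", "hr", "hr_lo", "hr_hi", "p"],
    )


# -- partial likelihood helpers ----------------------------------------


def breslow_loglik(
    beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow-approximation log partial likelihood (used for CV deviance
    and as an independent oracle for the Cox fitters)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = X @ beta
    order = np.argsort(-time, kind="stable")  # decreasing time
    eta_o, ev_o, t_o = eta[order], event[order], time[order]
    log_cumsum = np.logaddexp.accumulate(eta_o)
    ll = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j < n and t_o[j] == t_o[i]:
            j += 1
        # risk set for this time = subjects with time >= t (indices 0..j-1)
        d_idx = [k for k in range(i, j) if ev_o[k] == 1]
        if d_idx:
            ll += eta_o[d_idx].sum() - len(d_idx) * log_cumsum[j - 1]
        i = j
    return float(ll)


def breslow_newton(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton-Raphson maximum partial likelihood with Breslow ties.

    Returns (beta_hat, covariance); covariance is the inverse observed
    information at the maximum.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    order = np.argsort(-time, kind="stable")
    Xo, ev_o, t_o = X[order], event[order], time[order]
    for _ in range(max_iter):
        eta = Xo @ beta
        w = np.exp(eta)
        S0 = np.cumsum(w)
        S1 = np.cumsum(w[:, None] * Xo, axis=0)
        S2 = np.cumsum(w[:, None, None] * (Xo[:, :, None] * Xo[:, None, :]), axis=0)
        grad = np.zeros(p)
        info = np.zeros((p, p))
        i = 0
        while i < n:
            j = i
            while j < n and t_o[j] == t_o[i]:
                j += 1
            d_idx = [k for k in range(i, j) if ev_o[k] == 1]
            if d_idx:
                d = len(d_idx)
                s0, s1, s2 = S0[j - 1], S1[j - 1], S2[j - 1]
                grad += Xo[d_idx].sum(axis=0) - d * s1 / s0
                info += d * (s2 / s0 - np.outer(s1, s1) / s0**2)
            i = j
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SingularInformationError(
                [f"x{k}" for k in range(p)], f"singular information matrix: {exc}"
            ) from exc
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    cov = np.linalg.inv(info)
    return beta, cov


def _surv_arrays(surv: ClinicalTable, samples) -> tuple[np.ndarray, np.ndarray]:
    df = surv.data.loc[list(samples)]
    return df["os_time"].to_numpy(float), df["os_event"].to_numpy(int)


def _check_collinearity(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    centered = arr - arr.mean(axis=0)
    if np.linalg.matrix_rank(centered) < X.shape[1]:
        corr = np.corrcoef(centered, rowvar=False)
        offenders = set()
        p = X.shape[1]
        for i in range(p):
            for j in range(i + 1, p):
                if abs(corr[i, j]) > 1 - 1e-10:
                    offenders.update((X.columns[i], X.columns[j]))
        raise SingularInformationError(sorted(offenders) or list(X.columns))


def _fit_cox(
    X: pd.DataFrame, time: np.ndarray, event: np.ndarray, ties: str
) -> list[CoxFit]:
    if event.sum() < 2:
        raise ValidationError("need at least two events to fit a Cox model")
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise DegeneratePredictorError(f"predictor {col!r} is constant")
    _check_collinearity(X)
    if ties == "efron":
        df = X.copy()
        df["__time"], df["__event"] = time, event
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="__time", event_col="__event")
        betas = cph.params_
        ses = cph.standard_errors_
        return [_coxfit(c, float(betas[c]), float(ses[c])) for c in X.columns]
    if ties == "breslow":
        beta, cov = breslow_newton(X.to_numpy(float), time, event)
        se = np.sqrt(np.diag(cov))
        return [
            _coxfit(c, float(b), float(s)) for c, b, s in zip(X.columns, beta, se)
        ]
    raise ValidationError(f"unknown tie-handling method {ties!r}")


def cox_univariate(
    x: pd.Series, surv: ClinicalTable, name: str | None = None, ties: str = "efron"
) -> CoxFit:
    """Univariate Cox proportional-hazards fit of one indicator/covariate."""
    x = pd.Series(x)
    name = name or (x.name if x.name is not None else "x")
    time, event = _surv_arrays(surv, x.index)
    X = pd.DataFrame({str(name): x.to_numpy(float)})
    return _fit_cox(X, time, event, ties)[0]


def cox_multivariate(
    X: pd.DataFrame, surv: ClinicalTable, ties: str = "efron"
) -> list[CoxFit]:
    """Joint Cox fit; one CoxFit per column of the design matrix ``X``
    (rows = samples)."""
    time, event = _surv_arrays(surv, X.index)
    return _fit_cox(X.astype(float), time, event, ties)


# -- LASSO-Cox selection ------------------------------------------------


@dataclass
class LassoResult:
    selected: list[str]
    coefs: pd.Series  # nonzero coefficients at lambda_min
    alphas: np.ndarray
    coef_path: pd.DataFrame  # pairs x alphas
    cv_deviance: np.ndarray
    alpha_min: float


def lasso_cox_select(
    pm: PairMatrix,
    surv: ClinicalTable,
    n_folds: int = 10,
    seed: int = 0,
    alphas: np.ndarray | None = None,
) -> LassoResult:
    """L1-penalized Cox over a log-spaced lambda grid; lambda chosen by
    cross-validated partial-likelihood deviance (lambda_min)."""
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    X = pm.indicators.T.to_numpy(float)
    labels = pm.labels
    time, event = _surv_arrays(surv, pm.samples)
    if event.sum() < n_folds:
        raise ValidationError("need at least n_folds events for CV")
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    def make_model(a=None):
        kw = dict(l1_ratio=1.0, fit_baseline_model=False)
        if a is None:
            kw.update(n_alphas=50, alpha_min_ratio=0.01)
        else:
            kw.update(alphas=list(a))
        return CoxnetSurvivalAnalysis(**kw)

    path_model = make_model(alphas)
    path_model.fit(X, y)
    grid = np.asarray(path_model.alphas_)
    coef_path = pd.DataFrame(path_model.coef_, index=labels, columns=grid)

    rng = np.random.default_rng(seed)
    n = len(time)
    fold_of = np.repeat(np.arange(n_folds), math.ceil(n / n_folds))[:n]
    fold_of = fold_of[rng.permutation(n)]
    cv_dev = np.zeros(len(grid))
    for k in range(n_folds):
        tr = fold_of != k
        m = make_model(grid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(X[tr], Surv.from_arrays(event=event[tr].astype(bool), time=time[tr]))
        # the solver may truncate the requested path; align by alpha value
        fold_alphas = np.asarray(m.alphas_)
        for a_i in range(len(grid)):
            col = int(np.argmin(np.abs(fold_alphas - grid[a_i])))
            beta = m.coef_[:, col]
            # Verweij-van Houwelingen: full-data minus training contribution
            dev = -2.0 * (
                breslow_loglik(beta, X, time, event)
                - breslow_loglik(beta, X[tr], time[tr], event[tr])
            )
            cv_dev[a_i] += dev
    best = int(np.argmin(cv_dev))
    alpha_min = float(grid[best])
    final = make_model(grid)
    final.fit(X, y)
    coefs = pd.Series(final.coef_[:, best], index=labels)
    nz = coefs[coefs != 0.0]
    if nz.empty:
        warnings.warn("LASSO selected no pairs at lambda_min", stacklevel=2)
    return LassoResult(list(nz.index), nz, grid, coef_path, cv_dev, alpha_min)


# -- riskscore, stratification, evaluation ------------------------------


@dataclass
class RiskModel:
    """Selected pairs (display-oriented labels) with Cox coefficients."""

    pairs: list[str]
    coefs: list[float]

    def __post_init__(self):
        if len(self.pairs) != len(self.coefs):
            raise ValidationError("pairs and coefs must have the same length")

    def to_json(self, path, cutoff: float | None = None, cutoff_rule: str | None = None):
        payload = {"pairs": self.pairs, "coefs": self.coefs}
        if cutoff is not None:
            payload.update(cutoff=cutoff, cutoff_rule=cutoff_rule)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @staticmethod
    def from_json(path) -> "RiskModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return RiskModel(payload["pairs"], payload["coefs"])


def risk_score(model: RiskModel, pm: PairMatrix) -> pd.Series:
    """Per-sample riskscore = sum(coef_i * indicator_i), reconciling any
    display-flipped pair labels against the canonical pair matrix."""
    score = pd.Series(0.0, index=pm.samples, name="riskscore")
    for label, coef in zip(model.pairs, model.coefs):
        score = score + coef * pm.indicator_for(label).astype(float)
    return score


def stratify(
    scores: pd.Series,
    rule: str = "median",
    horizon: float | None = None,
    surv: ClinicalTable | None = None,
) -> pd.DataFrame:
    """Assign high/low risk groups. ``median``: cutoff at the median score,
    high iff score > cutoff (ties go low, so heavily tied scores may split
    unevenly). ``roc_optimal``: Youden-optimal cutoff of the time-dependent
    ROC at ``horizon`` (requires survival data)."""
    scores = pd.Series(scores)
    if scores.empty:
        raise ValidationError("no scores to stratify")
    if scores.nunique() == 1:
        raise DegenerateStratificationError("all riskscores identical")
    if rule == "median":
        cutoff = float(np.median(scores))
    elif rule == "roc_optimal":
        if horizon is None or surv is None:
            raise ValidationError("roc_optimal needs horizon and survival data")
        roc = time_roc(scores, surv, horizon)
        cutoff = roc.cutoff_star
    else:
        raise ValidationError(f"unknown stratification rule {rule!r}")
    group = np.where(scores > cutoff, HIGH, LOW)
    return pd.DataFrame(
        {
            "riskscore": scores,
            "group": group,
            "cutoff": cutoff,
            "cutoff_rule": rule,
        },
        index=scores.index,
    )


def km_logrank(
    assign: pd.DataFrame, surv: ClinicalTable
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per risk group plus the log-rank test.

    Returns ({group: DataFrame(time, survival)}, chi_sq, p); the two-group
    statistic is on 1 df.
    """
    groups = assign["group"]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValidationError("log-rank needs at least two groups")
    time, event = _surv_arrays(surv, assign.index)
    if event.sum() < 1:
        raise ValidationError("log-rank needs at least one event")
    curves = {}
    for level in levels:
        mask = (groups == level).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=str(level))
        sf = kmf.survival_function_
        curves[level] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    if len(levels) == 2:
        m0 = (groups == levels[0]).to_numpy()
        res = logrank_test(time[m0], time[~m0], event[m0], event[~m0])
    else:
        res = multivariate_logrank_test(time, groups.to_numpy(), event)
    return curves, float(res.test_statistic), float(res.p_value)


# -- time-dependent ROC -------------------------------------------------


@dataclass
class TimeROC:
    horizon: float
    fpr: np.ndarray
    tpr: np.ndarray
    cutoffs: np.ndarray
    auc: float
    cutoff_star: float
    estimator: str = "km"


def _km_survfun(time, event):
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    return kmf


def time_roc(
    scores: pd.Series,
    surv: ClinicalTable,
    horizon: float,
    estimator: str = "km",
) -> TimeROC:
    """Cumulative-case / dynamic-control ROC at ``horizon``.

    ``km`` (default): case and control probabilities from Kaplan-Meier
    estimates within the score-defined subsets (conditional-KM
    construction). ``ipcw``: inverse-probability-of-censoring weighted
    cases (weights 1/G(T-)) with unweighted dynamic controls. Both reduce
    to the empirical ROC — and the AUC to the Mann-Whitney statistic of
    scores against event-by-horizon labels — when there is no censoring
    before the horizon.
    """
    scores = pd.Series(scores)
    time, event = _surv_arrays(surv, scores.index)
    if horizon <= 0 or horizon > time.max():
        raise ValidationError("horizon must lie within follow-up range")
    if ((time <= horizon) & (event == 1)).sum() < 1:
        raise ValidationError("no events before horizon")
    x = scores.to_numpy(float)
    cutpoints = np.unique(x)
    # evaluate at thresholds between observed scores (and extremes)
    thresholds = np.concatenate(([-np.inf], cutpoints))
    if estimator == "km":
        tpr, fpr = _roc_km(x, time, event, horizon, thresholds)
    elif estimator == "ipcw":
        tpr, fpr = _roc_ipcw(x, time, event, horizon, thresholds)
    else:
        raise ValidationError(f"unknown time-ROC estimator {estimator!r}")
    # integrate along the staircase in descending-threshold order
    # (ascending fpr); signed trapezoid absorbs numerical jitter
    order = np.argsort(-thresholds)
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    youden = tpr - fpr
    best = int(np.argmax(youden))
    cutoff_star = float(thresholds[best]) if np.isfinite(thresholds[best]) else float(
        cutpoints[0]
    )
    return TimeROC(horizon, fpr, tpr, thresholds, auc, cutoff_star, estimator)


def _roc_km(x, time, event, horizon, thresholds):
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, c in enumerate(thresholds):
        hi = x > c
        p_hi = hi.mean()
        s_hi = _cond_surv(time[hi], event[hi], horizon) if hi.any() else 1.0
        s_lo = _cond_surv(time[~hi], event[~hi], horizon) if (~hi).any() else 1.0
        s_all = p_hi * s_hi + (1 - p_hi) * s_lo
        f_all = 1.0 - s_all
        tpr[i] = p_hi * (1.0 - s_hi) / f_all if f_all > 0 else 0.0
        fpr[i] = p_hi * s_hi / s_all if s_all > 0 else 0.0
    return tpr, fpr


def _cond_surv(time, event, horizon) -> float:
    if len(time) == 0:
        return 1.0
    kmf = _km_survfun(time, event)
    return float(kmf.predict(horizon))


def _roc_ipcw(x, time, event, horizon, thresholds):
    # censoring survival G from the reversed KM
    kmf_c = KaplanMeierFitter()
    kmf_c.fit(time, 1 - event)
    case = (time <= horizon) & (event == 1)
    with np.errstate(divide="ignore"):
        g_at = np.array([float(kmf_c.predict(t - 1e-9)) for t in time])
    w = np.where(case & (g_at > 0), 1.0 / np.where(g_at > 0, g_at, 1.0), 0.0)
    ctrl = time > horizon
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    wsum = w.sum()
    csum = ctrl.sum()
    for i, c in enumerate(thresholds):
        hi = x > c
        tpr[i] = (w * hi).sum() / wsum if wsum > 0 else 0.0
        fpr[i] = (hi & ctrl).sum() / csum if csum > 0 else 0.0
    return tpr, fpr


# -- clinical Cox -------------------------------------------------------

_FACTOR_REFS = {
    "sex": "Female",
    "tobacco": "No",
    "alcohol": "No",
    "t_stage": "T1",
    "n_stage": "N0",
    "tnm_stage": "Stage I",
    "grade": "Well",
}


def clinical_design(
    surv: ClinicalTable, age_cut: float = 60.0
) -> dict[str, pd.DataFrame]:
    """Per-factor indicator contrasts against stated reference levels;
    age dichotomized at ``age_cut``."""
    df = surv.data
    blocks: dict[str, pd.DataFrame] = {}
    if "age" in df.columns:
        blocks["age"] = pd.DataFrame(
            {f"age>={age_cut:g}": (df["age"] >= age_cut).astype(float)}
        )
    for col, ref in _FACTOR_REFS.items():
        if col not in df.columns:
            continue
        vals = df[col].dropna()
        if ref not in set(vals):
            raise ValidationError(f"reference level {ref!r} absent for {col!r}")
        levels = [lv for lv in dict.fromkeys(vals) if lv != ref]
        block = pd.DataFrame(index=df.index)
        for lv in sorted(levels):
            block[f"{col}:{lv}"] = (df[col] == lv).astype(float)
        blocks[col] = block
    return blocks


def cox_clinical(
    surv: ClinicalTable,
    riskscore: pd.Series,
    ties: str = "efron",
    age_cut: float = 60.0,
) -> dict[str, list[CoxFit]]:
    """Univariate (per clinical factor, and riskscore alone) and
    multivariate (all factors + riskscore) Cox fits."""
    blocks = clinical_design(surv, age_cut=age_cut)
    riskscore = pd.Series(riskscore).loc[surv.samples]
    out: dict[str, list[CoxFit]] = {"univariate": [], "multivariate": []}
    for name, block in blocks.items():
        X = block.set_axis(surv.samples, axis=0)
        out["univariate"].extend(cox_multivariate(X, surv, ties=ties))
    out["univariate"].append(
        cox_univariate(riskscore, surv, name="riskscore", ties=ties)
    )
    full = pd.concat(
        [b.set_axis(surv.samples, axis=0) for b in blocks.values()], axis=1
    )
    full["riskscore"] = riskscore.to_numpy(float)
    out["multivariate"] = cox_multivariate(full, surv, ties=ties)
    return out
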