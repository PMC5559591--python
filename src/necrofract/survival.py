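"""Survival stratification by dichotomized fractal features.

Machinery: Kaplan-Meier product-limit curves, two-group log-rank tests,
and Cox proportional-hazards models (Efron tie handling, Wald CIs and
p-values), run univariately for each dichotomized covariate and
multivariately with the clinical covariates plus one fractal indicator at
a time — FD and lacunarity are strongly anticorrelated, so they enter
separate adjusted models rather than one joint model.

Published cutoffs (defaults): FD < 1.56 and lacunarity > 0.46 define the
high-risk groups; age >= 50 years, KPS < 80, volume >= 50 cm^3 and
subtotal resection define the clinical risk indicators. Inequalities are
strict exactly as printed, so boundary values fall in the low-risk group
for the fractal features. No multiplicity adjustment is applied.

Estimation is delegated to lifelines; the Efron partial log-likelihood is
also exposed directly (:func:`cox_partial_loglik`) so fits can be checked
against brute-force likelihood maximization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from necrofract.errors import ConvergenceError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "RISK_INDICATORS",
    "HazardFit",
    "KMEstimate",
    "dichotomize_cohort",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_partial_loglik",
    "univariate_table",
    "multivariate_table",
]

#: dichotomized covariates in the univariate-table row order
RISK_INDICATORS = (
    "age_high",
    "kps_low",
    "vol_high",
    "subtotal_resection",
    "rt_tmz",
    "fd_low",
    "lac_high",
)

_CLINICAL_ADJUSTERS = ("age_high", "kps_low", "vol_high", "subtotal_resection", "rt_tmz")

_ENDPOINT_COLS = {"pfs": ("pfs_time", "pfs_event"), "os": ("os_time", "os_event")}


@dataclass
class HazardFit:
    """One fitted proportional-hazards model.

    ``table`` is indexed by covariate with columns ``coef``, ``hr``,
    ``ci_lower``, ``ci_upper``, ``p``.
    """

    endpoint: str
    covariates: tuple[str, ...]
    table: pd.DataFrame
    ties: str = "efron"
    n: int = 0
    n_events: int = 0
    log_likelihood: float = field(default=float("nan"))


def dichotomize_cohort(
    records: pd.DataFrame,
    fd_cut: float = 1.56,
    lac_cut: float = 0.46,
    age_cut: float = 50.0,
    kps_cut: float = 80.0,
    vol_cut: float = 50.0,
) -> pd.DataFrame:
    """Add binary risk indicators at the published cutoffs.

    Records missing a needed covariate are excluded with a log entry.
    """
    needed = ["age", "kps", "volume_cm3", "gtr_flag", "rt_tmz_flag", "fd", "lacunarity"]
    missing_cols = [c for c in needed if c not in records.columns]
    if missing_cols:
        raise ParameterError(f"cohort lacks columns: {missing_cols}")
    df = records.copy()
    bad = df[needed].isna().any(axis=1)
    if bad.any():
        for pid in df.loc[bad, "patient_id"] if "patient_id" in df else df.index[bad]:
            logger.warning("excluding record %s: missing covariate", pid)
        df = df.loc[~bad].copy()
    df["fd_low"] = (df["fd"] < fd_cut).astype(int)
    df["lac_high"] = (df["lacunarity"] > lac_cut).astype(int)
    df["age_high"] = (df["age"] >= age_cut).astype(int)
    df["kps_low"] = (df["kps"] < kps_cut).astype(int)
    df["vol_high"] = (df["volume_cm3"] >= vol_cut).astype(int)
    df["subtotal_resection"] = (~df["gtr_flag"].astype(bool)).astype(int)
    df["rt_tmz"] = df["rt_tmz_flag"].astype(bool).astype(int)
    return df


class KMEstimate:
    """Kaplan-Meier product-limit curve, evaluable as a right-continuous step function."""

    def __init__(self, times: np.ndarray, events: np.ndarray):
        times = np.asarray(times, float)
        events = np.asarray(events, bool)
        if times.size == 0:
            raise ParameterError("empty survival input")
        if times.size != events.size:
            raise ParameterError("times and events must have equal length")
        if (times <= 0).any():
            raise ParameterError("survival times must be > 0")
        fitter = KaplanMeierFitter()
        fitter.fit(times, events)
        sf = fitter.survival_function_
        self.step_times = sf.index.to_numpy(float)
        self.step_values = sf.iloc[:, 0].to_numpy(float)
        self._fitter = fitter

    def __call__(self, t: float | np.ndarray) -> np.ndarray | float:
        t = np.asarray(t, float)
        idx = np.searchsorted(self.step_times, t, side="right") - 1
        out = np.where(idx >= 0, self.step_values[np.maximum(idx, 0)], 1.0)
        return float(out) if out.ndim == 0 else out


def km_estimate(times, events) -> KMEstimate:
    """Product-limit survival estimate S(t); S(0) = 1, steps at event times."""
    return KMEstimate(np.asarray(times), np.asarray(events))


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its upper-tail p-value."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    group = np.asarray(group).astype(bool)
    if not group.any() or group.all():
        raise ParameterError("both groups must be non-empty")
    res = _ll_logrank(times[group], times[~group], events[group], events[~group])
    return float(res.test_statistic), float(res.p_value)


def cox_partial_loglik(
    times: np.ndarray,
    events: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
) -> float:
    """Efron partial log-likelihood — the objective every Cox fit here maximizes.

    Implemented directly (not via lifelines) so fitted coefficients can be
    validated against brute-force maximization of this function.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != times.size:
        X = X.T
    beta = np.atleast_1d(np.asarray(beta, float))
    eta = X @ beta
    theta = np.exp(eta)
    ll = 0.0
    for t in np.unique(times[events]):
        deaths = events & (times == t)
        at_risk = times >= t
        d = int(deaths.sum())
        sum_risk = theta[at_risk].sum()
        sum_dead = theta[deaths].sum()
        ll += eta[deaths].sum()
        for ell in range(d):
            ll -= np.log(sum_risk - (ell / d) * sum_dead)
    return float(ll)


def cox_fit(
    records: pd.DataFrame,
    endpoint: str,
    covariates: list[str],
) -> HazardFit:
    """Fit a Cox proportional-hazards model for PFS or OS.

    Efron ties, Wald 95% CIs and p-values. Constant covariates and
    non-convergence raise errors naming the covariate.
    """
    if endpoint not in _ENDPOINT_COLS:
        raise ParameterError("endpoint must be 'pfs' or 'os'")
    time_col, event_col = _ENDPOINT_COLS[endpoint]
    cols = [time_col, event_col, *covariates]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ParameterError(f"cohort lacks columns: {missing}")
    df = records[cols].astype(float)
    if df[event_col].sum() < 2:
        raise ParameterError("need at least 2 events to fit a Cox model")
    for cov in covariates:
        if df[cov].nunique() < 2:
            raise ParameterError(f"covariate {cov!r} is constant; model is degenerate")

    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col=time_col, event_col=event_col)
    except (_LLConvergenceError, Warning) as exc:
        raise ConvergenceError(
            f"Cox fit failed for covariates {covariates}: {exc}"
        ) from exc
    summ = fitter.summary
    table = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hr": summ["exp(coef)"],
            "ci_lower": summ["exp(coef) lower 95%"],
            "ci_upper": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    ).loc[list(covariates)]
    return HazardFit(
        endpoint=endpoint,
        covariates=tuple(covariates),
        table=table,
        ties="efron",
        n=len(df),
        n_events=int(df[event_col].sum()),
        log_likelihood=float(fitter.log_likelihood_),
    )


def univariate_table(records: pd.DataFrame) -> pd.DataFrame:
    """One single-covariate Cox model per risk indicator and endpoint.

    Returns a tidy table (covariate, endpoint, p, hr, ci_lower, ci_upper,
    status); rows whose model is degenerate are marked ``failed`` rather
    than aborting the table. No multiplicity adjustment is applied.
    """
    rows = []
    for cov in RISK_INDICATORS:
        for endpoint in ("pfs", "os"):
            try:
                fit = cox_fit(records, endpoint, [cov])
                rec = fit.table.loc[cov]
                rows.append(
                    {
                        "covariate": cov,
                        "endpoint": endpoint,
                        "p": rec["p"],
                        "hr": rec["hr"],
                        "ci_lower": rec["ci_lower"],
                        "ci_upper": rec["ci_upper"],
                        "status": "ok",
                    }
                )
            except (ParameterError, ConvergenceError) as exc:
                logger.warning("univariate row %s/%s failed: %s", cov, endpoint, exc)
                rows.append(
                    {
                        "covariate": cov,
                        "endpoint": endpoint,
                        "p": np.nan,
                        "hr": np.nan,
                        "ci_lower": np.nan,
                        "ci_upper": np.nan,
                        "status": "failed",
                    }
                )
    return pd.DataFrame(rows)


def multivariate_table(records: pd.DataFrame, fractal_param: str) -> dict[str, HazardFit]:
    """Adjusted Cox models (both endpoints) for one fractal indicator.

    ``fractal_param`` is ``"fd"`` or ``"lacunarity"``; the model adjusts
    for the five clinical indicators.
    """
    indicator = {"fd": "fd_low", "lacunarity": "lac_high"}.get(fractal_param)
    if indicator is None:
        raise ParameterError("fractal_param must be 'fd' or 'lacunarity'")
    covariates = [*_CLINICAL_ADJUSTERS, indicator]
    return {endpoint: cox_fit(records, endpoint, covariates) for endpoint in ("pfs", "os")}
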