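"""Kaplan-Meier, log-rank and Cox proportional-hazards analysis by SMS stratum.

Three endpoints, all clocked from diagnosis:

* overall survival (OS): death from any cause;
* cancer-specific survival (CSS): cancer death, with non-cancer deaths
  treated as censoring (no competing-risks model);
* disease-free survival (DFS): first of recurrence or death.

Survival is reported over the strata {0, 1-3, 4}: intermediate scores do
not separate survival and are grouped.  Cox models handle tied event
times with the Efron approximation and code the grouped stratum
ordinally (0, 1, 2) by default; the continuous 0-4 score is available as
an alternative coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .errors import DegenerateInputError, FitError, ValidationError
from .outcomes import _SMOKING_CODE
from .scoring import STRATA

ENDPOINTS = ("os", "css", "dfs")


@dataclass
class KMEstimate:
    """Product-limit estimate with its event table."""

    times: np.ndarray  # ordered distinct event/censor times
    survival: np.ndarray  # S(t) just after each time
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "censored": self.censored,
                "survival": self.survival,
            }
        )


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator.

    At tied times events precede censorings (the censored subjects are
    still at risk for the tied event), the standard convention.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise DegenerateInputError("empty sample")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValidationError("survival times must be finite and positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    # lifelines prepends a t=0 row with no observations; drop it
    table = kmf.event_table[kmf.event_table.index > 0]
    grid = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    return KMEstimate(
        times=grid,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        censored=table["censored"].to_numpy(dtype=int),
    )


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(times, events, groups) -> LogrankResult:
    """K-sample log-rank test (observed minus expected chi-squared)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) < 2:
        raise DegenerateInputError("log-rank needs >= 2 groups")
    if e.sum() == 0:
        raise DegenerateInputError("log-rank needs at least one event")
    res = multivariate_logrank_test(t, g, e)
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=len(labels) - 1,
        p_value=float(res.p_value),
    )


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald CIs and fit diagnostics."""

    terms: pd.DataFrame  # index covariate; columns hazard_ratio, ci_low, ci_high, p_value
    partial_log_likelihood: float
    converged: bool


def cox_fit(frame: pd.DataFrame, duration_col: str, event_col: str, covariates) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties, Newton iteration).

    ``frame`` must contain numeric covariate columns.  Monotone partial
    likelihood (e.g. a covariate level with no events) surfaces as a
    convergence error.
    """
    covariates = list(covariates)
    data = frame[[duration_col, event_col, *covariates]].astype(float)
    if data[event_col].sum() == 0:
        raise DegenerateInputError("Cox fit needs at least one event")
    X = data[covariates].to_numpy()
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < len(covariates):
        raise FitError("Cox design is rank deficient")
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as exc:
        raise FitError(f"Cox fit did not converge: {exc}") from exc
    summ = cph.summary
    terms = pd.DataFrame(
        {
            "hazard_ratio": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "p_value": summ["p"],
        }
    )
    return CoxResult(
        terms=terms,
        partial_log_likelihood=float(cph.log_likelihood_),
        converged=True,
    )


# ---------------------------------------------------------------------------
# endpoint construction and the stratified analysis
# ---------------------------------------------------------------------------


def endpoint_columns(cohort: pd.DataFrame, endpoint: str) -> tuple[pd.Series, pd.Series]:
    """(time, event) for one endpoint from the cohort follow-up columns.

    DFS takes the earlier of recurrence and death; because both clocks are
    censored at the same follow-up time, the minimum of the two censored
    times is the correct DFS censoring time.
    """
    if endpoint == "os":
        return cohort["death_time_years"], cohort["death_event"].astype(bool)
    if endpoint == "css":
        return cohort["cancer_death_time_years"], cohort["cancer_death_event"].astype(bool)
    if endpoint == "dfs":
        t_rec = cohort["recurrence_time_years"].to_numpy(dtype=float)
        t_death = cohort["death_time_years"].to_numpy(dtype=float)
        e_rec = cohort["recurrence_event"].to_numpy(dtype=bool)
        e_death = cohort["death_event"].to_numpy(dtype=bool)
        t = np.minimum(t_rec, t_death)
        e = (e_rec & (t_rec <= t_death)) | (e_death & (t_death <= t_rec))
        return pd.Series(t, index=cohort.index), pd.Series(e, index=cohort.index)
    raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")


@dataclass
class StratifiedSurvival:
    endpoint: str
    curves: dict[str, KMEstimate]  # stratum label -> curve
    logrank: LogrankResult | None
    omitted_strata: tuple[str, ...]


def survival_by_sms(scored: pd.DataFrame, endpoint: str) -> StratifiedSurvival:
    """KM curves per SMS stratum {0, 1-3, 4} plus the log-rank comparison.

    Empty strata are omitted with a record; the log-rank test runs over
    the non-empty strata (None if fewer than two remain or no events).
    """
    time, event = endpoint_columns(scored, endpoint)
    strata = scored["sms_stratum"]
    curves: dict[str, KMEstimate] = {}
    omitted = []
    for label in STRATA:
        mask = (strata == label).to_numpy()
        if mask.sum() == 0:
            omitted.append(label)
            continue
        curves[label] = km_estimate(time[mask], event[mask])
    present = strata.isin(list(curves)).to_numpy()
    lr = None
    if len(curves) >= 2 and event[present].sum() > 0:
        lr = logrank_test(time[present], event[present], strata[present])
    return StratifiedSurvival(
        endpoint=endpoint, curves=curves, logrank=lr, omitted_strata=tuple(omitted)
    )


#: covariates of the default survival models (grouped-stratum SMS coding)
DEFAULT_SURVIVAL_COVARIATES = (
    "sms_group", "age_years", "sex_female", "smoking_code", "t_stage", "n_stage_pos", "tnt",
)

_STRATUM_CODE = {"0": 0, "1-3": 1, "4": 2}


def build_survival_design(scored: pd.DataFrame, sms_coding: str = "grouped") -> pd.DataFrame:
    """Numeric covariates for the Cox models.

    ``sms_coding``: "grouped" codes the stratum ordinally (0 / 1-3 / 4 ->
    0 / 1 / 2, the default, matching how survival is reported); "linear"
    uses the raw 0-4 score.
    """
    out = pd.DataFrame(index=scored.index)
    if sms_coding == "grouped":
        out["sms_group"] = scored["sms_stratum"].map(_STRATUM_CODE).astype(float)
    elif sms_coding == "linear":
        out["sms_group"] = pd.to_numeric(scored["sms"]).astype(float)
    else:
        raise ValueError(f"unknown sms_coding {sms_coding!r}")
    out["age_years"] = pd.to_numeric(scored["age_years"])
    out["sex_female"] = (scored["sex"] == "female").astype(int)
    out["smoking_code"] = scored["smoking"].map(_SMOKING_CODE).astype(float)
    out["t_stage"] = pd.to_numeric(scored["t_stage"])
    out["n_stage_pos"] = (scored["n_stage"] == "N+").astype(int)
    out["tnt"] = scored["tnt"].astype(int)
    return out


def cox_by_endpoint(scored: pd.DataFrame, sms_coding: str = "grouped") -> dict[str, CoxResult]:
    """Fit the adjusted Cox model for each endpoint."""
    design = build_survival_design(scored, sms_coding=sms_coding)
    results: dict[str, CoxResult] = {}
    for endpoint in ENDPOINTS:
        time, event = endpoint_columns(scored, endpoint)
        frame = design.copy()
        frame["time"] = time.to_numpy(dtype=float)
        frame["event"] = event.to_numpy(dtype=float)
        results[endpoint] = cox_fit(
            frame, "time", "event", DEFAULT_SURVIVAL_COVARIATES
        )
    return results
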