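"""Association tests and multivariable logistic modelling of treatment response.

Covers the oCR analysis stack: Fisher's exact test (2x2 and r x c),
Mann-Whitney U for skewed continuous comparisons, the Breslow-Day test of
odds-ratio homogeneity across strata (train vs validation), the
multivariable logistic model of oCR with McFadden pseudo-R^2, and the model
ROC with a DeLong confidence interval.

Ordinary fits go through scipy/statsmodels; the r x c exact enumeration and
the DeLong variance are implemented here because no installed library
exposes them directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
import statsmodels.api as sm
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cutpoints import RocCurve, auc as roc_auc, roc_curve
from .errors import DegenerateInputError, FitError


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    method: str  # "exact-2x2" | "exact-enumeration" | "monte-carlo"
    mc_standard_error: float | None = None
    n_tables: int | None = None


def _log_table_prob(table: np.ndarray, log_margin_const: float) -> float:
    """log multivariate hypergeometric probability of a table given margins."""
    return log_margin_const - gammaln(table + 1.0).sum()


def _enumerate_tables(row_sums, col_sums, max_tables):
    """Yield all non-negative integer tables with the given margins.

    Fills row-major with feasibility bounds; returns None (via exception)
    if the count exceeds ``max_tables``.
    """
    r, c = len(row_sums), len(col_sums)
    tables: list[np.ndarray] = []

    def rec(i, remaining_cols, current):
        if len(tables) > max_tables:
            raise OverflowError
        if i == r - 1:
            last = np.asarray(remaining_cols)
            if (last >= 0).all():
                tables.append(np.vstack(current + [last]))
            return

        def fill(j, left, row):
            if len(tables) > max_tables:
                raise OverflowError
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    rec(i + 1,
                        [remaining_cols[k] - (row + [left])[k] for k in range(c)],
                        current + [np.asarray(row + [left])])
                return
            hi = min(left, remaining_cols[j])
            # lower bound: must leave enough for remaining columns
            lo = max(0, left - sum(remaining_cols[j + 1:]))
            for v in range(lo, hi + 1):
                fill(j + 1, left - v, row + [v])

        fill(0, row_sums[i], [])

    try:
        rec(0, list(col_sums), [])
    except OverflowError:
        return None
    return tables


def fisher_exact(
    table,
    *,
    seed: int = 0,
    n_mc: int = 100_000,
    max_enumeration: int = 200_000,
) -> FisherResult:
    """Two-sided Fisher exact test for an r x c contingency table.

    2x2 tables use the hypergeometric point-probability criterion (scipy).
    Larger tables are evaluated by exact enumeration of all tables sharing
    the margins when their number is tractable, otherwise by seeded
    Monte-Carlo sampling from the margin-conditional null with >= ``n_mc``
    replicates and a reported standard error.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("table must be a 2-D array of non-negative integers")
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise DegenerateInputError("contingency table has a zero margin")
    if table.shape == (2, 2):
        p = stats.fisher_exact(table, alternative="two-sided")[1]
        return FisherResult(p_value=float(min(p, 1.0)), method="exact-2x2")

    n = int(table.sum())
    log_margin_const = (
        gammaln(row_sums + 1.0).sum() + gammaln(col_sums + 1.0).sum() - gammaln(n + 1.0)
    )
    log_p_obs = _log_table_prob(table, log_margin_const)
    tol = 1e-9 * abs(log_p_obs)

    tables = _enumerate_tables(row_sums.tolist(), col_sums.tolist(), max_enumeration)
    if tables is not None:
        logps = np.array([_log_table_prob(t, log_margin_const) for t in tables])
        p = float(np.exp(logps[logps <= log_p_obs + tol]).sum())
        return FisherResult(
            p_value=min(p, 1.0), method="exact-enumeration", n_tables=len(tables)
        )

    # Monte-Carlo: permute column labels against row labels
    rng = np.random.default_rng(seed)
    row_idx = np.repeat(np.arange(len(row_sums)), row_sums)
    col_idx = np.repeat(np.arange(len(col_sums)), col_sums)
    c = len(col_sums)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(col_idx)
        counts = np.bincount(row_idx * c + perm, minlength=table.size).reshape(table.shape)
        if _log_table_prob(counts, log_margin_const) <= log_p_obs + tol:
            hits += 1
    p = hits / n_mc
    se = math.sqrt(p * (1 - p) / n_mc)
    return FisherResult(p_value=p, method="monte-carlo", mc_standard_error=se)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" | "asymptotic"


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration for small tie-free samples (both groups <= 20),
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DegenerateInputError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return MannWhitneyResult(
        u_statistic=float(res.statistic), p_value=float(res.pvalue), method=method
    )


# ---------------------------------------------------------------------------
# Breslow-Day homogeneity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HomogeneityResult:
    statistic: float
    df: int
    p_value: float
    stratum_odds_ratios: tuple[float, ...]
    mantel_haenszel_or: float
    n_strata_used: int
    dropped: tuple[int, ...] = ()


def breslow_day(strata, *, tarone: bool = False) -> HomogeneityResult:
    """Breslow-Day test of odds-ratio homogeneity across 2x2 strata.

    Strata with a zero margin carry no information about the odds ratio
    and are dropped with a record of their indices; fewer than two usable
    strata is an error.  ``tarone`` applies the Tarone correction (off by
    default).
    """
    usable = []
    dropped = []
    for i, t in enumerate(strata):
        t = np.asarray(t, dtype=float)
        if t.shape != (2, 2) or (t < 0).any():
            raise ValueError(f"stratum {i} is not a non-negative 2x2 table")
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            dropped.append(i)
        else:
            usable.append(t)
    if len(usable) < 2:
        raise DegenerateInputError(
            f"Breslow-Day needs >= 2 usable strata, got {len(usable)}"
        )
    st = StratifiedTable(usable)
    res = st.test_equal_odds(adjust=tarone)
    ors = tuple(
        float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])) if t[0, 1] * t[1, 0] > 0 else math.inf
        for t in usable
    )
    return HomogeneityResult(
        statistic=float(res.statistic),
        df=len(usable) - 1,
        p_value=float(res.pvalue),
        stratum_odds_ratios=ors,
        mantel_haenszel_or=float(st.oddsratio_pooled),
        n_strata_used=len(usable),
        dropped=tuple(dropped),
    )


# ---------------------------------------------------------------------------
# multivariable logistic regression
# ---------------------------------------------------------------------------


@dataclass
class LogisticModelResult:
    """Per-covariate odds ratios with Wald CIs, plus model-level fit."""

    terms: pd.DataFrame  # index: covariate; columns: or, ci_low, ci_high, p
    log_likelihood: float
    null_log_likelihood: float
    mcfadden_r2: float
    fitted_probabilities: np.ndarray
    converged: bool = True


def logistic_fit(design: pd.DataFrame, outcome) -> LogisticModelResult:
    """Maximum-likelihood logistic regression of a binary outcome.

    ``design`` holds the covariates (numeric; an intercept is added).
    Raises on single-class outcomes, rank-deficient designs (naming the
    collinear columns) and detected separation.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("outcome has a single class")
    X = design.apply(pd.to_numeric).astype(float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns whose removal restores full column rank
        collinear = [
            c
            for c in X.columns
            if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy()) == rank
        ]
        raise FitError(f"design is rank deficient; collinear columns: {collinear}")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200, tol=1e-10)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge (possible separation)")
    if np.abs(fit.params).max() > 15:
        raise FitError(
            "diverging coefficient detected (quasi-separation): "
            f"max |beta| = {np.abs(fit.params).max():.1f}"
        )
    ci = fit.conf_int(alpha=0.05)
    terms = pd.DataFrame(
        {
            "odds_ratio": np.exp(fit.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "p_value": fit.pvalues,
        }
    ).drop(index="const")
    return LogisticModelResult(
        terms=terms,
        log_likelihood=float(fit.llf),
        null_log_likelihood=float(fit.llnull),
        mcfadden_r2=float(1.0 - fit.llf / fit.llnull),
        fitted_probabilities=np.asarray(fit.predict(Xc)),
        converged=True,
    )


#: covariates of the default oCR model, in display order, with the codings
#: used to obtain a single odds ratio per variable
DEFAULT_OCR_COVARIATES = (
    "age_years", "sex", "smoking", "t_stage", "n_stage", "tnt", "sms",
)

_SMOKING_CODE = {"never": 0, "ex": 1, "current": 2}


def build_ocr_design(scored: pd.DataFrame, covariates=DEFAULT_OCR_COVARIATES) -> pd.DataFrame:
    """Numeric design matrix for the oCR logistic model.

    Codings (one odds ratio per variable): age continuous per year; sex
    female=1; smoking ordinal never/ex/current = 0/1/2; T stage numeric;
    N stage N+=1; TNT yes=1; SMS as the integer score 0-4.
    """
    cols = {}
    for cov in covariates:
        if cov == "sex":
            cols["sex"] = (scored["sex"] == "female").astype(int)
        elif cov == "smoking":
            cols["smoking"] = scored["smoking"].map(_SMOKING_CODE).astype(float)
        elif cov == "n_stage":
            cols["n_stage"] = (scored["n_stage"] == "N+").astype(int)
        elif cov == "tnt":
            cols["tnt"] = scored["tnt"].astype(int)
        else:
            cols[cov] = pd.to_numeric(scored[cov])
    return pd.DataFrame(cols, index=scored.index)


# ---------------------------------------------------------------------------
# model ROC with DeLong CI
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    variance: float


def delong_variance(scores_cases: np.ndarray, scores_controls: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from case/control score samples.

    Uses the structural components: V10_i = P-hat(case i outranks a random
    control), V01_j analogously; var = S10/m + S01/n.
    """
    x = np.asarray(scores_cases, dtype=float)
    y = np.asarray(scores_controls, dtype=float)
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise DegenerateInputError("both classes required for DeLong variance")
    # psi(x, y) = 1[x > y] + 0.5 * 1[x == y], computed via rank trick
    order_y = np.sort(y)
    gt = np.searchsorted(order_y, x, side="left")
    ge = np.searchsorted(order_y, x, side="right")
    v10 = (gt + 0.5 * (ge - gt)) / n
    order_x = np.sort(x)
    lt = len(x) - np.searchsorted(order_x, y, side="right")
    le = len(x) - np.searchsorted(order_x, y, side="left")
    v01 = (lt + 0.5 * (le - lt)) / m
    a = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return a, s10 / m + s01 / n


def model_roc(fitted_probabilities, outcome, alpha: float = 0.05) -> AucResult:
    """AUC of fitted probabilities against the outcome, with a DeLong
    normal-approximation confidence interval."""
    y = np.asarray(outcome, dtype=bool)
    p = np.asarray(fitted_probabilities, dtype=float)
    roc = roc_curve(p, y, "higher_is_positive")  # raises on single class
    a_trap = roc_auc(roc)
    a_delong, var = delong_variance(p[y], p[~y])
    assert abs(a_trap - a_delong) < 1e-9
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return AucResult(
        auc=a_trap,
        ci_low=max(0.0, a_trap - half),
        ci_high=min(1.0, a_trap + half),
        variance=var,
    )


def score_distribution_test(
    scored: pd.DataFrame, subset_col: str = "subset", seed: int = 0
) -> FisherResult:
    """Fisher r x c test that the SMS distribution is the same across
    subsets (train vs validation)."""
    tab = pd.crosstab(scored[subset_col], scored["sms"]).to_numpy()
    tab = tab[:, tab.sum(axis=0) > 0]
    return fisher_exact(tab, seed=seed)


def sms_ocr_homogeneity(
    scored: pd.DataFrame, subset_col: str = "subset", sms_cut: int = 2
) -> HomogeneityResult:
    """Breslow-Day homogeneity of the SMS-oCR odds ratio across subsets.

    SMS is dichotomised at >= ``sms_cut`` to form the 2x2 exposure in each
    subset stratum.
    """
    strata = []
    for _, grp in scored.groupby(subset_col, sort=True):
        high = grp["sms"] >= sms_cut
        ocr = grp["ocr"].astype(bool)
        strata.append(
            np.array(
                [
                    [int((high & ocr).sum()), int((high & ~ocr).sum())],
                    [int((~high & ocr).sum()), int((~high & ~ocr).sum())],
                ]
            )
        )
    return breslow_day(strata)
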