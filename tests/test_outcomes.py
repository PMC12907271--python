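"""Fisher exact, Mann-Whitney, Breslow-Day, logistic model and model ROC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smscore import fisher_exact, logistic_fit, mann_whitney, model_roc
from smscore.errors import DegenerateInputError, FitError
from smscore.outcomes import breslow_day, build_ocr_design, delong_variance

from conftest import pair_count_auc


# --------------------------------------------------------------------- fisher

def test_fisher_2x2_homogeneous_table_p_one():
    assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)


def test_fisher_2x2_perfect_association():
    """[[10,0],[0,10]]: only the two extreme tables are as unlikely as the
    observed one, p = 2 / C(20,10) = 2/184756."""
    res = fisher_exact([[10, 0], [0, 10]])
    assert res.p_value == pytest.approx(2 / 184756, rel=1e-9)


def test_fisher_3x2_exact_enumeration_matches_independent_values():
    """Frozen from an independent exact implementation (R fisher.test)."""
    res = fisher_exact([[3, 1, 2], [2, 3, 1]])
    assert res.method == "exact-enumeration"
    assert res.p_value == pytest.approx(0.6104, abs=5e-4)
    smoking = fisher_exact([[33, 65], [19, 52], [6, 51]])
    assert smoking.method == "exact-enumeration"
    assert smoking.p_value == pytest.approx(0.004024, abs=5e-5)


def test_fisher_monte_carlo_agrees_with_enumeration():
    table = [[8, 12, 6], [10, 4, 11]]
    exact = fisher_exact(table)
    mc = fisher_exact(table, seed=123, max_enumeration=10)
    assert mc.method == "monte-carlo" and mc.mc_standard_error is not None
    assert mc.p_value == pytest.approx(exact.p_value, abs=4 * mc.mc_standard_error + 1e-12)


def test_fisher_zero_margin_is_degenerate():
    with pytest.raises(DegenerateInputError):
        fisher_exact([[0, 0], [3, 4]])


# --------------------------------------------------------------- mann-whitney

def test_mann_whitney_identical_samples_centre_of_null():
    res = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.5, 2.5, 3.5, 0.5])
    assert res.p_value > 0.5


def test_mann_whitney_separated_exact_p():
    """n=3 vs 3 fully separated: 2 of the 20 orderings are as extreme."""
    res = mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
    assert res.method == "exact"
    assert res.p_value == pytest.approx(0.1, rel=1e-9)


def test_mann_whitney_u_complement_identity():
    rng = np.random.default_rng(2)
    x, y = rng.normal(size=15), rng.normal(1, 1, size=12)
    u_xy = mann_whitney(x, y).u_statistic
    u_yx = mann_whitney(y, x).u_statistic
    assert u_xy + u_yx == pytest.approx(len(x) * len(y))
    with pytest.raises(DegenerateInputError):
        mann_whitney([], [1.0])


# ---------------------------------------------------------------- breslow-day

def test_breslow_day_identical_strata_is_exactly_homogeneous():
    t = [[12, 8], [5, 15]]
    res = breslow_day([t, t])
    assert res.statistic == pytest.approx(0.0, abs=1e-9)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 1
    assert res.stratum_odds_ratios[0] == pytest.approx(res.mantel_haenszel_or, rel=1e-6)


def test_breslow_day_drops_zero_margin_strata_and_errors_below_two():
    good = [[12, 8], [5, 15]]
    bad = [[0, 0], [5, 15]]
    res = breslow_day([good, bad, [[10, 10], [8, 12]]])
    assert res.dropped == (1,) and res.n_strata_used == 2
    with pytest.raises(DegenerateInputError):
        breslow_day([good, bad])


def test_breslow_day_power_increases_with_heterogeneity():
    rng = np.random.default_rng(7)

    def sim_tables(or2):
        # stratum 1 OR=1, stratum 2 OR=or2, n=150 per arm
        def draw(p):
            return int(rng.binomial(150, p))

        p0 = 0.3
        t1 = [[draw(p0), 0], [draw(p0), 0]]
        t1 = [[t1[0][0], 150 - t1[0][0]], [t1[1][0], 150 - t1[1][0]]]
        p2 = (or2 * p0 / (1 - p0)) / (1 + or2 * p0 / (1 - p0))
        a, c = draw(p2), draw(p0)
        t2 = [[a, 150 - a], [c, 150 - c]]
        return [t1, t2]

    def reject_rate(or2, reps=150):
        r = 0
        for _ in range(reps):
            try:
                r += breslow_day(sim_tables(or2)).p_value < 0.05
            except DegenerateInputError:
                pass
        return r / reps

    assert reject_rate(6.0) > reject_rate(1.0) + 0.2


# ------------------------------------------------------------------- logistic

def test_logistic_single_binary_covariate_equals_cross_product_or():
    """Saturated 2x2 fit: the OR equals the cross-product ratio, checked on
    the current-smoker vs other response counts (6,52; 51,117)."""
    x = np.array([1] * 57 + [0] * 169)
    y = np.array([1] * 6 + [0] * 51 + [1] * 52 + [0] * 117)
    fit = logistic_fit(pd.DataFrame({"smoker": x}), y)
    expected = (6 * 117) / (51 * 52)
    assert fit.terms.loc["smoker", "odds_ratio"] == pytest.approx(expected, rel=1e-6)
    assert expected == pytest.approx(0.265, abs=5e-4)


def test_logistic_null_effect_or_near_one_and_null_model_r2_zero():
    rng = np.random.default_rng(1)
    n = 6000
    x = rng.normal(size=n)
    y = rng.random(n) < 0.3
    fit = logistic_fit(pd.DataFrame({"x": x}), y)
    assert fit.terms.loc["x", "odds_ratio"] == pytest.approx(1.0, abs=0.06)
    assert fit.mcfadden_r2 == pytest.approx(0.0, abs=1e-3)
    lo, hi = fit.terms.loc["x", ["ci_low", "ci_high"]]
    assert lo <= fit.terms.loc["x", "odds_ratio"] <= hi


def test_logistic_errors_on_degenerate_inputs():
    with pytest.raises(DegenerateInputError):
        logistic_fit(pd.DataFrame({"x": [1.0, 2.0]}), [1, 1])
    x = np.arange(40, dtype=float)
    with pytest.raises(FitError, match="collinear"):
        logistic_fit(pd.DataFrame({"a": x, "b": 2 * x}), np.tile([0, 1], 20))
    sep = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]})
    with pytest.raises(FitError):
        logistic_fit(sep, np.r_[np.zeros(20), np.ones(20)])


def test_build_ocr_design_codings(default_cohort):
    design = build_ocr_design(default_cohort.assign(sms=default_cohort["true_score"]))
    assert set(design.columns) == {"age_years", "sex", "smoking", "t_stage", "n_stage", "tnt", "sms"}
    assert design["sex"].isin([0, 1]).all()
    assert design["smoking"].isin([0, 1, 2]).all()
    assert design["sms"].between(0, 4).all()


def test_logistic_recovers_generating_log_odds():
    """Parameter recovery: a synthetic outcome with known slope is
    estimated with small bias at n=5000."""
    rng = np.random.default_rng(12)
    n = 5000
    x = rng.integers(0, 5, n).astype(float)
    true_slope = 0.45
    y = rng.random(n) < 1 / (1 + np.exp(-(-2.0 + true_slope * x)))
    fit = logistic_fit(pd.DataFrame({"score": x}), y)
    est = np.log(fit.terms.loc["score", "odds_ratio"])
    assert abs(est - true_slope) < 0.05 * true_slope + 0.03


# ------------------------------------------------------------------ model roc

def test_model_roc_trivial_cases():
    y = np.array([0, 0, 1, 1, 0, 1], bool)
    perfect = model_roc(y.astype(float), y)
    assert perfect.auc == pytest.approx(1.0)
    const = model_roc(np.full(6, 0.3), y)
    assert const.auc == pytest.approx(0.5)
    with pytest.raises(DegenerateInputError):
        model_roc(np.full(6, 0.3), np.ones(6, bool))


def test_model_roc_matches_pair_count_and_ci_brackets():
    rng = np.random.default_rng(5)
    n = 300
    y = rng.random(n) < 0.3
    p = np.clip(rng.normal(0.3 + 0.2 * y, 0.15), 0.01, 0.99)
    res = model_roc(p, y)
    assert res.auc == pytest.approx(pair_count_auc(p, y), abs=1e-9)
    assert res.ci_low <= res.auc <= res.ci_high
    assert 0 < res.variance < 0.01


def test_delong_variance_matches_analytic_null():
    """Under exchangeable continuous scores the DeLong variance estimates
    var(AUC-hat); compare with the closed-form null variance
    (m+n+1)/(12mn) in Monte-Carlo aggregate."""
    rng = np.random.default_rng(9)
    m, n = 30, 50
    vs = []
    for _ in range(200):
        vs.append(delong_variance(rng.normal(size=m), rng.normal(size=n))[1])
    analytic = (m + n + 1) / (12 * m * n)
    assert np.mean(vs) == pytest.approx(analytic, rel=0.15)
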