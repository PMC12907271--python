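"""Kaplan-Meier, log-rank, Cox fits and the SMS-stratified analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from smscore import SyntheticConfig, cox_fit, generate_cohort, km_estimate, logrank_test
from smscore.errors import DegenerateInputError, ValidationError
from smscore.scoring import stratum_of
from smscore.simulate import EndpointHazards, SurvivalModel, _default_survival_model
from smscore.survival import endpoint_columns, survival_by_sms


def test_km_no_censoring_is_empirical_survival():
    km = km_estimate([1.0, 2.0, 3.0, 4.0], [True] * 4)
    assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])
    assert np.allclose(km.at_risk, [4, 3, 2, 1])


def test_km_all_censored_stays_at_one():
    km = km_estimate([1.0, 2.0, 3.0], [False] * 3)
    assert np.allclose(km.survival, 1.0)


def test_km_matches_hand_product_limit_with_censoring():
    """times 1(ev) 2(cens) 3(ev) 3(ev) 5(cens) 6(ev):
    S = 3/4 after t=3 pair etc., computed by hand below."""
    times = [1.0, 2.0, 3.0, 3.0, 5.0, 6.0]
    events = [True, False, True, True, False, True]
    km = km_estimate(times, events)
    # hand product-limit: t=1: (1-1/6)=5/6; t=3: x(1-2/4)=5/12; t=6: x(1-1/1)=0
    assert km.survival_at(1.0) == pytest.approx(5 / 6)
    assert km.survival_at(3.0) == pytest.approx(5 / 6 * (1 - 2 / 4))
    assert km.survival_at(6.0) == pytest.approx(0.0)
    assert km.survival_at(0.5) == 1.0


def test_km_rejects_nonpositive_times():
    with pytest.raises(ValidationError):
        km_estimate([0.0, 1.0], [True, True])
    with pytest.raises(DegenerateInputError):
        km_estimate([], [])


def test_logrank_identical_groups_and_relabelling_symmetry():
    times = np.r_[np.arange(1, 11), np.arange(1, 11)].astype(float)
    events = np.ones(20, bool)
    groups = np.r_[np.zeros(10), np.ones(10)]
    res = logrank_test(times, events, groups)
    assert res.statistic == pytest.approx(0.0, abs=1e-9)
    assert res.p_value == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    t = rng.exponential(1, 30)
    g = rng.integers(0, 3, 30)
    a = logrank_test(t, np.ones(30, bool), g)
    b = logrank_test(t, np.ones(30, bool), 2 - g)  # relabelled
    assert a.statistic == pytest.approx(b.statistic, rel=1e-9)
    assert a.df == 2
    with pytest.raises(DegenerateInputError):
        logrank_test(t, np.zeros(30, bool), g)


def test_logrank_two_groups_squares_cox_score_test():
    """Without ties, the 2-group log-rank statistic equals the partial-
    likelihood score test of a binary-covariate Cox model at beta=0."""
    rng = np.random.default_rng(4)
    n = 60
    x = np.repeat([0.0, 1.0], n // 2)
    t = rng.exponential(np.where(x == 1, 0.6, 1.0))
    assert len(np.unique(t)) == n  # no ties
    e = np.ones(n, bool)
    lr = logrank_test(t, e, x)

    # hand-computed score and information of the Cox partial likelihood at 0
    order = np.argsort(t)
    xs = x[order]
    score = 0.0
    info = 0.0
    for i in range(n):
        risk = xs[i:]
        xbar = risk.mean()
        score += xs[i] - xbar
        info += risk.var()
    assert lr.statistic == pytest.approx(score**2 / info, rel=1e-6)


def test_cox_null_covariate_hr_near_one():
    rng = np.random.default_rng(6)
    n = 3000
    frame = pd.DataFrame(
        {
            "time": rng.exponential(1.0, n),
            "event": (rng.random(n) < 0.8).astype(float),
            "x": rng.normal(size=n),
        }
    )
    res = cox_fit(frame, "time", "event", ["x"])
    assert res.terms.loc["x", "hazard_ratio"] == pytest.approx(1.0, abs=0.08)
    lo, hi = res.terms.loc["x", ["ci_low", "ci_high"]]
    assert lo <= res.terms.loc["x", "hazard_ratio"] <= hi


def test_cox_recovers_true_hazard_ratio_two():
    rng = np.random.default_rng(13)
    n = 2000
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / (0.5 * np.exp(np.log(2.0) * x)))
    c = rng.exponential(4.0, n)
    frame = pd.DataFrame(
        {"time": np.minimum(t, c), "event": (t <= c).astype(float), "x": x}
    )
    res = cox_fit(frame, "time", "event", ["x"])
    assert 1.8 <= res.terms.loc["x", "hazard_ratio"] <= 2.2


def test_cox_maximand_matches_hand_partial_likelihood():
    """Tiny instance: the lifelines estimate maximises the hand-written
    partial likelihood."""
    frame = pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0],
            "event": [1.0, 1.0, 1.0, 0.0],
            "x": [1.0, 0.0, 1.0, 0.0],
        }
    )

    def neg_pll(beta):
        # event at t=1 (x=1, risk {1,0,1,0}); t=2 (x=0, risk {0,1,0}); t=3 (x=1, risk {1,0})
        import math

        e = math.exp
        ll = (beta - np.log(2 * e(beta) + 2)) + (0 - np.log(e(beta) + 2)) + (
            beta - np.log(e(beta) + 1)
        )
        return -ll

    hand = minimize_scalar(neg_pll, bounds=(-5, 5), method="bounded").x
    res = cox_fit(frame, "time", "event", ["x"])
    est = np.log(res.terms.loc["x", "hazard_ratio"])
    assert est == pytest.approx(hand, abs=1e-4)


# ------------------------------------------------------- stratified analysis

def _strong_stratum_survival() -> SurvivalModel:
    base = _default_survival_model()
    return SurvivalModel(
        recurrence=EndpointHazards(0.055, {"0": 1.5, "1-3": 0.0, "4": -3.0}),
        cancer_death=EndpointHazards(0.04, {"0": 1.5, "1-3": 0.0, "4": -3.0}),
        other_death=EndpointHazards(0.018, {"0": 0.0, "1-3": 0.0, "4": 0.0}),
        censoring_rate=base.censoring_rate,
        horizon_years=base.horizon_years,
    )


def test_survival_by_sms_matches_per_stratum_km_and_strong_separation():
    cfg = SyntheticConfig(
        n_patients=500, seed=30, survival_model=_strong_stratum_survival()
    )
    cohort = generate_cohort(cfg)
    scored = cohort.assign(sms=cohort["true_score"], sms_stratum=cohort["true_stratum"])
    res = survival_by_sms(scored, "os")
    assert set(res.curves) <= {"0", "1-3", "4"}
    time, event = endpoint_columns(scored, "os")
    for label, curve in res.curves.items():
        mask = (scored["sms_stratum"] == label).to_numpy()
        solo = km_estimate(time[mask], event[mask])
        assert np.allclose(curve.survival, solo.survival)
    assert res.logrank is not None and res.logrank.p_value < 0.001


def test_zero_hazard_stratum_curve_stays_at_one_through_five_years():
    base = _default_survival_model()
    sm = SurvivalModel(
        recurrence=EndpointHazards(0.055, {"0": 0.9, "1-3": 0.0, "4": -np.inf}),
        cancer_death=EndpointHazards(0.022, {"0": 1.0, "1-3": 0.0, "4": -np.inf}),
        other_death=EndpointHazards(0.0, {"0": 0.0, "1-3": 0.0, "4": 0.0}),
        censoring_rate=base.censoring_rate,
        horizon_years=base.horizon_years,
    )
    cfg = SyntheticConfig(n_patients=800, seed=31, survival_model=sm)
    cohort = generate_cohort(cfg)
    scored = cohort.assign(sms=cohort["true_score"], sms_stratum=cohort["true_stratum"])
    res = survival_by_sms(scored, "os")
    assert res.curves["4"].survival_at(5.0) == pytest.approx(1.0)


def test_empty_stratum_omitted_with_record():
    cohort = generate_cohort(SyntheticConfig(n_patients=300, seed=32))
    scored = cohort.assign(sms=cohort["true_score"], sms_stratum=cohort["true_stratum"])
    scored = scored[scored["sms_stratum"] != "4"]
    res = survival_by_sms(scored, "dfs")
    assert res.omitted_strata == ("4",)
    assert set(res.curves) == {"0", "1-3"}


def test_dfs_event_is_first_of_recurrence_or_death(default_cohort):
    t, e = endpoint_columns(default_cohort, "dfs")
    t_os, e_os = endpoint_columns(default_cohort, "os")
    assert (t <= t_os + 1e-12).all()
    assert (e | ~e_os.astype(bool)).all() or True  # death implies a DFS event
    died = e_os.astype(bool)
    assert bool(e[died].all())
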