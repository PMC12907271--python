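"""SMS assignment, response tables and the extreme-score classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from smscore import (
    extreme_score_classifier,
    reference_cutpoints,
    response_by_score,
    score_cohort,
    score_patient,
    stratum_of,
)
from smscore.cutpoints import METRICS
from smscore.errors import ScoringError

from conftest import scored_frame_from_counts

CPS = reference_cutpoints()


def metrics_dict(smv, smd, imv, imd):
    return {
        "sm_volume_index": smv,
        "sm_density": smd,
        "imat_volume_index": imv,
        "imat_density": imd,
    }


@pytest.mark.parametrize(
    "sex, values, expected",
    [
        # all four favourable against the male reference cutpoints
        ("male", (1700, 41, 130, -60), 4),
        # exactly at every cutpoint: strict inequalities score nothing
        ("male", (1650, 39.5, 125, -57.9), 0),
        # female just above the SM volume cutpoint, rest unfavourable
        ("female", (1331, 38.6, 129, -56.2), 1),
        # IMAT density below its cutpoint is the favourable direction
        ("female", (1000, 30, 100, -80), 1),
    ],
)
def test_score_counts_favourable_indicators(sex, values, expected):
    res = score_patient(metrics_dict(*values), sex, CPS)
    assert res.score == expected
    assert res.score == sum(res.indicators.values())
    assert res.stratum == stratum_of(res.score)


def test_stratum_mapping_is_exact():
    assert [stratum_of(s) for s in range(5)] == ["0", "1-3", "1-3", "1-3", "4"]


def test_missing_metric_or_cutpoint_raises_named_error():
    with pytest.raises(ScoringError, match="sm_density"):
        score_patient(metrics_dict(1700, np.nan, 130, -60), "male", CPS)
    half = reference_cutpoints()
    half.cells = {k: v for k, v in half.cells.items() if k[0] == "male"}
    with pytest.raises(ScoringError, match="female"):
        score_patient(metrics_dict(1700, 41, 130, -60), "female", half)


@given(st.data())
@settings(max_examples=80, deadline=None)
def test_score_is_monotone_in_each_favourable_direction(data):
    sex = data.draw(st.sampled_from(["male", "female"]))
    base = metrics_dict(
        data.draw(st.floats(500, 3000)),
        data.draw(st.floats(20, 60)),
        data.draw(st.floats(10, 300)),
        data.draw(st.floats(-120, -20)),
    )
    s0 = score_patient(base, sex, CPS).score
    bumped = dict(base)
    metric = data.draw(st.sampled_from(METRICS))
    delta = data.draw(st.floats(0, 500))
    bumped[metric] += -delta if metric == "imat_density" else delta
    s1 = score_patient(bumped, sex, CPS).score
    assert 0 <= s0 <= 4 and 0 <= s1 <= 4
    assert s1 >= s0


def test_score_cohort_matches_per_patient_recount_and_flags_errors():
    rng = np.random.default_rng(8)
    n = 120
    frame = pd.DataFrame(
        {
            "sex": rng.choice(["male", "female"], n),
            "sm_volume_index": rng.normal(1500, 300, n),
            "sm_density": rng.normal(39, 6, n),
            "imat_volume_index": rng.normal(127, 50, n),
            "imat_density": rng.normal(-57, 6, n),
            "ocr": rng.random(n) < 0.25,
        }
    )
    frame.loc[3, "sm_density"] = np.nan
    scored = score_cohort(frame, CPS)
    assert scored["score_error"].astype(bool).sum() == 1
    for i, row in frame.iterrows():
        if i == 3:
            assert pd.isna(scored.loc[i, "sms"])
            continue
        # independent re-count: sum of hand-checked indicators
        expected = sum(
            (
                row[m] > CPS.threshold(row["sex"], m)
                if m != "imat_density"
                else row[m] < CPS.threshold(row["sex"], m)
            )
            for m in METRICS
        )
        assert scored.loc[i, "sms"] == expected


def test_score_cohort_empty_and_all_favourable():
    empty = pd.DataFrame(columns=["sex", *METRICS, "ocr"])
    assert len(score_cohort(empty, CPS)) == 0
    n = 5
    allfav = pd.DataFrame(
        {
            "sex": ["male"] * n,
            "sm_volume_index": 2000.0,
            "sm_density": 50.0,
            "imat_volume_index": 200.0,
            "imat_density": -80.0,
            "ocr": True,
        },
        index=range(n),
    )
    assert (score_cohort(allfav, CPS)["sms"] == 4).all()


def test_response_table_reproduces_printed_total_cohort_rates(table3_scored):
    table = response_by_score(table3_scored, subset_col=None)
    total = table.set_index("sms")
    assert total["n"].tolist() == [14, 68, 87, 47, 10]
    assert total.loc[0, "ocr_rate_pct"] == 0.0
    assert total.loc[1, "ocr_rate_pct"] == pytest.approx(19.1, abs=0.05)
    assert total.loc[2, "ocr_rate_pct"] == pytest.approx(31.0, abs=0.05)
    assert total.loc[3, "ocr_rate_pct"] == pytest.approx(25.5, abs=0.05)
    assert total.loc[4, "ocr_rate_pct"] == pytest.approx(60.0, abs=0.05)
    # conservation: frequency x rate sums back to the responder count
    assert int(round((total["n"] * total["ocr_rate_pct"] / 100).sum())) == int(
        table3_scored["ocr"].sum()
    )


def test_response_table_single_patient_rates_are_0_or_100():
    one = pd.DataFrame({"sms": [2], "ocr": [True]})
    t = response_by_score(one, subset_col=None).set_index("sms")
    assert t.loc[2, "ocr_rate_pct"] == 100.0
    assert t.drop(index=2)["n"].sum() == 0


@given(st.data())
@settings(max_examples=60, deadline=None)
def test_extreme_classifier_equals_confusion_matrix_oracle(data):
    counts = {
        s: (
            n := data.draw(st.integers(0, 12)),
            data.draw(st.integers(0, n)),
        )
        for s in range(5)
    }
    scored = scored_frame_from_counts(counts)
    res = extreme_score_classifier(scored)
    sub = scored[scored["sms"].isin([0, 4])]
    tp = int(((sub["sms"] == 4) & sub["ocr"]).sum())
    fn = int(((sub["sms"] == 0) & sub["ocr"]).sum())
    tn = int(((sub["sms"] == 0) & ~sub["ocr"]).sum())
    fp = int(((sub["sms"] == 4) & ~sub["ocr"]).sum())
    assert res.n_evaluated == len(sub)
    if tp + fn == 0:
        assert res.sensitivity is None
    else:
        assert float(res.sensitivity) == pytest.approx(tp / (tp + fn))
    if tn + fp == 0:
        assert res.specificity is None
    else:
        assert float(res.specificity) == pytest.approx(tn / (tn + fp))


def test_extreme_classifier_undefined_when_no_nonresponders():
    scored = scored_frame_from_counts({0: (0, 0), 4: (3, 3)})
    res = extreme_score_classifier(scored)
    assert res.sensitivity == 1 and res.specificity is None
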