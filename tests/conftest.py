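import numpy as np
import pandas as pd
import pytest

from smscore import SyntheticConfig, generate_cohort

#: per-score (frequency, oCR count) of the development study's total cohort,
#: reconstructed from the printed frequencies and response rates
TOTAL_COHORT_SCORE_TABLE = {0: (14, 0), 1: (68, 13), 2: (87, 27), 3: (47, 12), 4: (10, 6)}


def scored_frame_from_counts(counts: dict[int, tuple[int, int]]) -> pd.DataFrame:
    """Build a minimal scored cohort from per-score (n, n_ocr) pairs."""
    rows = []
    for score, (n, n_ocr) in counts.items():
        for i in range(n):
            rows.append({"sms": score, "ocr": i < n_ocr})
    return pd.DataFrame(rows, columns=["sms", "ocr"])


@pytest.fixture(scope="session")
def table3_scored() -> pd.DataFrame:
    return scored_frame_from_counts(TOTAL_COHORT_SCORE_TABLE)


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    return generate_cohort(SyntheticConfig(seed=11))


def brute_force_roc(values, labels, orientation="higher_is_positive"):
    """Independent ROC oracle: loop over every threshold, count the
    confusion matrix directly."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    distinct = np.unique(values)
    thresholds = np.concatenate(
        ([-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf])
    )
    sens, spec = [], []
    for t in thresholds:
        if orientation == "higher_is_positive":
            pred = values > t
        else:
            pred = values < t
        tp = np.sum(pred & labels)
        fn = np.sum(~pred & labels)
        tn = np.sum(~pred & ~labels)
        fp = np.sum(pred & ~labels)
        sens.append(tp / (tp + fn))
        spec.append(tn / (tn + fp))
    return thresholds, np.array(sens), np.array(spec)


def pair_count_auc(values, labels):
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    cases, controls = values[labels], values[~labels]
    total = sum(
        (1.0 if c > d else 0.5 if c == d else 0.0) for c in cases for d in controls
    )
    return total / (len(cases) * len(controls))
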