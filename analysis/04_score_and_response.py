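"""Score every patient 0-4 and tabulate oCR by score and subset.

Writes scratch/data/scored.csv and results/response_by_score.csv, prints the response table
and the extreme-score classifier's operating characteristics.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from smscore import CutpointSet, extreme_score_classifier, response_by_score, score_cohort, split_cohort
from smscore.io import read_cohort_table, write_table

DATA = Path("scratch/data")
SPLIT_SEED = 20130


def main() -> None:
    cohort = read_cohort_table(DATA / "cohort.csv")
    metrics = pd.read_csv(DATA / "metrics.csv")
    merged = cohort.merge(metrics, on="patient_id", how="inner", suffixes=("_true", ""))
    train, _ = split_cohort(merged, 166 / 226, seed=SPLIT_SEED)
    merged["subset"] = np.where(
        merged["patient_id"].isin(train["patient_id"]), "train", "validation"
    )
    cps = CutpointSet.from_frame(pd.read_csv("results/cutpoints.csv"))
    scored = score_cohort(merged, cps)
    write_table(scored, DATA / "scored.csv")

    table = response_by_score(scored)
    write_table(table, Path("results/response_by_score.csv"))
    for subset in ("train", "validation", "total"):
        sub = table[table["subset"] == subset]
        row = "  ".join(
            f"{int(r['sms'])}:{int(r['n'])} ({r['ocr_rate_pct']:.0f}%)"
            for _, r in sub.iterrows() if r["n"] > 0
        )
        print(f"{subset:10s} {row}")

    ex = extreme_score_classifier(scored)
    print(
        f"extreme-score rule (SMS 0 or 4, n={ex.n_evaluated}): "
        f"sensitivity {ex.sensitivity_pct:.0f}%, specificity {ex.specificity_pct:.0f}%"
    )


if __name__ == "__main__":
    main()
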