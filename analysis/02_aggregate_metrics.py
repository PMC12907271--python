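"""Aggregate the per-slice table into patient-level body-composition metrics.

Reads scratch/data/{slices,cohort}.csv, applies the scan-quality filter,
sums area x thickness into volumes, averages slice densities, normalises
by height squared, and writes scratch/data/metrics.csv.
"""

from pathlib import Path

from smscore import qc_filter
from smscore.body_composition import aggregate_cohort
from smscore.io import read_cohort_table, read_slice_table, write_table

DATA = Path("scratch/data")


def main() -> None:
    slices = read_slice_table(DATA / "slices.csv")
    cohort = read_cohort_table(DATA / "cohort.csv")
    qc = qc_filter(slices)
    metrics = aggregate_cohort(slices, cohort.set_index("patient_id")["height_m"])
    write_table(metrics, DATA / "metrics.csv")

    print(f"patients with slices: {len(qc)}  included: {int(qc['included'].sum())}")
    excluded = qc[~qc["included"]]
    if len(excluded):
        print("exclusions:", excluded["reason"].value_counts().to_dict())
    print(metrics[["sm_volume_index", "sm_density", "imat_volume_index", "imat_density"]]
          .describe().loc[["mean", "std"]].round(1))


if __name__ == "__main__":
    main()
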