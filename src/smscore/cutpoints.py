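"""ROC analysis and sex-specific optimal cutpoints for body-composition metrics.

The skeletal muscle score is built from four CT body-composition metrics —
skeletal muscle (SM) volume index, SM density, intermuscular/intramuscular
adipose tissue (IMAT) volume index and IMAT density. For each sex and each
metric an ROC curve against overall complete response (oCR) is computed on
the training cohort only, and the optimal threshold is the one maximising
sensitivity x specificity (the Liu product criterion).

The favourable direction of each metric is fixed a priori: higher SM volume
index, higher SM density and higher IMAT volume index are favourable;
lower IMAT density (more lipid-rich, less fibrotic adipose tissue) is
favourable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, SplitError

#: metric column names, in canonical order
METRICS = ("sm_volume_index", "sm_density", "imat_volume_index", "imat_density")

#: favourable direction per metric: "above" means values above the cutpoint
#: score a point, "below" the reverse (IMAT density only).
DIRECTIONS = {
    "sm_volume_index": "above",
    "sm_density": "above",
    "imat_volume_index": "above",
    "imat_density": "below",
}

SEXES = ("male", "female")

#: Sex-specific thresholds of the original development cohort, used as the
#: default data-generating truth of the synthetic cohort simulator.
#: Units: volume indices cm^3/m^2, densities HU.
REFERENCE_CUTPOINTS_VALUES = {
    ("male", "sm_volume_index"): 1650.0,
    ("male", "sm_density"): 39.5,
    ("male", "imat_volume_index"): 125.0,
    ("male", "imat_density"): -57.9,
    ("female", "sm_volume_index"): 1330.0,
    ("female", "sm_density"): 38.6,
    ("female", "imat_volume_index"): 129.0,
    ("female", "imat_density"): -56.2,
}


@dataclass(frozen=True)
class Cutpoint:
    """A single threshold with its favourable direction and, when derived
    from data, the achieved operating characteristics."""

    threshold: float
    direction: str  # "above" | "below"
    sensitivity: float | None = None
    specificity: float | None = None
    auc: float | None = None
    non_informative: bool = False


@dataclass
class CutpointSet:
    """The 8 sex x metric thresholds that define the skeletal muscle score.

    ``cells`` maps (sex, metric) -> Cutpoint.  A cell may be absent when a
    derivation failed (e.g. a sex with a single outcome class in training);
    failures are recorded in ``errors``.
    """

    cells: dict[tuple[str, str], Cutpoint] = field(default_factory=dict)
    errors: dict[tuple[str, str], str] = field(default_factory=dict)

    def threshold(self, sex: str, metric: str) -> float:
        return self.cells[(sex, metric)].threshold

    def direction(self, metric: str) -> str:
        return DIRECTIONS[metric]

    def is_complete(self) -> bool:
        return all((s, m) in self.cells for s in SEXES for m in METRICS)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sex, metric), cp in sorted(self.cells.items()):
            rows.append(
                {
                    "sex": sex,
                    "metric": metric,
                    "threshold": cp.threshold,
                    "direction": cp.direction,
                    "sensitivity": cp.sensitivity,
                    "specificity": cp.specificity,
                    "auc": cp.auc,
                    "non_informative": cp.non_informative,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_values(cls, values: dict[tuple[str, str], float]) -> "CutpointSet":
        cells = {
            (sex, metric): Cutpoint(threshold=float(v), direction=DIRECTIONS[metric])
            for (sex, metric), v in values.items()
        }
        return cls(cells=cells)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CutpointSet":
        values = {
            (r["sex"], r["metric"]): float(r["threshold"]) for _, r in frame.iterrows()
        }
        return cls.from_values(values)


def reference_cutpoints() -> CutpointSet:
    """The published development-cohort cutpoints as a CutpointSet."""
    return CutpointSet.from_values(REFERENCE_CUTPOINTS_VALUES)


# ---------------------------------------------------------------------------
# cohort splitting
# ---------------------------------------------------------------------------


def split_cohort(
    cohort: pd.DataFrame, train_fraction: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simple random split without replacement, deterministic given seed.

    The training set gets round(n * train_fraction) patients, the
    validation set the remainder.  With the study's 226 patients and
    fraction 166/226 this reproduces the 166/60 allocation.
    """
    n = len(cohort)
    if n < 2:
        raise SplitError(f"cannot split a cohort of {n} patients")
    if not 0.0 < train_fraction < 1.0:
        raise SplitError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = cohort.iloc[np.sort(perm[:n_train])].copy()
    validation = cohort.iloc[np.sort(perm[n_train:])].copy()
    return train, validation


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclass
class RocCurve:
    """An ROC curve over the exhaustive candidate-threshold grid.

    Candidate thresholds are the midpoints between consecutive distinct
    marker values plus -inf/+inf sentinels, so every achievable
    classification of the sample corresponds to exactly one threshold.
    """

    thresholds: np.ndarray  # ascending
    sensitivity: np.ndarray
    specificity: np.ndarray
    orientation: str  # "higher_is_positive" | "lower_is_positive"
    n_cases: int
    n_controls: int


def roc_curve(values, labels, orientation: str = "higher_is_positive") -> RocCurve:
    """Exhaustive-counting ROC curve of a marker against a binary label.

    For ``higher_is_positive`` a subject is called positive when its value
    exceeds the threshold; ``lower_is_positive`` flips the comparison
    (used for IMAT density, where low values are the favourable ones).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    if not np.all(np.isfinite(values)):
        raise ValueError("marker values must be finite")
    if orientation not in ("higher_is_positive", "lower_is_positive"):
        raise ValueError(f"unknown orientation {orientation!r}")
    n_cases = int(labels.sum())
    n_controls = int((~labels).sum())
    if n_cases == 0 or n_controls == 0:
        raise DegenerateInputError(
            "ROC requires both classes present "
            f"(cases={n_cases}, controls={n_controls})"
        )

    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))

    cases = np.sort(values[labels])
    controls = np.sort(values[~labels])
    # number of cases/controls strictly above each threshold
    cases_above = n_cases - np.searchsorted(cases, thresholds, side="right")
    controls_above = n_controls - np.searchsorted(controls, thresholds, side="right")

    if orientation == "higher_is_positive":
        sens = cases_above / n_cases
        spec = (n_controls - controls_above) / n_controls
    else:
        # positive call: value strictly below threshold
        cases_below = np.searchsorted(cases, thresholds, side="left")
        controls_below = np.searchsorted(controls, thresholds, side="left")
        sens = cases_below / n_cases
        spec = (n_controls - controls_below) / n_controls

    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        orientation=orientation,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def auc(roc: RocCurve) -> float:
    """Area under the ROC curve by the trapezoidal rule.

    Equals the Mann-Whitney probability that a random case outranks a
    random control (ties credited 1/2) in the curve's positive direction.
    """
    fpr = 1.0 - roc.specificity
    # lexicographic (fpr, sens) ascending: vertical jumps get zero width and
    # horizontal runs carry the sensitivity already attained at their left end
    order = np.lexsort((roc.sensitivity, fpr))
    return float(np.trapezoid(roc.sensitivity[order], fpr[order]))


@dataclass(frozen=True)
class LiuCutpoint:
    threshold: float
    sensitivity: float
    specificity: float
    product: float
    non_informative: bool


def liu_cutpoint(roc: RocCurve) -> LiuCutpoint:
    """Optimal threshold maximising sensitivity x specificity.

    Ties are broken in favour of the smallest threshold.  A maximum
    product of zero (e.g. a constant marker, where only the sentinels
    remain) is flagged non-informative.
    """
    product = roc.sensitivity * roc.specificity
    idx = int(np.argmax(product))  # first max = smallest threshold
    best = product[idx]
    return LiuCutpoint(
        threshold=float(roc.thresholds[idx]),
        sensitivity=float(roc.sensitivity[idx]),
        specificity=float(roc.specificity[idx]),
        product=float(best),
        non_informative=bool(best <= 0.0 or not math.isfinite(roc.thresholds[idx])),
    )


def derive_cutpoint_set(train: pd.DataFrame, outcome_col: str = "ocr") -> CutpointSet:
    """Derive the 8 sex-specific Liu cutpoints from a training cohort.

    ``train`` must carry the four metric columns, a ``sex`` column and a
    boolean outcome column.  Metric orientation is fixed a priori (see
    DIRECTIONS); a sex with a single outcome class yields a per-cell error
    rather than a cutpoint.
    """
    out = CutpointSet()
    for sex in SEXES:
        sub = train[train["sex"] == sex]
        for metric in METRICS:
            direction = DIRECTIONS[metric]
            orientation = (
                "higher_is_positive" if direction == "above" else "lower_is_positive"
            )
            try:
                roc = roc_curve(
                    sub[metric].to_numpy(), sub[outcome_col].to_numpy(), orientation
                )
            except (DegenerateInputError, ValueError, KeyError) as exc:
                out.errors[(sex, metric)] = str(exc)
                continue
            liu = liu_cutpoint(roc)
            out.cells[(sex, metric)] = Cutpoint(
                threshold=liu.threshold,
                direction=direction,
                sensitivity=liu.sensitivity,
                specificity=liu.specificity,
                auc=auc(roc),
                non_informative=liu.non_informative,
            )
    return out
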