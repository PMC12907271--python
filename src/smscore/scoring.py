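"""The 0-4 skeletal muscle score (SMS) and its response summaries.

A patient scores one point for each favourable body-composition
indicator: SM volume index, SM density or IMAT volume index strictly
above its sex-specific cutpoint, or IMAT density strictly below its
cutpoint.  A value exactly equal to a cutpoint scores no point.  Zero is
the worst score.  For survival reporting scores 1-3 are grouped into a
single stratum, because intermediate scores do not separate survival;
response tables keep all five levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .cutpoints import METRICS, CutpointSet
from .errors import ScoringError

#: survival strata in display order
STRATA = ("0", "1-3", "4")


def stratum_of(score: int) -> str:
    """Map a 0-4 score onto the survival stratum label."""
    if score == 0:
        return "0"
    if score == 4:
        return "4"
    return "1-3"


@dataclass(frozen=True)
class SMSResult:
    """Score with its per-component indicators and survival stratum."""

    score: int
    indicators: dict[str, bool]  # metric name -> favourable?
    stratum: str


def _favourable(value: float, threshold: float, direction: str) -> bool:
    # strict inequalities: equality with the cutpoint is unfavourable
    return value > threshold if direction == "above" else value < threshold


def score_patient(
    metrics: dict[str, float], sex: str, cutpoints: CutpointSet
) -> SMSResult:
    """Score one patient from their four height-normalised metrics."""
    indicators: dict[str, bool] = {}
    for metric in METRICS:
        if metric not in metrics or metrics[metric] is None or not np.isfinite(metrics[metric]):
            raise ScoringError(f"missing or non-finite metric {metric!r}")
        if (sex, metric) not in cutpoints.cells:
            raise ScoringError(f"no cutpoint available for sex={sex!r}, metric={metric!r}")
        cp = cutpoints.cells[(sex, metric)]
        indicators[metric] = _favourable(float(metrics[metric]), cp.threshold, cp.direction)
    score = int(sum(indicators.values()))
    return SMSResult(score=score, indicators=indicators, stratum=stratum_of(score))


def data_generating_score(frame: pd.DataFrame, cutpoints: CutpointSet) -> np.ndarray:
    """Vectorised scoring of a frame with metric and ``sex`` columns."""
    score = np.zeros(len(frame), dtype=int)
    sex = frame["sex"].to_numpy()
    for metric in METRICS:
        values = frame[metric].to_numpy(dtype=float)
        for s in ("male", "female"):
            mask = sex == s
            if not mask.any():
                continue
            cp = cutpoints.cells[(s, metric)]
            fav = values[mask] > cp.threshold if cp.direction == "above" else values[mask] < cp.threshold
            score[mask] += fav.astype(int)
    return score


def score_cohort(cohort: pd.DataFrame, cutpoints: CutpointSet) -> pd.DataFrame:
    """Attach score, indicator and stratum columns to a metric-bearing cohort.

    Patients whose scoring fails (missing metric or cutpoint cell) get a
    ``score_error`` flag instead of a score; nothing is dropped.
    """
    out = cohort.copy()
    scores: list[float] = []
    strata: list[str | None] = []
    errors: list[str] = []
    ind_cols: dict[str, list] = {m: [] for m in METRICS}
    for _, row in cohort.iterrows():
        try:
            res = score_patient({m: row.get(m) for m in METRICS}, row["sex"], cutpoints)
            scores.append(res.score)
            strata.append(res.stratum)
            errors.append("")
            for m in METRICS:
                ind_cols[m].append(res.indicators[m])
        except ScoringError as exc:
            scores.append(np.nan)
            strata.append(None)
            errors.append(str(exc))
            for m in METRICS:
                ind_cols[m].append(None)
    out["sms"] = pd.array(scores, dtype="Int64") if any(np.isnan(scores)) else np.asarray(scores, dtype=int)
    out["sms_stratum"] = strata
    out["score_error"] = errors
    for m in METRICS:
        out[f"fav_{m}"] = ind_cols[m]
    return out


def response_by_score(scored: pd.DataFrame, subset_col: str | None = "subset") -> pd.DataFrame:
    """Per-score frequency and oCR rate, per subset and for the total cohort.

    Returns tidy rows (subset, sms, n, n_ocr, ocr_rate_pct).  Frequencies
    within a subset sum to the subset size; rates are exact fractions
    reported as unrounded percentages (rounding is the report layer's job).
    """
    frames = []
    subsets: list[tuple[str, pd.DataFrame]] = []
    if subset_col is not None and subset_col in scored.columns:
        for name, grp in scored.groupby(subset_col, sort=True):
            subsets.append((str(name), grp))
    subsets.append(("total", scored))
    for name, grp in subsets:
        grp = grp.dropna(subset=["sms"])
        for s in range(5):
            sub = grp[grp["sms"] == s]
            n = len(sub)
            n_ocr = int(sub["ocr"].sum())
            frames.append(
                {
                    "subset": name,
                    "sms": s,
                    "n": n,
                    "n_ocr": n_ocr,
                    "ocr_rate_pct": 100.0 * n_ocr / n if n else np.nan,
                }
            )
    return pd.DataFrame(frames)


@dataclass(frozen=True)
class ExtremeScoreResult:
    """Operating characteristics of the {0, 4}-restricted classifier.

    Undefined quantities (no responders, or no non-responders, among the
    extreme-score patients) are None, never a fabricated number.
    """

    sensitivity: Fraction | None
    specificity: Fraction | None
    n_evaluated: int

    @property
    def sensitivity_pct(self) -> float | None:
        return None if self.sensitivity is None else 100.0 * float(self.sensitivity)

    @property
    def specificity_pct(self) -> float | None:
        return None if self.specificity is None else 100.0 * float(self.specificity)


def extreme_score_classifier(scored: pd.DataFrame) -> ExtremeScoreResult:
    """Predict oCR from the extreme scores only: among patients with
    SMS 0 or 4, call oCR if and only if SMS = 4.

    Sensitivity and specificity are computed on that restricted set with
    exact integer arithmetic.
    """
    restricted = scored[scored["sms"].isin([0, 4])]
    responders = restricted[restricted["ocr"].astype(bool)]
    non_responders = restricted[~restricted["ocr"].astype(bool)]
    tp = int((responders["sms"] == 4).sum())
    tn = int((non_responders["sms"] == 0).sum())
    sens = Fraction(tp, len(responders)) if len(responders) else None
    spec = Fraction(tn, len(non_responders)) if len(non_responders) else None
    return ExtremeScoreResult(
        sensitivity=sens, specificity=spec, n_evaluated=len(restricted)
    )
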