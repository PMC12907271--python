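"""Synthetic rectal-cancer cohort generator.

Emulates the two tables the analysis pipeline consumes, with the
statistical structure the downstream stages assume:

* a patient-level cohort (demographics, staging, treatment, response,
  follow-up) whose overall-complete-response (oCR) indicator is drawn
  from a logistic model in the data-generating skeletal muscle score,
  and whose survival times follow exponential proportional hazards on
  the score strata {0, 1-3, 4};
* a per-slice segmentation summary (one row per patient x axial slice x
  compartment) whose areas and densities are *solved* so that slice
  aggregation recovers each patient's target metrics exactly.

Body-composition marginals are sex-specific Gaussians centred on the
sex-specific reference cutpoints (so roughly half of each sex falls on
the favourable side of each cutpoint, reproducing the heavy mid-score
mass seen in practice), truncated at physiologic bounds, and coupled by
an equicorrelated Gaussian copula.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cutpoints import (
    METRICS,
    SEXES,
    CutpointSet,
    reference_cutpoints,
)
from .errors import ConfigError
from .scoring import STRATA, data_generating_score, stratum_of

#: HU window outside which CT soft-tissue densities are clamped
DENSITY_BOUNDS = (-190.0, 150.0)


@dataclass(frozen=True)
class MetricDistribution:
    """Gaussian marginal of one metric for one sex (units of the metric)."""

    loc: float
    scale: float


@dataclass(frozen=True)
class OcrModel:
    """logit P(oCR) = intercept + slope * SMS."""

    intercept: float
    slope: float


@dataclass(frozen=True)
class EndpointHazards:
    """Exponential cause-specific hazard: rate * exp(log HR of stratum)."""

    baseline_rate: float  # events per year in the reference (1-3) stratum
    stratum_log_hr: dict[str, float]  # keys "0", "1-3", "4"


@dataclass(frozen=True)
class SurvivalModel:
    """Cause-specific exponential proportional-hazards generator.

    Overall death is the minimum of the cancer-death and other-death
    causes; recurrence runs on its own clock and is truncated by death.
    Censoring is the minimum of an exponential drop-out draw and the
    administrative follow-up horizon.
    """

    recurrence: EndpointHazards
    cancer_death: EndpointHazards
    other_death: EndpointHazards
    censoring_rate: float  # per year; 0 = administrative censoring only
    horizon_years: float


@dataclass(frozen=True)
class SliceModel:
    """Shape of the per-slice table: lumbosacral stacks of thin axial cuts."""

    n_slices_range: tuple[int, int] = (110, 150)
    slice_thickness_mm: float = 3.0
    area_noise_shape: float = 20.0  # gamma shape of per-slice area weights
    density_noise_sd: float = 8.0  # HU, within-patient slice-to-slice spread


def _default_metric_distributions() -> dict[tuple[str, str], MetricDistribution]:
    scales = {
        "sm_volume_index": 260.0,
        "sm_density": 5.5,
        "imat_volume_index": 50.0,
        "imat_density": 6.0,
    }
    ref = reference_cutpoints()
    return {
        (sex, metric): MetricDistribution(
            loc=ref.threshold(sex, metric), scale=scales[metric]
        )
        for sex in SEXES
        for metric in METRICS
    }


def _default_survival_model() -> SurvivalModel:
    return SurvivalModel(
        recurrence=EndpointHazards(
            baseline_rate=0.055,
            stratum_log_hr={"0": 0.9, "1-3": 0.0, "4": -2.2},
        ),
        cancer_death=EndpointHazards(
            baseline_rate=0.022,
            stratum_log_hr={"0": 1.0, "1-3": 0.0, "4": -2.8},
        ),
        other_death=EndpointHazards(
            baseline_rate=0.018,
            stratum_log_hr={"0": 0.0, "1-3": 0.0, "4": 0.0},
        ),
        censoring_rate=0.10,
        horizon_years=11.0,
    )


@dataclass
class SyntheticConfig:
    """Full specification of a synthetic cohort.

    Defaults mirror the development cohort's structure: 226 patients,
    69% male, ~25.7% oCR, metric marginals centred on the sex-specific
    reference cutpoints, and survival hazards that fall steeply from
    stratum 0 to stratum 4.
    """

    n_patients: int = 226
    male_fraction: float = 0.69
    metric_distributions: dict[tuple[str, str], MetricDistribution] = field(
        default_factory=_default_metric_distributions
    )
    metric_correlation: float = 0.3  # pairwise, equicorrelated Gaussian copula
    true_cutpoints: CutpointSet = field(default_factory=reference_cutpoints)
    # slope = ln(1.56), the published per-point oCR odds ratio; intercept
    # solved analytically (calibrate_ocr_intercept) so the expected oCR
    # proportion under the default score law equals 25.7%
    ocr_model: OcrModel = field(default_factory=lambda: OcrModel(-1.9980, 0.4447))
    survival_model: SurvivalModel = field(default_factory=_default_survival_model)
    slice_model: SliceModel = field(default_factory=SliceModel)
    # demographics (not outcome-linked): cohort-structure marginals
    age_mean: float = 62.5
    age_sd: float = 12.7
    height_mean: dict[str, float] = field(
        default_factory=lambda: {"male": 1.75, "female": 1.62}
    )
    height_sd: float = 0.07
    smoking_probs: tuple[float, float, float] = (0.434, 0.314, 0.252)
    t_stage_probs: tuple[float, float, float] = (0.157, 0.637, 0.206)
    n_positive_prob: float = 0.892
    tnt_prob: float = 0.226
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 0:
            raise ConfigError(f"n_patients must be a non-negative integer, got {self.n_patients!r}")
        for name, p in (
            ("male_fraction", self.male_fraction),
            ("n_positive_prob", self.n_positive_prob),
            ("tnt_prob", self.tnt_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 <= self.metric_correlation < 1.0:
            raise ConfigError(
                f"metric_correlation must be in [0, 1), got {self.metric_correlation}"
            )
        for key, dist in self.metric_distributions.items():
            if dist.scale <= 0:
                raise ConfigError(f"metric_distributions[{key}].scale must be > 0")
        for probs, name in ((self.smoking_probs, "smoking_probs"), (self.t_stage_probs, "t_stage_probs")):
            if len(probs) != 3 or any(p < 0 for p in probs) or abs(sum(probs) - 1) > 1e-9:
                raise ConfigError(f"{name} must be 3 non-negative values summing to 1")
        sm = self.survival_model
        for name, ep in (("recurrence", sm.recurrence), ("cancer_death", sm.cancer_death), ("other_death", sm.other_death)):
            if ep.baseline_rate < 0:
                raise ConfigError(f"survival_model.{name}.baseline_rate must be >= 0")
            if set(ep.stratum_log_hr) != set(STRATA):
                raise ConfigError(
                    f"survival_model.{name}.stratum_log_hr must have keys {STRATA}"
                )
        if sm.censoring_rate < 0:
            raise ConfigError("survival_model.censoring_rate must be >= 0")
        if sm.horizon_years <= 0:
            raise ConfigError("survival_model.horizon_years must be > 0")
        lo, hi = self.slice_model.n_slices_range
        if lo < 1 or hi < lo:
            raise ConfigError(
                f"slice_model.n_slices_range must satisfy 1 <= lo <= hi, got {(lo, hi)}"
            )
        if self.slice_model.slice_thickness_mm <= 0:
            raise ConfigError("slice_model.slice_thickness_mm must be > 0")
        if not (self.age_sd > 0 and self.height_sd > 0):
            raise ConfigError("age_sd and height_sd must be > 0")
        if not self.true_cutpoints.is_complete():
            raise ConfigError("true_cutpoints must have all 8 sex x metric cells")


# ---------------------------------------------------------------------------
# analytic expectations (used for calibration and as test oracles)
# ---------------------------------------------------------------------------


def favourable_probability(config: SyntheticConfig, sex: str, metric: str) -> float:
    """P(one metric falls on its favourable side) under the marginal."""
    dist = config.metric_distributions[(sex, metric)]
    cp = config.true_cutpoints.cells[(sex, metric)]
    z = (cp.threshold - dist.loc) / dist.scale
    p_above = 1.0 - stats.norm.cdf(z)
    return p_above if cp.direction == "above" else 1.0 - p_above


def score_distribution(config: SyntheticConfig, sex: str, n_quad: int = 80) -> np.ndarray:
    """Analytic P(SMS = 0..4) for one sex under the equicorrelated copula.

    With equicorrelation rho, the four latent normals share one factor W;
    conditional on W the indicators are independent, so the score law is a
    W-mixture of Poisson-binomials, integrated by Gauss-Hermite quadrature.
    """
    rho = config.metric_correlation
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    w_probs = weights / weights.sum()
    probs = np.zeros(5)
    p_marg = {m: favourable_probability(config, sex, m) for m in METRICS}
    for w, pw in zip(nodes, w_probs):
        # conditional favourable probability of each indicator given W = w;
        # Z = sqrt(rho) W + sqrt(1-rho) E.  "above" metrics fire on high Z,
        # the IMAT-density indicator fires on low Z (anti-correlated).
        pmf = np.array([1.0])
        for metric in METRICS:
            direction = config.true_cutpoints.cells[(sex, metric)].direction
            p = p_marg[metric]
            if direction == "above":
                z_cut = stats.norm.ppf(1.0 - p)
                p_cond = 1.0 - stats.norm.cdf(
                    (z_cut - math.sqrt(rho) * w) / math.sqrt(1.0 - rho)
                )
            else:
                z_cut = stats.norm.ppf(p)
                p_cond = stats.norm.cdf(
                    (z_cut - math.sqrt(rho) * w) / math.sqrt(1.0 - rho)
                )
            pmf = np.convolve(pmf, [1.0 - p_cond, p_cond])
        probs += pw * pmf
    return probs


def expected_ocr_rate(config: SyntheticConfig) -> float:
    """Analytic oCR proportion: the logistic model mixed over the score law
    and the sex mix."""
    total = 0.0
    for sex, w in (("male", config.male_fraction), ("female", 1 - config.male_fraction)):
        if w == 0:
            continue
        p_s = score_distribution(config, sex)
        scores = np.arange(5)
        rate = special.expit(config.ocr_model.intercept + config.ocr_model.slope * scores)
        total += w * float(p_s @ rate)
    return total


def calibrate_ocr_intercept(
    config: SyntheticConfig, target_rate: float, slope: float | None = None
) -> float:
    """Intercept making the analytic oCR proportion equal ``target_rate``
    at the given slope (default: the config's slope)."""
    slope = config.ocr_model.slope if slope is None else slope

    def gap(a: float) -> float:
        trial = SyntheticConfig(**{**asdict_shallow(config), "ocr_model": OcrModel(a, slope)})
        return expected_ocr_rate(trial) - target_rate

    return float(optimize.brentq(gap, -20.0, 20.0, xtol=1e-10))


def asdict_shallow(config: SyntheticConfig) -> dict:
    """Field dict without recursing into nested dataclasses."""
    return {f: getattr(config, f) for f in config.__dataclass_fields__}


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "patient_id", "sex", "age_years", "height_m", "smoking", "t_stage",
    "n_stage", "tnt",
    "sm_volume_index", "sm_density", "imat_volume_index", "imat_density",
    "true_score", "true_stratum", "ocr",
    "recurrence_time_years", "recurrence_event", "recurrence_censored",
    "death_time_years", "death_event", "death_censored",
    "cancer_death_time_years", "cancer_death_event", "cancer_death_censored",
]


def _draw_times(rng: np.random.Generator, rates: np.ndarray) -> np.ndarray:
    """Exponential event times; a zero rate means the event never occurs."""
    u = rng.random(len(rates))
    with np.errstate(divide="ignore"):
        return np.where(rates > 0, -np.log1p(-u) / np.where(rates > 0, rates, 1.0), np.inf)


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Draw a full synthetic cohort table (one row per patient).

    The returned frame carries the patients' *true* body-composition
    metrics (the targets the slice table is solved against), the
    data-generating score and stratum, the oCR draw and the observed,
    censored follow-up times with event and censoring flags.
    """
    config.validate()
    n = config.n_patients
    rng = np.random.default_rng(config.seed)
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)

    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 95.0)
    height = np.clip(
        rng.normal([config.height_mean[s] for s in sex], config.height_sd),
        1.40, 2.10,
    )
    smoking = rng.choice(["never", "ex", "current"], size=n, p=config.smoking_probs)
    t_stage = rng.choice([2, 3, 4], size=n, p=config.t_stage_probs)
    n_stage = np.where(rng.random(n) < config.n_positive_prob, "N+", "N0")
    tnt = rng.random(n) < config.tnt_prob

    # metrics: equicorrelated Gaussian copula via a shared factor
    rho = config.metric_correlation
    w = rng.standard_normal(n)
    eps = rng.standard_normal((n, len(METRICS)))
    z = math.sqrt(rho) * w[:, None] + math.sqrt(1.0 - rho) * eps
    metrics = {}
    for j, metric in enumerate(METRICS):
        loc = np.array([config.metric_distributions[(s, metric)].loc for s in sex])
        scale = np.array([config.metric_distributions[(s, metric)].scale for s in sex])
        x = loc + scale * z[:, j]
        if metric.endswith("volume_index"):
            # physiologic floor: every patient carries some tissue volume
            x = np.clip(x, 1.0, None)
        else:
            x = np.clip(x, *DENSITY_BOUNDS)
        metrics[metric] = x

    score = data_generating_score(pd.DataFrame({**metrics, "sex": sex}), config.true_cutpoints)
    stratum = np.array([stratum_of(s) for s in score])
    p_ocr = special.expit(config.ocr_model.intercept + config.ocr_model.slope * score)
    ocr = rng.random(n) < p_ocr

    sm = config.survival_model
    lhr = {
        name: np.array([ep.stratum_log_hr[st] for st in stratum])
        for name, ep in (
            ("recurrence", sm.recurrence),
            ("cancer_death", sm.cancer_death),
            ("other_death", sm.other_death),
        )
    }
    t_rec = _draw_times(rng, sm.recurrence.baseline_rate * np.exp(lhr["recurrence"]))
    t_cd = _draw_times(rng, sm.cancer_death.baseline_rate * np.exp(lhr["cancer_death"]))
    t_od = _draw_times(rng, sm.other_death.baseline_rate * np.exp(lhr["other_death"]))
    censor = np.minimum(
        _draw_times(rng, np.full(n, sm.censoring_rate)), sm.horizon_years
    )

    t_death = np.minimum(t_cd, t_od)
    death_event = t_death <= censor
    death_time = np.minimum(t_death, censor)
    cancer_death_event = death_event & (t_cd <= t_od)
    # for cancer-specific analyses non-cancer deaths act as censoring at the
    # death time, so the at-risk time is the same observed follow-up
    cancer_death_time = death_time
    rec_window = np.minimum(censor, t_death)
    rec_event = t_rec <= rec_window
    rec_time = np.minimum(t_rec, rec_window)

    frame = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "sex": sex,
            "age_years": age,
            "height_m": height,
            "smoking": smoking,
            "t_stage": t_stage,
            "n_stage": n_stage,
            "tnt": tnt,
            **metrics,
            "true_score": score,
            "true_stratum": stratum,
            "ocr": ocr,
            "recurrence_time_years": rec_time,
            "recurrence_event": rec_event,
            "recurrence_censored": ~rec_event,
            "death_time_years": death_time,
            "death_event": death_event,
            "death_censored": ~death_event,
            "cancer_death_time_years": cancer_death_time,
            "cancer_death_event": cancer_death_event,
            "cancer_death_censored": ~cancer_death_event,
        }
    )
    return frame[COHORT_COLUMNS]


SLICE_COLUMNS = [
    "patient_id", "slice_index", "compartment",
    "area_cm2", "mean_density_hu", "slice_thickness_mm",
]


def generate_slice_table(cohort: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Solve a per-slice table consistent with each patient's true metrics.

    Per patient a slice count is drawn, per-slice areas are gamma-weighted
    shares of the target volume (so the aggregated volume matches the
    target to machine precision) and per-slice densities are mean-centred
    noise around the target density (so the plain slice average matches
    exactly).  Uses a child seed of ``config.seed`` so the cohort and its
    slice table are jointly deterministic.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lo, hi = config.slice_model.n_slices_range
    thick = config.slice_model.slice_thickness_mm
    shape = config.slice_model.area_noise_shape
    dens_sd = config.slice_model.density_noise_sd

    parts: list[pd.DataFrame] = []
    for row in cohort.itertuples(index=False):
        n_slices = int(rng.integers(lo, hi + 1))
        h2 = row.height_m**2
        targets = {
            "SM": (row.sm_volume_index * h2, row.sm_density),
            "IMAT": (row.imat_volume_index * h2, row.imat_density),
        }
        for compartment, (volume, density) in targets.items():
            weights = rng.gamma(shape, size=n_slices)
            areas = volume * (weights / weights.sum()) / (thick / 10.0)
            noise = rng.normal(0.0, dens_sd, n_slices)
            dens = density + noise - noise.mean()
            parts.append(
                pd.DataFrame(
                    {
                        "patient_id": row.patient_id,
                        "slice_index": np.arange(n_slices),
                        "compartment": compartment,
                        "area_cm2": areas,
                        "mean_density_hu": dens,
                        "slice_thickness_mm": thick,
                    }
                )
            )
    if not parts:
        return pd.DataFrame(columns=SLICE_COLUMNS)
    return pd.concat(parts, ignore_index=True)[SLICE_COLUMNS]
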