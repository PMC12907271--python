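"""End-to-end driver: simulate/ingest -> aggregate -> split -> cutpoints ->
score -> response -> homogeneity -> logistic model -> survival.

Every artefact is a CSV (plus a plain-text summary) written into the
output directory together with a manifest carrying the seed and a hash of
the configuration, so equal configurations produce byte-identical
bundles.  A structured log records patient counts at each stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import body_composition, io, outcomes, scoring, survival
from .cutpoints import CutpointSet, derive_cutpoint_set, split_cohort
from .errors import ConfigError, SmsError
from .simulate import SyntheticConfig, generate_cohort, generate_slice_table

log = logging.getLogger("smscore")


@dataclass
class PipelineConfig:
    """Inputs and options of a full pipeline run.

    Either ``synthetic`` is set (the generator produces both tables) or
    both input paths point at existing CSVs.
    """

    output_dir: Path
    synthetic: SyntheticConfig | None = None
    slice_table_path: Path | None = None
    cohort_table_path: Path | None = None
    train_fraction: float = 166 / 226
    split_seed: int = 20130
    sms_coding: str = "grouped"
    thickness_weighted_density: bool = False
    covariates: tuple[str, ...] = outcomes.DEFAULT_OCR_COVARIATES
    verbosity: int = logging.INFO

    def validate(self) -> None:
        if self.synthetic is None:
            for name, p in (
                ("slice_table_path", self.slice_table_path),
                ("cohort_table_path", self.cohort_table_path),
            ):
                if p is None or not Path(p).exists():
                    raise ConfigError(f"{name} must point at an existing file, got {p}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError(f"train_fraction must be in (0, 1), got {self.train_fraction}")

    def hash(self) -> str:
        payload = {
            "synthetic": dataclasses.asdict(self.synthetic) if self.synthetic else None,
            "slice_table_path": str(self.slice_table_path),
            "cohort_table_path": str(self.cohort_table_path),
            "train_fraction": self.train_fraction,
            "split_seed": self.split_seed,
            "sms_coding": self.sms_coding,
            "thickness_weighted_density": self.thickness_weighted_density,
            "covariates": list(self.covariates),
        }

        def sanitize(o):
            if isinstance(o, dict):
                return {str(k): sanitize(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [sanitize(v) for v in o]
            if isinstance(o, (str, int, float, bool)) or o is None:
                return o
            return str(o)

        blob = json.dumps(sanitize(payload), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """In-memory handles to every artefact of a pipeline run."""

    output_dir: Path
    cohort: pd.DataFrame
    metrics: pd.DataFrame
    qc: pd.DataFrame
    cutpoints: CutpointSet
    scored: pd.DataFrame
    response: pd.DataFrame
    extreme: scoring.ExtremeScoreResult
    distribution_test: outcomes.FisherResult
    homogeneity: outcomes.HomogeneityResult | None
    logistic: outcomes.LogisticModelResult
    model_auc: outcomes.AucResult
    survival_by_stratum: dict[str, survival.StratifiedSurvival]
    cox: dict[str, survival.CoxResult]
    stage_counts: dict[str, int] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle.

    Any stage failure propagates as a :class:`SmsError` naming the stage;
    artefacts written before the failure are left on disk.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.verbosity)
    counts: dict[str, int] = {}
    stage = "setup"
    try:
        stage = "simulate" if config.synthetic else "ingest"
        if config.synthetic:
            cohort = generate_cohort(config.synthetic)
            slices = generate_slice_table(cohort, config.synthetic)
            io.write_table(cohort, out / "cohort.csv")
            io.write_table(slices, out / "slices.csv")
            seed = config.synthetic.seed
        else:
            cohort = io.read_cohort_table(config.cohort_table_path)
            slices = io.read_slice_table(config.slice_table_path)
            seed = config.split_seed
        counts["total"] = len(cohort)
        log.info("stage=%s patients=%d slices=%d", stage, len(cohort), len(slices))

        stage = "aggregate"
        qc = body_composition.qc_filter(slices)
        heights = cohort.set_index("patient_id")["height_m"]
        metrics = body_composition.aggregate_cohort(
            slices, heights, thickness_weighted_density=config.thickness_weighted_density
        )
        io.write_table(qc, out / "qc.csv")
        io.write_table(metrics, out / "metrics.csv")
        counts["excluded"] = int((~qc["included"]).sum())
        counts["included"] = len(metrics)
        log.info("stage=aggregate included=%d excluded=%d", counts["included"], counts["excluded"])

        analysed = cohort.drop(
            columns=[c for c in io.out_metric_columns(cohort)], errors="ignore"
        ).merge(metrics, on="patient_id", how="inner")

        stage = "split"
        train, validation = split_cohort(analysed, config.train_fraction, config.split_seed)
        analysed = analysed.copy()
        analysed["subset"] = np.where(
            analysed["patient_id"].isin(train["patient_id"]), "train", "validation"
        )
        counts["train"] = len(train)
        counts["validation"] = len(validation)
        log.info("stage=split train=%d validation=%d", len(train), len(validation))

        stage = "derive-cutpoints"
        cutpoints = derive_cutpoint_set(analysed[analysed["subset"] == "train"])
        io.write_table(cutpoints.to_frame(), out / "cutpoints.csv")

        stage = "score"
        scored = scoring.score_cohort(analysed, cutpoints)
        io.write_table(scored, out / "scored.csv")

        stage = "response"
        response = scoring.response_by_score(scored)
        extreme = scoring.extreme_score_classifier(scored)
        io.write_table(response, out / "response_by_score.csv")

        stage = "homogeneity"
        dist_test = outcomes.score_distribution_test(scored, seed=seed)
        try:
            homogeneity = outcomes.sms_ocr_homogeneity(scored)
        except SmsError as exc:
            log.warning("homogeneity test unavailable: %s", exc)
            homogeneity = None

        stage = "logistic-model"
        design = outcomes.build_ocr_design(scored, config.covariates)
        logistic = outcomes.logistic_fit(design, scored["ocr"].astype(bool))
        model_auc = outcomes.model_roc(
            logistic.fitted_probabilities, scored["ocr"].astype(bool)
        )
        terms = logistic.terms.copy()
        terms.index.name = "covariate"
        io.write_table(terms.reset_index(), out / "logistic_model.csv")

        stage = "survival"
        strat = {ep: survival.survival_by_sms(scored, ep) for ep in survival.ENDPOINTS}
        for ep, res in strat.items():
            for label, curve in res.curves.items():
                io.write_table(
                    curve.to_frame(), out / f"km_{ep}_stratum_{label.replace('-', 'to')}.csv"
                )
        cox = survival.cox_by_endpoint(scored, sms_coding=config.sms_coding)
        cox_rows = []
        for ep, res in cox.items():
            for cov, row in res.terms.iterrows():
                cox_rows.append({"endpoint": ep, "covariate": cov, **row.to_dict()})
        io.write_table(pd.DataFrame(cox_rows), out / "cox_models.csv")

        stage = "report"
        bundle = ReportBundle(
            output_dir=out, cohort=cohort, metrics=metrics, qc=qc,
            cutpoints=cutpoints, scored=scored, response=response,
            extreme=extreme, distribution_test=dist_test,
            homogeneity=homogeneity, logistic=logistic, model_auc=model_auc,
            survival_by_stratum=strat, cox=cox, stage_counts=counts,
        )
        _write_summary(bundle, config, seed)
        return bundle
    except SmsError as exc:
        raise type(exc)(f"[stage={stage}] {exc}") from exc


def _fmt_pct(x, decimals=1):
    return "undefined" if x is None else f"{x:.{decimals}f}%"


def _write_summary(bundle: ReportBundle, config: PipelineConfig, seed: int) -> None:
    lines = []
    lines.append(f"smscore pipeline summary (seed={seed}, config_hash={config.hash()})")
    for k, v in bundle.stage_counts.items():
        lines.append(f"  patients {k}: {v}")
    lines.append("")
    lines.append("Sex-specific cutpoints (training cohort, Liu product criterion):")
    for (sex, metric), cp in sorted(bundle.cutpoints.cells.items()):
        rel = ">" if cp.direction == "above" else "<"
        lines.append(
            f"  {sex:6s} {metric:18s} {rel} {cp.threshold:9.1f}"
            f"  (AUC {cp.auc:.3f}, sens {cp.sensitivity:.2f}, spec {cp.specificity:.2f})"
        )
    lines.append("")
    lines.append("Response by score (total cohort):")
    total = bundle.response[bundle.response["subset"] == "total"]
    for _, r in total.iterrows():
        rate = "-" if np.isnan(r["ocr_rate_pct"]) else f"{r['ocr_rate_pct']:.1f}%"
        lines.append(f"  SMS {r['sms']}: n={r['n']:4d}  oCR {rate}")
    n_total = int(total["n"].sum())
    n_ocr = int(total["n_ocr"].sum())
    lines.append(f"  overall oCR: {n_ocr}/{n_total} = {100.0 * n_ocr / max(n_total,1):.1f}%")
    lines.append(
        "Extreme-score classifier (SMS 0 or 4): sensitivity "
        f"{_fmt_pct(bundle.extreme.sensitivity_pct, 0)}, specificity "
        f"{_fmt_pct(bundle.extreme.specificity_pct, 0)} "
        f"(n={bundle.extreme.n_evaluated})"
    )
    lines.append("")
    lines.append(
        f"Train/validation score distribution: Fisher p = {bundle.distribution_test.p_value:.3f}"
    )
    if bundle.homogeneity is not None:
        lines.append(
            f"SMS-oCR odds-ratio homogeneity (Breslow-Day): p = {bundle.homogeneity.p_value:.3f}"
        )
    lines.append("")
    lines.append(
        f"Multivariable oCR model (McFadden pseudo-R2 = {bundle.logistic.mcfadden_r2:.3f}; "
        f"AUC {bundle.model_auc.auc:.3f}, 95% CI "
        f"{bundle.model_auc.ci_low:.3f}-{bundle.model_auc.ci_high:.3f}):"
    )
    for cov, r in bundle.logistic.terms.iterrows():
        lines.append(
            f"  {cov:12s} OR {r['odds_ratio']:.2f} "
            f"({r['ci_low']:.2f}-{r['ci_high']:.2f}) p={r['p_value']:.3f}"
        )
    lines.append("")
    for ep, res in bundle.survival_by_stratum.items():
        p = "n/a" if res.logrank is None else f"{res.logrank.p_value:.4g}"
        lines.append(f"Survival ({ep}): log-rank p = {p} across strata {list(res.curves)}")
        cox = bundle.cox[ep].terms
        sms_row = cox.iloc[0]
        lines.append(
            f"  Cox SMS HR {sms_row['hazard_ratio']:.2f} "
            f"({sms_row['ci_low']:.2f}-{sms_row['ci_high']:.2f}) p={sms_row['p_value']:.3f}"
        )
    text = "\n".join(lines) + "\n"
    (bundle.output_dir / "summary.txt").write_text(text)
    manifest = {"seed": seed, "config_hash": config.hash(), "counts": bundle.stage_counts}
    (bundle.output_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
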