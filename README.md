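# smscore

Analysis pipeline for a CT body-composition **skeletal muscle score
(SMS)** in locally advanced rectal cancer: from per-slice segmentation
summaries to sex-specific optimal cutpoints, a 0–4 risk score,
treatment-response prediction and survival analysis — exercised
end-to-end on a synthetic cohort generator, since no patient-level data
is publicly available for this problem.

**Who it is for:** biostatisticians and clinical researchers who want a
tested, reproducible implementation of the indicator-sum
body-composition score workflow — derive cutpoints on training data,
score, validate, model response and survival — or who want to stress
the machinery on simulated cohorts before touching real registries.

## The score

AI segmentation of the lumbosacral (L1–S5) CT stack yields per-slice
areas (cm²) and mean radiodensities (HU) for skeletal muscle (SM) and
intermuscular/intramuscular adipose tissue (IMAT). Per patient:

```
volume (cm³)        = Σ_slices area × thickness/10
volume index        = volume / height²            (cm³/m²)
density (HU)        = mean over slices of the slice mean density
```

Sex-specific cutpoints for the four metrics (SM volume index, SM
density, IMAT volume index, IMAT density) are derived on a random
training split by maximising sensitivity × specificity on the ROC
against overall complete response (oCR) — the **Liu criterion**. The
SMS then awards one point per favourable indicator (strictly above the
cutpoint; strictly below for IMAT density):

```
SMS = 1[SMVI > c₁] + 1[SMD > c₂] + 1[IMATVI > c₃] + 1[IMATD < c₄]  ∈ {0,…,4}
```

Downstream: score-stratified response tables, an extreme-score
({0, 4}-restricted) classifier, Fisher/Breslow–Day train-validation
homogeneity checks, a multivariable logistic model of oCR (McFadden
pseudo-R², DeLong AUC CI), and Kaplan–Meier / log-rank / Cox analyses
of overall, cancer-specific and disease-free survival over the strata
{0, 1–3, 4}.

## Worked example

The numbered drivers under `analysis/` run the whole study shape on a
simulated 226-patient cohort (seed 1), writing tables under `results/`
(bulky intermediates go to `scratch/data/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_aggregate_metrics.py
python analysis/03_derive_cutpoints.py
python analysis/04_score_and_response.py
python analysis/05_response_models.py
python analysis/06_survival.py
```

`03_derive_cutpoints.py` prints the derived thresholds next to the
generator's truth:

```
split: train=166  validation=60 (seed 20130)
cell                               derived     truth   err%  AUC
female sm_volume_index              1284.8    1330.0    3.4  0.490
male   sm_volume_index              1653.3    1650.0    0.2  0.626
male   imat_density                  -56.3     -57.9    2.7  0.532
...
```

— at n = 166 with study-like (modest) effect sizes the thresholds are
noisy and the per-metric AUCs hover near 0.5, exactly as on real data;
the 5%-recovery guarantee holds at n = 2000 with strong effects (see
`docs/methods.md`). `04_score_and_response.py` then prints the
score-stratified response rates:

```
total      0:12 (8%)  1:59 (17%)  2:71 (30%)  3:69 (43%)  4:15 (73%)
extreme-score rule (SMS 0 or 4, n=27): sensitivity 92%, specificity 73%
```

i.e. in this draw, score-4 patients respond at 73% versus 8% for
score 0, and restricting to the extreme scores yields a
high-sensitivity rule — the pattern the score is designed to surface.

The same end-to-end run is available as one call
(`smscore run-all --seed 1 --out results/run`) or via the library:

```python
from smscore import PipelineConfig, SyntheticConfig, run_pipeline
bundle = run_pipeline(PipelineConfig(output_dir="out", synthetic=SyntheticConfig(seed=1)))
print(bundle.cutpoints.to_frame())
```

## Layout

```
src/smscore/        library: simulate, body_composition, cutpoints,
                    scoring, outcomes, survival, io, pipeline, cli
analysis/           numbered narrative drivers (see worked example)
tests/              pytest suite incl. property-based oracles
scripts/acceptance.py
docs/methods.md     model, assumptions, defaults and their rationale
```
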