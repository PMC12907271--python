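# Methods

## The problem and the score

Patients with locally advanced rectal cancer receive neoadjuvant therapy
(long-course chemoradiotherapy, increasingly with total neoadjuvant
therapy, TNT) before surgery or non-operative management. Roughly a
quarter achieve an *overall complete response* (oCR): either a
pathological complete response at resection or a clinical complete
response sustained for at least three years of surveillance. Predicting
oCR at diagnosis from routinely acquired staging CT is the purpose of
the *skeletal muscle score* (SMS) implemented here.

AI segmentation of the lumbosacral (L1–S5) CT stack yields, per axial
slice and tissue compartment, a cross-sectional area (cm²) and a mean
radiodensity (HU). Four patient-level metrics are built from the
skeletal muscle (SM) and intermuscular/intramuscular adipose tissue
(IMAT) compartments:

- volume (cm³) = Σ slices area × thickness/10, height-normalised to a
  *volume index* (cm³/m²) by dividing by height²;
- density (HU) = the unweighted mean of per-slice mean densities
  (deliberately *not* thickness-weighted, even for external scans with
  1–5 mm cuts, to match the formula the score was developed with; a
  thickness-weighted variant sits behind a flag, off by default).

The SMS awards one point per favourable indicator against sex-specific
cutpoints: SM volume index, SM density and IMAT volume index strictly
*above* their cutpoints, IMAT density strictly *below* its cutpoint.
Equality with a cutpoint scores nothing — the inequalities are strict
because that is the only reading the published cutpoint table supports.
Zero is the worst score. In survival reporting scores 1–3 are grouped
(they do not separate survival); response tables keep all five levels.

## Cutpoint derivation

The cohort is split by simple random allocation into training
(round(n·fraction), default 166/226) and validation sets; only training
data enters cutpoint derivation. For each sex × metric, an ROC curve
against oCR is computed on the exhaustive candidate grid — midpoints
between consecutive distinct marker values plus ±∞ sentinels — by direct
counting, with the favourable orientation fixed a priori per metric.
The optimal cutpoint is the Liu criterion: the threshold maximising
sensitivity × specificity, ties broken toward the smallest threshold.
A maximum product of zero (constant marker) is flagged non-informative.
AUC is the trapezoidal area, which on this grid equals the
Mann–Whitney pair-counting probability with ties credited ½ (the points
must be sorted lexicographically by (FPR, sensitivity) for the
trapezoid to track the staircase exactly). Derived thresholds are kept
unrounded internally; rounding to printed precision is the report
layer's job.

Open design points resolved here: the split is simple random without
stratification by outcome or sex (how the original allocation was
stratified is not documented anywhere authoritative, and simple random
is the weakest assumption), and AUC confidence intervals use the DeLong
structural-components variance.

## Response analysis

- Fisher's exact test: 2×2 via the hypergeometric point-probability
  criterion; r×c by exact enumeration of all tables sharing the margins
  (feasible well beyond the 3×2/2×5 tables arising here; capped at
  2×10⁵ tables) with a seeded Monte-Carlo fallback (≥10⁵ margin-
  conditional permutations, standard error reported).
- Mann–Whitney U: exact enumeration for tie-free samples of ≤20 per
  group, tie-corrected normal approximation otherwise.
- Train/validation homogeneity of the SMS–oCR association: Breslow–Day
  test around the Mantel–Haenszel odds ratio (SMS dichotomised at ≥2 to
  form the 2×2 per subset), optional Tarone correction off by default.
  Strata with a zero margin carry no odds-ratio information and are
  dropped with a record.
- The multivariable oCR model is a maximum-likelihood logistic fit.
  Covariate codings produce one odds ratio per variable: age per year,
  sex (female = 1), smoking ordinal never/ex/current = 0/1/2, T stage
  numeric, N stage (N+ = 1), TNT (yes = 1), SMS as the integer 0–4.
  These codings are assumptions, configurable via the covariate list.
  McFadden pseudo-R² = 1 − ℓ/ℓ₀. Separation is detected (diverging
  coefficients) and raised, not silently reported. The model ROC's CI
  uses the DeLong variance. No multiple-testing correction is applied;
  all tests are two-sided at α = 0.05.

## Survival analysis

Three endpoints clocked from diagnosis: overall survival (any death),
cancer-specific survival (cancer death; non-cancer deaths censor — no
competing-risks model), and disease-free survival (first of recurrence
or death, the standard oncology convention, adopted because the term is
used without definition in this literature). Kaplan–Meier curves use
the product-limit estimator with events before censorings at ties;
log-rank compares the strata {0, 1–3, 4}. Cox models use Efron tie
handling and Newton iteration; the default SMS coding is the grouped
stratum as an ordinal 0/1/2 (matching how survival is grouped in
reporting), with the continuous 0–4 coding available — with ~226
patients neither coding can be singled out as "the" published one, so
both are exposed and neither is claimed to reproduce any particular
printed hazard ratio.

## The synthetic cohort generator

No patient-level data accompanies the published study, so the pipeline
is exercised end-to-end on synthetic cohorts whose *defaults are the
study conditions*: 226 patients, 69% male, and an expected oCR
proportion of 25.7%.

- **Metrics.** Per sex, each of the four metrics is Gaussian with its
  location at the sex-specific reference cutpoint (male
  1650 / 39.5 / 125 / −57.9, female 1330 / 38.6 / 129 / −56.2), so about
  half of each sex falls on the favourable side of each indicator,
  reproducing the heavy 1–3 score mass seen in the development cohort.
  Scales (260 cm³/m², 5.5 HU, 50 cm³/m², 6 HU) are realistic spreads
  chosen once; the published supplement that would pin them was not
  available, so they are declared, not fitted. Volume indices are
  floored at 1 cm³/m² (everyone carries some tissue); densities are
  clamped to the conventional CT soft-tissue window [−190, 150] HU.
  The four metrics share an equicorrelated Gaussian copula (ρ = 0.3 by
  default — SM density and IMAT volume are known to correlate, but no
  value is printed, so a moderate default is used).
- **Response.** oCR ~ Bernoulli(expit(a + b·SMS*)) on the
  data-generating score SMS*. The default slope is ln(1.56), the
  published per-point odds ratio; the intercept (−1.9980) is solved
  analytically so the *expected* oCR proportion equals 25.7%. The
  analytic score law (a Gauss–Hermite mixture of Poisson-binomials over
  the copula's shared factor, with the IMAT-density indicator firing on
  a *low* latent value and therefore anti-correlated with the other
  three) doubles as an independent oracle for the calibration tests.
- **Survival.** Three cause-specific exponential clocks — recurrence,
  cancer death, other death — each proportional-hazards on the strata
  {0, 1–3, 4}; overall death is the minimum of the two death causes and
  recurrence is truncated by death. This elaboration of a single-
  baseline design is the simplest generator that can produce all three
  endpoints while keeping every cause exactly exponential-PH, so the
  Cox stage can recover the configured log-hazard ratios. Defaults
  (baseline 0.055/0.022/0.018 events·yr⁻¹; stratum log-HRs
  +0.9/0/−2.2 for recurrence, +1.0/0/−2.8 for cancer death, none for
  other-cause death) give event counts over a ~5-year median follow-up
  of the same order as the development cohort (≈24% recurrence, ≈16%
  death), with the score-4 stratum rarely experiencing cancer events
  within 5 years. Censoring is exponential drop-out (0.10/yr) truncated
  at an 11-year administrative horizon.
- **Slice tables.** Per patient, 110–150 axial cuts of 3 mm; per-slice
  areas are gamma-weighted shares of the target volume and densities
  are mean-centred noise around the target density, *solved* so that
  aggregation recovers every patient's metrics to machine precision
  (well inside the 10⁻⁶ relative round-trip tolerance the tests
  assert). Generation is deterministic given the seed, with the slice
  table on a child seed of the cohort's.

What the generator does **not** emulate: metric–covariate confounding
(age, smoking and stage are drawn independently of body composition),
non-proportional hazards, informative censoring, inter-scanner density
shifts, and anatomically realistic slice-to-slice area profiles. Tests
passing on this generator therefore demonstrate the *machinery* —
estimation, calibration and bookkeeping — not clinical validity on real
cohorts, which requires external validation by construction.

## Numerical choices and problem sizes

- ROC thresholds are inter-value midpoints; AUC trapezoid equals
  pair-counting to ~10⁻¹⁶ on every tested instance.
- Logistic and Cox fits iterate Newton-type steps to tight gradient
  tolerances (statsmodels/lifelines defaults, 10⁻⁸-class); degenerate
  designs (rank deficiency, single-class outcomes, zero events,
  separation) raise typed errors naming the offender.
- Liu-cutpoint recovery is checked at n = 2000 with a strong response
  effect (per-point log-odds 2.5, i.e. OR ≈ 12): all eight sex-specific
  thresholds land within 5% of the generating truth, and the error
  shrinks from n = 400 to n = 5000. The strong effect is what makes
  the per-metric ROC kink identifiable at this size; the study-like
  default slope gives much flatter ROCs and correspondingly noisy
  thresholds at n = 166 — visible in `analysis/03_derive_cutpoints.py`.
- Statistical calibration suites run 1000 Breslow–Day replicates
  (two strata of 2×120, common OR 2), 12 Cox replicates at n = 5000
  for bias and 500 at n = 500 for CI coverage; these sizes keep the
  whole suite in the minutes range on a single CPU while leaving the
  Monte-Carlo error well below the asserted bands.
- The r×c Fisher enumeration cap (2×10⁵ tables) comfortably covers the
  3×2 tables of interest; the score-distribution 2×5 test at n = 226
  exceeds it and falls back to seeded Monte Carlo.

## Known limitations

- Covariate codings behind single-OR-per-variable outputs are
  assumptions; different codings change the printed odds/hazard ratios.
- Cancer-specific survival ignores competing risks (as does the
  KM/log-rank framework it mirrors); Fine–Gray modelling is out of
  scope.
- The generator's demographic covariates are outcome-independent, so
  adjusted and unadjusted SMS effects coincide in expectation on
  synthetic data.
- Derived cutpoints at the default n = 166 training size are noisy;
  the package reports them with their AUCs and operating points so the
  uncertainty is visible rather than hidden.
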