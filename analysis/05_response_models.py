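"""Model oCR: subset homogeneity, multivariable logistic regression, ROC.

Reads scratch/data/scored.csv; writes results/logistic_model.csv and prints the
Breslow-Day homogeneity check, the adjusted odds ratios and the model AUC.
"""

from pathlib import Path

import pandas as pd

from smscore import build_ocr_design, logistic_fit, model_roc
from smscore.io import write_table
from smscore.outcomes import score_distribution_test, sms_ocr_homogeneity

SEED = 1


def main() -> None:
    scored = pd.read_csv("scratch/data/scored.csv")

    dist = score_distribution_test(scored, seed=SEED)
    print(f"score distribution train vs validation: Fisher p = {dist.p_value:.3f} ({dist.method})")
    hom = sms_ocr_homogeneity(scored)
    print(
        f"SMS-oCR odds-ratio homogeneity: Breslow-Day chi2 = {hom.statistic:.3f}, "
        f"df={hom.df}, p = {hom.p_value:.3f} "
        f"(per-subset ORs {tuple(round(o, 2) for o in hom.stratum_odds_ratios)})"
    )

    design = build_ocr_design(scored)
    fit = logistic_fit(design, scored["ocr"].astype(bool))
    terms = fit.terms.copy()
    terms.index.name = "covariate"
    write_table(terms.reset_index(), Path("results/logistic_model.csv"))
    print(f"\nmultivariable oCR model (McFadden pseudo-R2 = {fit.mcfadden_r2:.3f}):")
    for cov, r in fit.terms.iterrows():
        print(
            f"  {cov:12s} OR {r['odds_ratio']:5.2f} "
            f"({r['ci_low']:.2f}-{r['ci_high']:.2f})  p={r['p_value']:.3f}"
        )
    auc = model_roc(fit.fitted_probabilities, scored["ocr"].astype(bool))
    print(f"model ROC: AUC {auc.auc:.3f} (95% CI {auc.ci_low:.3f}-{auc.ci_high:.3f})")


if __name__ == "__main__":
    main()
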