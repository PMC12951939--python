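"""End-to-end pCR response study on a synthetic cohort.

Simulates a cohort with a planted response signal (pCR more likely with
a larger high-perfusion habitat share and smaller tumors), extracts
pre-treatment subregion radiomics, selects features (Wilcoxon ->
Spearman pruning -> boosted stability selection), fits the SMOTE-balanced
gradient-boosted classifier, and reports held-out discrimination plus
the RadScore-adjusted multivariable logistic model.

Runs in roughly half a minute; larger cohorts sharpen the estimates.
"""

import warnings

from habitatomics import StudyConfig, run_response_study, simulate_cohort_tables
from habitatomics.synth import effectful_cohort_spec, study_phantom_spec

pspec = study_phantom_spec(seed=0)
cspec = effectful_cohort_spec(n_subjects=120, seed=1)
subjects, clinical, outcomes = simulate_cohort_tables(pspec, cspec)
print(f"cohort: {len(clinical)} subjects, {int(outcomes['pcr'].sum())} pCR")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = run_response_study(subjects, clinical, outcomes, StudyConfig(seed=0, n_boot=200))

auc = report["auc_test"]
print(f"radiomics RadScore held-out AUC: {auc['estimate']:.3f} "
      f"[{auc['ci_lower']:.3f}, {auc['ci_upper']:.3f}] ({auc['n_boot']} bootstraps)")
if report["auc_test_combined"]:
    comb = report["auc_test_combined"]
    print(f"combined model (RadScore + covariates) AUC: {comb['estimate']:.3f} "
          f"[{comb['ci_lower']:.3f}, {comb['ci_upper']:.3f}]")
print("selected signature:")
for f in report["selected_features"]:
    print(f"  {f} (selection frequency {report['selection_frequency'][f]:.2f})")
mv = report["multivariable"]
if "radscore_OR" in mv:
    print(f"RadScore adjusted OR: {mv['radscore_OR']:.2f} (p = {mv['radscore_p']:.2g})")
# an AUC well above 0.5 and a significant adjusted OR mean the planted
# habitat signal was recovered from images alone
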