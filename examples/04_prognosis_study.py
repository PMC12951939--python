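"""Multitemporal DFS prognosis study on a synthetic non-pCR cohort.

The planted hazard grows with on-treatment expansion of the
moderate-perfusion subregion, so delta features carry the prognostic
signal: the delta and multitemporal models should beat the
pre-treatment-only model, mirroring the value of longitudinal imaging.
"""

import warnings

from habitatomics import StudyConfig, run_prognosis_study, simulate_cohort_tables
from habitatomics.synth import effectful_cohort_spec, study_phantom_spec

pspec = study_phantom_spec(seed=0)
cspec = effectful_cohort_spec(n_subjects=100, seed=1)
subjects, clinical, outcomes = simulate_cohort_tables(pspec, cspec)
print(f"cohort: {len(clinical)} subjects, {int(outcomes['event'].sum())} recurrence events")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = run_prognosis_study(subjects, clinical, outcomes, StudyConfig(seed=0, n_boot=200))

print(f"non-pCR subjects analysed: {report['n_subjects']} "
      f"({report['n_excluded_pcr']} pCR excluded)")
print("held-out C-index by radiomic variant:")
for name, c in report["cindex_by_variant"].items():
    print(f"  {name:>14}: {c:.3f}")
km = report["km_logrank_test"]
if "p" in km:
    print(f"log-rank p (high vs low RadScore): {km['p']:.2g}")
mv = report["multivariable"]
if "radscore_HR" in mv:
    print(f"RadScore adjusted HR: {mv['radscore_HR']:.2f} (p = {mv['radscore_p']:.2g})")
# the planted hazard is temporal, so with enough subjects the delta and
# multitemporal models beat the pre-only model; at this demonstration size
# (~85 non-pCR subjects, ~50 training) the per-variant C-indices are noisy
# and the ordering can flip — the cohort-wide log-rank split is the more
# stable readout here
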