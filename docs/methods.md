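# Methods

This note documents the models and procedures the package implements,
the defaults it freezes, what the synthetic data do and do not emulate,
and the numerical choices a maintainer would want to know about.

## Kinetic maps

The DCE signal S(t) per voxel is summarized by four single-baseline
three-point kinetic parameters. With S0 the baseline frame (frame 0
unless configured), Speak the post-baseline maximum at time tpeak,
Searly the first post-baseline frame, and Slast the final frame:

* PE = 100·(Speak − S0)/S0 (percent)
* WIS = (Speak − S0)/(tpeak − t0) (intensity/s)
* WOS = (Slast − Speak)/(tlast − tpeak), defined 0 when the curve peaks
  at the last frame (no washout observed)
* SER = (Searly − S0)/(Slast − S0), clamped to 0 when the denominator is
  within ε = 1e-8 of zero

These are the standard three-point definitions; the "first
post-contrast" frame for SER is the first post-baseline acquisition.
PE and SER are ratios and invariant to global intensity rescaling; WIS
and WOS scale linearly with it (a tested homogeneity property).

## Habitat segmentation

* **Perfusion habitats**: Lloyd k-means (k = 3, k-means++ init, best of
  10 restarts by within-cluster SSE) on the four kinetic parameters,
  z-scored within the tumor before clustering (configurable). Because
  k-means indices are arbitrary, clusters are relabeled by descending
  mean PE — PE being the most direct perfusion surrogate — so label 1 is
  always high-perfusion, 3 poor-perfusion.
* **Cellularity**: voxels strictly below the tumor-mean ADC are high
  cellularity (label 1); voxels at or above it low cellularity (label
  2). A constant-ADC tumor degenerates to a single class with a warning.
* **Peritumoral ring**: voxels whose distance to the tumor boundary lies
  in (0, 5] mm. Distances are computed on voxel centers with physical
  spacing. The Euclidean distance transform to the nearest *inside voxel
  center* overestimates the distance to the digitized tumor boundary by
  about a quarter voxel on smooth surfaces, so that offset (0.25·min
  spacing) is subtracted. The corrected estimate still upper-bounds the
  distance to the tumor as a union of voxel cubes — which lies at least
  half a voxel inside the nearest center — so thresholding at 5 mm never
  admits tissue farther than 5 mm from the tumor, while ring volumes
  agree with continuous-geometry shell volumes to within ~2% on sphere
  phantoms (center-to-center thresholding is ~5% biased low).

## Radiomic features

Per ROI: 14 IBSI 3D morphology features (mesh volume and surface from a
closed marching-cubes triangulation on the padded mask; axis lengths
from PCA of physical voxel centers; 2D diameters as per-plane maxima of
boundary-voxel distances), 18 first-order statistics (population
moments; Kurtosis not excess-corrected, so a Gaussian scores 3; Entropy
and Uniformity from the histogram of observed values, or of fixed-width
bins when configured), and 75 texture features over gray-level matrices.

Texture conventions, frozen here: discretization by fixed bin width
(default 25 intensity units for DCE; 0.05×10⁻³ mm²/s for ADC; both
configurable — no standard bin rule exists for these sequences);
distance-1 neighbourhoods; GLCM symmetric, per-direction over the 13
unique 26-connectivity offsets with feature values averaged over
directions (IBSI "averaging" aggregation); GLRLM likewise per-direction
averaged; GLSZM zones and GLDM dependencies by full 26-connectivity;
GLDM dependence size = 1 + number of neighbours within the gray-level
tolerance α = 0 (the center always depends on itself, keeping the
small-dependence emphasis denominators positive); NGTDM neighbourhood
means exclude the center voxel. Degenerate single-level images give the
defined limits (ClusterShade 0, Correlation 1, MCC 1, NGTDM contrast 0).

Every matrix construction is tested against an independent brute-force
enumeration oracle on ≤5×5×5 volumes with ≤4 gray levels.

The wavelet bank is a single-level stationary (undecimated) 3D
decomposition with the coif1 filter into the 8 L/H axis combinations,
each band the same shape as the input; even-shaped inputs reconstruct
exactly (tested at 1e-6); odd dims are edge-padded internally and
cropped. Wavelet features apply to intensity and texture classes only —
shape features are mask properties and are computed once. The audited
per-ROI counts are therefore 107 features on the original image and
14 + 93·9 = 851 with the wavelet bank; the package reports its audited
count per configuration rather than a fixed headline total.

Delta features are post-treatment minus pre-treatment values for
identical feature definitions, named `delta_<sequence>_<region>_<Feature>`.
Names are the field's bare feature names; the handful of names shared by
several texture families (Contrast, GrayLevelNonUniformity(-Normalized),
GrayLevelVariance) carry a lowercase family prefix (`glcm_Contrast`) so
all table columns are unique while printed names like `ClusterShade` and
`MeshVolume` stay in their familiar form.

In the cohort pipeline each subregion additionally emits its volume
share of the whole tumor (`VolumeFraction`), the canonical habitat-level
summary in this literature.

## Harmonization

ComBat operates on the extracted feature table (the IBSI-compatible
reading), not voxels: per-batch feature means get a normal prior and
variances an inverse-gamma prior, hyperparameters by method of moments,
and the location/scale adjustment uses the iterated empirical-Bayes
estimates. The implementation reproduces the reference R implementation
(sva::ComBat) to ~1e-6 on shared inputs. Note the EB shrinkage
deliberately leaves per-feature residual batch differences of the order
of the batch-mean sampling noise (≈0.05–0.15 SD at 200 subjects/batch);
what it removes completely is the systematic common batch effect.
Single-batch input passes through unchanged; features constant within a
batch are passed through with a warning.

## Feature selection

Fixed order: ICC → Spearman → univariate → stability selection.

* ICC(2,1): two-way random effects, absolute agreement, single rater
  (the form is a package choice; verified against pingouin's ICC(A,1)).
  Features with ICC ≥ 0.80 are retained; undefined ICCs drop the
  feature with a warning.
* Spearman pruning is greedy: features visited in descending priority
  (univariate score), later features with |ρ| ≥ 0.9 against any kept
  feature are dropped. Output is invariant to column order given fixed
  priorities; exact ties in priority break alphabetically.
* Univariate screens: two-sided Wilcoxon rank-sum for the binary task
  (exact null when the smaller group has ≤ 10 subjects and no ties are
  present, normal approximation with tie correction otherwise; strict
  p < 0.05), and a vectorized Cox score (log-rank trend) test for the
  survival task. Clinical/conventional-MRI covariates are screened
  univariably at the relaxed P < 0.10 (Fisher's exact for binary
  covariates against a binary outcome, logistic/Cox otherwise).
* Stability selection: 20 resamples of 50% of subjects drawn without
  replacement (the canonical subsampling rate — it decorrelates
  resamples; larger fractions let dataset-specific spurious correlates
  through), an XGBoost ranking by total split gain per resample, top 10
  marked per resample, final set = frequency ≥ 0.7. On pure-noise
  designs (n = 300, 51 features) this keeps ≤ 1 feature on average.

The cohort studies pad a too-small stability-selected set to a minimum
signature size of 7 by descending selection frequency — radiomic
signatures in this setting typically carry 5–10 features, and a 2-
feature signature starves the boosted model.

## Models and evaluation

* pCR: XGBoost with logistic deviance; class imbalance handled by SMOTE
  (synthetic minority points uniformly on segments to k = 5 minority
  neighbours), applied strictly inside training folds. RadScore =
  predicted probability.
* DFS: XGBoost with the negative Cox partial likelihood
  (`survival:cox`); RadScore = risk rank-normalized to [0, 1] against
  the training cohort (the survival score has no natural scale).
* Hyperparameters: small grid (depth {2, 3} × learning rate
  {0.05, 0.1}) by inner 3-fold CV maximizing AUC / Harrell's C;
  subsample 0.8, colsample 0.8, min_child_weight 3, 150 rounds.
* Multivariable adjustment and the Youden cutoff use *out-of-fold*
  training RadScores (5-fold refits): in-sample boosted scores separate
  the training labels almost perfectly, which would degenerate the
  logistic fit and the cutoff. Covariates causing quasi-separation
  (zero-count cells happen at realistic prevalences) are dropped from
  the adjusted model one at a time, worst offender first.
* AUC is the normalized Mann–Whitney statistic; Harrell's C counts
  concordant over comparable pairs with half credit for risk ties (the
  lifelines convention). 95% CIs are percentile bootstrap over subjects
  (default 1,000 resamples). Note a balanced two-group marker with
  hazard ratio 3 tops out near C ≈ 0.62 under this convention — half of
  all comparable pairs are within-group risk ties.
* Kaplan–Meier/log-rank risk stratification splits at the training-
  median multitemporal RadScore and is reported cohort-wide (training
  subjects entering with out-of-fold scores) and test-only.
* The prognosis study fits pre-only, post-only, delta-only variants and
  a multitemporal model re-selected over the union of the three
  signatures; the expected contrast is that temporal (delta,
  multitemporal) models beat the pre-only model when the hazard is
  driven by on-treatment change.
* Attributions are TreeSHAP (`pred_contribs`), satisfying local
  efficiency to numerical tolerance. Greedy tree splits divide credit
  between duplicated features unevenly (≈2:1 in simulations), so global
  importances of collinear features should be read jointly, not
  individually.

## Radiogenomics

* Risk dichotomization at a training-derived cutoff (score ≥ cutoff →
  high risk).
* Moderated differential expression: gene-wise two-group linear model;
  residual variances shrunk toward an inverse-χ² prior fitted by the
  log-variance method of moments (trigamma inversion by Newton's
  method); moderated t on d₀ + d degrees of freedom; BH adjustment;
  DEG gate |log2FC| ≥ 2 and q < 0.05. d₀ → 0 recovers the ordinary t;
  d₀ → ∞ collapses all variances to s₀² (both are tested limits).
* ORA: one-sided hypergeometric tail P(X ≥ k) over the measured-gene
  universe, BH across sets; gene sets arrive as user GMT files (the
  shipped sets are synthetic labels, not curated pathways).
* ssGSEA: per sample, genes ranked by expression; score = integrated
  difference between the rank^0.25-weighted in-set ECDF and the uniform
  out-of-set ECDF. Being rank-based it is invariant to monotone
  transforms of a sample's values; it is also compositional — planting
  shifts in one gene set perturbs the ranks, and hence the scores, of
  every other set (visible in the examples).

## Synthetic data: what it emulates, and what it does not

Phantoms are digital spheres (default 1 mm isotropic) with three
concentric perfusion habitats — perfused rim (fast wash-in, net
washout), plateau mid-zone, and a slowly, persistently enhancing core —
whose enhancement curves are piecewise-linear rise/decay archetypes
chosen to be separable in (WIS, WOS, SER, PE) space, plus a two-level
ADC structure (low-ADC high-cellularity core at 0.8 vs 1.6 ×10⁻³ mm²/s)
and additive Gaussian noise. Post-treatment images shrink each habitat
by a planted multiplier; a non-concentric pattern shifts the residual
lesion off-center. Subject-level variability: lognormal radius (σ =
0.10), Dirichlet habitat fractions (concentration 25 around
0.40/0.35/0.25), independent per-habitat response multipliers.

Outcomes: pCR ~ Bernoulli(logistic(b₀ + Xβ)) with b₀ calibrated by
bisection to a 15% prevalence (the luminal NAC regime); DFS from a
Weibull proportional-hazards model (shape 1.2, scale 12 years) with
exponential censoring calibrated by bisection to a 70% censored
fraction plus administrative censoring at 7 years — matching a ~30%
5-plus-year event rate. Conventional-MRI covariates (diffuse edema,
non-concentric shrinkage, stage, Ki-67 class) are sampled categoricals
that may enter the planted outcome links; radiologist reads cannot be
simulated mechanistically from voxels.

The *effectful* study condition plants pCR effects on the high-perfusion
volume fraction (+, 30 per unit fraction ≈ 2.9 per SD), tumor volume
(−0.003/mm³), Ki-67 (+1.0) and diffuse edema (−1.0), and DFS log-hazards
on the on-treatment change in moderate-perfusion volume (+0.006/mm³),
Ki-67 (+0.6) and non-concentric shrinkage (+0.7). The magnitudes are
free parameters of the study condition — no published effect sizes exist
to emulate — chosen once to give a strong, clearly recoverable planted
signal (latent AUC ≈ 0.96); the package's claim is *recovery of planted
structure*, not reproduction of any clinical effect size. Expression
data are log₂-scale Gaussian (gene means ~ N(7, 1), noise SD 0.5) with
planted per-set shifts in high-risk samples.

What passing tests show: the pipeline recovers planted spatial,
temporal and transcriptomic structure from images/matrices with correct
null calibration. What they do not show: performance on real breast MRI
— real data add registration error, motion, bias fields, irregular
lesion shapes, non-spherical habitats, scanner batch structure beyond
location/scale, and radiologist variability, none of which the phantoms
contain.

## Study problem sizes

The shipped study conditions use 28³-voxel grids with 7 mm tumors,
6 DCE frames at 60 s spacing, n = 300 subjects for the response study,
n = 160 (≈135 non-pCR) for the prognosis study, and 200-bootstrap CIs
in the test suite (the `evaluate` default remains 1,000) — sizes chosen
to keep a full end-to-end run on a laptop in minutes while leaving the
Monte-Carlo tolerances comfortably inside the asserted bands.

## Known limitations

* Habitats are concentric and spherical; no spatial noise correlation.
* ComBat assumes location/scale batch effects only.
* The boosted Cox model ignores time-varying effects and competing
  risks; DFS events are single-type.
* The multitemporal variant is a re-selection over per-timepoint
  signatures, not a joint spatio-temporal model.
* ssGSEA scores are compositional (see above); between-set comparisons
  on strongly shifted data should lean on ORA.
* ICC screening requires two rating tables; the synthetic cohorts have
  no second human rater, so the cohort studies exercise the ICC filter
  only via its unit tests.
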