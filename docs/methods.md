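# Methods

This note records the models, conventions and design decisions behind
`radiopath`, in the spirit of a statistical package's methods appendix. It
describes what the code computes and why; every number quoted here is
produced by the test suite or the acceptance script, not asserted from
memory.

## Imaging features

### Geometry and I/O

Volumes and masks are NIfTI-1; data arrays are indexed (x, y, z) with voxel
spacing (dx, dy, dz) in mm taken from the header. Feature computation runs
on the native grid — CT of this kind is reconstructed with slice thickness
(2.5–5 mm) much larger than in-plane pixel size, and we deliberately do not
resample: interpolation would manufacture voxels and smooth texture.
Spacing enters wherever physical units matter (volumes, areas, distances);
a mask must match its volume's shape exactly and spacing within 1e-4 mm.

### The 52-feature roster

The tumor feature set is frozen in `FEATURE_CATEGORIES`: 2 global,
15 histogram, 5 lung cancer-specific, 7 shape, 15 local (GLCM), 8 regional
(GLSZM). The named core of each category (volume, mass, energy, range,
minimum, kurtosis, IQR, HU percentiles, MPP, surface area, maximum 3D
diameter, spherical disproportion, cluster shade/prominence, maximum
probability, size-zone variability, intensity variability) is completed
with the standard members of the same first-order/Haralick/size-zone
taxonomy to reach 52. The roster is a package constant so that downstream
bookkeeping (52 + 11 emphysema + 10 clinical = 73 features in 8 categories)
is stable and testable.

Conventions worth calling out:

* **Mass** converts HU to density as (HU + 1000)/1000 g/cm³, clipped at 0 —
  the only physically meaningful reading of "tumor mass" from CT (water
  = 0 HU → 1 g/cm³).
* **Energy** is the histogram-uniformity form Σpᵢ² over the discretized
  histogram (1 ⇔ homogeneous ROI, pairing with entropy 0). The
  sum-of-squared-intensities variant is a config option
  (`energy_variant="sum_squares"`), not the default, because the feature is
  classed as histogram-based.
* **Discretization** for energy/entropy and both texture matrices is
  equal-width over the ROI's own [min, max] with 32 bins by default
  (`n_bins`); the maximum maps to the top bin, constant ROIs map to level 1.
  ROI-relative binning makes texture features contrast-invariant; 32 is the
  common default in CT radiomics.
* **GLCM**: 13 unique 3D directions at Chebyshev distance 1; each
  direction's count matrix is symmetrized with its negation, normalized to
  a probability matrix, and the matrices are averaged (directions with no
  valid pair are dropped). Averaging probabilities rather than counts keeps
  thin ROIs from being dominated by their long axis.
* **GLSZM**: zones are 26-connected components of equal level inside the
  mask. Size-zone variability and intensity variability are the
  (unnormalized) size-zone and gray-level non-uniformity statistics
  Σ(marginal²)/N; "intensity variability" is read as gray-level
  non-uniformity, the only regional statistic that matches its name.
* **Surface area** counts exposed voxel faces (6-neighborhood, outside the
  grid counts as background) weighted by physical face area. This is exact
  for box-like phantoms — the closed forms used in tests (unit cube:
  6 mm², spherical disproportion 6/(4π(3/4π)^{2/3}) ≈ 1.2407) hold to
  1e-9 — and carries a known staircase *over*-estimate for smooth shapes
  (a digitized ball's face area converges to 1.5× the sphere's). We accept
  the bias: it is deterministic, monotone-stabilizing with resolution
  (verified in tests), and the statistical pipeline standardizes features
  anyway. Marching-cubes areas would trade exactness on phantoms for a
  different bias.
* **Maximum 3D diameter** is the largest pairwise distance between
  foreground voxel centers; for ROIs above 400 voxels the pair search runs
  on the convex hull's vertices (the diameter is attained there), falling
  back to the full set for degenerate hulls.
* **Missing values**: MPP with no positive voxel, skewness/kurtosis of a
  constant ROI, and GLCM correlation with zero marginal variance are NaN,
  never 0. Downstream models use pairwise deletion.

### Emphysema

Emphysema is lung attenuation ≤ −950 HU — the threshold is inclusive, and a
test pins the boundary case. Normal lung volume is defined by subtraction,
so emphysema + normal = lung volume holds exactly by construction, per side
and overall. The 11-feature list completes the canonical seven (total/right/
left lung volume, emphysema volume, emphysema index, normal lung volume,
normal lung percentage) with per-side emphysema volumes and indices.

The segmenter (HU < −300, border-connected air removed, two largest
26-connected components, left/right by centroid) is phantom-grade by design:
it recovers generating ellipsoids at Dice ≥ 0.99 but makes no attempt at
airway removal or separation of touching lungs. On real chest CT a
dedicated segmenter should produce the masks; the feature definitions are
the contract.

## Pathway alteration calls

Silent variants are dropped on read; every other variant class counts as an
aberration — a conservative functional reading, since variant-level
annotation is out of scope. A pathway is altered when at least one member
gene is hit. The phrase "more than one of the genes" in prose descriptions
of such rules is ambiguous; the ≥ 1 reading is forced by the arithmetic of
the emulated cohort (most altered patients carry exactly one hit gene), and
the strict ≥ 2 rule is exposed as `min_genes=2` for sensitivity analysis.

The shipped gene map assigns the recurrently mutated SQCC genes — TP53
(apoptosis), RB1/PTEN/PIK3CA (proliferation), NFE2L2/KEAP1 (redox stress),
MLL2 (chromatin remodelers) — plus the canonical squamous differentiation
regulators TP63/SOX2/NOTCH1. It is a deliberate placeholder kept small and
documented; a faithful analysis of a specific cohort must supply its own
pathway→gene YAML.

## Statistical pipeline

All continuous predictors are z-standardized inside each fit, so odds and
hazard ratios are per 1 SD. The source analyses' OR scale is unstated and
some printed unit-scale ORs imply internal scaling; per-SD is the one choice
that makes ORs comparable across features, and it is applied uniformly.

* **Screening**: univariate logistic (statsmodels `Logit`, Newton, Wald
  inference). Complete separation (|β̂| > 15 on the z-scale, or a failed
  solve), constant features and single-class labels yield *flagged* results
  with NaN p-values — flagged fits can never win selection.
* **Selection**: per category, the minimum-p feature iff p < 0.2, ties
  broken lexicographically; a category with nothing below the gate
  contributes no feature. The gate is strict (p = 0.2 fails).
* **Multivariate**: one joint logistic fit on the selected features; with a
  single feature it reduces to the univariate fit (same code path, verified
  to 1e-6). In-sample AUC of the fitted linear predictor is reported — no
  cross-validation, mirroring the small-cohort design this emulates, and
  labelled as in-sample.
* **AUC** is the Mann–Whitney probability P(case > control) + ½P(tie),
  computed by `sklearn.roc_auc_score` and checked against a brute-force
  pair-count oracle in tests.
* **Smoking**: Fisher's exact test on the 3×2 smoking-status × alteration
  table uses a hand-written exact r×2 enumeration (probability ordering;
  equal to `scipy.stats.fisher_exact` on 2×2 tables to 1e-9), because scipy
  implements only the 2×2 case. Pack-years use the two-sided Wilcoxon
  rank-sum (Mann–Whitney with tie correction).
* **Survival**: Cox partial likelihood via `lifelines` (Efron ties).
  The same selection machinery is reused for DFS and OS. The prognostic
  index is scored by AUC against the event-ever-observed indicator; this
  ignores censoring time and is labelled as such — time-dependent AUC is
  the principled alternative and is intentionally not implemented.
* **Multiple testing**: none, matching the emulated design; reports carry
  the number of univariate tests (73) as context.
* No multiple-imputation: a patient missing a value is dropped from that
  specific model only.

Calibration is enforced by the acceptance suite: null logistic p-values are
KS-uniform (200 replicates, n = 500), Cox 95% CIs cover the null HR at
90–99% over 200 replicates, logistic and Cox coefficients are recovered
within ±0.15 at n = 2000, and AUC matches the bi-normal closed form
Φ(δ/√2) within ±0.01 at n = 20000.

## Synthetic data: what it does and does not show

The generators exist to make every stage testable with known truth.

* **Tumor phantoms**: ellipsoids (default semi-axes 12/10/8 mm on a 48³
  1 mm grid) with Gaussian HU texture (default base 30 HU, SD 40 HU —
  soft-tissue attenuation with heterogeneity of realistic magnitude) on a
  −800 HU lung-like background, optional hypodense core. Ellipsoid voxel
  volume matches the analytic 4πabc/3 within 5%.
* **Lung phantoms**: two −850 HU ellipsoids in a 40 HU body; an exact
  rounded count of lung voxels is set to −1000 HU, so the emphysema index
  is recoverable to ±0.5 points across the tested 0–50% grid.
* **Cohorts**: default n = 57 with clinical margins matching the emulated
  surgical SQCC cohort (95% male, 3/29/25 never/former/current smokers,
  stage 22/25/8/2, ~33% DFS events, 15 patients ineligible for lung
  volumetry). Imaging features are standard normal (optionally
  equicorrelated within category); pathway labels are Bernoulli of a
  logistic linear predictor whose intercepts reproduce the five reference
  prevalences (36.8/80.7/56.1/24.6/49.1%) and whose default coefficients
  are the per-category univariate effect sizes reported for those pathways;
  survival is Weibull proportional hazards (shape 1.2 — mildly increasing
  hazard, testable against the exponential special case) with exponential
  censoring (mean 80 months). Mutations are emitted from pathway-exclusive
  genes so the mapping rule reproduces the generating labels exactly —
  mutagenesis is not simulated, the mapping contract is.

What passing tests on these data do **not** show: robustness to scanner and
reconstruction variability, to correlated non-Gaussian feature
distributions, to segmentation error, or to real mutational spectra
(subclonality, copy-number, fusions). The generators validate the
arithmetic and the statistical calibration of the pipeline, not its
clinical performance.

Worked-example tables (`demo_clinical_table`, `demo_mutation_table`)
deterministically encode the reference cohort's printed margins — per-pathway
alteration counts 21/46/32/14/28 of 57, 19 recurrences, 18 deaths, 42
patients eligible for emphysema analysis — and are what the acceptance
script pushes through the pipeline.

## Problem sizes

Default test and acceptance sizes were chosen to exercise each property at
the smallest scale where it is informative: texture oracles on 100 random
≤ 8³ ROIs, conformance on a 64³ phantom, calibration at n = 500 × 200
replicates, recovery at n = 2000, closed-form AUC at n = 20000, driver
recovery across 10 replicate cohorts of n = 2000.

## Known limitations

* Exposed-face surface area over-estimates smooth surfaces (documented
  staircase bias); affected features remain internally consistent.
* The segmenter assumes phantom-grade anatomy.
* The event-indicator survival AUC ignores censoring times.
* The default pathway map is a named placeholder, not a complete pathway
  membership.
* 2D (per-slice) texture, wavelet/filtered features, and cross-scanner
  harmonization are out of scope.
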