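# radiopath

Radiogenomic CT analysis for lung squamous cell carcinoma (SQCC):
quantitative tumor and lung features from CT, pathway-level alteration calls
from somatic mutation tables, and the category-wise statistical pipeline that
links the two to genomics and survival.

## Who this is for

SQCC carries few actionable single-gene targets, so radiogenomic work on this
histology operates at the level of five core signaling pathways — redox
stress, apoptosis, proliferation, differentiation, chromatin remodelers —
rather than individual genes. `radiopath` is for imaging/genomics researchers
who want that full analysis as a tested, reproducible pipeline: given CT
volumes with tumor masks (NIfTI), a mutation table (TSV/MAF-aliased) and a
clinical table, it produces the feature matrix, the pathway-alteration
matrix, and the association and survival reports. A synthetic-data module
generates phantoms and cohorts with known ground truth, so every stage is
verifiable without patient data.

## What it computes

**Imaging.** 52 tumor features in six categories — global (volume in ml,
mass in g via HU→density (HU+1000)/1000), histogram-based (mean, SD, range,
energy = Σpᵢ², entropy, kurtosis, IQR, HU percentiles, …), lung
cancer-specific (MPP = mean of voxels > 0 HU, composition fractions), shape
(surface area A by exposed-face counting, maximum 3D diameter, spherical
disproportion A/4πr² with r the equal-volume-sphere radius), local (15
GLCM/Haralick statistics, 13 symmetric 3D directions at distance 1) and
regional (8 GLSZM statistics, 26-connected zones). Plus 11 emphysema
features from lung CT, with emphysema defined as attenuation ≤ −950 HU.

**Genomics.** Non-silent mutations are mapped through a pathway→gene config;
a pathway is altered when ≥ 1 member gene is hit (≥ 2 available as an
option).

**Statistics.** For each pathway, every one of the 73 clinicoradiological
features (8 categories: clinical + the 7 imaging categories) is screened by
univariate logistic regression on the z-scale; within each category the
smallest-p feature is selected iff p < 0.2; selected features enter a joint
logistic model reported as odds ratios per SD with 95% CIs, Wald p-values
and in-sample AUC. Survival (DFS/OS) uses the same selection with Cox
models (Efron ties, hazard ratios per SD) via `lifelines`, plus Fisher's
exact and Wilcoxon rank-sum tests for smoking.

## Worked example

```python
from radiopath.synthetic_data import CohortSpec, simulate_cohort
from radiopath import PathwayAssociationModel, SurvivalAssociationModel

cohort, mutations, truth = simulate_cohort(CohortSpec(seed=3))  # 57 patients
print(PathwayAssociationModel(cohort, "apoptosis").fit().summary())
```

```
Pathway association model: apoptosis
  univariate screens: 73 features, gate p < 0.2
  category              feature                     OR (95% CI)                      p
  clinical              t_descriptor                2.04 (0.55-7.59)             0.289
  global                —
  histogram             range                       0.13 (0.02-0.82)             0.030
  lung_cancer_specific  —
  shape                 max_3d_diameter_mm          2.72 (0.88-8.42)             0.083
  local                 cluster_prominence          2.75 (0.67-11.40)            0.162
  regional              low_gray_level_zone_emphasis0.51 (0.14-1.85)             0.308
  emphysema             left_lung_volume_ml         0.21 (0.04-1.11)             0.066
  in-sample AUC: 0.928
```

The generating model for this cohort drives the apoptosis label mainly
through `range` (histogram category) with a strong negative coefficient; the
fitted model recovers it as the one significant multivariate predictor
(OR 0.13 per SD, p = 0.03) — the empty category rows are those where no
feature cleared the p < 0.2 screen. The survival side reads the same way:

```python
print(SurvivalAssociationModel(cohort, "dfs").fit().summary())
```

```
Survival model (DFS): 73 screens, gate p < 0.2
  category              feature                     HR (95% CI)                        p
  clinical              n_descriptor                1.52 (0.97-2.40)               0.069
  histogram             kurtosis                    2.41 (1.25-4.65)               0.009
  shape                 surface_area_mm2            1.71 (1.00-2.94)               0.050
  local                 sum_variance                1.35 (0.81-2.22)               0.247
  regional              zone_entropy                1.56 (0.78-3.13)               0.212
  emphysema             normal_lung_pct             1.81 (1.03-3.17)               0.040
  AUC vs event indicator: 0.875
```

Here kurtosis and surface area — two of the generating DFS drivers — come
back with HR > 1 per SD at p ≤ 0.05.

## Command line

```bash
radiopath simulate  --out-dir sim --n-patients 57 --seed 0   # phantoms + cohort + truth
radiopath extract   --volumes-dir sim/volumes --masks-dir sim/masks --out-dir out
radiopath associate --config run.yaml
radiopath survive   --config run.yaml
radiopath all       --config run.yaml
```

Outputs are tidy CSV (features), JSON + text tables (association, survival)
and a per-run manifest with the config hash and library versions.

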