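# radrobust

Radiomic feature robustness databanks via image perturbation, with one-way
ICC repeatability scoring and survival-model generalizability analysis.

## The problem

Radiomic models quantify tumors on CT by hundreds of shape, intensity, and
gray-level texture descriptors extracted from a segmented region of interest.
Many of those descriptors are not repeatable: re-scanning the same patient, or
re-contouring the same tumor, changes their values enough to break models
trained on them — a major reason radiomic signatures fail on external cohorts.
Test–retest imaging is rarely available, so `radrobust` instead *simulates*
re-acquisition by perturbing each image/mask pair:

* in-plane **translations** (0, 0.4, 0.8 pixels, per axis) and **rotations**
  (−20°, 0°, 20°) about the tumor centroid,
* additive Gaussian **noise** at 0, 1, 2, or 5 × the image's own (estimated)
  noise level,
* **contour randomization** — the mask is deformed by a smoothed,
  RMS-normalized random displacement field whose z-component is constant per
  slice, mimicking slice-by-slice inter-observer contouring variability.

Sixty random combinations of the four modes are applied per patient. For each
feature, the measurements form an *n* patients × *k* repeats matrix, and
repeatability is scored by the one-way random-effects, absolute-agreement,
single-measurement intraclass correlation

```
ICC(1,1) = (MS_n − MS_W) / (MS_n + (k − 1) MS_W)
```

where `MS_n` is the between-patient and `MS_W` the within-patient mean square.
Features are classed poor (< 0.5), moderate [0.5, 0.75), good [0.75, 0.90], or
excellent (> 0.9); the per-feature records form a robustness **databank**.

The databank's payoff is measured downstream: features preselected at an ICC
threshold feed a univariate-Cox → bootstrap-LASSO-Cox → multivariate-Cox
cascade, and each model's transportability is summarized by the
generalizability index

```
G = (1/M) Σ_m | C_train − C_EV_m |
```

the mean absolute gap between the training Harrell concordance and the
concordance on each of M external-validation cohorts (lower is better).

Everything runs on synthetic CT phantom cohorts — textured ellipsoid tumors
in a soft-tissue background with known acquisition noise and simulated
proportional-hazards outcomes — so the entire pipeline is testable with no
data download.

## Worked example

```python
import radrobust as rr

# 1. a synthetic cohort: 8 phantoms, anisotropic (3,1,1) mm CT geometry
cohort = rr.generate_cohort(8, seed=1)

# 2. perturb each patient 10 times and extract the 14 shape features
table = rr.extract_measurements(
    cohort,
    rr.PerturbationGrid(n_realizations=10),
    rr.ExtractionConfig(enabled_classes=("shape",), image_types=()),
    seed=2,
)

# 3. score repeatability
databank = rr.build_databank(table, n_resamples=10, seed=3)
print(databank[["mean_icc", "class_label"]].round(3))
```

prints (volume- and area-type features are highly repeatable; the
orientation-sensitive axis ratios less so):

```
                                        mean_icc class_label
feature_name
original_shape_MeshVolume                  0.952   excellent
original_shape_VoxelVolume                 0.952   excellent
original_shape_SurfaceArea                 0.955   excellent
original_shape_SurfaceVolumeRatio          0.947   excellent
original_shape_Sphericity                  0.903   excellent
original_shape_Maximum3DDiameter           0.911   excellent
original_shape_Maximum2DDiameterSlice      0.998   excellent
original_shape_Maximum2DDiameterColumn     0.921   excellent
original_shape_Maximum2DDiameterRow        0.905   excellent
original_shape_MajorAxisLength             0.911   excellent
original_shape_MinorAxisLength             0.937   excellent
original_shape_LeastAxisLength             0.943   excellent
original_shape_Elongation                  0.810        good
original_shape_Flatness                    0.952   excellent
```

`mean_icc` is the mean one-way ICC over 10 patient-resampling rounds;
`class_label` applies the 0.5/0.75/0.9 repeatability thresholds. The full
configuration (`rr.ExtractionConfig()`) extracts 1409 features per volume:
14 shape + 93 first-order/texture features for each of 15 image types
(unfiltered, LoG σ = 1…6 mm, and 8 Coiflet-1 wavelet subbands).

A command-line interface mirrors the library stage by stage
(`radrobust phantom | perturb | extract | icc | databank | samplesize |
model | end-to-end`); `radrobust end-to-end --config cfg.yaml --out run/`
runs the whole pipeline from one YAML file and writes a manifest with the
configuration hash and seeds, so reruns are bit-identical.

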