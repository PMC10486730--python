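# bonetex

Opportunistic CT bone-texture analysis: estimating DXA-style bone mineral
density (BMD, g/cm²) and content (BMC, g) from the trabecular texture of a
single axial CT cut.

## The problem

Dual-energy X-ray absorptiometry (DXA) is the clinical reference for BMD,
but chest CT scans acquired for unrelated indications already contain the
L1 vertebra — an opportunity to screen bone status at no extra dose. The
question this package addresses is whether simple texture statistics of the
trabecular compartment predict DXA references, and whether that coupling
differs between type 2 diabetes (T2D) patients and normative subjects. T2D
is the interesting case because of the *BMD paradox*: diabetic patients
show normal-to-high DXA BMD yet elevated fracture risk, so texture-level
information beyond areal density is clinically valuable.

`bonetex` implements the full analysis as a tested, seeded library:

1. **ROI isolation** (`bonetex.roi`) — threshold the slice to a trabecular
   HU window (default 0–400 HU), take the largest connected component, and
   inscribe the largest circle in it (distance-transform maximum), shrunk
   by a safety margin.
2. **Feature grid** (`bonetex.features`) — 45 features per ROI: 5 histogram
   statistics (mean, SD, skewness, kurtosis, entropy) and 40 gray-level
   co-occurrence matrix (GLCM) statistics over 2 directions (H, V) ×
   4 quantization levels (16/32/64/128) × 5 statistics (contrast,
   correlation, energy, homogeneity, variance). Order is frozen and
   versioned.
3. **Models** (`bonetex.models`) — the linear estimator
   ŷⱼ = w₀ + Σᵢ wᵢ xᵢⱼ fitted on z-scored features by minimum-norm least
   squares (Moore–Penrose pseudoinverse; whole cohort, no train/test
   split, no regularization), plus a fixed 8-8-2 ReLU network trained by
   seeded full-batch Adam.
4. **Inference** (`bonetex.stats`) — per-weight t-tests (two-sided p on
   n−46 df), per-group significant-feature tables at α = 0.05, and the
   cross-group discordance list.
5. **Synthetic cohorts** (`bonetex.synthetic`) — because institutional
   CT/DXA data cannot be redistributed, a seeded phantom generator
   produces axial slices (cortical ring + speckled trabecular disc driven
   by a latent BMD) and cohort tables (default 145 T2D / 365 normal) with
   group-specific DXA noise that reproduces the tight-T2D / moderate-normal
   correlation pattern.

## Worked example

```python
import bonetex as bt

# one subject: phantom slice -> ROI -> 45 features
ct = bt.generate_phantom(latent_bmd=0.95, config=bt.PhantomConfig(seed=7))
roi = bt.extract_roi(ct)
fv = bt.extract_features(roi)
print(f"ROI: {roi.n_pixels} px, radius {roi.radius:.1f} px")
print(f"Mean={fv['Mean']:.1f} HU  SD={fv['SD']:.1f}  Contrast_V_64={fv['Contrast_V_64']:.1f}")

# the full default study, in memory
res = bt.run_study(bt.CohortConfig(seed=1), bt.PhantomConfig(seed=1),
                   bt.PipelineConfig(seed=1))
print(res["correlations"].to_string(index=False))
```

prints

```
ROI: 2601 px, radius 28.8 px
Mean=167.8 HU  SD=23.9  Contrast_V_64=24.2
 target  group pearson_r      sse   mse   n
hip_bmc    t2d     0.982   23.946 0.165 145
hip_bmc normal     0.773 1293.005 3.542 365
hip_bmd    t2d     0.983    0.087 0.001 145
hip_bmd normal     0.712    6.017 0.016 365
 l1_bmc    t2d     0.985   27.239 0.188 145
 l1_bmc normal     0.737 1809.754 4.958 365
 l1_bmd    t2d     0.984    0.104 0.001 145
 l1_bmd normal     0.745    7.027 0.019 365
```

The ROI mean tracks the latent BMD through the phantom's affine HU map, so
the fitted linear model recovers it almost perfectly; the per-group Pearson
r then reflects each group's DXA measurement noise — tight coupling
(r ≈ 0.98) in the T2D group, moderate coupling (r ≈ 0.71–0.77) in the
normative group. `sse` is the raw sum of squared errors and `mse` its
per-subject mean; both conventions are always reported.
`res["comparison"].discordant` lists, per target, the features significant
(p < 0.05) in exactly one group.

## Command line

```sh
bonetex simulate --n-t2d 145 --n-normal 365 --seed 1 --out-dir data
bonetex run --slices-dir data/slices --cohort-csv data/cohort.csv --out-dir run
```

`run/` then holds `features.csv`, per-target/per-group model JSONs and
coefficient CSVs, `group_comparison.csv`, `correlations.csv`,
`summary.txt`, `manifest.json` and `run.log`. Reruns with the same config
and seed are byte-identical (timestamps live only in the log).

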