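# canopyscale

Two-stage estimation of **forest canopy closure (FCC)** — the fraction of
ground covered by the vertical projection of tree crowns — from spaceborne
LiDAR footprints and multi-source raster covariates.

Spaceborne photon-counting LiDAR samples forests along orbital strips: dense,
accurate, but spatially discontinuous. Field plots are accurate but few.
`canopyscale` bridges the two scales the way a forest remote-sensing study
does:

1. **Footprint scale.** A small plot sample (n = 54 by default, one plot per
   co-located laser footprint) trains ensemble regressors — k-nearest
   neighbors (KNN), random-forest regression (RFR) and gradient-boosted
   regression trees (GBRT) — on ATL08-style segment features
   (`landsat_perc`, `toc_roughness`, `h_min_canopy`, `h_dif_canopy`,
   `n_toc_photons`, `asr`, plus distractors removed by a 5% random-forest
   importance screen). Hyperparameters are tuned by **Bayesian
   optimization** (Gaussian-process surrogate, Matern-5/2 kernel, expected
   improvement) minimizing the leave-one-out cross-validation (LOOCV) RMSE.
   The winning model predicts FCC for every footprint.

2. **Regional scale.** The footprint predictions become training labels for a
   **geographically weighted regression (GWR)**,

   y_i = a_0(u_i, v_i) + Σ_k a_k(u_i, v_i) x_ik + ε_i,

   fitted at each location by kernel-weighted least squares
   (Gaussian `w = exp(−d²/θ²)` or bisquare `w = (1−(d/θ)²)²`, fixed or
   adaptive k-nearest-neighbor bandwidth) with the bandwidth chosen by
   golden-section search on the corrected Akaike criterion
   AICc = 2n·ln σ̂ + n·ln 2π + n·(n + tr S)/(n − 2 − tr S). Regional
   covariates (vegetation indices, VV−VH radar backscatter, 5×5 GLCM
   textures at 64 gray levels, terrain derivatives) pass a Pearson screen
   (|r| ≥ 0.2, p < 0.01), an iterative VIF > 10 filter and a normality
   assessment before entering the model. The result is a wall-to-wall FCC
   map with local diagnostics, class proportions and plot-based validation.

A seeded **synthetic scene generator** supplies every input — spatially
varying coefficient (SVC) surfaces, raster bands, strip-sampled footprints,
and plots whose measured-FCC marginal matches the survey statistics (range
0.20–0.83, mean 0.50, SD 0.176) — so the whole chain runs and is tested
offline.

## Worked example

```python
from canopyscale import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=7), outdir="out")
print(report.best_model)
for row in report.footprint_comparison:
    print(f"{row['stage']:>13} {row['model']:>8}: "
          f"R2={row['r2_resid']:.2f} RMSE={row['rmse']:.3f} P={row['p_accuracy']:.1f}%")
print("GWR:", {k: round(report.gwr[k], 3) for k in ("r2_resid", "rmse", "aicc")})
print("FCC classes:", report.fcc_class_proportions)
print("plot validation:", report.plot_validation)
```

prints (seed 7, default desk-scale budget of 50 BO evaluations per learner):

```
gbrt
 un-optimized      KNN: R2=0.48 RMSE=0.127 P=74.6%
    optimized   BO-KNN: R2=0.53 RMSE=0.121 P=75.8%
 un-optimized      RFR: R2=0.58 RMSE=0.114 P=77.2%
    optimized   BO-RFR: R2=0.59 RMSE=0.112 P=77.5%
 un-optimized     GBRT: R2=0.62 RMSE=0.109 P=78.2%
    optimized  BO-GBRT: R2=0.67 RMSE=0.101 P=79.7%
GWR: {'r2_resid': 0.669, 'rmse': 0.085, 'aicc': -571.647}
FCC classes: {'[0,0.3)': 0.035, '[0.3,0.6)': 0.769, '[0.6,1]': 0.196}
plot validation: {'r2': 0.423, 'pearson_r': 0.909, 'p_value': 0.0, 'n': 54, 'n_excluded': 0}
```

Reading the numbers: Bayesian optimization lifts every learner's LOOCV R²
and lowers its RMSE relative to the scikit-learn defaults; the tuned GBRT
wins (R² 0.67, RMSE 0.101) and labels every footprint; the GWR then
explains ~0.67 of the label variance in-sample, the mapped FCC concentrates
in the 0.3–0.6 class as expected for a mid-density montane conifer
landscape, and the map correlates r ≈ 0.91 with the held-aside plot
measurements. Exact values vary with the seed; regenerate them with the
snippet above.

The same pipeline is available from the shell:

```bash
canopyscale simulate --seed 3 --out demo          # scene + footprints + plots
canopyscale run --seed 3 --models knn,gbrt --budget 30 --out demo_run
canopyscale report --report demo_run/report.json
```

## Layout

| module | contents |
| --- | --- |
| `canopyscale.scene` | synthetic scenes, footprint tables, plot samples |
| `canopyscale.covariates` | indices, SAR transforms, GLCM textures, terrain |
| `canopyscale.selection` | RF-importance, Pearson, VIF and normality gates |
| `canopyscale.footprint` | LOOCV metrics, Bayesian optimization, learners |
| `canopyscale.gwr` | kernels, local WLS, AICc, bandwidth search, mapping |
| `canopyscale.pipeline` | orchestration, comparison arithmetic, validation |
| `canopyscale.cli` | `canopyscale simulate|footprint|regional|run|report` |

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
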