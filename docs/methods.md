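# Methods

This note records the models implemented in `canopyscale`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## The two-stage estimation problem

Forest canopy closure (FCC) is a proportion in [0, 1]. Spaceborne
photon-counting LiDAR yields per-segment vegetation features along orbital
strips (~100 m along-track segments); field plots give accurate FCC at a
few dozen locations; optical/radar rasters cover the whole region. The
pipeline estimates FCC footprint-by-footprint from the LiDAR features
(supervised by the plots), then treats those footprint estimates as dense
training labels for a spatial regression onto wall-to-wall raster
covariates.

## Footprint stage

**Learners.** KNN, random-forest and gradient-boosted regression trees
(scikit-learn). The GBRT learning rate is fixed at 0.1 and not tuned; tree
learners are seeded.

**Evaluation.** Leave-one-out cross-validation with four metrics:

* `ratio_r2` — Σ(ŷᵢ−ȳ)² / Σ(yᵢ−ȳ)², ȳ the observed mean. This is the
  classical explained/total decomposition, exact for least-squares fitted
  values. For out-of-fold machine-learning predictions it degenerates into
  a spread ratio: adding pure prediction noise *raises* it. It is kept
  because it is the printed form of the field's evaluation protocol and its
  identities (perfect predictor → 1) are tested.
* `resid_r2` — 1 − RSS/TSS, the conventional coefficient of determination.
  All *comparisons* (model selection, before/after improvement
  percentages, directional tests) rank by this form, because only it moves
  in the same direction as RMSE when prediction noise changes; the joint
  movement "R² up, RMSE down" reported for optimization effects is
  meaningful only under this reading.
* RMSE, `P = (1 − RMSE/ȳ)·100 %`, and the mean absolute residual MAR.

Using the observed mean for ȳ (rather than the mean prediction) preserves
the R² = 1 perfect-predictor identity.

**Bayesian optimization.** Gaussian-process surrogate (Matern-5/2 ARD
kernel plus a small white-noise term, standardized objective), expected
improvement maximized over 320 seeded candidates (256 global + 64 local
perturbations of the incumbent). Integer parameters are relaxed to [0, 1]
and rounded; categoricals use indicator coding. Duplicate proposals are
perturbed to a nearby unevaluated point; non-finite objective values are
recorded as worst-so-far penalties. The initial design is a seeded Latin
hypercube, *warm-started with the learner's scikit-learn default
configuration* — standard practice that also guarantees the tuned incumbent
never scores worse than the default on the optimization objective. The
objective is the LOOCV RMSE.

**Search spaces.** Two are provided. `paper_scale_space` reflects a
full-budget (1,000-evaluation) campaign: n_estimators 50–1000, max_depth
2–20, min_samples_split 2–20, min_samples_leaf 1–10, n_neighbors 2–20.
`desk_scale_space` (the default and the one used in tests and the
acceptance script, with a budget of 50 evaluations) narrows the tree
domains to n_estimators 10–80, max_depth 2–8, split 2–10, leaf 1–5: with
~53-row training folds, larger ensembles change runtime but not accuracy.

## Regional stage

**Covariates.** Vegetation indices by their standard formulas (SAVI with
L = 0.5; OSAVI with 0.16; EVI with G = 2.5, C1 = 6, C2 = 7.5, L = 1 when a
blue band exists; EVI2 as the blue-free variant; MASVI treated as an alias
of MSAVI; IDVI — not a standard name — implemented as the 1 + NDVI
placeholder). Radar: VV−VH in dB and the linear power ratio
10^((VV−VH)/10). Textures: per-pixel gray-level co-occurrence features in
a 5×5 window, step 1, 64 gray levels, min–max quantized *per window*,
symmetric matrix averaged over the four standard directions
(configurable); entropy uses the natural log. The implementation computes
the eight Haralick features directly from per-window pair lists
(no per-pixel matrices), and is unit-tested against an explicit
co-occurrence-matrix construction and against scikit-image. Terrain: Horn
3×3 slope (degrees) and compass aspect with a −1 sentinel for flat cells.

**Screens.** Pearson: keep |r| ≥ 0.2 (boundary inclusive) with two-sided
p < 0.01. VIF: iteratively drop the worst variable while any VIF > 10;
infinite VIFs (perfect collinearity) are handled by removal. Normality:
D'Agostino–Pearson omnibus test; failing variables get a one-parameter
power transform (Box–Cox when strictly positive, Yeo–Johnson otherwise)
whose exponent is recorded so the identical transform replays on the
raster grids at prediction time. A transformed variable can still fail at
very large n — the omnibus test eventually detects any residual
non-normality — and the report says so rather than hiding it.

**GWR.** Local weighted least squares â(i) = (XᵀWᵢX)⁻¹XᵀWᵢy with an
intercept column. Kernels: Gaussian `exp(−d²/θ²)` (fixed distance) and
bisquare `(1−(d/θ)²)²` with compact support, fixed or adaptive
(θᵢ = distance to the k-th nearest training point, self included). The
pipeline default is adaptive-neighbor bisquare; the Gaussian fixed kernel
is retained for its closed form and the global-OLS limit. Effective
parameters come from the hat diagonal sᵢᵢ = wᵢᵢ·xᵢᵀ(XᵀWᵢX)⁻¹xᵢ; the
bandwidth minimizes AICc = 2n·ln σ̂ + n·ln 2π + n(n + tr S)/(n − 2 − tr S)
by golden-section search (integer neighbor counts are rounded and
memoized, ties to the smaller bandwidth; a minimizer at the search bound
emits a boundary warning). Local R² uses kernel-weighted residual and
total sums around the kernel-weighted local mean. Numerical choices:
coordinates must be projected meters (Euclidean distances; no spherical
fallback); singular local systems get a ridge of 10⁻⁸ on the normal
equations with a warning (configurable; zero means raise); prediction at
unsampled locations refits local coefficients from training data only and
clamps proportions to [0, 1]; fixed-bandwidth bisquare points beyond every
kernel support return NaN with a warning.

## Synthetic scenes

The generator emulates the *statistical structure* the analysis assumes,
not radiometric or geographic realism:

* **Coefficient surfaces** aₖ(u, v): deterministic low-order harmonics
  (default wavelength 4,000 m) plus a small seeded smooth field, around
  means 0.50 (intercept), 0.13, 0.08, 0.06. True FCC is
  clip₀₁(a₀ + Σ aₖ zₖ + ε) with ε ~ N(0, 0.05).
* **Latent covariates** zₖ: standardized smooth fields at wavelength
  L/8 plus a white component. The scale separation is essential — local
  kernel regression can only identify spatially varying coefficients if
  the design varies *within* a kernel window; long-wavelength covariates
  make the local design collinear with the intercept. The coefficient
  amplitudes are sized so that kernel-smoothing leakage between surfaces
  stays well below their spatial variation, keeping recovery meaningful.
* **Bands** realize the latents: NDVI/GNDVI targets are monotone in z_veg
  (with independent detail so the two are collinear but not degenerate,
  VIF ≈ 6–9), B8A follows z_bright, VV−VH = 6 − 1.5·z_radar dB (so the
  backscatter difference *falls* as closure rises), and the DEM is an
  independent smooth field.
* **Footprints** lie on parallel north–south strips, one per track column,
  spaced 100 m along-track. The six informative features are monotone
  transforms of local true FCC with calibrated noise (e.g.
  `landsat_perc = 100·FCC + N(0, 14)`, photon counts Poisson with
  lognormal overdispersion); the noise levels are set so the footprint
  stage reaches the difficulty reported for real segment features
  (default-model LOOCV RMSE ≈ 0.13–0.15 at plot SD 0.176) rather than a
  near-perfect fit. 44 distractor features are pure noise, every third one
  spatially autocorrelated at wavelength L/8 so chance spatial correlation
  is represented. At n ≥ 5,000 footprints every informative feature
  out-correlates every distractor (tested).
* **Plots** are drawn at footprint positions; measured FCC = true FCC +
  N(0, 0.05), then *rank-matched* to a Beta law truncated to [0.20, 0.83].
  Rank-matching preserves the spatial association while pinning the
  marginal. The default shapes (1.374, 1.561) are solved so the
  *truncated* marginal has mean 0.500 and SD 0.176 — matching the
  untruncated moments first (shapes ≈ 3.535, kept as
  `beta_shapes_from_moments`) and then truncating would undershoot the SD
  (0.154).

All randomness descends from one integer seed through a fixed
`SeedSequence` child order (coefficients, fields, bands, FCC noise,
footprints, plots); identical configurations give bit-identical output.

Because the generator's feature links, noise laws and coefficient surfaces
are stand-ins (no published noise structure links segment features to
FCC), passing tests demonstrate that the *methods* behave correctly under
the assumed structure — parameter recovery, selection behavior, direction
of optimization effects — not that real-world accuracies are reproduced.

## Problem sizes and comparison conventions

Tests and the acceptance script run desk-scale sizes chosen as the
package's own defaults: 128×128–256×256 scenes at 30 m cells, ~300–5,000
footprints, 54 plots, BO budget 50 (10 initial + 40 guided), GWR training
capped at 2,000 footprints. Full-budget settings (1,000 BO evaluations,
tens of thousands of footprints) are configuration changes, not code
changes.

Improvement percentages make their convention explicit:
`delta_over_before` (change relative to the unoptimized value, errors
sign-flipped so improvements are positive), `delta_over_after`, or
`averaged` — per-model relative changes averaged, using after-denominators
for gain metrics and before-denominators for error metrics, the mixed
arithmetic that multi-model comparison tables in this field use. The
optimized-vs-unoptimized GWR comparison is made on the in-sample
validation accuracy against each label set (and AICc): smoother, less
noisy labels are both genuinely better estimates and spatially more
predictable. A map-vs-truth comparison is also reported for the synthetic
scene but is *not* the directional criterion: spatial smoothing removes
iid label noise but preserves shrinkage bias, so it can rank label sources
differently.

## Known limitations

* The GLCM window is mirror-padded, so edge-pixel textures are slightly
  autocorrelated with their reflection.
* Golden-section bandwidth search assumes a roughly unimodal AICc profile;
  the evaluated profile and a boundary warning are returned so a flat or
  multimodal profile is visible to the caller.
* `ratio_r2` can exceed 1 and is not a goodness-of-fit measure for
  out-of-sample predictions; it is reported alongside `resid_r2`, never
  alone.
* The plot sample is co-located with footprints by construction; real
  stake-out error and the measuring-line protocol are represented only as
  additive Gaussian noise before rank-matching.
* GWR assumes projected coordinates; geographic (lon/lat) input is
  rejected rather than approximated.
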