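# Methods

This note documents the models, defaults and numerical choices behind
`epinet`, and what the synthetic experiments do and do not demonstrate.

## Synthetic BOLD model

Each simulated brain is two hemisphere blocks of gray matter (default
1000 voxels each, emulating a ~2000-voxel rodent gray-matter mask), each
containing a sensorimotor seed ROI (`roi_fraction`, default 0.3), plus
white-matter and CSF compartments. The acquisition defaults are 1200
frames at TR 0.5 s (10 min) with coherent fluctuations confined to
0.01–0.1 Hz.

Latent signals are random mixtures of the orthonormal Fourier (sin/cos)
basis of the passband. Voxel series are built as

- sensorimotor voxel, hemisphere h: `√intra · u_h + √(1−intra) · e_v`
- background gray matter: `√(bg_coupling·intra) · u_h + √(1−·) · e_v`
- white matter / CSF: `√0.5 · g_tissue + √0.5 · e_v`

with `corr(u_L, u_R) = inter_corr`, all deviations `e_v` independent, and
white Gaussian noise (`noise_sd`, default 1.0) added last. Consequences
worth knowing:

- Within-ROI voxel-pair correlation is `intra_corr`; the cross-hemisphere
  ROI-*mean* correlation approaches `inter_corr` as the ROI grows
  (attenuation factor `intra / (intra + (1−intra)/V + noise²/V)`), which
  is why estimator-consistency checks use ROIs of a few hundred voxels.
- When the number of latent components fits inside the passband dimension
  (2 × number of Fourier bins), the mixtures are taken exactly
  orthonormal, so with `noise_sd = 0` the sample correlation matrix equals
  the planted one to machine precision. Beyond that dimension planted
  correlations hold in expectation only — at 1200 frames the 0.01–0.1 Hz
  band holds 110 real dimensions, so a full-size run is in the approximate
  regime, like real data.
- Observed correlations are attenuated by `1/(1 + noise_sd²)` per voxel
  pair; this is deliberate measurement realism, not a bug.

The planted correlation strengths are free parameters: no empirical
voxel-pair correlation magnitudes exist to calibrate them against (maps in
the emulated experiment are only reported thresholded), so defaults
(inter 0.6, intra 0.6) were chosen once as plausible mid-range couplings.

What the generator does **not** emulate: hemodynamic response functions,
neural-mass dynamics, scanner drift/motion artifacts (motion parameters
are attached as nominal regressors but do not corrupt the data), spatial
autocorrelation beyond the planted structure, and physiological noise
spectra. Passing tests therefore demonstrate correctness of the
*measurement chain*, not robustness to every property of real BOLD data.

## Preprocessing

Order fixed as smooth → band-pass → nuisance regression, recorded in the
output metadata.

- **Smoothing**: per-frame Gaussian, σ = FWHM/(2√(2 ln 2)) scaled by voxel
  size per axis; mask-weighted and renormalized inside the mask so edge
  voxels are not diluted by zeros. Default FWHM 1.0 mm for full-size
  grids. The scaled-down cohort default is 0 mm: on a synthetic
  hemisphere a few voxels across, a 1.0 mm kernel averages most of the
  block and saturates every correlation.
- **Band-pass**: zero-phase (forward–backward) Butterworth, order 2 per
  pass, 0.01–0.1 Hz default. Zero-phase filtering avoids lag that would
  distort correlations.
- **Nuisance regression**: OLS residuals against [intercept, global mean,
  WM mean, CSF mean, 6 motion parameters]; motion columns are band-pass
  filtered with the same filter first so regression cannot reintroduce
  out-of-band variance; rank-deficient designs drop dependent columns with
  a warning. The global-mean column is optional (`include_global` /
  `global_regressor`): with only a handful of planted latents the global
  mean *is* the signal of interest, and regressing it out forces the two
  hemispheres into near-perfect anti-correlation (the well-known
  global-signal-regression artifact, in its most extreme form). The
  synthetic cohort pipeline therefore runs without it; on real data the
  full column set is the intended configuration.

## Connectivity

`z' = arctanh(r)` without a √(n−3) scaling, so the conventional z' > 0.15
threshold keeps its meaning; |r| = 1 is clamped to arctanh(1 − 1e-7)
(z' ≈ 8.38) with a warning. Graph edges zero negative correlations; ROI
measures (interhemispheric z', seed maps) keep the sign, since
interhemispheric anti-correlations are a finding in their own right.
Zero-variance voxels get zero rows rather than being dropped, keeping V
comparable across scans of one subject. The intrahemispheric connected
volume counts seed voxels by default (`include_seed=False` to exclude);
threshold comparisons are strict (`z' > t`).

## Graph metrics

- Onnela weighted clustering with per-network max-weight normalization;
  nodes with binary degree < 2 get C_i = 0; the scalar C averages nodes
  with degree ≥ 2 (they are the only ones that can close a triangle); a
  flag averages over all nodes instead.
- Harmonic-mean path length with edge length ℓ = 1/w (the convention of
  the global-efficiency literature; ℓ = 1 − ŵ available). Distances via
  Dijkstra per source; the brute-force Floyd–Warshall lives only in the
  test oracle.
- Maslov–Sneppen surrogates: double-edge swaps on the binary topology,
  each edge keeping its weight, so degree sequence and weight multiset are
  preserved exactly; no self-loops or multi-edges; default budget 10
  accepted swaps per edge, with an attempt cap for graphs (complete or
  near-complete) where few valid swaps exist — a complete graph is
  returned unchanged with a warning, since no degree-preserving swap
  exists at all. An alternative null (`shuffle_weights`) permutes weights
  over the fixed topology.
- γ = C/⟨C_surr⟩ and λ = L/⟨L_surr⟩ over 100 surrogates by default, one
  spawned seed per surrogate; per-surrogate values are kept so dispersion
  (e.g. ±3 SD bands) can be reported.

Voxel-level z' networks are dense (more than half of all pairs positive),
which makes binary rewiring both slow (acceptance rate falls as density
rises) and weak as a null. Cohort runs therefore subsample the graph to
60 evenly spaced voxels and use 2 accepted swaps per edge; full-size
graphs (≈2000 nodes) are supported but surrogate generation is then the
dominant cost of the whole pipeline.

## Diffusion

Log-linear least squares on `ln S = ln S0 − b gᵀDg` (7 parameters per
voxel, one shared pseudoinverse); nonpositive signals are floored at
1e-6·S0 and flagged; voxels without positive S0 are flagged invalid.
Eigenvalues sorted descending; negatives clipped to zero (flagged) before
FA = √(3/2)·‖λ−λ̄‖/‖λ‖. ADC is reported as the *trace* λ1+λ2+λ3 (a
mean-diffusivity property exists). Axial = λ1, radial = (λ2+λ3)/2. The
default estimator is unweighted log-linear LSQ; weighting or nonlinear
refinement is out of scope. Gradient schemes come from antipodally
symmetric electrostatic repulsion (charge pairs ±g, L-BFGS on the sphere,
seeded and deterministic), 50 directions at b = 1184.33 s/mm² by default,
plus two b = 0 volumes.

## Longitudinal model

For each measure y of subject s at day t:

y_st = β0 + β1·group + β2·day + β3·group×day + b_s + e_st,
b_s ~ N(0, σ_b²), corr(e_st, e_su) = φ^|t−u| (t in days), e ~ N(0, σ²).

Variance parameters (σ_b²/σ², φ, optionally a random-slope variance) are
estimated by profiled REML (Nelder–Mead over 2–3 transformed parameters,
with the residual variance and fixed effects solved in closed form given
the correlation structure); subjects sharing a day pattern share one
Cholesky factorization. Fixed-effect tests use containment degrees of
freedom (between-subject effects: n_subjects − 2; within-subject effects:
n_obs − n_subjects − p_within), matching nlme's conventions — the fitter
reproduces nlme's estimates, standard errors, dfs and restricted
log-likelihood on a reference dataset to ~1e-4. "Random group and time
effects" is interpreted as fixed group/time/interaction plus a subject
random intercept (a random-slope option exists); time is continuous by
default, categorical for per-day contrasts. Per-day group contrasts are
adjusted with the studentized range (family size = number of days,
between-subject df), a single-step Tukey-style correction. Non-positive-
definite or degenerate fits raise `ConvergenceError` with diagnostics —
there is no silent fallback.

Null simulations put the group-effect type-I error at ≈0.02–0.05 at
nominal 0.05 (slightly conservative, as containment dfs tend to be), and
a group×time slope difference worth 3 residual SDs over the follow-up
window is detected in >80% of runs at 8 subjects/group.

## Cohort pipeline and problem sizes

`RunConfig` defaults are scaled for interactive use: 100 voxels per
hemisphere, 300 frames, 20 surrogates, 12 gradient directions, graphs
subsampled to 60 nodes; `full_scale=True` switches to 1000 voxels, 1200
frames, 100 surrogates, 50 directions and 1.0 mm smoothing. Three hundred
frames is the floor at which the 0.01–0.1 Hz band still holds ~14 Fourier
bins; below that, per-scan correlation estimates become too noisy for
well-powered group comparisons. The planted schedule follows the
qualitative longitudinal pattern under study: epilepsy-group
interhemispheric coupling dips to anti-correlation at day 21 and recovers
by day 70, intrahemispheric coupling is elevated up to day 49, and
callosal FA starts lower and converges to control values; controls are
stable apart from an age-related FA increase. Every seed derives from
`master_seed` (per-scan seeds, per-surrogate seeds, subject-level
jitter), and the manifest echoes the full configuration, so a run is
reproducible from its manifest alone.

## Known limitations

- No registration, motion correction, slice timing, TBSS or tractography;
  ROIs and masks are taken as given.
- The mixed model supports exactly two groups and Wald-type tests with
  containment dfs; no Satterthwaite/Kenward–Roger approximation.
- Surrogate normalization of full-size dense voxel graphs is expensive
  (minutes per scan) and the binary-topology null is weak at very high
  densities; the weight-shuffling null is offered as an alternative.
- Whether longitudinal FA increases in controls reflect maturation cannot
  be addressed synthetically; that question belongs to real data.
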