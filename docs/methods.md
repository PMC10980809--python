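# Methods

## The APRW model and its inference chain

A cell's 2D trajectory (3D tracks are first projected onto the imaging
plane) is modelled as two independent persistent random walks along a
cell-specific primary axis **p** and the orthogonal non-primary axis
**np**. Along each axis the velocity is an Ornstein–Uhlenbeck (OU) process
with correlation time P (the persistence time, hours) and stationary
variance S²/2 (S the speed scale, μm/hr); the position is its time
integral, plus independent Gaussian localisation noise of variance σ² per
coordinate. The per-axis MSD is then

    MSD(τ) = S² P² (e^(−τ/P) + τ/P − 1) + 2σ²,

ballistic (∝τ²) below P, diffusive (slope S²P) far above it, with the
2σ² noise floor at τ → 0. Diffusivities are defined per axis as
D = S²P/4, so that the total 2D MSD grows as 4·D_t·τ with
D_t = D_p + D_np; the anisotropy index is φ = D_p/D_np.

Assumptions: the migration statistics are stationary over the analysed
interval (live-imaging data are gated to t ≥ 30 h after spheroid
embedding, where the population speed profile is flat), sampling is
uniform, and proliferation during the window is negligible. Tracker
exports with frame gaps are split at gaps > 1.5·dt rather than
interpolated, so no position is fabricated.

The inference chain per cell: velocities at the sampling interval →
migration axes from SVD of the (non-mean-centred) velocity matrix, primary
= larger singular value → 1D time-averaged MSDs of the coordinates
projected on each axis → joint nonlinear least squares of the two curves
with shared σ². Population values are arithmetic means of the per-cell
quantities; diffusivities and φ are computed per cell *before* averaging,
and the ratio of mean diffusivities (`phi_of_means`) is reported alongside
because the two differ for heavy-tailed per-cell ratios.

## Fitting design

Per-cell time-averaged MSDs have strongly lag-dependent noise: at lag τ a
track of duration T averages ~T/τ overlapping, mutually correlated pairs,
and the relative scatter grows like √(τ/T). Two design choices follow:

- **Log-space residuals (default).** MSD values span orders of magnitude
  and their fluctuations are approximately multiplicative. Plain
  unweighted residuals let the largest, noisiest lags dominate the loss;
  on simulated single-cell curves at the study conditions this drives a
  quarter or more of the fits into a spurious ballistic solution (fitted
  P of 10³–10⁴ hr). With log residuals the same curves return the
  generating S within ~1–2% and P within ~5% in the population mean.
  Linear residuals remain available (`residuals="linear"`).
- **Short fit window.** Per-cell fits use lags up to 10% of the track
  duration by default (`fit_lag_fraction = 0.1`), or an absolute window
  (`fit_window`, hours) for very long tracks; the population MSD for the
  power-law exponent uses lags up to 50%. Measured per-axis scatter of
  ln D at the study conditions: 0.36–0.45 for windows ≤ 10% of the track,
  > 1.0 at 30%.
- **Bounds.** All parameters ≥ 0; P ≤ the largest fitted lag (a
  correlation time beyond the window is not identifiable); σ² ≤ the
  first-lag MSD (the noise floor cannot exceed the shortest-lag MSD — this
  removes a degenerate optimum in which one axis's entire curve is
  absorbed into the shared noise term). Five multi-starts with
  persistence guesses log-spaced across the window and speed guesses from
  the long-lag slope.
- **Axis ordering.** After fitting, axes are swapped if needed so that
  D_p ≥ D_np, hence φ ≥ 1 by convention.

## Known estimator biases (quantified on synthetic data)

Two biases of the standard per-cell pipeline are worth stating explicitly,
because they are properties of the estimator, not bugs:

- **The power-law exponent over a finite window.** The model's own log–log
  slope over lags [2P, 20P] is 1.167 (closed form, linear lag grid); the
  crossover to slope 1 completes only for lags ≳ 20P. Fits of α ≈ 1
  therefore require windows well beyond the persistence time, and an α
  fitted at [2P, 20P] reads ~1.15 even on perfect model data.
- **Anisotropy inflation.** φ ≥ 1 by convention, so per-cell estimator
  noise folds upwards: with per-axis ln-D scatter ~0.4 (the time-averaged
  MSD noise floor at 40-h tracks; the information-theoretic limit would be
  ~0.17), the per-cell ratio mean reads ~2.5–2.8 when the generating ratio
  is 1.9, and ~1.5–1.7 for an exactly isotropic walk even with 150–200-h
  tracks. The data-driven axis choice (SVD picks the empirically fastest
  direction) contributes a further ~10%. Population anisotropy indices
  from this estimator class should therefore be read as upper bounds and
  compared only between conditions analysed identically.

## The trajectory simulator

Velocities and positions are advanced with the *exact* transition kernel
of the integrated OU process: over a step Δ, (position increment, new
velocity) is jointly Gaussian with

    v' = a v + η_v,  Δx = P(1−a) v + η_x,  a = e^(−Δ/P),
    Var η_v = q(1−a²),  Cov = qP(1−a)²,
    Var η_x = qP²(2Δ/P − 3 + 4a − a²),  q = S²/2.

Because this is the exact kernel and the velocity starts in its stationary
distribution, the simulated process is stationary from the first sample
and its ensemble MSD equals the closed form above at *any* step size — no
burn-in and no continuum-limit error. Sub-stepping (internal step ≤
min(P)/20 by default) is retained only for interface compatibility. Each
track's (p, np) frame is rotated by an independent uniform angle, and iid
Gaussian noise (sd σ) is added per coordinate. RNG: numpy PCG64
(`default_rng`), seeded per configuration; outputs are bit-reproducible
for a given numpy version.

What the generator emulates: stationary anisotropic migration with
tracker localisation noise at the study's sampling. What it does not:
spheroid egress transients (real tracks are non-stationary before ~30 h),
cell–cell interactions, gaps/mislinks in tracking, and confinement by the
hydrogel geometry. Passing recovery tests therefore validates the
inference chain, not the biological fidelity of the model.

## Two-phase volumes

The synthetic bicontinuous volume is a thresholded Gaussian random field:
seeded white noise, Gaussian-smoothed at the length scale (voxel-size
aware, periodic boundary), thresholded at the (1 − fill) quantile so the
phase-1 fraction is exact to within one voxel. Near 50% fill both phases
percolate; low fill gives isolated blobs in a connected matrix.

Metrics: connectivity and object counts use 26-connectivity by default
(configurable to 6; both phases measured with the same neighbourhood, a
deliberate simplification even though foreground/background connectivity
is topologically non-dual). Interfacial surface area is exact face
counting with per-axis face areas (dy·dz, dx·dz, dx·dy) — deterministic
and oracle-verifiable, unlike marching-cubes estimates; array-edge faces
are excluded (internal interface only). Fluorescence stacks are binarised
by Otsu's threshold by default, GP as the complement of GR.

## Outgrowth, extent, infiltration

Radial outgrowth casts 8 equally spaced rays (start angle 0°, east,
counterclockwise; all configurable) from the spheroid centre, samples
every 0.25 pixel, records the farthest mask-positive sample per ray,
averages, and subtracts the spheroid radius; a negative difference is
floored at 0 and rays with no hit are flagged. Perpendicular extent of a
3D point cloud is the max − min of projections on the smallest-variance
principal axis — an approximation to a minimum-volume oriented bounding
box that is exact for box-like clouds and rotation invariant. Infiltration
summaries use the 95th percentile by linear interpolation between order
statistics and half-open depth bins [edge_i, edge_{i+1}) with the last bin
closed; default edges 0/50/100 μm.

## Indentation

The spherical Hertz relation F = (4/3)·E_ind/(1−ν²)·√R·δ^{3/2} with
ν = 0.49 fixed; with forces in nN and lengths in μm, E_ind is in kPa
directly. Curves are assumed zeroed at contact (fits start at δ = 0);
an optional contact offset δ₀ is fitted for un-zeroed curves. Without the
offset the model is linear in E_ind and solved in closed form (projection,
clipped at 0). Force maps are summarised by mean and CV after removing
entries outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] (quartiles by linear
interpolation); removed entries are counted, never silently dropped.

## Validation design and problem sizes

Every estimator is checked against an independent oracle: O(N²)
double-loop MSDs (tracks ≤ 50 samples), stack-based flood fill and
triple-loop face counting (volumes ≤ 16³), sort-based percentile and IQR
rules, and noiseless forward-model round trips (Hertz and APRW, 1e-4
relative). Recovery experiments use 200 tracks × 3 seeds at the study
conditions (40 h, 0.1 h sampling, σ = 0.5 μm) for the migration chain and
three 128³ volumes (length scale 8 voxels, fill 0.5) for connectivity;
these sizes put Monte-Carlo error well inside the stated tolerances while
keeping the full suite and the acceptance script within a few minutes on
one CPU.

## Limitations

- No 3D (unprojected) APRW variant; no Bayesian or state-space fitting.
- The per-cell anisotropy index is biased upwards (see above); only the
  relative comparison between identically analysed conditions is safe.
- Persistence times below the sampling interval are at the edge of
  identifiability; recovery experiments use 0.1-h sampling for P = 0.56 h.
- Oriented-bounding-box extent is a covariance approximation, not the
  exact minimum-volume box.
- Segmentation of fluorescence stacks is a plain global threshold; no
  deconvolution, registration or colocalisation.
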