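# Methods

This document records the mathematical model, parameter conventions and
numerical choices behind each stage of the pipeline, and the scope of
the synthetic-data generator.

## Conventions

- Coordinates are 2D, in µm, with the cell centred at the origin and
  its long axis along x. Image arrays are indexed (row, col) =
  (y, x); a point at x µm maps to column ⌊x / pixel_size⌋.
- Δt₀ = 5.76 ms is the interval between consecutive imaging frames
  (camera exposure 2.4 ms plus readout at 174 frames/s with one
  activation frame interleaved every 10 imaging frames).
- Diffusion coefficients appear in two conventions. `d_paper` is the
  slope of the zero-intercept MSD fit using MSD = D·Δt; the
  conventional 2D coefficient (MSD = 4DΔt) is `d_conv = d_paper / 4`,
  an exact identity, not a fit. The mixture model's per-state
  coefficients D′ᵢ are likewise "one-step" coefficients in the
  exponential scale 4·D′ᵢ·t.

## Acquisition optics (`optics`)

Effective pixel size: native 130 nm pixels, 2×2 hardware binning, and a
1.5× tube lens give 130 × 2 / 1.5 = 173.33 nm ≈ 173 nm. Per-pixel
photon gain of binning against the tube-lens magnification:
(2/1.5)² − 1 = 77.78 % ≈ 77 %. Both are pure arithmetic and serve as
deterministic anchors for the default pixel size used throughout
(0.173 µm).

## Cell geometry (`geometry`)

The cell is a 2D spherocylinder: a rectangle of length L − W and width
W capped by two half-discs (defaults L = 3.0 µm, W = 1.0 µm). The
membrane region is a band of configurable width (default 0.173 µm, one
pixel) inside the boundary; the nucleoid is an axis-aligned ellipse
(default semi-axes 1.0 × 0.3 µm). Brownian steps are confined by
iterative specular reflection across the boundary circle around the
clamped axis point, which preserves the uniform stationary
distribution.

## Synthetic data (`simulate`)

Ground-truth emitters are activated in Poisson numbers at each 405 nm
pulse (every 11th frame), carry a geometric photobleaching lifetime,
and diffuse with per-emitter state drawn from the configured
(fraction, D_conv) mixture — defaults 40 % at 2.0 µm²/s and 60 % at
0.05 µm²/s. Closed forms used by the tests:

- unconfined: E[osd²] = 4·D_conv·Δt₀;
- with localization noise σ: E[osd²] = 4·D_conv·Δt₀ + 4σ²;
- per-state osd² is exponential with mean 4·D′·t.

Rendering integrates a symmetric Gaussian PSF (σ = 0.13 µm) over each
pixel via the error function, adds constant expected background, and
draws Poisson counts. Activation frames contain background only. A
linear stage drift (px/frame) can be injected for drift-correction
tests. The simulator refuses configurations whose single-frame step
s.d. is comparable to the cell width (temporal resolution too coarse
for the reflection scheme to be meaningful).

Scope: the generator covers everything the analysis consumes — movies,
ground-truth tables with observed (noisy) positions, region masks,
decay series (plateau-then-exponential with mean-one lognormal noise).
It does not model sCMOS pixel noise maps, astigmatic 3D PSFs, emitter
blinking within an on-period, or state switching within a trajectory
(a `switching_rate` hook exists but defaults to 0).

## Localization (`reconstruction`)

Candidates are pixels strictly above frame mean + 3·s.d. that are
maximal in their 5×5 neighbourhood; ties go to the lexicographically
smallest pixel so one flat-topped spot yields one candidate; pixels
within 3 px of the border are dropped. Each candidate seeds a 7×7
symmetric-Gaussian-plus-offset least-squares fit. A fit is rejected
(`fit_ok = False`) when the optimizer fails, the amplitude is
non-positive, σ leaves [0.5, 3.5] px, or the centre leaves the window.

Because the threshold is a 3σ tail cut on Poisson images, raw
candidates include occasional noise maxima (~1 per frame at a
background of 5 photons/px); the Gaussian-fit rejection removes nearly
all of them (≲ 0.1 per frame survive).

Drift is estimated by rendering temporal blocks (default 1000 frames)
of the localization table as 2×-upsampled histograms and locating the
phase-correlation peak of each block against the first, with 1/50 px
subpixel interpolation; shifts are linearly interpolated between block
centres. Cross-correlation requires shared structure between blocks:
on sparse tracking movies where each block sees a different emitter
set, the estimate is unreliable, so drift tests and calibration use
persistent (fiducial-like) emitters. Correction is idempotent to
≤ 0.1 px.

## Tracking (`tracking`)

Localizations in consecutive frames are linked when they are mutual
nearest neighbours and closer than `max_disp` = 0.400 µm (chosen to
suppress artificial links between different molecules). No gap
closing: a missed frame terminates the trajectory. Trajectories with
more than 5 steps enter MSD analysis; more than 3 steps, osd²
analysis. The linking radius can be calibrated from a fixed
(immobilized) sample as the 0.999 quantile of its step lengths.

The residual mislink rate measured on analysis-grade trajectories
(> 3 steps) of sparse rendered movies — a step counted correct when a
single ground-truth emitter matches both endpoints within 1.5 px — is
≈ 0.3 % (4/1549 across six seeds).

## Diffusion inference (`diffusion`)

Ensemble MSD uses all start points of all trajectories per lag. The
zero-intercept linear fit over the first 4 lags gives `d_paper`;
negative slopes are clamped to 0 and flagged.

The mixture model fits the empirical CDF of osd² on 200
quantile-spaced points with
CDF(osd²) = 1 − Σᵢ Pᵢ·exp(−osd²/(4·D′ᵢ·t)), t = Δt₀. Fractions use a
stick-breaking parametrization and coefficients are fitted in log
space, with 5 multi-starts of trust-region least squares; states are
reported sorted by descending D′. The state number is the smallest n
whose successor improves the RSS by less than a factor 2 (fits n = 1,
2, 3). At 2×10⁴ samples this selects n = 2 on two-state data in the
overwhelming majority of seeds; occasionally the RSS ratio lands
within noise of the factor and a trace (< 1 % weight) third state is
admitted without disturbing the two real states.

For conditions with scarce fast-state data, the fast coefficient can
be box-constrained to mean ± 2·sample s.d. of replicate fits from a
reference condition (`constrain_from_reference`).

Estimator caveat: osd² measured on rendered movies carries the
localization-error floor + 4σ² per step, so the apparent slow-state
D′ is inflated by ≈ σ²/t (≈ 0.15 µm²/s at a 500-photon budget). The
estimator is unbiased on noise-free ground-truth tables.

## Spatial enrichment (`spatial`)

Regions partition the cell mask exactly: membrane = an erosion band
(3×3 structuring element applied band-width times), nucleoid = Otsu
threshold of the stain within the remaining cell (or a provided mask),
cytoplasm = the rest. Enrichment of region r is
(count_r / count_cell) / (area_r / area_cell); localizations outside
the cell are dropped and reported. Two identities hold by
construction: uniform occupancy gives enrichment ≈ 1 everywhere, and
the area-weighted mean enrichment over any partition is exactly 1.

## Decay model (`decay`)

ln I(t) is flat at ln I₀ until the delay α, then decreases linearly
with slope −k (k ≥ 0): I(t) = I₀·exp(−k·max(t − α, 0)). Fitting is on
ln I (so late, low-intensity points carry relatively more weight),
with α profiled on a 513-point grid over [0, second-to-last timepoint]
followed by bounded Brent refinement; for each α the inner problem
(ln I₀, k) is solved in closed form. The half-life is τ = ln 2 / k —
natural logarithm — an exact identity of every fit; k = 0 yields
τ = ∞, which is flagged and excluded from replicate means.
Loading-control normalization is assumed already applied; ln I(0) is
fitted by default and can be pinned to 0 (`fix_i0`).

## Pipeline and reproducibility

All randomness derives from a single top-level seed via seeded
`numpy` generators with stage-specific stream keys; a rerun with the
same config reproduces reports byte-for-byte. Every report embeds the
fully resolved configuration and library versions. Unknown
configuration keys are rejected.

## Limitations

- 2D only; no astigmatic/3D localization, no multi-emitter fitting.
- Linking is greedy mutual-NN; no motion models or gap closing.
- The drift estimator needs structure shared across blocks (dense or
  persistent emitters).
- Mixture-state selection uses a fixed RSS-improvement factor, not
  information criteria or Bayesian selection.
- Decay fitting is per-replicate least squares; no mixed-effects
  modelling.
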