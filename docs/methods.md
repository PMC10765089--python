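# Methods

This note documents the models and procedures implemented in `parquant`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## Object-based colocalization

Two particles detected in different channels are declared colocalized
when the Euclidean distance between their fitted centroids is strictly
below a direction-dependent reference distance

r_ref(Θ) = sqrt( resol_xy² · sin²Θ + resol_z² · cos²Θ ),

the radius of the resolution ellipsoid along the inter-particle
direction, with Θ the polar angle of the displacement (Θ = 0 along the
optical axis). The azimuth Φ cancels because lateral resolution is
isotropic, so the code computes r_ref from cosΘ directly. Defaults are
the bead-calibrated resolutions resol_xy = 0.293 μm and
resol_z = 0.498 μm; any calibration can be supplied.

Matching is existence-based: an anchor-channel particle colocalizes if
*any* partner-channel particle lies within r_ref, and one partner may
serve several anchors. This is the literal reading of the distance rule;
a one-to-one assignment mode (minimum total distance over admissible
pairs) is available for sensitivity analysis. A KD-tree prunes candidate
pairs at radius max(resol_xy, resol_z) before the exact anisotropic test,
so accelerated results are identical to the all-pairs computation (this
is asserted against a brute-force oracle in the tests).

The colocalization percentage is intensity-weighted: 100 × (summed
background-corrected intensity of colocalized anchor particles) / (summed
intensity of all anchor particles). An empty anchor channel yields a
missing value, not 0. Triple colocalization requires a partner within
r_ref in each of two other channels independently, anchored on the
clustered-array channel by default (configurable).

Because percentages are ratios of intensities, percent(A vs B) generally
differs from percent(B vs A); both directions can be computed.

### Ventral exclusion

Particles within a margin of the coverslip are removed before
colocalization to avoid substrate artefacts. The margin defaults to
0.6 μm — three z-planes at the 0.2 μm z-step. The rule is strict:
particles with z > coverslip_z + margin are kept, everything else
dropped. The coverslip height is estimated as the kernel-density mode of
the lowest-quartile particle z positions (a stack-intensity-gradient
fallback and an explicit override exist); this estimator is a convention
of this package, so the override should be used when an independent
calibration is available.

## Spot detection

Diffraction-limited spots are detected per channel and frame in three
stages: (1) candidates are local maxima of a Laplacian-of-Gaussian
response above `threshold_k` (default 5) times the response's robust
noise scale (MAD/0.6745); (2) each candidate is refined by least-squares
fitting of an anisotropic 3D Gaussian plus a constant local background
over a ±3σ window; (3) a fit is accepted only when its amplitude is
significant against the local background (t-test on the fit covariance,
default α = 0.05) and its σ stays within 0.3–3× the expected PSF widths.
The defaults are standard guard rails, declared rather than derived. The
reported integrated intensity is the fitted Gaussian volume
A·(2π)^{3/2}·σ_xy²·σ_z per voxel volume, which is background-free by
construction — adding a constant offset to the stack changes intensities
by <2% (tested).

Per-cell particle counts (mean ± SEM across cells per frame) are exposed
as the run-to-run QC statistic used to keep segmentation comparable
between datasets; the package reports the statistic rather than
auto-tuning thresholds against it.

## Drift correction and display filtering

Drift is estimated on one reference channel by cross-correlation between
*successive* frames, with cumulative summation — robust to slow
morphology changes. The correlation surface is mildly smoothed (Gaussian,
σ = 1 px, periodic boundaries) and the peak refined by a 3-point
quadratic fit per axis (on log-values when positive, which is exact for
Gaussian-shaped peaks). The smoothing stabilizes the interpolation under
noise without breaking exactness for integer shifts, because the
correlation of a frame with an integer-shifted copy of itself is
symmetric about the true peak. Typical accuracy: exact for integer
shifts, ≲0.1 px for sub-pixel shifts at SNR 10. Registration is 2D by
default (on the max-intensity projection when a z axis is present); a
full-3D mode exists. The estimated trace is applied, negated, to all
channels with linear interpolation; out-of-field voxels are filled with
the frame median.

The à-trous filter is a stationary B3-spline wavelet decomposition
(kernel [1,4,6,4,1]/16 with 2^(level−1)-spaced taps, mirror boundaries).
Detail planes are hard-thresholded at `k_sigma` times their MAD-based
noise scale and summed back with the smooth residual; at zero threshold
the input is reconstructed to machine precision. Filtering exists for
display only — the display convention averages the raw image with the
filtered one — and quantitative measurements are always computed on raw,
drift-corrected data.

## Central-spindle asymmetry

The spindle stack is max-projected over a 6 μm z window, then a
pseudo-linescan integrates intensity across the spindle width (ROI:
10 μm along the spindle axis × spindle width across, linear
interpolation after rotating onto the axis). The profile shows two peaks
flanking a midzone minimum; the two peak values are the profile maxima
on either side of the minimum between the two most prominent peaks. The
local background is the mean of the five width-integrated samples just
beyond each ROI end, averaged over both ends (the direction of the
"adjacent" background pixels is not uniquely determined by the
measurement description; averaging both ends is this package's
convention). Background-subtracted peaks give

Δ = (P_anterior − P_posterior) / (P_anterior + P_posterior) ∈ [−1, 1],

antisymmetric under swapping the labels. Anterior/posterior is an
explicit per-cell polarity annotation (the cap-containing daughter is
posterior by convention). Δ is a ratio, hence invariant to global
intensity scaling. Profiles are averaged across cells after registration
on the midzone minimum; group statistics use a paired t-test between the
two per-cell peaks and Mann-Whitney U between conditions.

On noiseless phantoms the pipeline recovers the generating Δ to 1e−6;
with noise at 5% of the peak amplitude, bias ≤ 0.02 and SD ≤ 0.05 over
100 seeds (tested).

## Cap geometry and division angle

Cortical intensity sampled on the equatorial circle yields the cap
direction (normalized intensity-weighted mean of sample direction
vectors) and the cap angular size, measured as the great-circle span of
the longest contiguous above-threshold arc in degrees (a single sample
counts as one angular bin; a uniform profile has undefined direction and
size 360°). The above-threshold fraction of the sampled cortex is
reported alongside, since "cap size" conventions vary. The division
plane passes through the cell centre with the spindle axis as normal;
the cap/division-plane angle is 90° − angle(cap direction, axis), folded
to [0, 90], so 90° means perfect cap–spindle alignment. The angle is
invariant to sign flips of either vector and to joint rotations.
Angle samples are tested against a 45° reference by a one-sample
Wilcoxon signed-rank test (n ≥ 5), with Mann-Whitney U between
conditions and Spearman correlation against covariates such as cap size.

## Tracking and anomalous diffusion

Per-frame particles are linked by a frame-to-frame assignment that
maximizes the number of links whose displacement is at most `max_disp`
and, among those, minimizes the total squared displacement
(Hungarian algorithm with a big-M cost for inadmissible pairs; ties
resolved deterministically by particle index). Unmatched particles start
tracks; a track survives up to `memory` skipped frames. On small
instances the result equals an exhaustive assignment oracle (tested).

The ensemble MSD at delay k·dt pools, per track, every displacement
between samples k frames apart; the across-track mean is weighted by
each track's pair count, equivalent to pooling all pairs — tracks with
more pairs (greater certainty) count more. Both a 3D MSD (default,
including Δz²) and a lateral-only 2D MSD are available; the model fitted
is MSD(t) = 6·D·t^α, whose prefactor 6 is the 3D isotropic constant,
which is why 3D is the default.

The fit is a weighted least-squares line in log-log space over the first
25% of delays (long delays have few pairs and high variance; the
fraction is configurable), exact for a noiseless power law; a direct
nonlinear fit is also provided. D (μm²/s^α), α, R² and 95% CIs are
reported; α with CI entirely below 1 is flagged subdiffusive/confined.

## Lattice-concentration equivalence

For a 3D Poisson point process of density n, the mean nearest-neighbour
distance is ⟨r⟩ = Γ(4/3)·(3/(4πn))^{1/3}. Solving ⟨r⟩ = 8 nm — the
inter-protein spacing enforced by the crystalline 2D arrays — gives
n ≈ 3.32·10²³ m⁻³, i.e. ≈ 0.55 mM: the solution concentration that
would reproduce the array's enforced proximity by chance. A Monte-Carlo
cross-check samples uniform points in a periodic cube and measures
nearest-neighbour distances directly (periodic boundaries remove edge
bias; 4000 points agree with the closed form to well under 2%).

## Synthetic-data generator

The generator provides ground truth for every analysis stage:

* **Spot stacks** — anisotropic 3D Gaussians (defaults σ_xy = 0.13 μm,
  σ_z = 0.25 μm, matching the calibrated resolutions via
  resol ≈ 2.3σ) on a constant background, with Poisson shot noise on
  signal+background scaled by a camera gain plus additive Gaussian read
  noise (the standard sCMOS model). Spots stay ≥3σ from stack borders so
  truth intensities are never truncated; a crowding flag is raised when
  the mean nearest-neighbour distance drops below 2σ_xy. An optional
  minimum pairwise separation (rejection sampling) reproduces the
  well-separated regime in which detection performance targets are
  stated.
* **Colocalization stacks** — channel-A spots placed uniformly;
  round(f_coloc·n) channel-B (and -C) spots at A positions plus
  isotropic Gaussian jitter, the rest uniform. With three channels the
  same fraction applies to B and C independently. Truth tables mark each
  spot colocalized or not, so the estimator can be validated against an
  exact generating fraction.
* **Spindle images** — two elliptical Gaussian peaks on the spindle axis
  with amplitudes A₀(1±Δ_true), so the noiseless peak amplitudes
  round-trip Δ exactly; additive Gaussian noise.
* **Tracks** — per-axis fractional Brownian motion with per-axis
  MSD = 2Dt^α (3D total 6Dt^α), generated by exact Cholesky
  factorization of the fBm increment covariance
  D·dt^α·(|k+1|^α + |k−1|^α − 2|k|^α). Exact covariance by construction
  simplifies testing, and O(n³) is acceptable at the ≤512-step lengths
  used; empirical increment covariances are checked against the analytic
  law. Localization error is iid Gaussian per coordinate; the
  cortical-array preset (137 tracks × 100 steps, dt = 0.5 s, D = 0.007 μm²/s^α,
  α = 0.65) uses 10 nm, a typical precision for bright array puncta in
  high-NA light-sheet imaging.

What the generator does **not** emulate: cell geometry and cap
coalescence, membrane mechanics, photobleaching, spatially varying
background, PSF aberrations and axial astigmatism, emitter blinking, and
motion blur. Passing recovery tests on this synthetic data therefore
demonstrates correctness of the estimators under their stated
assumptions, not robustness to every artefact of real microscopy data.

## Numerical conventions and degenerate inputs

* Physical coordinates in μm, 0-based voxel indices, position = voxel
  centre.
* Colocalization inequality is strict (d < r_ref); a boundary pair does
  not colocalize. A zero displacement has no direction and uses
  min(resol_xy, resol_z), flagged with a warning.
* Δ with both peaks zero is a missing value; negative
  background-subtracted peaks are clipped to 0 with a warning.
* Empty particle sets give missing (NaN) percentages, not 0.
* Single-cell groups report SEM 0 with an explicit n = 1.
* All generators and stochastic tests are seeded; identical config +
  seed reproduces outputs bit-for-bit.

## Problem sizes

Simulation sizes in the tests and the reproduction script were chosen as
desk-scale defaults that keep Monte-Carlo error comfortably inside the
stated tolerances: 137 tracks × 100 steps × 50 repeats for the
anomalous-exponent recovery, 4000 points for the nearest-neighbour
Monte-Carlo, 10⁴ randomized pairs for the Δ property sweep, 100 noisy
phantoms for Δ recovery, and 24-spot sparse stacks for the end-to-end
detection/colocalization recovery.
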