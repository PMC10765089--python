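# parquant

Quantitative 3D image analysis for cortical polarity experiments, in
which clustered Par-complex components (Par3, Par6, aPKC) appear as
diffraction-limited spots at the cell cortex and their recruitment,
motion and downstream effects on the mitotic spindle are measured from
multi-channel fluorescence z-stacks.

The package implements, as a tested and reusable library:

* **Object-based 3D colocalization** with an anisotropic reference
  distance: particles in two channels colocalize when their centroid
  distance is strictly below the resolution-ellipsoid radius along their
  joint direction,
  `r_ref = sqrt(resol_xy²·sin²Θ + resol_z²·cos²Θ)`
  (defaults resol_xy = 0.293 μm, resol_z = 0.498 μm), with
  intensity-weighted dual and triple colocalization percentages.
* **Spot detection** by 3D Gaussian PSF fitting with local-background
  correction, coverslip estimation, and the ventral-exclusion filter
  (drop particles within 600 nm = 3 z-planes of the coverslip).
* **Central-spindle asymmetry**: max-intensity projection,
  width-integrated pseudo-linescan over a 10 μm ROI, peak/background
  extraction, and the asymmetry statistic
  `Δ = (P_ant − P_post)/(P_ant + P_post) ∈ [−1, 1]`.
* **Cap/division geometry**: cap direction and angular size from
  cortical profiles, the cap/division-plane angle (90° = aligned), and
  a one-sample Wilcoxon test against 45°.
* **Drift correction** (successive-frame cross-correlation, sub-pixel)
  and an **à-trous B3-spline wavelet filter** for display.
* **3D particle tracking** and **anomalous-diffusion fitting** of the
  weighted ensemble MSD to `MSD(t) = 6·D·t^α` (α < 1: confined,
  subdiffusive motion).
* A **synthetic-data generator** (spot stacks, colocalization pairs and
  triples, spindle phantoms, fractional-Brownian 3D tracks) so that
  every stage is exercisable against exact ground truth with no
  external data.

See `docs/methods.md` for models, assumptions, defaults and
limitations.

## Worked example

Generate a two-channel synthetic stack in which exactly half of the
channel-B spots sit at channel-A positions, run detection and
colocalization, and fit the motion model on simulated cortical-array
tracks:

```python
import numpy as np
from parquant import synthgen as sg
from parquant.spots import detect_particles
from parquant.coloc import (ResolutionCalibration, match_particles,
                            percent_colocalization)
from parquant.motion import weighted_msd, fit_anomalous

base = sg.SyntheticSpotConfig(shape_voxels=(20, 192, 192), n_spots=24,
                              seed=42, min_separation=1.0)
stack, truth = sg.make_coloc_stack(
    sg.ColocConfig(base=base, f_coloc=0.5, jitter_sd=0.05))

calib = ResolutionCalibration()          # resol_xy=0.293, resol_z=0.498 um
a = detect_particles(stack, channel=0)
b = detect_particles(stack, channel=1)
match = match_particles(a, b, calib)
print(f"channel A: {len(a)} particles, channel B: {len(b)}")
print(f"colocalized: {int(match.colocalized.sum())} of {len(a)}")
print(f"percent colocalization: {percent_colocalization(a, match):.1f}%")

tracks = sg.make_tracks(sg.TrackSimConfig.cortical_array_preset(seed=42))
fit = fit_anomalous(weighted_msd(tracks))
print(f"alpha = {fit.alpha:.3f} "
      f"(95% CI {fit.alpha_ci[0]:.3f}-{fit.alpha_ci[1]:.3f})")
print(f"D = {fit.D:.4f} um^2/s^alpha, R^2 = {fit.r2:.3f}")
print(f"subdiffusive: {fit.subdiffusive}")
```

Output:

```
channel A: 24 particles, channel B: 26
colocalized: 12 of 24
percent colocalization: 52.0%
alpha = 0.643 (95% CI 0.641-0.646)
D = 0.0071 um^2/s^alpha, R^2 = 1.000
subdiffusive: True
```

The measured 52.0% recovers the generating fraction (50%) within
counting error — the percentage is intensity-weighted, so it tracks but
does not exactly equal the count fraction 12/24. The fitted exponent
α ≈ 0.64 with a confidence interval below 1 classifies the simulated
array motion as subdiffusive, and D is the generalized diffusion
coefficient of the `6·D·t^α` model in μm²/s^α.

A command-line interface wraps the same functions for shell use:

```sh
parquant detect --sigma-xy 0.13 --sigma-z 0.25 stack.tif particles.csv
parquant coloc --resol-xy 0.293 --resol-z 0.498 particles.csv out.json
parquant track --max-disp 0.5 --memory 1 particles.csv tracks.csv
parquant msdfit --mode 3d --fit-fraction 0.25 tracks.csv fit.json
```

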