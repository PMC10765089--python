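"""Synthetic ground-truth generators.

Emulates the statistical structure of the imaging data the analysis modules
expect, so that every stage of the pipeline can be exercised against known
truth:

* 3D stacks of diffraction-limited spots (anisotropic Gaussian PSF,
  Poisson photon noise + Gaussian read noise, sCMOS-style),
* multi-channel stacks in which a controlled fraction of spots in the
  second (and optionally third) channel sit at first-channel positions,
* 2D anaphase central-spindle images: two peaks flanking a midzone with a
  controlled asymmetry Δ,
* 3D subdiffusive tracks: per-axis fractional Brownian motion scaled so the
  ensemble 3D mean-squared displacement is MSD(t) = 6·D·t^α, plus iid
  Gaussian localization error.

All generators are deterministic given their ``seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .stack import ImageStack

__all__ = [
    "SyntheticSpotConfig", "ColocConfig", "SpindleConfig", "TrackSimConfig",
    "make_spot_stack", "make_coloc_stack", "make_spindle_image", "make_tracks",
    "fbm_increment_covariance",
]


# ---------------------------------------------------------------------------
# configs

@dataclass
class SyntheticSpotConfig:
    """Parameters of a single-channel 3D spot stack.

    Lengths are micrometres; the default z-step of 0.2 um matches a
    confocal stack acquired at dz = 200 nm.  ``min_separation`` (um)
    enforces a minimum pairwise spot distance by rejection sampling
    (0 = fully uniform placement).
    """

    shape_voxels: tuple[int, int, int] = (20, 96, 96)   # (z, y, x)
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1)
    n_spots: int = 20
    psf_sigma_xy: float = 0.13
    psf_sigma_z: float = 0.25
    amplitude_range: tuple[float, float] = (800.0, 1200.0)
    background: float = 100.0
    poisson_gain: float = 1.0      # electrons per count; 0 disables shot noise
    gaussian_sd: float = 2.0       # read noise, counts; 0 disables
    min_separation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")
        if self.psf_sigma_xy <= 0 or self.psf_sigma_z <= 0:
            raise ValueError("PSF sigmas must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        lo, hi = self.amplitude_range
        if lo > hi:
            raise ValueError("amplitude_range low must be <= high")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("shape_voxels", "voxel_size", "amplitude_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class ColocConfig:
    """Two- or three-channel spot stack with controlled colocalization.

    ``f_coloc`` is the fraction of channel-B (and -C) spots placed at
    channel-A positions, jittered isotropically by ``jitter_sd``.
    With three channels the same fraction is applied to B and C
    independently.
    """

    base: SyntheticSpotConfig = field(default_factory=SyntheticSpotConfig)
    f_coloc: float = 0.5
    jitter_sd: float = 0.05
    n_channels: int = 2

    def __post_init__(self):
        if not 0.0 <= self.f_coloc <= 1.0:
            raise ValueError("f_coloc must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.n_channels not in (2, 3):
            raise ValueError("n_channels must be 2 or 3")


@dataclass
class SpindleConfig:
    """Anaphase central-spindle phantom: two peaks flanking a midzone.

    The two peak amplitudes are ``A0*(1 + delta_true)`` (anterior) and
    ``A0*(1 - delta_true)`` (posterior), so the asymmetry statistic
    Δ = (P_ant − P_post)/(P_ant + P_post) applied to the noiseless peaks
    returns ``delta_true`` exactly.  By image convention the anterior
    (cap-free) side is at negative x (left).
    """

    image_shape: tuple[int, int] = (64, 128)            # (y, x) pixels
    pixel_size: float = 0.1                             # um
    peak_sep: float = 4.0                               # um between peaks
    peak_sd: float = 0.6                                # um, along x
    base_amplitude: float = 1000.0
    delta_true: float = 0.0
    background: float = 50.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not -1.0 <= self.delta_true <= 1.0:
            raise ValueError("delta_true must be in [-1, 1]")
        if self.peak_sep <= 0:
            raise ValueError("peak_sep must be positive")


@dataclass
class TrackSimConfig:
    """3D fractional-Brownian-motion track simulation.

    ``D`` is the generalized diffusion coefficient (um^2 / s^alpha) and
    ``alpha`` the anomalous exponent of the target ensemble model
    MSD(t) = 6 D t^alpha (3D, all three axes).
    """

    n_tracks: int = 137
    n_steps: int = 100
    dt: float = 0.5
    D: float = 0.007
    alpha: float = 0.65
    loc_error_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_tracks <= 0 or self.n_steps <= 0:
            raise ValueError("n_tracks and n_steps must be positive")
        if not 0.0 < self.alpha < 2.0:
            raise ValueError("alpha must be in (0, 2)")
        if self.D <= 0:
            raise ValueError("D must be positive")

    @classmethod
    def cortical_array_preset(cls, seed: int = 0) -> "TrackSimConfig":
        """Preset of the cortical-array motion analysis: 137 tracks,
        alpha = 0.65, D = 0.007 um^2/s^alpha."""
        return cls(n_tracks=137, n_steps=100, dt=0.5, D=0.007, alpha=0.65,
                   loc_error_sd=0.01, seed=seed)


# ---------------------------------------------------------------------------
# spot stacks

def _render_gaussian(img, pos_um, amplitude, sigma_xy, sigma_z, voxel_size):
    """Add one anisotropic 3D Gaussian to ``img`` in place.

    ``pos_um`` is (x, y, z) in um; voxel centres sit at index*voxel_size.
    Rendering is restricted to a +/-5 sigma window for speed.  Returns the
    numerically integrated (summed) intensity of the rendered profile.
    """
    vz, vy, vx = voxel_size
    x, y, z = pos_um
    nz, ny, nx = img.shape
    iz = int(round(z / vz)); iy = int(round(y / vy)); ix = int(round(x / vx))
    hz = max(2, int(np.ceil(5 * sigma_z / vz)))
    hxy_y = max(2, int(np.ceil(5 * sigma_xy / vy)))
    hxy_x = max(2, int(np.ceil(5 * sigma_xy / vx)))
    z0, z1 = max(0, iz - hz), min(nz, iz + hz + 1)
    y0, y1 = max(0, iy - hxy_y), min(ny, iy + hxy_y + 1)
    x0, x1 = max(0, ix - hxy_x), min(nx, ix + hxy_x + 1)
    zz = (np.arange(z0, z1) * vz - z)[:, None, None]
    yy = (np.arange(y0, y1) * vy - y)[None, :, None]
    xx = (np.arange(x0, x1) * vx - x)[None, None, :]
    g = amplitude * np.exp(
        -(xx ** 2 + yy ** 2) / (2 * sigma_xy ** 2) - zz ** 2 / (2 * sigma_z ** 2))
    img[z0:z1, y0:y1, x0:x1] += g
    return float(g.sum())


def _apply_noise(img, cfg, rng):
    out = img
    if cfg.poisson_gain > 0:
        out = cfg.poisson_gain * rng.poisson(
            np.maximum(out, 0.0) / cfg.poisson_gain).astype(float)
    if cfg.gaussian_sd > 0:
        out = out + rng.normal(0.0, cfg.gaussian_sd, size=out.shape)
    return out


def _uniform_positions(rng, n, cfg):
    """Uniform (x, y, z) positions in um, >= 3 sigma from every border."""
    vz, vy, vx = cfg.voxel_size
    nz, ny, nx = cfg.shape_voxels
    mz = 3 * cfg.psf_sigma_z
    mxy = 3 * cfg.psf_sigma_xy
    extents = ((nx - 1) * vx, (ny - 1) * vy, (nz - 1) * vz)
    lo = np.array([mxy, mxy, mz])
    hi = np.array(extents) - lo
    if np.any(hi <= lo):
        raise ValueError("stack too small for 3-sigma edge margin")
    if cfg.min_separation <= 0 or n < 2:
        return rng.uniform(lo, hi, size=(n, 3))
    out: list[np.ndarray] = []
    tries = 0
    while len(out) < n:
        p = rng.uniform(lo, hi)
        if all(np.linalg.norm(p - q) >= cfg.min_separation for q in out):
            out.append(p)
        tries += 1
        if tries > 1000 * n:
            raise ValueError("cannot satisfy min_separation at this density")
    return np.array(out)


def make_spot_stack(cfg: SyntheticSpotConfig, *, rng=None, positions=None,
                    amplitudes=None):
    """Render a single-channel 3D stack of diffraction-limited spots.

    Returns ``(stack, truth)`` where truth is a DataFrame with columns
    ``x_um, y_um, z_um, amplitude, intensity`` (``intensity`` is the
    noiseless summed signal of the spot over the voxel grid).  The stack
    meta carries ``crowded=True`` when the mean nearest-neighbour spot
    distance falls below twice the lateral PSF sigma, a regime in which
    detection is expected to be unreliable.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    img = np.zeros(cfg.shape_voxels, dtype=float)
    if positions is None:
        positions = (_uniform_positions(rng, cfg.n_spots, cfg)
                     if cfg.n_spots else np.empty((0, 3)))
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if amplitudes is None:
        amplitudes = rng.uniform(*cfg.amplitude_range, size=n)
    rows = []
    for (x, y, z), a in zip(positions, np.atleast_1d(amplitudes)):
        inten = _render_gaussian(img, (x, y, z), a, cfg.psf_sigma_xy,
                                 cfg.psf_sigma_z, cfg.voxel_size)
        rows.append((x, y, z, a, inten))
    truth = pd.DataFrame(rows, columns=["x_um", "y_um", "z_um",
                                        "amplitude", "intensity"])
    crowded = False
    if n >= 2:
        from scipy.spatial import cKDTree
        d, _ = cKDTree(positions).query(positions, k=2)
        crowded = bool(d[:, 1].mean() < 2 * cfg.psf_sigma_xy)
    noisy = _apply_noise(img + cfg.background, cfg, rng)
    stack = ImageStack(noisy, cfg.voxel_size, "ZYX",
                       meta={"seed": cfg.seed, "crowded": crowded})
    return stack, truth


def make_coloc_stack(cfg: ColocConfig):
    """Render a multi-channel stack with a controlled colocalized fraction.

    Channel A spots are uniform; ``round(f_coloc * n)`` spots of each other
    channel are placed at (distinct) A positions plus isotropic Gaussian
    jitter, the remainder uniform.  Returns ``(stack, truth)`` where truth
    has one row per spot with columns ``channel, x_um, y_um, z_um,
    amplitude, intensity, colocalized``.
    """
    base = cfg.base
    rng = np.random.default_rng(base.seed)
    n = base.n_spots
    pos_a = _uniform_positions(rng, n, base) if n else np.empty((0, 3))
    channels = []
    frames = []
    stack_a, truth_a = make_spot_stack(base, rng=rng, positions=pos_a)
    truth_a.insert(0, "channel", 0)
    truth_a["colocalized"] = 0
    channels.append(stack_a.data)
    frames.append(truth_a)
    n_col = int(round(cfg.f_coloc * n))
    for ci in range(1, cfg.n_channels):
        idx = rng.choice(n, size=n_col, replace=False) if n_col else []
        pos = np.empty((n, 3))
        pos[:n_col] = pos_a[idx]
        if cfg.jitter_sd > 0 and n_col:
            pos[:n_col] += rng.normal(0.0, cfg.jitter_sd, size=(n_col, 3))
        if n - n_col:
            pos[n_col:] = _uniform_positions(rng, n - n_col, base)
        st, tr = make_spot_stack(base, rng=rng, positions=pos)
        tr.insert(0, "channel", ci)
        tr["colocalized"] = (np.arange(n) < n_col).astype(int)
        channels.append(st.data)
        frames.append(tr)
    stack = ImageStack(np.stack(channels), base.voxel_size, "CZYX",
                       meta={"seed": base.seed, "f_coloc": cfg.f_coloc})
    return stack, pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# spindle phantom

def make_spindle_image(cfg: SpindleConfig):
    """Render a 2D central-spindle phantom and return ``(image, delta_true)``.

    Two elliptical Gaussian peaks sit on the horizontal (spindle) axis at
    x = centre +/- peak_sep/2; the anterior peak (left) has amplitude
    ``A0*(1+delta)``, the posterior ``A0*(1-delta)``.
    """
    rng = np.random.default_rng(cfg.seed)
    ny, nx = cfg.image_shape
    p = cfg.pixel_size
    yy, xx = np.mgrid[0:ny, 0:nx]
    xu = xx * p
    yu = yy * p
    cx = (nx - 1) * p / 2.0
    cy = (ny - 1) * p / 2.0
    sx = cfg.peak_sd
    sy = 1.5 * cfg.peak_sd            # spindle is wider than each peak
    amp_ant = cfg.base_amplitude * (1.0 + cfg.delta_true)
    amp_post = cfg.base_amplitude * (1.0 - cfg.delta_true)
    img = np.full((ny, nx), float(cfg.background))
    for amp, x0 in ((amp_ant, cx - cfg.peak_sep / 2),
                    (amp_post, cx + cfg.peak_sep / 2)):
        img += amp * np.exp(-(xu - x0) ** 2 / (2 * sx ** 2)
                            - (yu - cy) ** 2 / (2 * sy ** 2))
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    stack = ImageStack(img, (cfg.pixel_size, cfg.pixel_size, cfg.pixel_size),
                       "YX", meta={"seed": cfg.seed,
                                   "delta_true": cfg.delta_true,
                                   "anterior": "left"})
    return stack, cfg.delta_true


# ---------------------------------------------------------------------------
# fractional Brownian motion tracks

def fbm_increment_covariance(n_steps: int, dt: float, D: float,
                             alpha: float) -> np.ndarray:
    """Covariance matrix of successive 1D fBm increments.

    For per-axis MSD(t) = 2 D t^alpha the increment covariance is
    ``D dt^a (|i-j+1|^a + |i-j-1|^a - 2|i-j|^a)`` with ``a = alpha``.
    """
    k = np.abs(np.arange(n_steps)[:, None] - np.arange(n_steps)[None, :])
    a = alpha
    return D * dt ** a * (np.abs(k + 1.0) ** a + np.abs(k - 1.0) ** a
                          - 2.0 * k.astype(float) ** a)


def _fbm_cholesky(n_steps, dt, D, alpha):
    cov = fbm_increment_covariance(n_steps, dt, D, alpha)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        # near-singular for alpha close to 2; regularize minimally
        eps = 1e-12 * np.trace(cov) / n_steps
        return np.linalg.cholesky(cov + eps * np.eye(n_steps))


def make_tracks(cfg: TrackSimConfig) -> list[pd.DataFrame]:
    """Simulate 3D subdiffusive tracks.

    Each track is fractional Brownian motion, independent per axis, with
    per-axis MSD = 2 D t^alpha so the 3D ensemble MSD is 6 D t^alpha.
    Increments are generated by exact Cholesky factorization of the fBm
    increment covariance (guaranteed covariance for the desk-scale track
    lengths used here).  Localization error is iid Gaussian per coordinate.

    Returns a list of DataFrames with columns ``t, x, y, z``.
    """
    if cfg.n_steps > 512:
        raise ValueError("exact Cholesky generation is limited to <=512 steps")
    rng = np.random.default_rng(cfg.seed)
    L = _fbm_cholesky(cfg.n_steps, cfg.dt, cfg.D, cfg.alpha)
    t = np.arange(cfg.n_steps + 1) * cfg.dt
    tracks = []
    for _ in range(cfg.n_tracks):
        z = rng.standard_normal((cfg.n_steps, 3))
        incr = L @ z                                  # (n_steps, 3)
        pos = np.vstack([np.zeros(3), np.cumsum(incr, axis=0)])
        if cfg.loc_error_sd > 0:
            pos = pos + rng.normal(0.0, cfg.loc_error_sd, size=pos.shape)
        tracks.append(pd.DataFrame(
            {"t": t, "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2]}))
    return tracks
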