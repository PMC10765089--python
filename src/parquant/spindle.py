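"""Central-spindle asymmetry: pseudo-linescan, peaks, and the Δ statistic.

Anaphase central spindles are projected (max-intensity over a 6-um z
window), a rectangular ROI 10 um long and one spindle-width wide is laid
along the spindle axis, and the signal is integrated across the width at
each axial position.  The resulting profile shows two peaks (one per
daughter), whose background-subtracted values give the asymmetry

    Δ = (P_anterior − P_posterior) / (P_anterior + P_posterior),

bounded in [−1, 1] and antisymmetric under swapping the anterior /
posterior labels.  Anterior/posterior is an explicit polarity annotation
(by convention the cap-containing daughter is posterior).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .stack import ImageStack

__all__ = ["SpindleROI", "LineProfile", "AsymmetryScore", "project_stack",
           "pseudo_linescan", "find_spindle_peaks", "delta",
           "average_profiles", "summarize_deltas"]


@dataclass
class SpindleROI:
    """Rectangular ROI along the spindle axis.

    ``centre`` is (x, y) in um, ``angle_deg`` the orientation of the
    spindle (x-)axis counter-clockwise from the image x-axis, ``length``
    the ROI extent along the spindle (10 um by default) and ``width`` the
    per-cell spindle width across it.
    """

    centre: tuple[float, float]
    angle_deg: float = 0.0
    length: float = 10.0
    width: float = 2.0

    def __post_init__(self):
        if self.length <= 0 or self.width <= 0:
            raise ValueError("ROI length and width must be positive")


@dataclass
class LineProfile:
    """Width-integrated intensity versus position along the spindle axis.

    ``x_um`` is position relative to the ROI centre (strictly increasing);
    ``bg_left``/``bg_right`` hold the width-integrated samples just beyond
    each ROI end used for local background estimation.
    """

    x_um: np.ndarray
    intensity: np.ndarray
    n_pixels_y: int
    bg_left: np.ndarray = field(default_factory=lambda: np.empty(0))
    bg_right: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if np.any(np.diff(self.x_um) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class AsymmetryScore:
    peak_anterior: float
    peak_posterior: float
    background: float
    delta: float


def project_stack(stack: ImageStack, depth: float = 6.0,
                  z_center: float | None = None) -> ImageStack:
    """Max-intensity projection over a z window of the given depth (um).

    The window is centred on ``z_center`` (default: stack centre); a depth
    exceeding the stack uses the full stack with a warning.
    """
    vol = np.asarray(stack.data, dtype=float)
    if vol.ndim == 2:
        return ImageStack(vol.copy(), stack.voxel_size, "YX", dict(stack.meta))
    if vol.ndim != 3:
        raise ValueError("expected a ZYX stack")
    vz = stack.voxel_size[0]
    extent = (vol.shape[0] - 1) * vz
    if depth >= extent + vz:
        if depth > extent + vz:
            warnings.warn("requested depth exceeds stack: using full stack")
        z0, z1 = 0, vol.shape[0]
    else:
        zc = extent / 2 if z_center is None else z_center
        z0 = max(0, int(round((zc - depth / 2) / vz)))
        z1 = min(vol.shape[0], z0 + int(round(depth / vz)) + 1)
    return ImageStack(vol[z0:z1].max(axis=0), stack.voxel_size, "YX",
                      dict(stack.meta))


def pseudo_linescan(image: ImageStack, roi: SpindleROI,
                    pad_px: int = 5) -> LineProfile:
    """Width-integrated profile along the ROI's long axis.

    The image is resampled (linear interpolation) on a grid aligned with
    the spindle axis; at each x-bin the intensity is summed over the ROI
    width.  ``pad_px`` extra bins are sampled beyond each ROI end for
    local-background estimation.
    """
    img = np.asarray(image.data, dtype=float)
    if img.ndim != 2:
        raise ValueError("pseudo_linescan expects a 2D (projected) image")
    p = image.voxel_size[-1]
    ny_roi = int(round(roi.width / p))
    if ny_roi < 1:
        raise ValueError("degenerate ROI: width below one pixel")
    nx_roi = int(round(roi.length / p))
    nx = nx_roi + 2 * pad_px
    xs = (np.arange(nx) - (nx - 1) / 2) * p                 # along spindle
    ys = (np.arange(ny_roi) - (ny_roi - 1) / 2) * p          # across
    ang = np.deg2rad(roi.angle_deg)
    ca, sa = np.cos(ang), np.sin(ang)
    cx, cy = roi.centre
    X = cx + xs[None, :] * ca - ys[:, None] * sa
    Y = cy + xs[None, :] * sa + ys[:, None] * ca
    inside = ((X >= 0) & (X <= (img.shape[1] - 1) * p)
              & (Y >= 0) & (Y <= (img.shape[0] - 1) * p))
    if not inside.all():
        warnings.warn("ROI extends beyond the image: clipped at the border")
    vals = ndimage.map_coordinates(img, [Y / p, X / p], order=1,
                                   mode="nearest")
    prof = vals.sum(axis=0)
    sl = slice(pad_px, pad_px + nx_roi)
    return LineProfile(xs[sl], prof[sl], ny_roi,
                       bg_left=prof[:pad_px], bg_right=prof[pad_px + nx_roi:])


def _central_minimum(intensity: np.ndarray) -> int:
    """Index of the midzone minimum between the two most prominent peaks."""
    peaks, props = signal.find_peaks(intensity, prominence=0.0)
    if len(peaks) < 2:
        raise ValueError("no central-spindle morphology: fewer than two peaks")
    top = peaks[np.argsort(props["prominences"])[-2:]]
    lo, hi = int(top.min()), int(top.max())
    return lo + int(np.argmin(intensity[lo:hi + 1]))


def find_spindle_peaks(profile: LineProfile,
                       anterior: str = "left") -> AsymmetryScore:
    """Extract the two spindle-half peaks, subtract local background, and
    score the asymmetry.

    The two peaks are the profile maxima on either side of the midzone
    minimum.  The local background is the mean of the (up to) five
    width-integrated samples just beyond each ROI end, averaged over both
    ends.  ``anterior`` ('left' or 'right') states which side of the
    profile is the anterior (cap-free) daughter.
    """
    if anterior not in ("left", "right"):
        raise ValueError("anterior must be 'left' or 'right'")
    y = np.asarray(profile.intensity, dtype=float)
    imin = _central_minimum(y)
    left = float(y[:imin + 1].max())
    right = float(y[imin:].max())
    bg_samples = np.concatenate([profile.bg_left[-5:], profile.bg_right[:5]])
    if len(bg_samples) == 0:
        bg_samples = np.concatenate([y[:2], y[-2:]])
        warnings.warn("no out-of-ROI samples: background from profile ends")
    bg = float(bg_samples.mean())
    left -= bg
    right -= bg
    if left < 0 or right < 0:
        warnings.warn("background exceeds a peak: clipping to zero")
        left, right = max(left, 0.0), max(right, 0.0)
    ant, post = (left, right) if anterior == "left" else (right, left)
    return AsymmetryScore(ant, post, bg, delta(ant, post))


def delta(peak_anterior: float, peak_posterior: float) -> float:
    """Normalized central-spindle asymmetry.

    Δ = (P_ant − P_post)/(P_ant + P_post), in [−1, 1], antisymmetric
    under label swap; NaN when both peaks are zero.
    """
    if peak_anterior < 0 or peak_posterior < 0:
        raise ValueError("peak intensities must be non-negative")
    s = peak_anterior + peak_posterior
    if s == 0:
        return float("nan")
    return float((peak_anterior - peak_posterior) / s)


def average_profiles(profiles: list[LineProfile]) -> pd.DataFrame:
    """Pointwise mean +/- SEM of profiles registered on the midzone.

    Each profile is re-centred on its midzone minimum (the registration
    cue), interpolated onto the common overlapping grid of the first
    profile, and averaged.  Returns columns ``x_um, mean, sem, n``.
    """
    if not profiles:
        raise ValueError("no profiles")
    recentred = []
    for pr in profiles:
        x0 = pr.x_um[_central_minimum(pr.intensity)]
        recentred.append((pr.x_um - x0, pr.intensity))
    lo = max(x.min() for x, _ in recentred)
    hi = min(x.max() for x, _ in recentred)
    step = np.median(np.diff(recentred[0][0]))
    grid = np.arange(lo, hi + step / 2, step)
    mat = np.vstack([np.interp(grid, x, y) for x, y in recentred])
    mean = mat.mean(axis=0)
    n = len(profiles)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return pd.DataFrame({"x_um": grid, "mean": mean, "sem": sem, "n": n})


def summarize_deltas(per_cell: pd.DataFrame, group_col: str = "group",
                     reference: str | None = None) -> pd.DataFrame:
    """Per-group Δ mean +/- SEM with the standard significance tests.

    Expects per-cell columns ``peak_ant, peak_post, delta`` plus the group
    column.  Within each group the two per-cell peak values are compared
    by a paired t-test (skipped, NaN, below two cells); when ``reference``
    names a group, each other group's Δ is compared to it by a
    Mann-Whitney U test.
    """
    rows = []
    ref_vals = None
    if reference is not None:
        ref_vals = per_cell.loc[per_cell[group_col] == reference,
                                "delta"].to_numpy(dtype=float)
    for grp, g in per_cell.groupby(group_col, sort=True):
        d = g["delta"].to_numpy(dtype=float)
        d = d[np.isfinite(d)]
        n = len(d)
        sem = float(d.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        if len(g) >= 2:
            p_paired = float(stats.ttest_rel(g["peak_ant"], g["peak_post"]).pvalue)
        else:
            p_paired = float("nan")
        p_mw = float("nan")
        if (ref_vals is not None and grp != reference
                and n > 0 and len(ref_vals) > 0):
            p_mw = float(stats.mannwhitneyu(d, ref_vals,
                                            alternative="two-sided").pvalue)
        rows.append((grp, float(d.mean()) if n else float("nan"),
                     sem, n, p_paired, p_mw))
    return pd.DataFrame(rows, columns=[group_col, "mean_delta", "sem", "n",
                                       "p_paired_peaks", "p_vs_reference"])
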