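"""Drift correction and à-trous wavelet filtering.

Drift between successive frames is estimated by cross-correlation on one
reference channel and the cumulative shift is applied to all channels.
Quantitative measurements are always performed on raw, drift-corrected
data; the à-trous filter exists purely to enhance spots for display, where
the convention is to average the raw image with the filtered one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .stack import ImageStack

__all__ = ["DriftTrace", "estimate_drift", "apply_drift",
           "atrous_filter", "display_blend"]


@dataclass
class DriftTrace:
    """Cumulative per-frame shift relative to the first frame.

    ``shifts`` has shape (n_frames, ndim) in pixel units (sub-pixel
    allowed), axis order matching the image axes ((y, x) in 2D,
    (z, y, x) in 3D).  The first row is zero by construction.
    """

    shifts: np.ndarray
    reference_channel: int = 0

    def __post_init__(self):
        self.shifts = np.atleast_2d(np.asarray(self.shifts, dtype=float))
        if not np.allclose(self.shifts[0], 0.0):
            raise ValueError("shift of the first frame must be zero")

    def __len__(self) -> int:
        return len(self.shifts)

    def to_csv(self, path) -> None:
        cols = ["dz", "dy", "dx"][-self.shifts.shape[1]:]
        df = pd.DataFrame(self.shifts, columns=cols)
        df.insert(0, "frame", np.arange(len(df)))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, reference_channel: int = 0) -> "DriftTrace":
        df = pd.read_csv(path)
        cols = [c for c in ("dz", "dy", "dx") if c in df.columns]
        return cls(df[cols].to_numpy(), reference_channel)


def _xcorr_shift(ref: np.ndarray, img: np.ndarray) -> np.ndarray:
    """Shift of ``img`` relative to ``ref`` by FFT cross-correlation with
    local quadratic refinement of the correlation peak."""
    a = ref - ref.mean()
    b = img - img.mean()
    if not (a.any() and b.any()):
        warnings.warn("all-zero frame: correlation undefined, zero shift")
        return np.zeros(ref.ndim)
    axes = tuple(range(a.ndim))
    corr = np.fft.irfftn(np.fft.rfftn(a).conj() * np.fft.rfftn(b),
                         s=a.shape, axes=axes)
    # mild smoothing stabilizes the 3-point interpolation under noise while
    # preserving the symmetry of the (auto)correlation around integer shifts
    corr = ndimage.gaussian_filter(corr, 1.0, mode="wrap")
    peak = np.array(np.unravel_index(np.argmax(corr), corr.shape))
    shift = peak.astype(float)
    # quadratic (log-parabolic when possible) interpolation per axis
    for ax in range(corr.ndim):
        vals = []
        for off in (-1, 0, 1):
            j = list(peak)
            j[ax] = (peak[ax] + off) % corr.shape[ax]
            vals.append(float(corr[tuple(j)]))
        cm, c0, cp = vals
        if cm > 0 and c0 > 0 and cp > 0:
            cm, c0, cp = np.log(cm), np.log(c0), np.log(cp)
        denom = cm - 2 * c0 + cp
        if denom < 0:
            shift[ax] += 0.5 * (cm - cp) / denom
    # wrap circular shifts to the centred interval
    dims = np.array(corr.shape)
    shift = (shift + dims / 2) % dims - dims / 2
    return shift


def estimate_drift(stack: ImageStack, reference_channel: int = 0,
                   mode: str = "2d") -> DriftTrace:
    """Estimate per-frame cumulative drift on one channel.

    Registration is successive-frame (frame t against frame t-1) with the
    per-step shifts accumulated, which is robust to slow changes of the
    scene.  In the default ``"2d"`` mode a stack with a Z axis is
    registered on its max-intensity projection and the trace is lateral
    only; ``"3d"`` correlates the full volume and yields (z, y, x) shifts.
    """
    if mode not in ("2d", "3d"):
        raise ValueError("mode must be '2d' or '3d'")
    if "T" not in stack.axes or stack.n_frames < 2:
        raise ValueError("need a time axis with >= 2 frames")
    frames = [stack.frame(t).channel(reference_channel).data
              for t in range(stack.n_frames)]
    if mode == "2d" and frames[0].ndim == 3:
        frames = [f.max(axis=0) for f in frames]
    steps = [np.zeros(frames[0].ndim)]
    for prev, cur in zip(frames[:-1], frames[1:]):
        steps.append(_xcorr_shift(prev, cur))
    return DriftTrace(np.cumsum(steps, axis=0), reference_channel)


def apply_drift(stack: ImageStack, trace: DriftTrace) -> ImageStack:
    """Shift every channel of every frame by the negated drift trace.

    Out-of-field voxels are filled with the frame's median as a background
    estimate.  Interpolation is linear, so integer shifts are exact.
    """
    if len(trace) != stack.n_frames:
        raise ValueError("trace length does not match number of frames")
    data = np.asarray(stack.data, dtype=float).copy()
    ti = stack.axes.index("T")
    ndim_shift = trace.shifts.shape[1]
    for t in range(stack.n_frames):
        sh = -trace.shifts[t]
        sl = [slice(None)] * data.ndim
        sl[ti] = t
        frame = data[tuple(sl)]
        lead = frame.shape[:frame.ndim - ndim_shift]
        flat = frame.reshape((-1,) + frame.shape[frame.ndim - ndim_shift:])
        for i in range(flat.shape[0]):
            flat[i] = ndimage.shift(flat[i], sh, order=1, mode="constant",
                                    cval=float(np.median(flat[i])))
        data[tuple(sl)] = flat.reshape(lead + frame.shape[len(lead):])
    return replace(stack, data=data)


# ---------------------------------------------------------------------------
# à-trous wavelet filter

_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _atrous_smooth(img: np.ndarray, level: int) -> np.ndarray:
    """One B3-spline smoothing pass with 2^(level-1)-spaced taps."""
    step = 2 ** (level - 1)
    kernel = np.zeros(4 * step + 1)
    kernel[::step] = _B3
    out = img
    for ax in range(img.ndim):
        out = ndimage.convolve1d(out, kernel, axis=ax, mode="mirror")
    return out


def atrous_decompose(img: np.ndarray, n_levels: int):
    """Stationary B3-spline à-trous decomposition.

    Returns ``(planes, residual)`` with ``len(planes) == n_levels``;
    ``sum(planes) + residual`` reconstructs the input exactly.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    span = 4 * 2 ** (n_levels - 1) + 1
    if span > min(img.shape):
        raise ValueError(
            f"n_levels={n_levels} needs images of size >= {span} per axis")
    planes = []
    c = np.asarray(img, dtype=float)
    for lvl in range(1, n_levels + 1):
        s = _atrous_smooth(c, lvl)
        planes.append(c - s)
        c = s
    return planes, c


def atrous_filter(img: np.ndarray, n_levels: int = 4,
                  k_sigma: float = 3.0) -> np.ndarray:
    """Denoise by hard-thresholding à-trous detail planes.

    Each detail plane is thresholded at ``k_sigma`` times its robust noise
    scale (median absolute deviation / 0.6745); the output is the sum of
    thresholded planes plus the smooth residual.  With ``k_sigma = 0`` the
    input is reconstructed to machine precision.
    """
    planes, residual = atrous_decompose(np.asarray(img, dtype=float), n_levels)
    out = residual.copy()
    for p in planes:
        if k_sigma > 0:
            sigma = np.median(np.abs(p - np.median(p))) / 0.6745
            p = np.where(np.abs(p) >= k_sigma * sigma, p, 0.0)
        out += p
    return out


def display_blend(raw: np.ndarray, filtered: np.ndarray) -> np.ndarray:
    """Voxel-wise mean of raw and filtered images (display convention)."""
    raw = np.asarray(raw, dtype=float)
    filtered = np.asarray(filtered, dtype=float)
    if raw.shape != filtered.shape:
        raise ValueError("raw and filtered images must have the same shape")
    return 0.5 * (raw + filtered)
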