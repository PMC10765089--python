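"""Cortical-cap geometry and the cap / division-plane angle.

A rounded mitotic cell carries a coalesced cortical cap of clustered
polarity proteins.  The cap is summarized by a direction (unit vector from
the cell centre to the intensity-weighted cap centroid) and an angular
size (extent of the contiguous above-threshold arc on the equatorial
great circle through the cap).  The division plane passes through the
cell centre with the spindle axis as its normal; the angle between the
cap direction and that plane is folded to [0, 90] degrees, with 90
meaning perfect cap/spindle alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CapGeometry", "DivisionGeometry", "fit_cap", "division_angle",
           "angle_vs_reference"]


@dataclass
class CapGeometry:
    """Direction and angular size of a cortical cap.

    ``direction`` is a unit vector (None when the signal is uniform and no
    direction is defined); ``angular_size_deg`` is the great-circle extent
    of the above-threshold arc; ``above_threshold_fraction`` the fraction
    of the sampled cortex above threshold.
    """

    direction: np.ndarray | None
    angular_size_deg: float
    above_threshold_fraction: float

    def __post_init__(self):
        if self.direction is not None:
            n = np.linalg.norm(self.direction)
            if not np.isclose(n, 1.0):
                raise ValueError("cap direction must be a unit vector")
        if not 0.0 < self.angular_size_deg <= 360.0:
            raise ValueError("angular size must be in (0, 360]")


@dataclass
class DivisionGeometry:
    """Division plane through the cell centre, normal to the spindle axis."""

    spindle_axis: np.ndarray

    def __post_init__(self):
        self.spindle_axis = np.asarray(self.spindle_axis, dtype=float)
        n = np.linalg.norm(self.spindle_axis)
        if n == 0:
            raise ValueError("spindle axis must be non-zero")
        self.spindle_axis = self.spindle_axis / n

    @classmethod
    def from_poles(cls, pole1, pole2) -> "DivisionGeometry":
        return cls(np.asarray(pole2, dtype=float)
                   - np.asarray(pole1, dtype=float))


def fit_cap(angles_deg, intensity, threshold) -> CapGeometry:
    """Fit cap geometry from cortical intensity sampled on the equatorial
    circle.

    ``angles_deg`` are sample azimuths (degrees, any order), ``intensity``
    the cortical signal at each sample.  The direction is the normalized
    intensity-weighted mean of the sample direction vectors; the angular
    size is the longest contiguous above-threshold arc (wrap-around
    included).  A uniform profile has no defined direction and reports
    360 degrees.
    """
    ang = np.deg2rad(np.asarray(angles_deg, dtype=float))
    inten = np.asarray(intensity, dtype=float)
    above = inten >= threshold
    if not above.any():
        raise ValueError("no cap: no above-threshold cortical signal")
    order = np.argsort(ang)
    ang, inten, above = ang[order], inten[order], above[order]
    frac = float(above.mean())
    n = len(ang)
    if above.all():
        size = 360.0
    else:
        # longest run of above-threshold samples, circularly
        ext = np.concatenate([above, above])
        best = run = 0
        i0 = best_i0 = 0
        for i, a in enumerate(ext):
            if a:
                if run == 0:
                    i0 = i
                run += 1
                if run > best:
                    best, best_i0 = run, i0
            else:
                run = 0
        best = min(best, n)
        # great-circle span between the outermost samples of the run;
        # a single sample counts as one angular bin
        idx = (best_i0 + np.arange(best)) % n
        a0, a1 = ang[idx[0]], ang[idx[-1]]
        span = (a1 - a0) % (2 * np.pi)
        size = float(max(np.rad2deg(span), 360.0 / n))
        size = min(size, 360.0)
    w = inten[above]
    vx = float(np.sum(w * np.cos(ang[above])))
    vy = float(np.sum(w * np.sin(ang[above])))
    norm = np.hypot(vx, vy)
    if norm < 1e-9 * w.sum():
        return CapGeometry(None, size, frac)
    return CapGeometry(np.array([vx, vy]) / norm, size, frac)


def division_angle(cap: CapGeometry, div: DivisionGeometry) -> float:
    """Angle (degrees, in [0, 90]) between the cap direction and the
    division plane; 90 means the cap is aligned with the spindle axis.

    NaN when the cap direction is undefined.  Invariant to sign flips of
    either vector and to rigid rotations applied to both.
    """
    if cap.direction is None:
        return float("nan")
    d = np.asarray(cap.direction, dtype=float)
    axis = div.spindle_axis
    if d.size < axis.size:
        d = np.concatenate([d, np.zeros(axis.size - d.size)])
    elif axis.size < d.size:
        axis = np.concatenate([axis, np.zeros(d.size - axis.size)])
    cosang = abs(float(np.dot(d, axis)) / np.linalg.norm(d))
    cosang = min(cosang, 1.0)
    theta_to_normal = np.rad2deg(np.arccos(cosang))   # in [0, 90]
    return float(90.0 - theta_to_normal)


def angle_vs_reference(angles, reference: float = 45.0,
                       other=None, covariate=None) -> dict:
    """Test a sample of division angles against a reference angle.

    Runs a one-sample Wilcoxon signed-rank test of ``angles`` against
    ``reference`` (skipped below n = 5).  Optionally compares against a
    second condition by Mann-Whitney U, and reports the Spearman
    correlation of angle with a per-cell covariate (e.g. cap size).
    Returns a dict of summary statistics.
    """
    a = np.asarray(angles, dtype=float)
    a = a[np.isfinite(a)]
    out = {"n": int(len(a)), "median": float(np.median(a)) if len(a) else
           float("nan"), "reference": float(reference)}
    diffs = a - reference
    if len(a) < 5:
        out["p_wilcoxon"] = float("nan")
        out["note"] = "n < 5: signed-rank test skipped"
    elif np.all(diffs == 0):
        out["p_wilcoxon"] = 1.0
        out["note"] = "degenerate sample: all angles equal the reference"
    else:
        res = stats.wilcoxon(diffs[diffs != 0])
        out["p_wilcoxon"] = float(res.pvalue)
    if other is not None:
        b = np.asarray(other, dtype=float)
        b = b[np.isfinite(b)]
        out["p_mannwhitney"] = (float(stats.mannwhitneyu(
            a, b, alternative="two-sided").pvalue)
            if len(a) and len(b) else float("nan"))
    if covariate is not None:
        c = np.asarray(covariate, dtype=float)
        rho, p = stats.spearmanr(a, c)
        out["spearman_rho"] = float(rho)
        out["p_spearman"] = float(p)
    return out
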