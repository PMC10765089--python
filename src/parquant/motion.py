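"""3D particle linking, weighted MSD, and anomalous-diffusion fitting.

Cortical arrays are linked frame-to-frame by a minimum-total-squared-
displacement assignment with a per-link distance cap and optional gap
closing.  The ensemble mean-squared displacement is a weighted mean over
tracks, each track weighted at every delay by the number of displacement
pairs it contributes (more pairs, greater certainty).  The ensemble curve
is fitted to the subdiffusion model

    MSD(t) = 6 D t^alpha

with D the generalized diffusion coefficient (um^2/s^alpha) and alpha the
anomalous exponent; alpha significantly below 1 indicates confined
(subdiffusive) motion.  The 6 is the 3D isotropic prefactor, so the
default MSD includes all three displacement components; a lateral-only
2D mode is provided as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, linear_sum_assignment

__all__ = ["MSDCurve", "AnomalousFit", "link_tracks", "weighted_msd",
           "fit_anomalous"]

_BIG = 1e12


@dataclass
class MSDCurve:
    """Delay-indexed weighted ensemble MSD.

    ``weights`` counts the displacement pairs contributing at each delay
    (summed over tracks).
    """

    delays: np.ndarray      # s
    msd: np.ndarray         # um^2
    weights: np.ndarray     # pair counts
    n_tracks: int = 0

    def __post_init__(self):
        if np.any(np.asarray(self.msd) < 0):
            raise ValueError("MSD values must be non-negative")


@dataclass
class AnomalousFit:
    D: float                 # um^2 / s^alpha
    alpha: float
    r2: float
    D_ci: tuple[float, float]
    alpha_ci: tuple[float, float]
    n_tracks: int
    n_delays_fit: int

    @property
    def subdiffusive(self) -> bool:
        """True when alpha is significantly below 1 (95% CI)."""
        return self.alpha_ci[1] < 1.0


# ---------------------------------------------------------------------------
# linking

def link_tracks(particles: pd.DataFrame, max_disp: float,
                memory: int = 0, dt: float = 1.0) -> pd.DataFrame:
    """Link per-frame particles into 3D tracks.

    Frame-to-frame correspondence minimizes the total squared displacement
    over the maximum number of links whose individual displacement is at
    most ``max_disp``; unmatched particles start new tracks and tracks
    skipped for more than ``memory`` consecutive frames are terminated.
    Ties are broken deterministically by particle index order.

    Returns a DataFrame with columns ``track_id, frame, t, x, y, z``.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    cols = ["x_um", "y_um", "z_um"] if "x_um" in particles.columns else \
        ["x", "y", "z"]
    out_rows = []
    active: list[dict] = []      # {'id', 'pos', 'last_frame'}
    next_id = 0
    for f in sorted(particles["frame"].unique()):
        pts = particles.loc[particles["frame"] == f, cols]\
            .to_numpy(dtype=float)
        alive = [tr for tr in active if f - tr["last_frame"] - 1 <= memory]
        if alive and len(pts):
            cost = np.full((len(alive), len(pts)), _BIG)
            for i, tr in enumerate(alive):
                d2 = np.sum((pts - tr["pos"]) ** 2, axis=1)
                ok = d2 <= max_disp ** 2
                cost[i, ok] = d2[ok]
            ri, ci = linear_sum_assignment(cost)
            matched_p = set()
            for i, j in zip(ri, ci):
                if cost[i, j] < _BIG:
                    tr = alive[i]
                    tr["pos"] = pts[j]
                    tr["last_frame"] = f
                    out_rows.append((tr["id"], f, *pts[j]))
                    matched_p.add(j)
        else:
            matched_p = set()
        for j in range(len(pts)):
            if j not in matched_p:
                active.append({"id": next_id, "pos": pts[j], "last_frame": f})
                out_rows.append((next_id, f, *pts[j]))
                next_id += 1
        active = [tr for tr in active if f - tr["last_frame"] <= memory]
    df = pd.DataFrame(out_rows, columns=["track_id", "frame", "x", "y", "z"])
    df.insert(2, "t", df["frame"] * dt)
    return df.sort_values(["track_id", "frame"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# MSD

def _as_track_list(tracks) -> list[pd.DataFrame]:
    if isinstance(tracks, pd.DataFrame):
        return [g for _, g in tracks.groupby("track_id", sort=True)]
    return list(tracks)


def weighted_msd(tracks, mode: str = "3d") -> MSDCurve:
    """Weighted ensemble MSD over all overlapping segment pairs.

    Per track and delay k the MSD averages every displacement between
    samples k frames apart; the ensemble value is the across-track mean
    weighted by each track's pair count — identical to pooling all pairs.
    ``mode`` is ``"3d"`` (default; consistent with the 6 D t^alpha model)
    or ``"2d"`` (lateral x/y displacements only).
    """
    if mode not in ("2d", "3d"):
        raise ValueError("mode must be '2d' or '3d'")
    track_list = _as_track_list(tracks)
    track_list = [t for t in track_list if len(t) >= 2]
    if not track_list:
        raise ValueError("need at least one track with >= 2 samples")
    ncoord = 3 if mode == "3d" else 2
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    dt = None
    for tr in track_list:
        t = tr["t"].to_numpy(dtype=float)
        step = np.min(np.diff(t))
        dt = step if dt is None else min(dt, step)
    for tr in track_list:
        t = tr["t"].to_numpy(dtype=float)
        pos = tr[["x", "y", "z"][:ncoord]].to_numpy(dtype=float)
        fidx = np.round(t / dt).astype(int)
        n = len(t)
        gapless = bool(np.all(np.diff(fidx) == 1))
        if gapless:
            # all pairs at delay k are pos[k:] - pos[:-k]
            for k in range(1, n):
                d2 = np.sum((pos[k:] - pos[:-k]) ** 2, axis=1)
                sums[k] = sums.get(k, 0.0) + float(d2.sum())
                counts[k] = counts.get(k, 0) + len(d2)
        else:
            for i in range(n - 1):
                d2 = np.sum((pos[i + 1:] - pos[i]) ** 2, axis=1)
                for kk, v in zip(fidx[i + 1:] - fidx[i], d2):
                    kk = int(kk)
                    sums[kk] = sums.get(kk, 0.0) + float(v)
                    counts[kk] = counts.get(kk, 0) + 1
    ks = np.array(sorted(sums))
    msd = np.array([sums[k] / counts[k] for k in ks])
    w = np.array([counts[k] for k in ks])
    return MSDCurve(ks * dt, msd, w, n_tracks=len(track_list))


# ---------------------------------------------------------------------------
# fitting

def fit_anomalous(curve: MSDCurve, fit_fraction: float = 0.25,
                  method: str = "loglog") -> AnomalousFit:
    """Fit MSD(t) = 6 D t^alpha to the short-delay part of the curve.

    Only the first ``fit_fraction`` of available delays enters the fit
    (long delays carry few pairs and high variance).  The default is a
    weighted least-squares line in log-log space (exact for a noiseless
    power law); ``method="nonlinear"`` fits the power law directly.
    Weights are the pair counts of the curve.
    """
    import statsmodels.api as sm

    n_fit = max(4, int(np.ceil(fit_fraction * len(curve.delays))))
    if len(curve.delays) < 4:
        raise ValueError("need >= 4 delay points")
    t = np.asarray(curve.delays[:n_fit], dtype=float)
    y = np.asarray(curve.msd[:n_fit], dtype=float)
    w = np.asarray(curve.weights[:n_fit], dtype=float)
    ok = (y > 0) & (t > 0)
    if not ok.all():
        import warnings
        warnings.warn(f"dropping {int((~ok).sum())} non-positive MSD value(s)")
    t, y, w = t[ok], y[ok], w[ok]
    if len(t) < 4:
        raise ValueError("fewer than 4 usable delay points in fit range")

    if method == "loglog":
        X = sm.add_constant(np.log(t))
        res = sm.WLS(np.log(y), X, weights=w).fit()
        intercept, alpha = res.params
        ci = res.conf_int(alpha=0.05)
        D = float(np.exp(intercept) / 6.0)
        D_ci = (float(np.exp(ci[0, 0]) / 6.0), float(np.exp(ci[0, 1]) / 6.0))
        a_ci = (float(ci[1, 0]), float(ci[1, 1]))
        return AnomalousFit(D, float(alpha), float(res.rsquared),
                            D_ci, a_ci, curve.n_tracks, len(t))
    elif method == "nonlinear":
        p, cov = curve_fit(lambda tt, D, a: 6.0 * D * tt ** a, t, y,
                           p0=[max(y[0] / (6 * t[0]), 1e-6), 1.0],
                           sigma=1.0 / np.sqrt(w), absolute_sigma=False,
                           maxfev=10000)
        D, alpha = p
        se = np.sqrt(np.diag(cov))
        from scipy import stats as sps
        tcrit = sps.t.ppf(0.975, max(len(t) - 2, 1))
        pred = 6.0 * D * t ** alpha
        ss_res = float(np.sum(w * (y - pred) ** 2))
        ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        return AnomalousFit(float(D), float(alpha), r2,
                            (float(D - tcrit * se[0]), float(D + tcrit * se[0])),
                            (float(alpha - tcrit * se[1]),
                             float(alpha + tcrit * se[1])),
                            curve.n_tracks, len(t))
    raise ValueError("method must be 'loglog' or 'nonlinear'")
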