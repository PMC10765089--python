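"""Tracking, weighted MSD and anomalous-fit tests with brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from parquant import synthgen as sg
from parquant.motion import (MSDCurve, fit_anomalous, link_tracks,
                             weighted_msd)


def brute_force_link(frame_a, frame_b, max_disp):
    """Exhaustive assignment: maximize feasible links, then minimize total
    squared displacement, tie-break by lexicographic pair order."""
    na, nb = len(frame_a), len(frame_b)
    best = (0, 0.0, ())
    found = False
    for k in range(min(na, nb), -1, -1):
        cands = []
        for rows in itertools.combinations(range(na), k):
            for cols in itertools.permutations(range(nb), k):
                cost = 0.0
                ok = True
                for i, j in zip(rows, cols):
                    d2 = np.sum((frame_a[i] - frame_b[j]) ** 2)
                    if d2 > max_disp ** 2:
                        ok = False
                        break
                    cost += d2
                if ok:
                    cands.append((cost, tuple(zip(rows, cols))))
        if cands:
            cands.sort()
            best = (k, *cands[0])
            found = True
            break
    return set(best[2]) if found else set()


class TestLinking:
    def test_static_particle_single_track(self):
        p = pd.DataFrame({"frame": range(10), "x": 1.0, "y": 2.0, "z": 3.0})
        out = link_tracks(p, max_disp=0.5)
        assert out["track_id"].nunique() == 1
        assert len(out) == 10

    def test_distant_particles_never_swapped(self):
        rows = []
        for f in range(8):
            rows.append((f, 0.0 + 0.01 * f, 0.0, 0.0))
            rows.append((f, 5.0 - 0.01 * f, 0.0, 0.0))
        p = pd.DataFrame(rows, columns=["frame", "x", "y", "z"])
        out = link_tracks(p, max_disp=0.5)
        assert out["track_id"].nunique() == 2
        for _, g in out.groupby("track_id"):
            assert g["x"].max() - g["x"].min() < 1.0

    def test_track_broken_when_jump_exceeds_cap(self):
        p = pd.DataFrame({"frame": [0, 1, 2], "x": [0.0, 0.1, 5.0],
                          "y": 0.0, "z": 0.0})
        out = link_tracks(p, max_disp=0.5)
        assert out["track_id"].nunique() == 2

    def test_gap_bridged_with_memory(self):
        p = pd.DataFrame({"frame": [0, 1, 3, 4], "x": [0.0, 0.1, 0.2, 0.3],
                          "y": 0.0, "z": 0.0})
        assert link_tracks(p, 0.5, memory=1)["track_id"].nunique() == 1
        assert link_tracks(p, 0.5, memory=0)["track_id"].nunique() == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_assignment(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 6, 2)
        a = rng.uniform(0, 2, (na, 3))
        b = rng.uniform(0, 2, (nb, 3))
        max_disp = 1.0
        rows = [(0, *p) for p in a] + [(1, *p) for p in b]
        df = pd.DataFrame(rows, columns=["frame", "x", "y", "z"])
        out = link_tracks(df, max_disp)
        got = set()
        for _, g in out.groupby("track_id"):
            if len(g) == 2:
                ai = int(np.argmin(np.linalg.norm(
                    a - g.iloc[0][["x", "y", "z"]].to_numpy(dtype=float),
                    axis=1)))
                bi = int(np.argmin(np.linalg.norm(
                    b - g.iloc[1][["x", "y", "z"]].to_numpy(dtype=float),
                    axis=1)))
                got.add((ai, bi))
        oracle = brute_force_link(a, b, max_disp)
        # the solver must achieve the oracle's cardinality and total cost
        assert len(got) == len(oracle)
        cost = sum(np.sum((a[i] - b[j]) ** 2) for i, j in got)
        ocost = sum(np.sum((a[i] - b[j]) ** 2) for i, j in oracle)
        assert cost == pytest.approx(ocost, abs=1e-9)


def brute_force_msd(tracks, ncoord=3):
    sums, counts = {}, {}
    for tr in tracks:
        pos = tr[["x", "y", "z"][:ncoord]].to_numpy(dtype=float)
        t = tr["t"].to_numpy(dtype=float)
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                k = round((t[j] - t[i]) / (t[1] - t[0]))
                d2 = float(np.sum((pos[j] - pos[i]) ** 2))
                sums[k] = sums.get(k, 0.0) + d2
                counts[k] = counts.get(k, 0) + 1
    ks = sorted(sums)
    return (np.array([k * (tracks[0]["t"].iloc[1] - tracks[0]["t"].iloc[0])
                      for k in ks]),
            np.array([sums[k] / counts[k] for k in ks]),
            np.array([counts[k] for k in ks]))


class TestWeightedMSD:
    def test_static_track_zero(self):
        tr = pd.DataFrame({"t": np.arange(5.0), "x": 1.0, "y": 1.0, "z": 1.0})
        curve = weighted_msd([tr])
        assert np.allclose(curve.msd, 0.0)

    def test_ballistic_track_quadratic(self):
        v = 0.3
        t = np.arange(10.0)
        tr = pd.DataFrame({"t": t, "x": v * t, "y": 0.0, "z": 0.0})
        curve = weighted_msd([tr])
        assert np.allclose(curve.msd, v ** 2 * curve.delays ** 2, rtol=1e-12)

    def test_weights_and_ensemble_mean(self):
        t1 = pd.DataFrame({"t": np.arange(11.0), "x": np.arange(11.0),
                           "y": 0.0, "z": 0.0})
        t2 = pd.DataFrame({"t": np.arange(3.0), "x": 0.0, "y": 0.0, "z": 0.0})
        curve = weighted_msd([t1, t2])
        # delay 1: 10 pairs from the long track (msd 1), 2 from the short
        assert curve.weights[0] == 12
        assert curve.msd[0] == pytest.approx((10 * 1.0 + 2 * 0.0) / 12)

    def test_matches_all_pairs_oracle(self, rng):
        tracks = []
        for _ in range(5):
            n = rng.integers(3, 10)
            tracks.append(pd.DataFrame({
                "t": np.arange(n, dtype=float),
                "x": rng.normal(0, 1, n), "y": rng.normal(0, 1, n),
                "z": rng.normal(0, 1, n)}))
        curve = weighted_msd(tracks)
        od, om, ow = brute_force_msd(tracks)
        assert np.allclose(curve.delays, od)
        assert np.allclose(curve.msd, om)
        assert np.array_equal(curve.weights, ow)

    def test_2d_mode_excludes_z(self):
        t = np.arange(6.0)
        tr = pd.DataFrame({"t": t, "x": 0.0, "y": 0.0, "z": t})
        assert np.allclose(weighted_msd([tr], mode="2d").msd, 0.0)
        assert weighted_msd([tr], mode="3d").msd[0] > 0


class TestFitAnomalous:
    def _noiseless_curve(self, D=0.007, alpha=0.65, n=20):
        t = np.arange(1, n + 1) * 0.5
        return MSDCurve(t, 6 * D * t ** alpha, np.ones(n))

    def test_roundtrip_machine_precision(self):
        fit = fit_anomalous(self._noiseless_curve(), fit_fraction=1.0)
        assert fit.D == pytest.approx(0.007, rel=1e-6)
        assert fit.alpha == pytest.approx(0.65, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0)

    def test_brownian_curve_alpha_one(self):
        fit = fit_anomalous(self._noiseless_curve(alpha=1.0))
        assert fit.alpha == pytest.approx(1.0, rel=1e-9)

    def test_nonlinear_agrees_on_noiseless(self):
        fit = fit_anomalous(self._noiseless_curve(), fit_fraction=1.0,
                            method="nonlinear")
        assert fit.D == pytest.approx(0.007, rel=1e-5)
        assert fit.alpha == pytest.approx(0.65, rel=1e-5)

    def test_scaling_property(self):
        c = self._noiseless_curve()
        s = 2.0
        scaled = MSDCurve(c.delays, c.msd * s ** 2, c.weights)
        f1 = fit_anomalous(c)
        f2 = fit_anomalous(scaled)
        assert f2.alpha == pytest.approx(f1.alpha, rel=1e-9)
        assert f2.D == pytest.approx(f1.D * s ** 2, rel=1e-9)

    def test_too_few_points_rejected(self):
        t = np.arange(1, 4.0)
        with pytest.raises(ValueError):
            fit_anomalous(MSDCurve(t, t, np.ones(3)))

    def test_subdiffusive_flag(self):
        # ensemble simulation at the array-motion preset: alpha CI below 1
        tracks = sg.make_tracks(sg.TrackSimConfig.cortical_array_preset(seed=4))
        fit = fit_anomalous(weighted_msd(tracks))
        assert fit.subdiffusive
        assert fit.alpha == pytest.approx(0.65, abs=0.08)


class TestEndToEndTracking:
    def test_link_then_msd_recovers_alpha(self):
        # simulate, scatter into per-frame particle rows, re-link, fit
        cfg = sg.TrackSimConfig(n_tracks=30, n_steps=60, dt=0.5, D=0.007,
                                alpha=0.65, loc_error_sd=0.01, seed=11)
        tracks = sg.make_tracks(cfg)
        rows = []
        for k, tr in enumerate(tracks):
            # spread tracks far apart so identities are unambiguous
            off = np.array([10.0 * k, 0.0, 0.0])
            for f, (_, r) in enumerate(tr.iterrows()):
                rows.append((f, r["x"] + off[0], r["y"], r["z"]))
        df = pd.DataFrame(rows, columns=["frame", "x", "y", "z"])
        linked = link_tracks(df, max_disp=1.0, dt=0.5)
        assert linked["track_id"].nunique() == 30
        fit = fit_anomalous(weighted_msd(linked))
        assert fit.alpha == pytest.approx(0.65, abs=0.15)
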