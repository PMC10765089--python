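"""Spindle asymmetry tests: projection, linescan, peaks, Δ properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parquant import synthgen as sg
from parquant.spindle import (LineProfile, SpindleROI, average_profiles,
                              delta, find_spindle_peaks, project_stack,
                              pseudo_linescan, summarize_deltas)
from parquant.stack import ImageStack


def _centre_roi(img, width=3.0, length=10.0):
    p = img.voxel_size[-1]
    ny, nx = img.data.shape
    return SpindleROI(((nx - 1) * p / 2, (ny - 1) * p / 2), 0.0, length, width)


class TestProjectStack:
    def test_single_plane_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        st_ = ImageStack(img[None], (0.2, 0.1, 0.1), "ZYX")
        with pytest.warns(UserWarning):
            out = project_stack(st_, depth=6.0)
        assert np.allclose(out.data, img)

    def test_disjoint_bright_pixels_union(self):
        a = np.zeros((4, 4)); a[0, 0] = 9
        b = np.zeros((4, 4)); b[3, 3] = 7
        st_ = ImageStack(np.stack([a, b]), (0.2, 0.1, 0.1), "ZYX")
        with pytest.warns(UserWarning):
            out = project_stack(st_, depth=6.0)
        assert out.data[0, 0] == 9 and out.data[3, 3] == 7

    def test_projection_matches_analytic_max(self):
        # 3D Gaussian phantom: max over z equals the z=z0 plane
        zz, yy, xx = np.mgrid[0:31, 0:20, 0:20].astype(float)
        vol = np.exp(-(zz - 15) ** 2 / 18 - (yy - 10) ** 2 / 8
                     - (xx - 10) ** 2 / 8)
        st_ = ImageStack(vol, (0.2, 0.1, 0.1), "ZYX")
        out = project_stack(st_, depth=6.0)
        assert np.allclose(out.data, vol[15], atol=1e-12)


class TestPseudoLinescan:
    def test_uniform_image_flat_profile(self):
        img = ImageStack(np.full((64, 128), 3.0), (0.1, 0.1, 0.1), "YX")
        roi = _centre_roi(img, width=2.0)
        prof = pseudo_linescan(img, roi)
        assert np.allclose(prof.intensity, prof.n_pixels_y * 3.0)

    def test_symmetric_phantom_two_equal_maxima(self):
        img, _ = sg.make_spindle_image(sg.SpindleConfig(delta_true=0.0))
        prof = pseudo_linescan(img, _centre_roi(img))
        score = find_spindle_peaks(prof)
        assert score.peak_anterior == pytest.approx(score.peak_posterior,
                                                    rel=1e-6)
        assert score.delta == pytest.approx(0.0, abs=1e-6)

    def test_rotated_roi_matches_rotated_phantom(self):
        cfg = sg.SpindleConfig(image_shape=(128, 128), delta_true=0.3)
        img, _ = sg.make_spindle_image(cfg)
        # same phantom transposed = spindle axis vertical
        img_t = ImageStack(img.data.T.copy(), img.voxel_size, "YX")
        roi_h = _centre_roi(img)
        p = img.voxel_size[-1]
        roi_v = SpindleROI(roi_h.centre, 90.0, roi_h.length, roi_h.width)
        prof_h = pseudo_linescan(img, roi_h)
        prof_v = pseudo_linescan(img_t, roi_v)
        assert np.allclose(prof_h.intensity, prof_v.intensity, rtol=1e-6)

    def test_degenerate_roi_rejected(self):
        img = ImageStack(np.zeros((32, 32)), (0.1, 0.1, 0.1), "YX")
        with pytest.raises(ValueError):
            pseudo_linescan(img, SpindleROI((1.6, 1.6), 0, 2.0, 0.01))


class TestFindPeaks:
    def _profile(self, values, pad_value=20.0):
        x = np.arange(len(values)) * 0.1
        x -= x.mean()
        return LineProfile(x, np.asarray(values, dtype=float), 1,
                           bg_left=np.full(5, pad_value),
                           bg_right=np.full(5, pad_value))

    def test_background_subtraction(self):
        vals = [30, 300, 50, 100, 30]       # peaks 300 and 100, valley 50
        score = find_spindle_peaks(self._profile(vals, 20.0))
        assert score.peak_anterior == pytest.approx(280.0)
        assert score.peak_posterior == pytest.approx(80.0)

    def test_anterior_label_swap_flips_delta(self):
        vals = [30, 300, 50, 100, 30]
        s1 = find_spindle_peaks(self._profile(vals), anterior="left")
        s2 = find_spindle_peaks(self._profile(vals), anterior="right")
        assert s1.delta == pytest.approx(-s2.delta)

    def test_monotone_profile_errors(self):
        with pytest.raises(ValueError, match="morphology"):
            find_spindle_peaks(self._profile([1, 2, 3, 4, 5]))

    def test_noiseless_phantom_recovers_three_to_one_ratio(self):
        img, _ = sg.make_spindle_image(
            sg.SpindleConfig(delta_true=0.5, noise_sd=0.0))
        score = find_spindle_peaks(pseudo_linescan(img, _centre_roi(img)))
        assert score.peak_anterior / score.peak_posterior == pytest.approx(
            3.0, rel=1e-3)
        assert score.delta == pytest.approx(0.5, abs=1e-4)


class TestDelta:
    def test_examples(self):
        assert delta(1.0, 1.0) == 0.0
        assert delta(3.0, 1.0) == pytest.approx(0.5)
        assert delta(1.0, 0.0) == 1.0

    def test_both_zero_missing(self):
        assert np.isnan(delta(0.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            delta(-1.0, 1.0)

    @given(a=st.floats(0, 1e6), p=st.floats(0, 1e6))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_bounds_and_antisymmetry(self, a, p):
        if a + p == 0:
            return
        d = delta(a, p)
        assert -1.0 <= d <= 1.0
        assert delta(p, a) == pytest.approx(-d, abs=1e-12)

    def test_scale_invariance(self):
        img, _ = sg.make_spindle_image(
            sg.SpindleConfig(delta_true=0.3, noise_sd=0.0))
        s1 = find_spindle_peaks(pseudo_linescan(img, _centre_roi(img)))
        img2 = ImageStack(img.data * 7.0, img.voxel_size, "YX")
        s2 = find_spindle_peaks(pseudo_linescan(img2, _centre_roi(img2)))
        assert s1.delta == pytest.approx(s2.delta, abs=1e-9)


class TestRecovery:
    def test_noiseless_recovery_machine_precision(self):
        for dt in (-0.6, -0.2, 0.0, 0.4, 0.8):
            img, _ = sg.make_spindle_image(
                sg.SpindleConfig(delta_true=dt, noise_sd=0.0, background=0.0))
            score = find_spindle_peaks(pseudo_linescan(img, _centre_roi(img)))
            assert score.delta == pytest.approx(dt, abs=1e-6)

    def test_noisy_recovery_bias_and_sd(self):
        # noise at 5% of peak amplitude: bias <= 0.02, SD <= 0.05 (100 seeds)
        errs = []
        for seed in range(100):
            cfg = sg.SpindleConfig(delta_true=0.3, noise_sd=50.0, seed=seed)
            img, _ = sg.make_spindle_image(cfg)
            score = find_spindle_peaks(pseudo_linescan(img, _centre_roi(img)))
            errs.append(score.delta - 0.3)
        errs = np.array(errs)
        assert abs(errs.mean()) <= 0.02
        assert errs.std() <= 0.05


class TestAveraging:
    def test_identical_profiles_zero_sem(self):
        img, _ = sg.make_spindle_image(sg.SpindleConfig(delta_true=0.2))
        prof = pseudo_linescan(img, _centre_roi(img))
        out = average_profiles([prof, prof, prof])
        assert np.allclose(out["sem"], 0.0)
        assert (out["n"] == 3).all()

    def test_single_profile_passthrough(self):
        img, _ = sg.make_spindle_image(sg.SpindleConfig(delta_true=0.2))
        prof = pseudo_linescan(img, _centre_roi(img))
        out = average_profiles([prof])
        assert (out["n"] == 1).all()
        assert np.allclose(out["sem"], 0.0)
        assert out["mean"].max() == pytest.approx(prof.intensity.max(),
                                                  rel=1e-6)

    def test_delta_group_stats(self):
        df = pd.DataFrame({
            "group": ["a", "a", "b", "b"],
            "peak_ant": [6.0, 7.0, 5.0, 5.5],
            "peak_post": [4.0, 3.5, 5.0, 4.5],
            "delta": [0.2, 0.4, 0.0, 0.1]})
        out = summarize_deltas(df, reference="b")
        row_a = out[out["group"] == "a"].iloc[0]
        assert row_a["mean_delta"] == pytest.approx(0.3)
        assert row_a["sem"] == pytest.approx(0.1, rel=1e-6)
        assert np.isfinite(row_a["p_paired_peaks"])
        assert np.isfinite(row_a["p_vs_reference"])
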