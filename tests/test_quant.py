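"""Unit and property tests for ROI traces and the normalization chain."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import frapkit as fk
from frapkit.quant import DiscRoi, PolygonRoi, RoiSet, _smooth

from conftest import make_curve, random_traces, small_noisy_config


# ---------------------------------------------------------------------------
# ROIs and trace extraction
# ---------------------------------------------------------------------------


def _uniform_series(value=100.0, shape=(40, 40), n=8, n_pre=3):
    frames = np.full((n,) + shape, float(value), dtype=np.float32)
    return fk.ImageSeries(frames=frames, pixel_size=0.1, frame_interval=0.2,
                          bleach_frame_index=n_pre)


def _simple_rois():
    return RoiSet(
        bleach_disc=DiscRoi(center=(2.0, 2.0), radius=0.6),
        reference_region=DiscRoi(center=(3.3, 2.0), radius=0.5),
        background_region=PolygonRoi(
            vertices=((0.0, 0.0), (0.9, 0.0), (0.9, 0.9), (0.0, 0.9))),
    )


class TestRois:
    def test_disc_pixel_count_at_paper_scale(self):
        # 2.5 um disc at 22.49/256 um/px covers ~pi r^2 = 2544 pixel centres
        mask = DiscRoi(center=(11.2, 11.2), radius=2.5).rasterize(
            (256, 256), 22.49 / 256)
        assert 2400 <= mask.sum() <= 2650

    def test_polygon_rasterization_area(self):
        # unit square at 0.1 um/px contains ~100 pixel centres
        poly = PolygonRoi(vertices=((0.05, 0.05), (1.05, 0.05),
                                    (1.05, 1.05), (0.05, 1.05)))
        assert poly.rasterize((40, 40), 0.1).sum() == pytest.approx(100, abs=15)

    def test_overlapping_rois_rejected(self):
        rois = RoiSet(bleach_disc=DiscRoi(center=(2.0, 2.0), radius=0.6),
                      reference_region=DiscRoi(center=(2.2, 2.0), radius=0.5),
                      background_region=DiscRoi(center=(0.5, 0.5), radius=0.4))
        with pytest.raises(ValueError, match="overlap"):
            rois.masks((40, 40), 0.1)

    def test_tiny_roi_rejected(self):
        rois = RoiSet(bleach_disc=DiscRoi(center=(2.0, 2.0), radius=0.05),
                      reference_region=DiscRoi(center=(3.3, 2.0), radius=0.5),
                      background_region=DiscRoi(center=(0.5, 0.5), radius=0.4))
        with pytest.raises(ValueError, match="pixels"):
            rois.masks((40, 40), 0.1)

    def test_roundtrip_dict(self):
        rois = _simple_rois()
        assert RoiSet.from_dict(rois.to_dict()) == rois


class TestExtractTraces:
    def test_uniform_frame_gives_constant_trace(self):
        curve = fk.extract_traces(_uniform_series(100.0), _simple_rois())
        assert np.allclose(curve.I, 100.0)
        assert np.allclose(curve.I_r, 100.0)
        assert np.allclose(curve.I_b, 100.0)

    def test_times_zero_at_bleach(self):
        curve = fk.extract_traces(_uniform_series(), _simple_rois())
        assert curve.t[curve.bleach_index] == 0.0
        assert curve.t[0] == pytest.approx(-3 * 0.2)

    def test_reference_decays_under_monitor_bleaching(self):
        slopes = []
        for seed in range(5):
            cfg = small_noisy_config(seed=seed)
            series, _ = fk.simulate_frap(cfg)
            curve = fk.extract_traces(series, fk.default_roiset(cfg))
            slopes.append(np.polyfit(curve.t, curve.I_r, 1)[0])
        assert all(s < 0 for s in slopes)


# ---------------------------------------------------------------------------
# the correction / normalization chain
# ---------------------------------------------------------------------------


class TestCorrectPhotobleach:
    def test_identity_when_reference_constant_and_no_background(self):
        rng = np.random.default_rng(0)
        curve = make_curve(rng)
        curve = dataclasses.replace(curve, I_b=np.zeros(curve.n_frames),
                                    I_r=np.full(curve.n_frames, 80.0))
        out = fk.correct_photobleach(curve)
        np.testing.assert_allclose(out.I_c, curve.I, rtol=1e-12)

    def test_direct_substitution(self):
        # frame with I=100, I_b=10, I_r=55 and pre-bleach mean(I_r-I_b)=90
        n, n_pre = 6, 3
        i = np.array([95.0, 95.0, 95.0, 100.0, 100.0, 100.0])
        i_b = np.full(n, 10.0)
        i_r = np.array([100.0, 100.0, 100.0, 55.0, 55.0, 55.0])
        curve = fk.RecoveryCurve(t=np.arange(n, dtype=float), I=i, I_b=i_b,
                                 I_r=i_r, n_prebleach=n_pre, bleach_index=n_pre)
        out = fk.correct_photobleach(curve)
        assert out.I_c[3] == pytest.approx((100 - 10) * 90.0 / 45.0)  # = 180
        assert out.I_c[3] == pytest.approx(180.0)

    def test_background_equals_signal_gives_zero(self):
        rng = np.random.default_rng(1)
        curve = make_curve(rng)
        curve = dataclasses.replace(curve, I=curve.I_b.copy())
        out = fk.correct_photobleach(curve)
        np.testing.assert_allclose(out.I_c, 0.0, atol=1e-12)

    def test_nonpositive_reference_rejected_with_frame(self):
        rng = np.random.default_rng(2)
        curve = make_curve(rng)
        i_r = curve.I_r.copy()
        i_r[7] = curve.I_b[7] - 1.0
        with pytest.raises(ValueError, match="frame 7"):
            fk.correct_photobleach(dataclasses.replace(curve, I_r=i_r))


class TestNormalizePrebleach:
    def test_constant_becomes_one(self):
        rng = np.random.default_rng(3)
        curve = make_curve(rng)
        curve = dataclasses.replace(curve, I_c=np.full(curve.n_frames, 42.0))
        out = fk.normalize_prebleach(curve)
        np.testing.assert_allclose(out.I_cn, 1.0)

    def test_half_of_prebleach_mean(self):
        n, n_pre = 8, 4
        i_c = np.array([90.0] * 4 + [45.0] * 4)
        curve = fk.RecoveryCurve(t=np.arange(n, dtype=float), I=i_c,
                                 I_b=np.zeros(n), I_r=np.ones(n),
                                 n_prebleach=n_pre, bleach_index=n_pre, I_c=i_c)
        out = fk.normalize_prebleach(curve)
        assert out.I_cn[5] == pytest.approx(0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        curve = make_curve(rng)
        curve = fk.correct_photobleach(curve)
        a = fk.normalize_prebleach(curve)
        b = fk.normalize_prebleach(
            dataclasses.replace(curve, I_c=2.0 * curve.I_c))
        np.testing.assert_allclose(a.I_cn, b.I_cn, rtol=1e-12)

    def test_requires_correction_first(self):
        with pytest.raises(ValueError, match="correct_photobleach"):
            fk.normalize_prebleach(make_curve(np.random.default_rng(5)))


class TestRenormalizePostbleach:
    def _with_icn(self, i_cn, n_pre=2):
        n = len(i_cn)
        return fk.RecoveryCurve(t=np.arange(n, dtype=float),
                                I=np.ones(n), I_b=np.zeros(n), I_r=np.ones(n),
                                n_prebleach=n_pre, bleach_index=n_pre,
                                I_c=np.asarray(i_cn, dtype=float),
                                I_cn=np.asarray(i_cn, dtype=float))

    def test_arithmetic(self):
        out = fk.renormalize_postbleach(self._with_icn([1.0, 1.0, 0.2, 0.6]))
        assert out.I_dcn[3] == pytest.approx(0.5)
        assert out.I_dcn[2] == 0.0

    def test_constant_immobile_curve_is_zero(self):
        out = fk.renormalize_postbleach(self._with_icn([1.0, 1.0, 0.2, 0.2, 0.2]))
        np.testing.assert_allclose(out.I_dcn[2:], 0.0, atol=1e-12)

    def test_full_recovery_maps_to_one(self):
        out = fk.renormalize_postbleach(self._with_icn([1.0, 1.0, 0.2, 1.0]))
        assert out.I_dcn[3] == pytest.approx(1.0)

    def test_no_bleach_rejected(self):
        with pytest.raises(ValueError, match="no bleach"):
            fk.renormalize_postbleach(self._with_icn([1.0, 1.0, 1.1, 1.2]))


@settings(max_examples=50, deadline=None)
@given(n=st.integers(10, 60), n_pre=st.integers(1, 6),
       seed=st.integers(0, 2 ** 31))
def test_normalization_identities_property(n, n_pre, seed):
    """Pre-bleach mean of I_cn is 1 and I_dcn at the bleach frame is 0."""
    rng = np.random.default_rng(seed)
    i, i_b, i_r = random_traces(rng, n, n_pre)
    t = (np.arange(n) - n_pre) * 0.2
    curve = fk.RecoveryCurve(t=t, I=i, I_b=i_b, I_r=i_r,
                             n_prebleach=n_pre, bleach_index=n_pre)
    curve = fk.normalize_prebleach(fk.correct_photobleach(curve))
    assert curve.I_cn[:n_pre].mean() == pytest.approx(1.0, abs=1e-9)
    curve = fk.renormalize_postbleach(curve)
    assert curve.I_dcn[curve.bleach_index] == 0.0


def test_reduced_chain_matches_closed_form():
    """Constant reference + zero background collapses the chain to
    (I/m - I[b]/m) / (1 - I[b]/m) with m the pre-bleach mean of I."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        n, n_pre = 30, 4
        i = rng.uniform(10.0, 100.0, n)
        i[n_pre] = rng.uniform(0.5, 5.0)
        curve = fk.RecoveryCurve(t=(np.arange(n) - n_pre) * 0.1, I=i,
                                 I_b=np.zeros(n), I_r=np.full(n, 70.0),
                                 n_prebleach=n_pre, bleach_index=n_pre)
        out = fk.renormalize_postbleach(
            fk.normalize_prebleach(fk.correct_photobleach(curve)))
        m = i[:n_pre].mean()
        expected = (i / m - i[n_pre] / m) / (1.0 - i[n_pre] / m)
        np.testing.assert_allclose(out.I_dcn, expected, rtol=1e-12)


# ---------------------------------------------------------------------------
# final level and half-recovery time
# ---------------------------------------------------------------------------


def _curve_from_idcn(i_dcn, n_pre=3, dt=0.2):
    n = len(i_dcn)
    i_dcn = np.asarray(i_dcn, dtype=float)
    return fk.RecoveryCurve(t=(np.arange(n) - n_pre) * dt,
                            I=np.ones(n), I_b=np.zeros(n), I_r=np.ones(n),
                            n_prebleach=n_pre, bleach_index=n_pre,
                            I_c=np.ones(n), I_cn=np.ones(n), I_dcn=i_dcn)


class TestFinalRecovery:
    def test_immobile_curve_gives_zero(self):
        curve = _curve_from_idcn([1, 1, 1] + [0.0] * 30)
        assert fk.final_recovery(curve) == 0.0

    def test_saturating_exponential_tail(self):
        # half level 0.5, tau = 1 s << 400 s of sampling
        t = np.arange(2000) * 0.2
        i_dcn = np.concatenate([[1, 1, 1], 0.5 * (1 - np.exp(-t / 1.0))])
        curve = _curve_from_idcn(i_dcn)
        assert fk.final_recovery(curve, 10) == pytest.approx(0.5, abs=1e-3)

    def test_single_frame_is_last_measurement(self):
        i_dcn = np.array([1, 1, 1, 0.0, 0.3, 0.7])
        curve = _curve_from_idcn(i_dcn)
        assert fk.final_recovery(curve, 1) == pytest.approx(0.7)

    def test_tail_longer_than_postbleach_rejected(self):
        curve = _curve_from_idcn([1, 1, 1, 0.0, 0.5])
        with pytest.raises(ValueError, match="tail_frames"):
            fk.final_recovery(curve, 3)


class TestHalfRecoveryTime:
    def test_exponential_half_rise(self):
        dt = 195.6 / 994
        tau = 20.0
        t = np.arange(994) * dt
        i_f = 0.8
        i_dcn = np.concatenate([np.ones(6), i_f * (1 - np.exp(-t / tau))])
        curve = _curve_from_idcn(i_dcn, n_pre=6, dt=dt)
        # half level here is half of the *measured* tail mean, itself ~ i_f
        level = fk.final_recovery(curve, 10)
        _, _, tau_half = fk.half_recovery_time(curve, level)
        assert abs(tau_half - tau * np.log(2)) <= dt + tau * 0.01

    def test_step_gives_zero(self):
        curve = _curve_from_idcn([1, 1, 1] + [0.8] * 40)
        tau_a, tau_b, tau_half = fk.half_recovery_time(curve, 0.8)
        assert (tau_a, tau_b, tau_half) == (0.0, 0.0, 0.0)

    def test_tau_ordering(self):
        rng = np.random.default_rng(6)
        t = np.arange(300) * 0.2
        i_dcn = np.concatenate([np.ones(3),
                                0.7 * (1 - np.exp(-t / 8)) + rng.normal(0, 0.01, 300)])
        curve = _curve_from_idcn(i_dcn)
        level = fk.final_recovery(curve)
        tau_a, tau_b, tau_half = fk.half_recovery_time(curve, level)
        assert tau_a <= tau_half <= tau_b

    def test_nonrecovering_curve_reports_nan(self):
        curve = _curve_from_idcn([1, 1, 1] + [0.0] * 30)
        tau_a, tau_b, tau_half = fk.half_recovery_time(curve, final_level=-0.01)
        assert np.isnan(tau_half) and np.isnan(tau_a) and np.isnan(tau_b)

    def test_literal_rule_on_clean_curve(self):
        t = np.arange(400) * 0.2
        i_dcn = np.concatenate([np.ones(3), 0.6 * (1 - np.exp(-t / 5))])
        curve = _curve_from_idcn(i_dcn)
        _, _, tau_interp = fk.half_recovery_time(curve, 0.6)
        _, _, tau_lit = fk.half_recovery_time(curve, 0.6, method="literal")
        assert tau_lit == pytest.approx(tau_interp, abs=0.2)

    def test_smoothing_stability_on_noiseless_curve(self):
        dt = 0.2
        t = np.arange(500) * dt
        i_dcn = np.concatenate([np.ones(3), 0.7 * (1 - np.exp(-t / 6))])
        curve = _curve_from_idcn(i_dcn, dt=dt)
        taus = [fk.half_recovery_time(curve, 0.7, smoothing_window=w)[2]
                for w in (1, 5, 11, 21)]
        assert max(taus) - min(taus) <= 2 * dt

    def test_even_window_rejected(self):
        curve = _curve_from_idcn([1, 1, 1] + list(np.linspace(0, 0.9, 40)))
        with pytest.raises(ValueError, match="odd"):
            fk.half_recovery_time(curve, 0.8, smoothing_window=4)


def test_smooth_preserves_constant():
    out = _smooth(np.full(50, 3.3), 11)
    np.testing.assert_allclose(out, 3.3, rtol=1e-12)


class TestAnalyzeFrap:
    def test_deterministic(self, noisy_cfg):
        r1 = fk.analyze_frap(*_sim(noisy_cfg))
        r2 = fk.analyze_frap(*_sim(noisy_cfg))
        assert r1.final_level == r2.final_level
        assert r1.tau_half == r2.tau_half

    def test_fractions_sum_to_100(self, noisy_cfg):
        res = fk.analyze_frap(*_sim(noisy_cfg))
        assert res.mobile_fraction + res.immobile_fraction == pytest.approx(100.0)
        assert 0.0 <= res.mobile_fraction <= 100.0

    def test_recovers_small_scale_truth(self):
        # long-run small config: measured mobile fraction ~ f_m
        vals = []
        for seed in range(5):
            cfg = small_noisy_config(diffusion_coeff=0.5, mobile_fraction=0.6,
                                     n_recovery=320, seed=seed)
            vals.append(run_pipeline_mobile(cfg))
        assert np.mean(vals) == pytest.approx(60.0, abs=3.0)

    def test_monitor_bleach_corrected(self):
        # strong monitor bleaching: corrected final level still ~ f_m while
        # the uncorrected tail is depressed by at least the cumulative loss
        cfg = small_noisy_config(diffusion_coeff=0.5, mobile_fraction=1.0,
                                 bleach_depth=1.0, monitor_bleach_rate=2e-3,
                                 noise_model="none", n_recovery=320)
        series, _ = fk.simulate_frap(cfg)
        rois = fk.default_roiset(cfg)
        res = fk.analyze_frap(series, rois)
        assert res.final_level == pytest.approx(1.0, abs=0.02)
        curve = fk.extract_traces(series, rois)
        raw = curve.I - curve.I_b
        raw_norm = raw / raw[: curve.n_prebleach].mean()
        raw_dcn = ((raw_norm - raw_norm[curve.bleach_index])
                   / (1 - raw_norm[curve.bleach_index]))
        cumulative_loss = 1 - (1 - 2e-3) ** curve.n_frames
        assert 1.0 - raw_dcn[-10:].mean() >= cumulative_loss * 0.95


def _sim(cfg):
    series, _ = fk.simulate_frap(cfg)
    return series, fk.default_roiset(cfg)


def run_pipeline_mobile(cfg):
    series, _ = fk.simulate_frap(cfg)
    return fk.analyze_frap(series, fk.default_roiset(cfg)).mobile_fraction
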