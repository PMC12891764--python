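"""Cine phase-contrast flow quantification against phantom ground truth."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfquant import flow as fl
from csfquant.phantoms import (
    CinePCSeries,
    CinePhantomSpec,
    generate_cine_series,
    sine_waveform,
)


def manual_series(vel, venc=10.0, cycle_ms=1000.0, pixel_area=1.0, mag=None):
    vel = np.asarray(vel, dtype=float)
    if mag is None:
        mag = np.full_like(vel, 80.0)
    return CinePCSeries(mag, vel, venc, cycle_ms, pixel_area)


class TestSegmentation:
    def test_clean_lumen_area_within_10pct(self, cine_clean):
        spec, ser = cine_clean
        ser, _ = fl.dealias(ser)
        roi = fl.segment_csf_roi(ser, tuple(ser.meta["seed_pixel"]))
        area = roi.sum() * ser.pixel_area_mm2
        assert abs(area / ser.meta["lumen_area_mm2"] - 1) < 0.10

    def test_zero_flow_raises(self):
        vel = np.zeros((32, 16, 16))
        with pytest.raises(ValueError, match="dynamic"):
            fl.segment_csf_roi(manual_series(vel), (8, 8))

    def test_static_background_excluded(self, cine_clean):
        spec, ser = cine_clean
        roi = fl.segment_csf_roi(ser, tuple(ser.meta["seed_pixel"]))
        lumen = ser.meta["lumen_mask"]
        # no ROI pixel further than one pixel outside the true lumen
        from scipy.ndimage import binary_dilation

        assert not (roi & ~binary_dilation(lumen, iterations=1)).any()


class TestDealias:
    def test_single_wrap_restored(self):
        # stored -8 at VENC 10 must come back as 12
        t = np.arange(32)
        true = 12.0 * np.sin(2 * np.pi * t / 32)
        from csfquant.phantoms import wrap_velocity

        wrapped = wrap_velocity(true, 10.0)
        ser = manual_series(wrapped[:, None, None] * np.ones((1, 3, 3)))
        out, qc = fl.dealias(ser)
        assert np.allclose(out.velocity_cms[:, 1, 1], true, atol=1e-9)
        assert qc["residual_jumps"] == 0

    def test_unwrapped_series_unchanged(self):
        t = np.arange(32)
        v = 3.0 * np.sin(2 * np.pi * t / 32)
        ser = manual_series(v[:, None, None] * np.ones((1, 2, 2)))
        out, _ = fl.dealias(ser)
        assert np.allclose(out.velocity_cms, ser.velocity_cms)

    def test_idempotent(self):
        spec = CinePhantomSpec(
            waveform=sine_waveform(3.0), venc_cms=5.0, alias=True, noise_sd_cms=0.1, seed=3
        )
        ser = generate_cine_series(spec)
        once, _ = fl.dealias(ser)
        twice, _ = fl.dealias(once)
        assert np.allclose(once.velocity_cms, twice.velocity_cms, atol=1e-12)

    def test_aliased_sinusoid_rms_error_below_5pct(self):
        kw = dict(
            lumen_radius_mm=2.0,
            waveform=sine_waveform(3.0),  # peak voxel velocity 6 = 1.2 * VENC
            venc_cms=5.0,
            cycle_ms=800.0,
            noise_sd_cms=0.0,
            seed=3,
        )
        aliased = generate_cine_series(CinePhantomSpec(alias=True, **kw))
        clean = generate_cine_series(CinePhantomSpec(alias=False, **kw))
        restored, _ = fl.dealias(aliased)
        lum = clean.meta["lumen_mask"]
        rms = np.sqrt(np.mean((restored.velocity_cms - clean.velocity_cms)[:, lum] ** 2))
        assert rms < 0.05 * 6.0


class TestBackgroundCorrection:
    def test_injected_offset_removed(self, cine_clean):
        spec, ser = cine_clean
        ser, _ = fl.dealias(ser)
        roi = fl.segment_csf_roi(ser, tuple(ser.meta["seed_pixel"]))
        corrected, offset = fl.correct_background(ser, roi)
        assert abs(offset - 0.5) < 0.02

    def test_zero_offset_correction_below_noise(self):
        spec = CinePhantomSpec(background_offset_cms=0.0, noise_sd_cms=0.2, seed=13)
        ser = generate_cine_series(spec)
        roi = fl.segment_csf_roi(ser, tuple(ser.meta["seed_pixel"]))
        _, offset = fl.correct_background(ser, roi)
        assert abs(offset) < 0.02

    def test_static_mean_zero_after_correction(self, cine_clean):
        spec, ser = cine_clean
        roi = fl.segment_csf_roi(ser, tuple(ser.meta["seed_pixel"]))
        corrected, offset = fl.correct_background(ser, roi)
        again, offset2 = fl.correct_background(corrected, roi)
        assert abs(offset2) < 1e-9

    def test_no_static_tissue_warns(self):
        t = np.arange(32)
        v = 3.0 * np.sin(2 * np.pi * t / 32)[:, None, None] * np.ones((1, 8, 8))
        ser = manual_series(v, mag=np.zeros((32, 8, 8)))
        roi = np.zeros((8, 8), bool)
        roi[3:5, 3:5] = True
        with pytest.warns(UserWarning, match="static"):
            out, offset = fl.correct_background(ser, roi)
        assert offset == 0.0


class TestFlowCurveAndStrokeVolume:
    def test_uniform_velocity_unit_conversion(self):
        vel = np.ones((32, 10, 10))  # 1 cm/s everywhere
        ser = manual_series(vel, pixel_area=1.0)
        mask = np.ones((10, 10), bool)  # 100 mm^2
        curve = fl.compute_flow_curve(ser, mask)
        assert np.allclose(curve.flow_mm3_s, 1000.0)

    def test_parabolic_profile_mean_velocity_equivalence(self, cine_clean):
        spec, ser = cine_clean
        lum = ser.meta["lumen_mask"]
        spec0 = CinePhantomSpec(
            lumen_radius_mm=2.0, waveform=sine_waveform(2.5), cycle_ms=800.0, noise_sd_cms=0.0
        )
        clean = generate_cine_series(spec0)
        curve = fl.compute_flow_curve(clean, clean.meta["lumen_mask"])
        vbar = clean.meta["vbar_cms"]
        area = clean.meta["lumen_mask"].sum() * clean.pixel_area_mm2
        # mean of the discrete parabola over in-lumen pixels approximates vbar
        assert np.allclose(curve.flow_mm3_s, area * vbar * 10, rtol=0.12)

    def test_phantom_sinusoid_curve(self):
        spec = CinePhantomSpec(
            lumen_radius_mm=2.0, waveform=sine_waveform(2.5), cycle_ms=800.0, noise_sd_cms=0.0
        )
        ser = generate_cine_series(spec)
        curve = fl.compute_flow_curve(ser, ser.meta["lumen_mask"])
        S = ser.meta["lumen_mask"].sum() * ser.pixel_area_mm2
        expected = S * 10 * ser.meta["vbar_cms"]
        resid = np.linalg.norm(curve.flow_mm3_s - expected) / np.linalg.norm(expected)
        assert resid < 0.02

    def test_sinusoid_closed_form_stroke_volume(self):
        t = np.arange(32) / 32 * 1000.0
        q = math.pi * np.sin(2 * np.pi * t / 1000.0)
        sv = fl.stroke_volume(fl.FlowCurve(t, q, 10.0, 1000.0))
        assert sv.sv_pos_mm3 == pytest.approx(1.0, rel=0.005)
        assert sv.sv_neg_mm3 == pytest.approx(1.0, rel=0.005)
        assert sv.sv_mm3 == pytest.approx(1.0, rel=0.005)

    def test_zero_curve(self):
        t = np.arange(32) / 32 * 800.0
        sv = fl.stroke_volume(fl.FlowCurve(t, np.zeros(32), 5.0, 800.0))
        assert sv.sv_pos_mm3 == sv.sv_neg_mm3 == sv.sv_mm3 == 0.0

    def test_offset_shifts_directional_difference(self):
        T = 0.9
        t = np.arange(32) / 32 * T * 1000
        q = 5.0 * np.sin(2 * np.pi * t / (T * 1000)) + 2.0
        sv = fl.stroke_volume(fl.FlowCurve(t, q, 5.0, T * 1000))
        assert sv.sv_pos_mm3 - sv.sv_neg_mm3 == pytest.approx(2.0 * T, rel=0.01)


class TestRatioSV:
    def test_worked_example(self):
        r = fl.ratio_sv(30.0, 600.0, 800.0, 800.0)
        assert r.ratio_pct == pytest.approx(5.0)
        assert r.cycle_mismatch_pct == 0.0 and not r.flagged

    def test_mismatch_flag(self):
        r = fl.ratio_sv(30.0, 600.0, 900.0, 800.0)
        assert r.cycle_mismatch_pct == pytest.approx(100 / 850 * 100, rel=1e-9)
        assert r.flagged

    def test_zero_cervical_sv_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fl.ratio_sv(30.0, 0.0, 800.0, 800.0)


class TestRecoveryProperties:
    @pytest.mark.parametrize(
        "amp,cycle,radius,noise",
        [(1.0, 700.0, 1.0, 0.3), (2.5, 825.0, 2.0, 0.2), (5.0, 1000.0, 3.0, 0.3)],
    )
    def test_stroke_volume_recovered_within_5pct(self, amp, cycle, radius, noise):
        spec = CinePhantomSpec(
            lumen_radius_mm=radius,
            waveform=sine_waveform(amp),
            cycle_ms=cycle,
            noise_sd_cms=noise,
            venc_cms=12.0,
            seed=42,
        )
        ser = generate_cine_series(spec)
        res = fl.process_cine(ser, tuple(ser.meta["seed_pixel"]))
        assert abs(res["sv"].sv_mm3 / ser.meta["sv_mm3"] - 1) < 0.05

    def test_ratio_sv_invariant_under_cycle_changes(self):
        """SVs held fixed while the cardiac cycle varies +-20%."""
        ratios = []
        for T in (660.0, 825.0, 990.0):
            sa = CinePhantomSpec(
                lumen_radius_mm=2.0,
                waveform=sine_waveform(2.5 * 825.0 / T),
                cycle_ms=T,
                noise_sd_cms=0.15,
                seed=5,
            )
            sc = CinePhantomSpec(
                lumen_radius_mm=4.5,
                waveform=sine_waveform(3.7 * 825.0 / T),
                cycle_ms=T,
                voxel_spacing_mm=0.5,
                noise_sd_cms=0.15,
                seed=6,
            )
            ra = generate_cine_series(sa)
            rc = generate_cine_series(sc)
            res_a = fl.process_cine(ra, tuple(ra.meta["seed_pixel"]))
            res_c = fl.process_cine(rc, tuple(rc.meta["seed_pixel"]))
            ratios.append(
                fl.ratio_sv(res_a["sv"], res_c["sv"], T, T).ratio_pct
            )
        assert (max(ratios) - min(ratios)) / np.mean(ratios) < 0.02

    @settings(max_examples=25, deadline=None)
    @given(
        venc=st.floats(2.0, 20.0),
        v=st.floats(-39.0, 39.0),
    )
    def test_wrap_stays_in_interval_and_preserves_congruence(self, venc, v):
        from csfquant.phantoms import wrap_velocity

        w = float(wrap_velocity(np.array([v]), venc)[0])
        assert -venc < w <= venc + 1e-9
        assert (w - v) / (2 * venc) == pytest.approx(round((w - v) / (2 * venc)), abs=1e-6)
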