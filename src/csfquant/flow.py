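"""CSF flow quantification from cine phase-contrast series.

Per site (aqueduct or cervical C2-C3 level):

1. semi-automatic ROI segmentation from velocity-spectrum characteristics:
   region growing from a seed pixel, keeping connected pixels whose
   temporal waveform has peak-to-peak amplitude well above the background
   level and correlates with the seed waveform,
2. velocity de-aliasing (single wrap) by temporal unwrapping with period
   2*VENC,
3. background phase correction: the time-mean velocity of static tissue in
   an annulus around the ROI (bright on magnitude, temporally quiet) is
   subtracted as the new zero-velocity reference,
4. flow curve Q(t) = ROI area x mean in-ROI velocity (32 samples over the
   averaged cardiac cycle; cm/s converted to mm/s at this boundary),
5. directional stroke volumes by periodic trapezoid integration:
   SV+ = integral of max(Q, 0) dt, SV- = |integral of min(Q, 0) dt|,
   SV = (SV+ + SV-)/2,

and across the two sites Ratio-SV = SV_aq / SV_cv, with a QC flag when the
two series' averaged cardiac cycles disagree by more than 10%.

The velocity sign convention (positive = caudo-cranial / fourth-to-third
ventricle) is carried in the series metadata and never inferred from data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import trapezoid
from scipy.ndimage import binary_dilation
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .phantoms import CinePCSeries

__all__ = [
    "FlowConfig",
    "FlowCurve",
    "StrokeVolume",
    "RatioSV",
    "segment_csf_roi",
    "dealias",
    "correct_background",
    "compute_flow_curve",
    "stroke_volume",
    "ratio_sv",
    "process_cine",
]


@dataclass(frozen=True)
class FlowConfig:
    """Thresholds of the semi-automatic segmentation and correction steps."""

    k_amp: float = 3.0  # core dynamic-pixel amplitude multiple of background
    k_grow: float = 1.0  # growth amplitude multiple (hysteresis lower level)
    c_min: float = 0.5  # min waveform correlation with the seed pixel
    annulus_px: int = 6  # dilation radius defining the static-tissue ring
    magnitude_floor_frac: float = 0.5  # of the mean in-ROI magnitude
    velocity_sd_cap_cms: float = 1.0  # max temporal SD for "static"
    mismatch_limit_pct: float = 10.0


@dataclass
class FlowCurve:
    """32-point flow-rate waveform over one averaged cardiac cycle."""

    times_ms: np.ndarray
    flow_mm3_s: np.ndarray
    roi_area_mm2: float
    cycle_ms: float

    def __post_init__(self) -> None:
        if len(self.times_ms) != len(self.flow_mm3_s):
            raise ValueError("times and flow must have equal length")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("times must be strictly increasing within one cycle")


@dataclass
class StrokeVolume:
    sv_pos_mm3: float
    sv_neg_mm3: float

    @property
    def sv_mm3(self) -> float:
        return 0.5 * (self.sv_pos_mm3 + self.sv_neg_mm3)


@dataclass
class RatioSV:
    sv_aq_mm3: float
    sv_cv_mm3: float
    ratio: float  # fraction
    cycle_mismatch_pct: float  # signed
    flagged: bool

    @property
    def ratio_pct(self) -> float:
        return self.ratio * 100.0


def segment_csf_roi(
    series: CinePCSeries,
    seed_pixel: tuple[int, int],
    config: FlowConfig = FlowConfig(),
) -> np.ndarray:
    """Fixed (time-invariant) CSF ROI by amplitude + correlation growing.

    Two-level (hysteresis) criterion: the seed must show a peak-to-peak
    velocity amplitude at least ``k_amp`` times the background amplitude
    (the image-wide median, i.e. the noise floor); the ROI then grows over
    connected pixels whose amplitude exceeds ``k_grow`` times background
    and whose temporal waveform correlates with the seed waveform at
    ``c_min`` or better.  The lower growth level keeps the slow near-wall
    rim of the lumen, whose flux a single high threshold would discard.
    De-alias first when velocities may wrap: wrapped waveforms decorrelate
    from their neighbours.
    """
    vel = np.asarray(series.velocity_cms, dtype=float)
    amp = vel.max(axis=0) - vel.min(axis=0)
    bg_amp = float(np.median(amp))
    r0, c0 = seed_pixel
    seed_wave = vel[:, r0, c0]
    if amp[r0, c0] <= 0 or amp[r0, c0] < config.k_amp * bg_amp:
        raise ValueError("seed pixel shows no dynamic signal above background")
    sw = seed_wave - seed_wave.mean()
    sn = np.linalg.norm(sw)
    dem = vel - vel.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(dem, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.einsum("tij,t->ij", dem, sw) / (norms * sn)
    corr = np.nan_to_num(corr, nan=0.0)
    grow = (amp >= config.k_grow * bg_amp) & (corr >= config.c_min)
    if not grow.any():
        raise ValueError("no dynamic pixels: velocity amplitude never exceeds background")
    labels = cc_label(grow, connectivity=2)
    lab = labels[r0, c0]
    if lab == 0:
        raise ValueError("seed pixel excluded by the amplitude/correlation criteria")
    return labels == lab


def dealias(
    series: CinePCSeries, mask: np.ndarray | None = None
) -> tuple[CinePCSeries, dict]:
    """Temporal phase unwrapping of each pixel waveform (single wrap).

    Jumps larger than VENC between consecutive frames are corrected by
    +-2*VENC; the unwrapped waveform is then re-centered by the multiple of
    2*VENC nearest its own mean, which anchors oscillatory CSF waveforms
    around zero even when frame 0 happens to be aliased.  Residual
    super-VENC jumps after one pass are reported in the QC record.
    """
    venc = series.venc_cms
    vel = np.asarray(series.velocity_cms, dtype=float)
    unwrapped = np.unwrap(vel, axis=0, period=2.0 * venc)
    shift = 2.0 * venc * np.round(unwrapped.mean(axis=0) / (2.0 * venc))
    unwrapped = unwrapped - shift[None]
    if mask is not None:
        out = vel.copy()
        out[:, mask] = unwrapped[:, mask]
        unwrapped = out
    residual = int(np.sum(np.abs(np.diff(unwrapped, axis=0)) > venc))
    qc = {"n_wrapped_samples": int(np.sum(np.abs(unwrapped - vel) > venc * 1e-9)),
          "residual_jumps": residual}
    if residual:
        warnings.warn(f"{residual} residual super-VENC jumps after de-aliasing", stacklevel=2)
    return series.replace_velocity(unwrapped), qc


def correct_background(
    series: CinePCSeries,
    roi: np.ndarray,
    config: FlowConfig = FlowConfig(),
) -> tuple[CinePCSeries, float]:
    """Re-zero velocities on surrounding static tissue; returns the offset.

    Static tissue = pixels in a dilated annulus around the ROI whose mean
    magnitude exceeds a floor and whose temporal velocity SD is below a
    cap.  If no pixel qualifies, a warning is issued and no correction is
    applied.
    """
    ring = binary_dilation(roi, disk(config.annulus_px)) & ~roi
    magmean = np.asarray(series.magnitude, dtype=float).mean(axis=0)
    floor = config.magnitude_floor_frac * float(magmean[roi].mean()) if roi.any() else 0.0
    vsd = np.asarray(series.velocity_cms, dtype=float).std(axis=0)
    static = ring & (magmean >= floor) & (vsd <= config.velocity_sd_cap_cms)
    if not static.any():
        warnings.warn("no static tissue found: background correction skipped", stacklevel=2)
        return series, 0.0
    offset = float(np.asarray(series.velocity_cms)[:, static].mean())
    return series.replace_velocity(series.velocity_cms - offset), offset


def compute_flow_curve(series: CinePCSeries, mask: np.ndarray) -> FlowCurve:
    """Q(t) = ROI area (mm^2) x mean in-ROI velocity (cm/s -> mm/s)."""
    if not mask.any():
        raise ValueError("empty ROI mask")
    area = float(mask.sum()) * series.pixel_area_mm2
    mean_v = np.asarray(series.velocity_cms, dtype=float)[:, mask].mean(axis=1)
    times = np.arange(series.n_frames) / series.n_frames * series.cycle_ms
    return FlowCurve(times, area * mean_v * 10.0, area, series.cycle_ms)


def stroke_volume(curve: FlowCurve) -> StrokeVolume:
    """Directional integrals over the closed (periodic) cardiac cycle."""
    t = np.concatenate([curve.times_ms, [curve.times_ms[0] + curve.cycle_ms]]) / 1000.0
    q = np.concatenate([curve.flow_mm3_s, [curve.flow_mm3_s[0]]])
    pos = float(trapezoid(np.clip(q, 0.0, None), t))
    neg = float(abs(trapezoid(np.clip(q, None, 0.0), t)))
    return StrokeVolume(pos, neg)


def ratio_sv(
    sv_aq: StrokeVolume | float,
    sv_cv: StrokeVolume | float,
    cycle_aq_ms: float,
    cycle_cv_ms: float,
    mismatch_limit_pct: float = 10.0,
) -> RatioSV:
    """Ratio-SV plus the cardiac-cycle-mismatch QC flag.

    The signed mismatch uses the mean of the two cycles as denominator:
    100 * (cycle_aq - cycle_cv) / mean(cycle_aq, cycle_cv).
    """
    a = sv_aq.sv_mm3 if isinstance(sv_aq, StrokeVolume) else float(sv_aq)
    c = sv_cv.sv_mm3 if isinstance(sv_cv, StrokeVolume) else float(sv_cv)
    if c <= 0:
        raise ZeroDivisionError("cervical stroke volume must be positive")
    mism = (cycle_aq_ms - cycle_cv_ms) / (0.5 * (cycle_aq_ms + cycle_cv_ms)) * 100.0
    return RatioSV(a, c, a / c, mism, abs(mism) > mismatch_limit_pct)


def process_cine(
    series: CinePCSeries,
    seed_pixel: tuple[int, int],
    config: FlowConfig = FlowConfig(),
) -> dict:
    """Full single-site pipeline: de-alias, segment, correct, integrate.

    De-aliasing runs first because wrapped lumen waveforms would fail the
    correlation criterion of the ROI segmentation.
    """
    series, alias_qc = dealias(series)
    roi = segment_csf_roi(series, seed_pixel, config)
    series, offset = correct_background(series, roi, config)
    curve = compute_flow_curve(series, roi)
    sv = stroke_volume(curve)
    return {
        "roi": roi,
        "roi_area_mm2": curve.roi_area_mm2,
        "curve": curve,
        "sv": sv,
        "background_offset_cms": offset,
        "alias_qc": alias_qc,
        "cycle_ms": series.cycle_ms,
    }
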