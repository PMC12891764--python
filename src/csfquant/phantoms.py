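"""Synthetic phantoms with closed-form ground truth.

Four generators emulate the inputs the three measurement pipelines expect:

* :func:`generate_tube_volume` — a tube-like lumen with a spatially varying
  diameter on a dark background, standing in for a high-contrast
  morphological acquisition of the cerebral aqueduct.
* :func:`generate_brain_slice` — a stack of elliptical "brain" slices with
  dark ventricles and an optional bright choroid-plexus inclusion, standing
  in for a T1-weighted axial series.
* :func:`generate_cine_series` — a 32-frame velocity/magnitude cine series
  with a parabolic (Poiseuille) lumen profile, constant background phase
  offset, optional single-wrap velocity aliasing, and Gaussian noise.
* :func:`generate_cohort_table` — per-subject parameter tables drawn from
  stated per-sex means/SDs with optional correlation targets and injected
  outliers.

Every generator is deterministic given its spec (same spec + seed =>
bit-identical output) and records its ground truth in the ``meta`` record
of the returned object.  Lumen membership uses a voxel-center test: a voxel
belongs to the lumen iff its center lies inside the swept circle.  No
partial-volume averaging or MR physics is simulated; noise is additive
Gaussian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Volume3D

__all__ = [
    "TubePhantomSpec",
    "BrainPhantomSpec",
    "CinePhantomSpec",
    "CinePCSeries",
    "CohortSpec",
    "generate_tube_volume",
    "generate_brain_slice",
    "generate_cine_series",
    "generate_cohort_table",
    "sine_waveform",
    "wrap_velocity",
    "TABLE1_PARAMS",
]


# --------------------------------------------------------------------------
# Tube phantom
# --------------------------------------------------------------------------

def _uniform_diameter(_s: float) -> float:
    return 1.9


@dataclass(frozen=True)
class TubePhantomSpec:
    """Geometry and imaging parameters of a synthetic aqueduct-like tube.

    The tube centerline lies in a single axial (fixed-z) plane.  It is a
    straight chord tilted by ``tilt_deg`` against the image x-axis, or a
    circular arc turning ``bend_deg`` in total when nonzero.  A small
    nonzero tilt is the recommended default: a perfectly grid-aligned tube
    is a degenerate geometry in which voxelization errors are perfectly
    correlated along the length instead of averaging out, which no real
    acquisition exhibits.

    ``diameter_fn`` maps arc-length fraction ``s`` in [0, 1] to the local
    lumen diameter in mm.
    """

    length_mm: float = 19.0
    diameter_fn: Callable[[float], float] = _uniform_diameter
    bend_deg: float = 0.0
    tilt_deg: float = 7.0
    voxel_spacing_mm: float | tuple[float, float, float] = 0.35
    fg_intensity: float = 100.0
    bg_intensity: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0
    margin_mm: float = 2.0
    fov_mm: tuple[float, float] | None = None

    @property
    def spacing(self) -> tuple[float, float, float]:
        s = self.voxel_spacing_mm
        if np.isscalar(s):
            return (float(s),) * 3
        return tuple(float(v) for v in s)  # type: ignore[return-value]

    def validate(self) -> None:
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")
        if min(self.spacing) <= 0:
            raise ValueError("voxel spacing must be positive")
        ss = np.linspace(0.0, 1.0, 201)
        dd = np.array([self.diameter_fn(s) for s in ss], dtype=float)
        if np.any(dd <= 0):
            raise ValueError("diameter_fn must be positive on [0, 1]")
        if self.fov_mm is not None:
            if dd.max() >= min(self.fov_mm):
                raise ValueError(
                    f"lumen diameter {dd.max():.2f} mm does not fit in the "
                    f"field of view {self.fov_mm}"
                )


def _tube_centerline(spec: TubePhantomSpec, step_mm: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """Dense centerline samples in (row_mm, col_mm), plus arc-length array."""
    n = max(int(math.ceil(spec.length_mm / step_mm)) + 1, 2)
    t = np.linspace(0.0, spec.length_mm, n)
    tilt = math.radians(spec.tilt_deg)
    if abs(spec.bend_deg) < 1e-12:
        rows = t * math.sin(tilt)
        cols = t * math.cos(tilt)
    else:
        theta = math.radians(spec.bend_deg)
        radius = spec.length_mm / abs(theta)
        phi = t / radius * math.copysign(1.0, theta)
        # arc starting at origin, initial heading = tilt
        rows = radius * (np.sin(tilt + phi) - math.sin(tilt)) * math.copysign(1.0, theta)
        cols = radius * (np.cos(tilt) - np.cos(tilt + phi)) * math.copysign(1.0, theta)
        if theta < 0:
            rows, cols = -rows, cols
    pts = np.column_stack([rows, cols])
    return pts, t


def generate_tube_volume(spec: TubePhantomSpec) -> Volume3D:
    """Voxelize a swept-circle tube; ground truth rides in ``meta``.

    A voxel receives ``fg_intensity`` iff its center lies within
    ``diameter_fn(s)/2`` of the nearest centerline point; all other voxels
    receive ``bg_intensity``.  The centerline plane coincides exactly with
    a z voxel-center plane so that the maximum-intensity projection along z
    has silhouette width equal to the true local diameter.
    """
    spec.validate()
    sz, sy, sx = spec.spacing
    pts, arc = _tube_centerline(spec)
    diam = np.array([spec.diameter_fn(s) for s in arc / spec.length_mm])
    rmax = diam.max() / 2.0

    m = spec.margin_mm
    r0, c0 = pts[:, 0].min() - rmax - m, pts[:, 1].min() - rmax - m
    r1, c1 = pts[:, 0].max() + rmax + m, pts[:, 1].max() + rmax + m
    if spec.fov_mm is not None and (r1 - r0 > spec.fov_mm[0] or c1 - c0 > spec.fov_mm[1]):
        raise ValueError("tube (with margins) exceeds the requested field of view")
    ny = int(math.ceil((r1 - r0) / sy)) + 1
    nx = int(math.ceil((c1 - c0) / sx)) + 1
    nz = 2 * int(math.ceil((rmax + 1.0) / sz)) + 1  # odd: center plane on a voxel center

    # voxel-center coordinates; tube plane at z=0 == center plane
    zc = (np.arange(nz) - nz // 2) * sz
    yc = r0 + np.arange(ny) * sy
    xc = c0 + np.arange(nx) * sx

    tree = cKDTree(pts)
    yy, xx = np.meshgrid(yc, xc, indexing="ij")
    q = np.column_stack([yy.ravel(), xx.ravel()])
    d2d, idx = tree.query(q)
    rad = diam[idx] / 2.0
    vol = np.full((nz, ny, nx), float(spec.bg_intensity))
    for k in range(nz):
        dist = np.hypot(d2d, zc[k])
        inside = (dist <= rad).reshape(ny, nx)
        vol[k][inside] = spec.fg_intensity

    lumen_voxels = int(np.sum(vol == spec.fg_intensity)) if spec.fg_intensity != spec.bg_intensity else 0
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, vol.shape)

    # ground truth: analytic lumen volume by quadrature of the disc area
    s_dense = np.linspace(0.0, 1.0, 4001)
    d_dense = np.array([spec.diameter_fn(s) for s in s_dense])
    analytic_volume = float(np.trapezoid(np.pi * d_dense**2 / 4.0, s_dense * spec.length_mm))

    # In the cell-centered frame used by the measurement modules, pixel i's
    # center is at (i + 0.5) * s; voxel centers here are at r0 + i * s.
    # The phantom's mm frame therefore maps to measurement-frame mm via
    # mm_meas = mm_phantom - origin, origin = (r0 - s/2, c0 - s/2).
    origin = (r0 - 0.5 * sy, c0 - 0.5 * sx)
    ctr_mm_meas = np.column_stack([pts[:, 0] - origin[0], pts[:, 1] - origin[1]])

    meta = {
        "kind": "tube",
        "length_mm": spec.length_mm,
        "arc_mm": arc,
        "diameters_mm": diam,
        "centerline_mm": ctr_mm_meas,
        "analytic_lumen_volume_mm3": analytic_volume,
        "lumen_voxel_count": lumen_voxels,
        "center_plane_index": nz // 2,
        "spacing_mm": [sz, sy, sx],
        "seed": spec.seed,
    }
    return Volume3D(vol, (sz, sy, sx), meta)


def tube_point_mm(vol: Volume3D, arc_mm: float) -> np.ndarray:
    """Ground-truth centerline point (row_mm, col_mm) at a given arc length."""
    arc = np.asarray(vol.meta["arc_mm"], dtype=float)
    ctr = np.asarray(vol.meta["centerline_mm"], dtype=float)
    r = np.interp(arc_mm, arc, ctr[:, 0])
    c = np.interp(arc_mm, arc, ctr[:, 1])
    return np.array([r, c])


# --------------------------------------------------------------------------
# Brain-slice phantom
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BrainPhantomSpec:
    """Elliptical brain stack with two dark ventricles and a bright plexus.

    The ventricle semi-axes are scaled per slice by a smooth profile that
    peaks at ``peak_slice``, so that slice carries the maximal
    ventricle-to-brain area ratio by construction.  Intensities mimic a
    T1-weighted contrast: bright parenchyma, dark CSF, bright choroid
    plexus, near-black background.
    """

    brain_axes_mm: tuple[float, float] = (70.0, 55.0)  # (col/x semi-axis, row/y semi-axis)
    vent_axes_mm: tuple[float, float] = (10.0, 4.0)  # (row/y semi-axis, col/x semi-axis)
    vent_offset_mm: tuple[float, float] = (0.0, 7.0)  # ventricle centers at (row, +-col)
    plexus_radius_mm: float = 0.0
    plexus_center_mm: tuple[float, float] | None = None
    n_slices: int = 9
    peak_slice: int = 4
    pixel_spacing_mm: float = 0.5
    slice_thickness_mm: float = 1.2
    bg_intensity: float = 5.0
    brain_intensity: float = 100.0
    vent_intensity: float = 20.0
    plexus_intensity: float = 95.0
    noise_sd: float = 0.0
    seed: int = 0

    def vent_centers(self) -> list[tuple[float, float]]:
        r, c = self.vent_offset_mm
        return [(r, -c), (r, +c)]

    def validate(self) -> None:
        ax, ay = self.brain_axes_mm
        va, vb = self.vent_axes_mm
        if min(ax, ay) <= 0 or self.pixel_spacing_mm <= 0:
            raise ValueError("axes and spacing must be positive")
        if va > 0 or vb > 0:
            if va <= 0 or vb <= 0:
                raise ValueError("ventricle semi-axes must both be positive or both zero")
            th = np.linspace(0, 2 * np.pi, 181)
            for (r0, c0) in self.vent_centers():
                rr = r0 + va * np.sin(th)
                cc = c0 + vb * np.cos(th)
                if np.any((cc / ax) ** 2 + (rr / ay) ** 2 >= 1.0):
                    raise ValueError("ventricle ellipse not contained in brain ellipse")
            # ventricles must not overlap each other
            if 2 * vb > 2 * abs(self.vent_offset_mm[1]):
                raise ValueError("ventricle ellipses overlap")
        if self.plexus_radius_mm > 0:
            pr, pc = self.plexus_center()
            va, vb = self.vent_axes_mm
            r0, c0 = self.vent_centers()[1]
            th = np.linspace(0, 2 * np.pi, 181)
            rr = pr + self.plexus_radius_mm * np.sin(th)
            cc = pc + self.plexus_radius_mm * np.cos(th)
            if np.any(((rr - r0) / va) ** 2 + ((cc - c0) / vb) ** 2 >= 1.0):
                raise ValueError("plexus disc not contained in the ventricle")

    def plexus_center(self) -> tuple[float, float]:
        if self.plexus_center_mm is not None:
            return self.plexus_center_mm
        return self.vent_centers()[1]


def _vent_scale(spec: BrainPhantomSpec, k: int) -> float:
    """Per-slice ventricle scale factor, maximal (=1) at ``peak_slice``."""
    if spec.n_slices == 1:
        return 1.0
    w = max(spec.n_slices, 2)
    return float(max(0.25, 1.0 - 0.6 * ((k - spec.peak_slice) / w) ** 2 * 4))


def generate_brain_slice(spec: BrainPhantomSpec) -> Volume3D:
    """Rasterize the brain-slice stack; per-slice analytic areas in ``meta``."""
    spec.validate()
    s = spec.pixel_spacing_mm
    ax, ay = spec.brain_axes_mm
    margin = 6.0
    ny = int(math.ceil(2 * (ay + margin) / s))
    nx = int(math.ceil(2 * (ax + margin) / s))
    # cell-centered pixel coordinates with the brain center mid-image
    yc = (np.arange(ny) + 0.5) * s - ny * s / 2.0
    xc = (np.arange(nx) + 0.5) * s - nx * s / 2.0
    yy, xx = np.meshgrid(yc, xc, indexing="ij")
    brain = (xx / ax) ** 2 + (yy / ay) ** 2 <= 1.0

    va, vb = spec.vent_axes_mm
    rng = np.random.default_rng(spec.seed)
    vol = np.empty((spec.n_slices, ny, nx))
    gt_rows = []
    for k in range(spec.n_slices):
        f = _vent_scale(spec, k)
        img = np.full((ny, nx), spec.bg_intensity)
        img[brain] = spec.brain_intensity
        vent_area = 0.0
        plexus_area = 0.0
        if va > 0:
            for (r0, c0) in spec.vent_centers():
                vent = ((yy - r0) / (va * f)) ** 2 + ((xx - c0) / (vb * f)) ** 2 <= 1.0
                img[vent] = spec.vent_intensity
                vent_area += math.pi * (va * f) * (vb * f)
            if spec.plexus_radius_mm > 0 and k == spec.peak_slice:
                pr, pc = spec.plexus_center()
                plex = (yy - pr) ** 2 + (xx - pc) ** 2 <= spec.plexus_radius_mm**2
                img[plex] = spec.plexus_intensity
                plexus_area = math.pi * spec.plexus_radius_mm**2
        vol[k] = img
        brain_area = math.pi * ax * ay
        tissue_area = brain_area - vent_area
        net_vent = vent_area - plexus_area
        gt_rows.append(
            {
                "slice": k,
                "area_vent_mm2": net_vent,
                "area_brain_mm2": tissue_area,
                "ratio_area": (net_vent / tissue_area) if tissue_area > 0 else 0.0,
            }
        )
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, vol.shape)

    meta = {
        "kind": "brain",
        "ground_truth": gt_rows,
        "peak_slice": spec.peak_slice,
        "brain_axes_mm": list(spec.brain_axes_mm),
        "vent_axes_mm": list(spec.vent_axes_mm),
        "vent_offset_mm": list(spec.vent_offset_mm),
        "plexus_radius_mm": spec.plexus_radius_mm,
        "image_center_px": [ny / 2.0 - 0.5, nx / 2.0 - 0.5],
        "pixel_spacing_mm": s,
        "seed": spec.seed,
    }
    return Volume3D(vol, (spec.slice_thickness_mm, s, s), meta)


def brain_default_rois(spec: BrainPhantomSpec, vol: Volume3D) -> dict:
    """Scripted stand-ins for the hand-drawn ventricle/brain ROIs.

    Returns polygons in 0-based pixel coordinates of the stored grid, plus a
    threshold line crossing one ventricle boundary.
    """
    s = spec.pixel_spacing_mm
    ctr = np.asarray(vol.meta["image_center_px"], dtype=float)

    def to_px(points_mm: np.ndarray) -> np.ndarray:
        return points_mm / s + ctr

    ax, ay = spec.brain_axes_mm
    th = np.linspace(0, 2 * np.pi, 73)[:-1]
    brain_poly = to_px(np.column_stack([1.06 * ay * np.sin(th), 1.06 * ax * np.cos(th)]))

    va, vb = spec.vent_axes_mm
    r0, c0 = spec.vent_offset_mm
    pad = 2.5
    vent_box = np.array(
        [
            [-va - pad, -c0 - vb - pad],
            [-va - pad, c0 + vb + pad],
            [va + pad + r0 * 2, c0 + vb + pad],
            [va + pad + r0 * 2, -c0 - vb - pad],
        ]
    )
    vent_poly = to_px(vent_box)
    # line crossing the right ventricle's lateral boundary
    line = to_px(np.array([[r0, c0], [r0, c0 + vb + 3.0]]))
    return {"brain_roi": brain_poly, "vent_roi": vent_poly, "line": line}


# --------------------------------------------------------------------------
# Cine phase-contrast phantom
# --------------------------------------------------------------------------


def sine_waveform(amplitude_cms: float) -> Callable[[float, float], float]:
    """Mean-velocity waveform v(t) = A sin(2*pi*t/T), A in cm/s, t/T in s."""

    def wave(t_s: float, period_s: float) -> float:
        return amplitude_cms * math.sin(2.0 * math.pi * t_s / period_s)

    return wave


def wrap_velocity(v: np.ndarray, venc: float) -> np.ndarray:
    """Wrap velocities into the interval (-VENC, +VENC] (period 2*VENC)."""
    return venc - np.mod(venc - np.asarray(v, dtype=float), 2.0 * venc)


@dataclass(frozen=True)
class CinePhantomSpec:
    """Cine phase-contrast acquisition over one averaged cardiac cycle.

    The velocity frames hold a parabolic (Poiseuille) profile
    ``v(r, t) = 2 v_mean(t) (1 - (r/R)^2)`` inside a circular lumen of
    radius ``lumen_radius_mm``, a constant background phase offset
    everywhere, optional single-wrap aliasing into ``(-VENC, +VENC]``, and
    additive Gaussian noise.  Magnitude frames are bright in the lumen on a
    mid-gray static-tissue background.
    """

    n_frames: int = 32
    cycle_ms: float = 825.0
    lumen_radius_mm: float = 2.0
    waveform: Callable[[float, float], float] = field(default_factory=lambda: sine_waveform(2.5))
    venc_cms: float = 10.0
    background_offset_cms: float = 0.0
    alias: bool = False
    noise_sd_cms: float = 0.0
    voxel_spacing_mm: float = 0.35
    fov_margin_mm: float = 4.0
    lumen_magnitude: float = 100.0
    tissue_magnitude: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.venc_cms <= 0:
            raise ValueError("venc_cms must be positive")
        if self.lumen_radius_mm <= 0 or self.voxel_spacing_mm <= 0:
            raise ValueError("radius and spacing must be positive")
        if self.alias:
            T = self.cycle_ms / 1000.0
            tt = np.linspace(0, T, 2048, endpoint=False)
            peak = 2.0 * max(abs(self.waveform(t, T)) for t in tt) + abs(self.background_offset_cms)
            if peak >= 2.0 * self.venc_cms:
                raise ValueError(
                    "peak velocity exceeds 2*VENC: double-wrap aliasing is out of scope"
                )


@dataclass
class CinePCSeries:
    """Paired magnitude/velocity frame stacks over one averaged cycle."""

    magnitude: np.ndarray  # (T, ny, nx), >= 0
    velocity_cms: np.ndarray  # (T, ny, nx), signed
    venc_cms: float
    cycle_ms: float
    pixel_area_mm2: float
    positive_direction_label: str = "fourth-to-third-ventricle"
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    def replace_velocity(self, vel: np.ndarray) -> "CinePCSeries":
        return CinePCSeries(
            self.magnitude,
            vel,
            self.venc_cms,
            self.cycle_ms,
            self.pixel_area_mm2,
            self.positive_direction_label,
            dict(self.meta),
        )


def generate_cine_series(spec: CinePhantomSpec) -> CinePCSeries:
    """Simulate the cine series; ground-truth stroke volumes in ``meta``."""
    spec.validate()
    s = spec.voxel_spacing_mm
    R = spec.lumen_radius_mm
    half = R + spec.fov_margin_mm
    n = int(math.ceil(2 * half / s))
    yc = (np.arange(n) + 0.5) * s - n * s / 2.0
    yy, xx = np.meshgrid(yc, yc, indexing="ij")
    rr = np.hypot(yy, xx)
    lumen = rr <= R
    shape_fac = np.where(lumen, 2.0 * (1.0 - (rr / R) ** 2), 0.0)

    T_s = spec.cycle_ms / 1000.0
    times = np.arange(spec.n_frames) / spec.n_frames * T_s
    vbar = np.array([spec.waveform(t, T_s) for t in times])

    rng = np.random.default_rng(spec.seed)
    vel = vbar[:, None, None] * shape_fac[None] + spec.background_offset_cms
    if spec.noise_sd_cms > 0:
        vel = vel + rng.normal(0.0, spec.noise_sd_cms, vel.shape)
    if spec.alias:
        vel = wrap_velocity(vel, spec.venc_cms)
    mag = np.where(lumen, spec.lumen_magnitude, spec.tissue_magnitude)
    mag = np.broadcast_to(mag, (spec.n_frames, n, n)).copy()
    if spec.noise_sd_cms > 0:
        mag = mag + rng.normal(0.0, spec.noise_sd_cms, mag.shape)

    # closed-form-by-quadrature ground truth stroke volumes (mm^3):
    # Q(t) = S * vbar(t), S in mm^2, vbar cm/s -> *10 mm/s
    area = math.pi * R**2
    tt = np.linspace(0.0, T_s, 20001)
    q = np.array([spec.waveform(t, T_s) for t in tt]) * 10.0 * area
    sv_pos = float(np.trapezoid(np.clip(q, 0, None), tt))
    sv_neg = float(abs(np.trapezoid(np.clip(q, None, 0), tt)))

    meta = {
        "kind": "cine",
        "lumen_mask": lumen,
        "lumen_area_mm2": area,
        "vbar_cms": vbar,
        "sv_pos_mm3": sv_pos,
        "sv_neg_mm3": sv_neg,
        "sv_mm3": 0.5 * (sv_pos + sv_neg),
        "background_offset_cms": spec.background_offset_cms,
        "seed_pixel": [n // 2, n // 2],
        "seed": spec.seed,
    }
    return CinePCSeries(mag, vel, spec.venc_cms, spec.cycle_ms, s * s, meta=meta)


# --------------------------------------------------------------------------
# Cohort phantom
# --------------------------------------------------------------------------

#: Per-sex mean/SD of each base parameter at the scale of a healthy young
#: adult cohort.  Ratio columns are not listed: they are derived from their
#: numerator/denominator so the table stays internally consistent.
#: Strictly positive parameters with large coefficients of variation are
#: drawn from a moment-matched lognormal ("dist"), which reproduces both
#: the mean/SD and the right-skewed, comparatively tight interquartile
#: ranges such cohorts show; a normal with the same SD would not.
TABLE1_PARAMS: Mapping[str, dict] = {
    "age_years": {"male": (26.2, 4.3), "female": (24.2, 3.3)},
    "area_vent_mm2": {"male": (5.8, 1.7), "female": (7.2, 2.2), "dist": "lognormal"},
    "area_brain_mm2": {"male": (151.0, 10.0), "female": (140.0, 9.0)},
    "user_length_mm": {"male": (16.6, 2.8), "female": (14.2, 2.5)},
    "d_min_mm": {"male": (1.3, 0.2), "female": (1.2, 0.2)},
    "d_mean_mm": {"male": (2.0, 0.2), "female": (1.8, 0.3)},
    "resistance": {"male": (62.0, 38.0), "female": (82.0, 45.0), "dist": "lognormal"},
    "cycle_ms": {"male": (862.0, 151.0), "female": (788.0, 112.0)},
    "sv_aq_mm3": {"male": (41.0, 18.0), "female": (30.0, 13.0), "dist": "lognormal"},
    "sv_cv_mm3": {"male": (595.0, 161.0), "female": (600.0, 127.0), "dist": "lognormal"},
}


@dataclass(frozen=True)
class CohortSpec:
    """Sampling plan for a synthetic per-subject parameter table."""

    n_per_group: int = 17
    params: Mapping[str, dict] = field(default_factory=lambda: dict(TABLE1_PARAMS))
    correlations: Sequence[tuple[str, str, float]] = (("resistance", "sv_aq_mm3", -0.6),)
    outlier_injections: Sequence[tuple[str, float]] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        for name, bysex in self.params.items():
            for sex in ("male", "female"):
                mean, sd = bysex[sex]
                if sd < 0:
                    raise ValueError(f"SD for {name}/{sex} must be >= 0")
        names = set(self.params)
        for a, b, rho in self.correlations:
            if a not in names or b not in names:
                raise ValueError(f"correlation target references unknown parameter {a!r}/{b!r}")
            if not -1.0 < rho < 1.0:
                raise ValueError("correlation targets must lie in (-1, 1)")


def _corr_matrix(names: Sequence[str], targets: Sequence[tuple[str, str, float]]) -> np.ndarray:
    k = len(names)
    C = np.eye(k)
    pos = {n: i for i, n in enumerate(names)}
    for a, b, rho in targets:
        C[pos[a], pos[b]] = C[pos[b], pos[a]] = rho
    # nudge to positive definite if the targets conflict
    w, V = np.linalg.eigh(C)
    if w.min() <= 1e-8:
        w = np.clip(w, 1e-6, None)
        C = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    return C


def _from_gaussian(z: float, mean: float, sd: float, dist: str) -> float:
    """Transform a standard-normal draw to the requested marginal.

    The lognormal branch is moment-matched: its mean and SD equal the
    requested ones exactly.  Drawing through a Gaussian copula preserves
    rank correlations across differently-distributed parameters.
    """
    if dist == "lognormal" and mean > 0 and sd > 0:
        s2 = math.log1p((sd / mean) ** 2)
        mu = math.log(mean) - s2 / 2.0
        return float(math.exp(mu + math.sqrt(s2) * z))
    return float(mean + sd * z)


def generate_cohort_table(spec: CohortSpec) -> pd.DataFrame:
    """Draw per-subject rows; ratio columns derived, outliers appended.

    Normally-distributed positive-scale parameters are truncated at 5% of
    their group mean so a wide SD cannot produce nonphysical negative
    values; lognormal parameters are positive by construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = list(spec.params)
    L = np.linalg.cholesky(_corr_matrix(names, spec.correlations))
    rows = []
    sid = 0
    for sex in ("male", "female"):
        z = rng.standard_normal((spec.n_per_group, len(names))) @ L.T
        for j in range(spec.n_per_group):
            sid += 1
            row = {"id": f"S{sid:03d}", "sex": sex}
            for i, name in enumerate(names):
                mean, sd = spec.params[name][sex]
                dist = spec.params[name].get("dist", "normal")
                val = _from_gaussian(z[j, i], mean, sd, dist)
                if dist == "normal" and name != "age_years":
                    val = max(val, 0.05 * mean)
                row[name] = val
            rows.append(row)
    for pname, pval in spec.outlier_injections:
        sid += 1
        sex = "male" if sid % 2 else "female"
        row = {"id": f"S{sid:03d}", "sex": sex}
        for name in names:
            mean, sd = spec.params[name][sex]
            row[name] = mean
        row[pname] = pval
        rows.append(row)
    df = pd.DataFrame(rows)
    df["ratio_area"] = df["area_vent_mm2"] / df["area_brain_mm2"] * 100.0
    df["ratio_sv"] = df["sv_aq_mm3"] / df["sv_cv_mm3"] * 100.0
    # re-apply injections that target a derived ratio column
    for k, (pname, pval) in enumerate(spec.outlier_injections):
        idx = len(df) - len(spec.outlier_injections) + k
        if pname in ("ratio_area", "ratio_sv"):
            df.loc[df.index[idx], pname] = pval
    return df
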