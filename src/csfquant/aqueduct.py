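"""Aqueductal diameter profiling and Poiseuille hydraulic resistance.

Workflow (all deterministic):

1. maximum intensity projection (MIP) of the slab of slices containing the
   aqueduct,
2. bilinear interpolation of the projection to a fine grid (default
   0.03 x 0.03 mm^2) and binarization at the maximum-gradient threshold of
   a line drawn across the narrowest point, keeping the connected bright
   component under that line,
3. centerline extraction between user start/end points: morphological
   skeleton, shortest path on the skeleton graph, moving-average smoothing,
   uniform arc-length resampling,
4. division of the centerline into ``n_segments`` equal-arc-length
   microchannels; the local diameter D_i is the full chord of the lumen
   mask along the normal at each segment midpoint,
5. segmental resistance by Poiseuille's law for laminar flow in a
   cylindrical duct,

       R_i = 128 * mu * L_i / (pi * D_i**4)   [mPa s / mm^3]

   with L_i, D_i in mm and the dynamic viscosity mu in mPa s (default 0.71,
   water at body temperature), and
6. endpoint standardization: the effective endpoint is the first
   microchannel at which cumulative resistance reaches
   ``endpoint_fraction`` (default 95%) of the total, which suppresses
   operator variability in placing the distal end in the wide,
   low-resistance outlet.

Units contract: mm, mPa s, and mPa s/mm^3 throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

from .core import Volume3D, mm_to_px, px_to_mm
from .morphometry import interpolate_to_resolution, scale_points, threshold_max_gradient

__all__ = [
    "ResistanceParams",
    "Centerline",
    "AqueductProfile",
    "mip_project",
    "binarize_aqueduct",
    "extract_centerline",
    "measure_microchannels",
    "poiseuille_resistance",
    "effective_endpoint",
    "summarize_aqueduct",
    "run_aqueduct",
    "poiseuille_segment_resistance",
    "poiseuille_integral",
]


@dataclass(frozen=True)
class ResistanceParams:
    """Tunable parameters of the resistance computation."""

    mu_mPa_s: float = 0.71
    n_segments: int = 100
    endpoint_fraction: float = 0.95
    target_spacing_mm: float = 0.03
    smooth_window: int = 5
    smooth_passes: int = 8
    tangent_halfstep_mm: float = 0.75

    def __post_init__(self) -> None:
        if self.mu_mPa_s <= 0:
            raise ValueError("viscosity must be positive")
        if self.n_segments < 2:
            raise ValueError("n_segments must be >= 2")
        if not 0.0 < self.endpoint_fraction <= 1.0:
            raise ValueError("endpoint_fraction must be in (0, 1]")


@dataclass
class Centerline:
    """Smoothed, uniformly resampled lumen centerline (mm coordinates)."""

    points_mm: np.ndarray  # (N, 2) as (row_mm, col_mm)
    arc_mm: np.ndarray  # (N,), strictly increasing, arc_mm[0] == 0

    @property
    def length_mm(self) -> float:
        return float(self.arc_mm[-1])

    def at(self, s_mm: np.ndarray | float) -> np.ndarray:
        """Interpolated point(s) at arc length s."""
        r = np.interp(s_mm, self.arc_mm, self.points_mm[:, 0])
        c = np.interp(s_mm, self.arc_mm, self.points_mm[:, 1])
        return np.stack([r, c], axis=-1)

    def tangent(self, s_mm: np.ndarray | float, h_mm: float = 0.1) -> np.ndarray:
        """Unit tangent(s) by central differences along the smoothed path."""
        s = np.atleast_1d(np.asarray(s_mm, dtype=float))
        lo = np.clip(s - h_mm, 0.0, self.length_mm)
        hi = np.clip(s + h_mm, 0.0, self.length_mm)
        d = self.at(hi) - self.at(lo)
        n = np.linalg.norm(d, axis=-1, keepdims=True)
        n[n == 0] = 1.0
        out = d / n
        return out[0] if np.isscalar(s_mm) else out


@dataclass
class AqueductProfile:
    """Microchannel decomposition of the aqueduct plus derived resistances."""

    L_mm: np.ndarray  # (n,) segment lengths
    D_mm: np.ndarray  # (n,) local diameters at segment midpoints
    mu_mPa_s: float
    user_length_mm: float
    R: np.ndarray | None = None  # (n,) segmental resistance, mPa s/mm^3
    cumulative_R: np.ndarray | None = None
    endpoint_index: int | None = None
    effective_length_mm: float | None = None
    effective_R: float | None = None
    total_R: float | None = None
    d_mean_mm: float | None = None
    d_min_mm: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return len(self.L_mm)

    def segment_midpoints_mm(self) -> np.ndarray:
        edges = np.concatenate([[0.0], np.cumsum(self.L_mm)])
        return 0.5 * (edges[:-1] + edges[1:])

    def to_records(self) -> list[dict]:
        """Per-segment rows (i, L_i, D_i, R_i, cumulative_R) for CSV export."""
        out = []
        for i in range(self.n_segments):
            out.append(
                {
                    "i": i,
                    "L_mm": float(self.L_mm[i]),
                    "D_mm": float(self.D_mm[i]),
                    "R_mPa_s_mm3": float(self.R[i]) if self.R is not None else None,
                    "cumulative_R": float(self.cumulative_R[i])
                    if self.cumulative_R is not None
                    else None,
                }
            )
        return out


def poiseuille_segment_resistance(L_mm: float, D_mm: float, mu_mPa_s: float = 0.71) -> float:
    """Closed-form laminar resistance of one cylindrical segment."""
    if D_mm <= 0 or L_mm <= 0:
        raise ValueError("length and diameter must be positive")
    return 128.0 * mu_mPa_s * L_mm / (np.pi * D_mm**4)


def poiseuille_integral(diameter_fn, s0_mm: float, s1_mm: float, mu_mPa_s: float = 0.71, n: int = 100_000) -> float:
    """Dense-quadrature oracle: 128 mu / pi * integral ds / D(s)^4.

    ``diameter_fn`` takes arc length in mm and returns diameter in mm.
    Used in tests as the independent reference for smooth-profile phantoms.
    """
    s = np.linspace(s0_mm, s1_mm, n)
    d = np.array([diameter_fn(v) for v in s], dtype=float)
    return float(128.0 * mu_mPa_s / np.pi * np.trapezoid(1.0 / d**4, s))


# --------------------------------------------------------------------------
# Imaging steps
# --------------------------------------------------------------------------


def mip_project(volume: Volume3D, slab_range: tuple[int, int]) -> tuple[np.ndarray, tuple[float, float]]:
    """Per-pixel maximum across the slab axis (z); returns image + spacing."""
    z0, z1 = slab_range
    if not (0 <= z0 < z1 <= volume.shape[0]):
        raise ValueError(f"empty or out-of-range slab {slab_range}")
    return volume.data[z0:z1].max(axis=0), volume.plane_spacing_mm


def binarize_aqueduct(
    image: np.ndarray,
    spacing_mm: tuple[float, float],
    narrowest_line_px: np.ndarray,
    params: ResistanceParams = ResistanceParams(),
) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Interpolate, threshold at the narrowest-point line, keep the lumen.

    Returns ``(mask, threshold, fine_spacing)`` where ``mask`` is the
    connected bright component containing the midpoint of the line, on the
    interpolated grid.
    """
    fine, t = interpolate_to_resolution(image, spacing_mm, params.target_spacing_mm)
    line = scale_points(np.asarray(narrowest_line_px, dtype=float), spacing_mm, t)
    # gradient smoothing at ~half the source-pixel ramp width puts the
    # steepest point at the half-level of the edge
    thr = threshold_max_gradient(fine, line, smooth_px=0.5 * spacing_mm[0] / t[0])
    bw = fine >= thr
    labels = cc_label(bw, connectivity=2)
    mid = 0.5 * (line[0] + line[-1])
    # search the line for a labeled pixel nearest its midpoint
    n = 64
    cand = np.linspace(line[0], line[-1], n)
    order = np.argsort(np.linalg.norm(cand - mid, axis=1))
    lab = 0
    for j in order:
        r, c = (int(round(cand[j][0])), int(round(cand[j][1])))
        if 0 <= r < bw.shape[0] and 0 <= c < bw.shape[1] and labels[r, c]:
            lab = labels[r, c]
            break
    if lab == 0:
        raise ValueError("no bright component under the narrowest-point line")
    return labels == lab, float(thr), t


def _skeleton_graph(skel: np.ndarray, spacing: tuple[float, float]) -> nx.Graph:
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pix = set(zip(rows.tolist(), cols.tolist()))
    sy, sx = spacing
    for (r, c) in pix:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nb = (r + dr, c + dc)
                if nb in pix:
                    w = float(np.hypot(dr * sy, dc * sx))
                    g.add_edge((r, c), nb, weight=w)
    if not g.nodes and pix:
        g.add_nodes_from(pix)
    return g


def _moving_average(points: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(points) < window:
        return points
    pad = window // 2
    ext = np.vstack([np.repeat(points[:1], pad, axis=0), points, np.repeat(points[-1:], pad, axis=0)])
    kernel = np.ones(window) / window
    sm = np.column_stack(
        [np.convolve(ext[:, j], kernel, mode="valid") for j in range(points.shape[1])]
    )
    # pin endpoints: smoothing must not retract the user-defined ends
    sm[0], sm[-1] = points[0], points[-1]
    return sm


def extract_centerline(
    mask: np.ndarray,
    spacing_mm: tuple[float, float],
    start_px: tuple[float, float],
    end_px: tuple[float, float],
    params: ResistanceParams = ResistanceParams(),
) -> Centerline:
    """Skeleton shortest path between start and end, smoothed and resampled.

    Start/end are given in (row, col) pixels of the mask grid and must lie
    inside (or within one pixel of) the mask; they are projected onto the
    skeleton.  Raises if the mask is disconnected between the two points or
    if start == end.
    """
    start = np.asarray(start_px, dtype=float)
    end = np.asarray(end_px, dtype=float)
    if np.allclose(start, end):
        raise ValueError("start and end points coincide")
    for name, p in (("start", start), ("end", end)):
        r, c = int(round(p[0])), int(round(p[1]))
        r = np.clip(r, 0, mask.shape[0] - 1)
        c = np.clip(c, 0, mask.shape[1] - 1)
        win = mask[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
        if not win.any():
            raise ValueError(f"{name} point lies outside the lumen mask")

    skel = skeletonize(mask)
    if not skel.any():
        raise ValueError("mask has an empty skeleton")
    g = _skeleton_graph(skel, spacing_mm)
    nodes = np.array(list(g.nodes))
    tree = cKDTree(nodes * np.asarray(spacing_mm))
    _, i0 = tree.query(start * np.asarray(spacing_mm))
    _, i1 = tree.query(end * np.asarray(spacing_mm))
    n0, n1 = tuple(nodes[i0]), tuple(nodes[i1])
    if n0 == n1:
        raise ValueError("start and end project to the same skeleton point")
    try:
        path = nx.shortest_path(g, n0, n1, weight="weight")
    except nx.NetworkXNoPath as exc:
        raise ValueError("lumen mask is disconnected between start and end") from exc

    pts_mm = px_to_mm(np.asarray(path, dtype=float), spacing_mm)
    # Resample the (jagged, single-pixel-step) skeleton path to
    # n_segments + 1 uniformly spaced points, then smooth with an iterated
    # 5-sample moving average (the iteration approximates a Gaussian of
    # physical width ~0.5 mm at typical aqueduct lengths).  Skeletons of
    # masks interpolated from coarse voxels wobble at the source-voxel
    # scale; un-smoothed tangents would tilt the diameter chords obliquely
    # and bias every D_i upward.
    d = np.linalg.norm(np.diff(pts_mm, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(d)])
    s = np.linspace(0.0, arc[-1], params.n_segments + 1)
    pts = np.column_stack(
        [np.interp(s, arc, pts_mm[:, 0]), np.interp(s, arc, pts_mm[:, 1])]
    )
    for _ in range(max(params.smooth_passes, 1)):
        pts = _moving_average(pts, params.smooth_window)
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(d)])
    if arc[-1] <= 0:
        raise ValueError("degenerate centerline after smoothing")
    return Centerline(pts, arc)


def _chord_half_length(
    maskf: np.ndarray,
    spacing: tuple[float, float],
    point_mm: np.ndarray,
    direction: np.ndarray,
    step_mm: float,
    max_steps: int = 4000,
) -> float:
    """March from an interior point along ``direction`` to the 0.5 crossing.

    The binary mask is sampled bilinearly, so the boundary is located with
    sub-step linear refinement.
    """
    ts = step_mm * np.arange(1, max_steps + 1)
    pts = point_mm[None, :] + ts[:, None] * direction[None, :]
    idx = mm_to_px(pts, spacing)
    vals = map_coordinates(maskf, [idx[:, 0], idx[:, 1]], order=1, mode="constant", cval=0.0)
    below = np.nonzero(vals < 0.5)[0]
    if len(below) == 0:
        raise ValueError("chord march did not exit the mask (max_steps exceeded)")
    k = below[0]
    v_prev = (
        float(map_coordinates(maskf, [[mm_to_px(point_mm, spacing)[0, 0]], [mm_to_px(point_mm, spacing)[0, 1]]], order=1)[0])
        if k == 0
        else float(vals[k - 1])
    )
    t_prev = 0.0 if k == 0 else float(ts[k - 1])
    v_cur = float(vals[k])
    frac = (v_prev - 0.5) / max(v_prev - v_cur, 1e-12)
    return t_prev + (float(ts[k]) - t_prev) * frac


def measure_microchannels(
    centerline: Centerline,
    mask: np.ndarray,
    spacing_mm: tuple[float, float],
    params: ResistanceParams = ResistanceParams(),
) -> AqueductProfile:
    """Split the centerline into equal-arc microchannels and measure D_i.

    D_i is the full chord of the mask along the normal to the centerline at
    each segment midpoint, found by bilinear sampling of the mask at the
    fine-grid spacing with sub-step crossing refinement.  L_i = total arc
    length / n_segments, so sum(L_i) equals the centerline length exactly.
    """
    n = params.n_segments
    total = centerline.length_mm
    if total <= 0:
        raise ValueError("degenerate centerline")
    L = np.full(n, total / n)
    mids = (np.arange(n) + 0.5) * total / n
    maskf = np.asarray(mask, dtype=float)
    step = params.target_spacing_mm
    D = np.empty(n)
    for i, s in enumerate(mids):
        p = centerline.at(s)
        tang = centerline.tangent(s, h_mm=params.tangent_halfstep_mm)
        normal = np.array([-tang[1], tang[0]])
        ctr_val = float(
            map_coordinates(maskf, [[mm_to_px(p, spacing_mm)[0, 0]], [mm_to_px(p, spacing_mm)[0, 1]]], order=1)[0]
        )
        if ctr_val < 0.5:
            raise ValueError(f"segment {i}: midpoint outside the lumen (D_i = 0)")
        plus = _chord_half_length(maskf, spacing_mm, p, normal, step)
        minus = _chord_half_length(maskf, spacing_mm, p, -normal, step)
        D[i] = plus + minus
        if D[i] <= 0:
            raise ValueError(f"segment {i}: zero diameter")
    return AqueductProfile(L, D, params.mu_mPa_s, user_length_mm=total)


def poiseuille_resistance(profile: AqueductProfile, params: ResistanceParams = ResistanceParams()) -> AqueductProfile:
    """Fill R_i = 128 mu L_i / (pi D_i^4) and the cumulative-resistance curve."""
    if np.any(profile.D_mm <= 0):
        raise ValueError("diameters must be positive")
    R = 128.0 * params.mu_mPa_s * profile.L_mm / (np.pi * profile.D_mm**4)
    out = replace(profile)
    out.mu_mPa_s = params.mu_mPa_s
    out.R = R
    out.cumulative_R = np.cumsum(R)
    out.total_R = float(out.cumulative_R[-1])
    return out


def effective_endpoint(profile: AqueductProfile, params: ResistanceParams = ResistanceParams()) -> AqueductProfile:
    """Standardize the distal endpoint at the cumulative-resistance cutoff.

    The endpoint is the smallest microchannel index whose cumulative
    resistance reaches ``endpoint_fraction * total_R`` (ties resolved by
    the >= comparison, i.e. the first index attaining the bound).
    """
    if profile.cumulative_R is None:
        raise ValueError("run poiseuille_resistance first")
    cum = profile.cumulative_R
    target = params.endpoint_fraction * cum[-1]
    idx = int(np.searchsorted(cum, target - 1e-12 * cum[-1]))
    idx = min(idx, len(cum) - 1)
    out = replace(profile)
    out.endpoint_index = idx
    edges = np.concatenate([[0.0], np.cumsum(profile.L_mm)])
    out.effective_length_mm = float(edges[idx + 1])
    out.effective_R = float(cum[idx])
    out.total_R = float(cum[-1])
    out.d_mean_mm = float(np.mean(profile.D_mm[: idx + 1]))
    out.d_min_mm = float(np.min(profile.D_mm[: idx + 1]))
    return out


def summarize_aqueduct(profile: AqueductProfile) -> dict:
    """Reported record: resistance over the effective length + morphometrics."""
    if profile.endpoint_index is None:
        raise ValueError("profile is incomplete: run effective_endpoint first")
    return {
        "resistance_mPa_s_mm3": profile.effective_R,
        "user_length_mm": profile.user_length_mm,
        "effective_length_mm": profile.effective_length_mm,
        "d_mean_mm": profile.d_mean_mm,
        "d_min_mm": profile.d_min_mm,
    }


def run_aqueduct(
    volume: Volume3D,
    slab_range: tuple[int, int],
    narrowest_line_px: np.ndarray,
    start_px: tuple[float, float],
    end_px: tuple[float, float],
    params: ResistanceParams = ResistanceParams(),
) -> tuple[AqueductProfile, dict]:
    """Full pipeline from a morphological volume to the summary record.

    Landmarks (``narrowest_line_px``, ``start_px``, ``end_px``) are given
    in 0-based pixels of the original projection grid and are rescaled
    internally to the interpolated grid.
    """
    img, spacing = mip_project(volume, slab_range)
    mask, thr, fine_spacing = binarize_aqueduct(img, spacing, narrowest_line_px, params)
    start = scale_points(np.asarray(start_px, dtype=float), spacing, fine_spacing)[0]
    end = scale_points(np.asarray(end_px, dtype=float), spacing, fine_spacing)[0]
    cl = extract_centerline(mask, fine_spacing, tuple(start), tuple(end), params)
    prof = measure_microchannels(cl, mask, fine_spacing, params)
    prof = poiseuille_resistance(prof, params)
    prof = effective_endpoint(prof, params)
    prof.meta.update({"threshold": thr, "centerline_points": cl.points_mm})
    return prof, summarize_aqueduct(prof)


def plot_profile(profile: AqueductProfile, path) -> None:
    """Basic three-panel profile figure: D_i, R_i, cumulative R vs position."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = profile.segment_midpoints_mm()
    fig, axes = plt.subplots(3, 1, figsize=(6, 8), sharex=True)
    axes[0].plot(x, profile.D_mm)
    axes[0].set_ylabel("diameter (mm)")
    if profile.R is not None:
        axes[1].plot(x, profile.R)
        axes[1].set_ylabel("R_i (mPa s/mm$^3$)")
        axes[2].plot(x, profile.cumulative_R)
        axes[2].set_ylabel("cumulative R")
        if profile.effective_length_mm is not None:
            axes[2].axvline(profile.effective_length_mm, ls="--", color="k")
    axes[2].set_xlabel("arc length (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
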