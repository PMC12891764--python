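"""Per-subject orchestration and cohort aggregation.

A *subject* is a directory of NIfTI volumes plus JSON landmark/ROI files
(the scripted stand-ins for the protocol's manual inputs):

* ``t1.nii`` + ``t1_rois.json`` — axial T1-like stack and per-slice
  ventricle/brain ROIs;
* ``bffe.nii`` + ``bffe_landmarks.json`` — aqueduct morphological volume
  with slab range, narrowest-point line, and start/end points (0-based
  pixel coordinates of the projection grid);
* ``cine_aq_mag.nii`` / ``cine_aq_vel.nii`` + ``cine_aq.json`` (and the
  same for ``cine_cv``) — cine phase-contrast magnitude/velocity stacks
  with VENC, cycle duration, pixel area, and seed pixel.

``run_subject`` composes the three measurement modules into one row of the
cohort table; ``run_cohort`` applies the exclusion cascade (stage failure,
>10% cardiac-cycle mismatch, 3xIQR screening — in that order), then the
summaries, sex comparisons, and Spearman correlation matrix.  Every
exclusion is logged with its reason, and identical inputs + config produce
identical reports.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aqueduct, cohort_stats, flow, morphometry, phantoms
from .core import Volume3D, load_json, load_volume, save_json, save_volume

log = logging.getLogger("csfquant")

__all__ = [
    "RunConfig",
    "SubjectRecord",
    "make_phantom_subject",
    "make_phantom_cohort",
    "run_subject",
    "run_cohort",
]

REPORT_COLUMNS = [
    "area_vent_mm2",
    "area_brain_mm2",
    "ratio_area",
    "user_length_mm",
    "effective_length_mm",
    "d_min_mm",
    "d_mean_mm",
    "resistance",
    "cycle_ms",
    "sv_aq_mm3",
    "sv_cv_mm3",
    "ratio_sv",
]

MATRIX_COLUMNS = [
    "resistance",
    "area_vent_mm2",
    "area_brain_mm2",
    "ratio_area",
    "cycle_ms",
    "sv_aq_mm3",
    "sv_cv_mm3",
    "ratio_sv",
    "age_years",
]


@dataclass
class RunConfig:
    """All tunables of a cohort run, serializable to one YAML file."""

    resistance: aqueduct.ResistanceParams = field(default_factory=aqueduct.ResistanceParams)
    flow: flow.FlowConfig = field(default_factory=flow.FlowConfig)
    morph_target_spacing_mm: float = 0.1
    outlier_rule: cohort_stats.OutlierRule = field(default_factory=cohort_stats.OutlierRule)
    mismatch_limit_pct: float = 10.0
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["outlier_rule"]["columns"] = list(d["outlier_rule"]["columns"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        rule = d.get("outlier_rule", {})
        if "columns" in rule:
            rule["columns"] = tuple(rule["columns"])
        return cls(
            resistance=aqueduct.ResistanceParams(**d.get("resistance", {})),
            flow=flow.FlowConfig(**d.get("flow", {})),
            morph_target_spacing_mm=d.get("morph_target_spacing_mm", 0.1),
            outlier_rule=cohort_stats.OutlierRule(**rule),
            mismatch_limit_pct=d.get("mismatch_limit_pct", 10.0),
            seed=d.get("seed", 0),
            log_level=d.get("log_level", "INFO"),
        )


@dataclass
class SubjectRecord:
    """One manifest row: identity plus paths to the subject's files."""

    id: str
    sex: str
    age_years: float
    path: Path  # subject directory

    @classmethod
    def from_row(cls, row) -> "SubjectRecord":
        return cls(str(row["id"]), str(row["sex"]), float(row["age_years"]), Path(row["path"]))


# --------------------------------------------------------------------------
# Phantom subjects on disk
# --------------------------------------------------------------------------


def _aqueduct_diameter_fn(d_base: float, d_min: float, pad_mm: float, length_mm: float):
    """Aqueduct-like profile: localized narrowing near the proximal end."""
    total = length_mm
    center = (pad_mm + 0.25 * (total - 2 * pad_mm)) / total
    width = 0.10
    depth = d_base - d_min

    def fn(s: float) -> float:
        return d_base - depth * math.exp(-(((s - center) / width) ** 2))

    return fn


def make_phantom_subject(
    out_dir: str | Path,
    subject_id: str,
    sex: str,
    seed: int,
    cycle_mismatch_pct: float = 0.0,
    resistance_scale: float = 1.0,
) -> dict:
    """Generate one synthetic subject's images + landmarks on disk.

    Anatomy and flow amplitudes are drawn around sex-specific population
    scales; the ground truth of every phantom is written to JSON sidecars.
    ``cycle_mismatch_pct`` plants a cardiac-cycle disagreement between the
    two cine series (for QC tests); ``resistance_scale`` shrinks all
    aqueduct diameters by ``scale**(-1/4)`` to plant resistance outliers.
    """
    rng = np.random.default_rng(seed)
    out = Path(out_dir) / subject_id
    out.mkdir(parents=True, exist_ok=True)
    male = sex == "male"
    age = float(np.clip(rng.normal(26.2 if male else 24.2, 4.0), 19, 35))

    # --- T1-like brain stack
    brain_f = rng.normal(1.0, 0.04)
    vent_f = float(np.clip(rng.normal(1.0 if not male else 0.88, 0.12), 0.5, 1.3))
    bspec = phantoms.BrainPhantomSpec(
        brain_axes_mm=(70.0 * brain_f, 55.0 * brain_f),
        vent_axes_mm=(13.0 * vent_f, 6.5 * vent_f),
        vent_offset_mm=(0.0, 9.0),
        plexus_radius_mm=1.2 * vent_f,
        n_slices=5,
        peak_slice=2,
        noise_sd=2.0,
        seed=int(rng.integers(2**31 - 1)),
    )
    bvol = phantoms.generate_brain_slice(bspec)
    save_volume(bvol, out / "t1.nii")
    rois = phantoms.brain_default_rois(bspec, bvol)
    save_json(
        {
            "slices": {
                str(k): {
                    "vent_roi": rois["vent_roi"].tolist(),
                    "brain_roi": rois["brain_roi"].tolist(),
                    "line": rois["line"].tolist(),
                }
                for k in range(bspec.n_slices)
            }
        },
        out / "t1_rois.json",
    )

    # --- aqueduct morphological volume
    pad = 2.0
    d_base = float(np.clip(rng.normal(2.0 if male else 1.8, 0.15), 1.4, 2.6))
    d_min = float(np.clip(rng.normal(1.3 if male else 1.2, 0.12), 0.9, d_base - 0.3))
    scale = resistance_scale ** (-0.25)
    user_len = float(np.clip(rng.normal(16.6 if male else 14.2, 2.0), 10.0, 20.0))
    length = user_len + 2 * pad
    tspec = phantoms.TubePhantomSpec(
        length_mm=length,
        diameter_fn=_scaled(_aqueduct_diameter_fn(d_base, d_min, pad, length), scale),
        tilt_deg=float(rng.uniform(4.0, 12.0)),
        bend_deg=float(rng.uniform(-30.0, 30.0)),
        voxel_spacing_mm=0.15,
        noise_sd=2.0,
        seed=int(rng.integers(2**31 - 1)),
    )
    tvol = phantoms.generate_tube_volume(tspec)
    save_volume(tvol, out / "bffe.nii")
    sp = tvol.plane_spacing_mm
    from .core import mm_to_px

    start = mm_to_px(phantoms.tube_point_mm(tvol, pad), sp)[0]
    end = mm_to_px(phantoms.tube_point_mm(tvol, pad + user_len), sp)[0]
    narrow_arc = pad + 0.25 * user_len
    mid = phantoms.tube_point_mm(tvol, narrow_arc)
    tang = (
        phantoms.tube_point_mm(tvol, narrow_arc + 0.5)
        - phantoms.tube_point_mm(tvol, narrow_arc - 0.5)
    )
    tang /= np.linalg.norm(tang)
    normal = np.array([-tang[1], tang[0]])
    line = mm_to_px(np.array([mid - 2.5 * normal, mid + 2.5 * normal]), sp)
    save_json(
        {
            "slab": [0, tvol.shape[0]],
            "line": line.tolist(),
            "start": start.tolist(),
            "end": end.tolist(),
        },
        out / "bffe_landmarks.json",
    )

    # --- cine series at the two sites
    cycle = float(np.clip(rng.normal(862 if male else 788, 120), 600, 1100))
    cycle_cv = cycle * (1.0 - cycle_mismatch_pct / 100.0 / (1 + cycle_mismatch_pct / 200.0))
    amp_aq = float(np.clip(rng.normal(2.6 if male else 2.0, 0.5), 0.8, 4.5))
    amp_cv = float(np.clip(rng.normal(3.6, 0.6), 1.5, 5.5))
    r_cv = float(np.clip(rng.normal(4.5, 0.3), 3.5, 5.5))
    for site, spec in {
        "aq": phantoms.CinePhantomSpec(
            cycle_ms=cycle,
            lumen_radius_mm=d_base / 2 * 1.25,
            waveform=phantoms.sine_waveform(amp_aq),
            venc_cms=10.0,
            background_offset_cms=float(rng.normal(0.0, 0.25)),
            noise_sd_cms=0.2,
            voxel_spacing_mm=0.35,
            seed=int(rng.integers(2**31 - 1)),
        ),
        "cv": phantoms.CinePhantomSpec(
            cycle_ms=cycle_cv,
            lumen_radius_mm=r_cv,
            waveform=phantoms.sine_waveform(amp_cv),
            venc_cms=10.0,
            background_offset_cms=float(rng.normal(0.0, 0.25)),
            noise_sd_cms=0.2,
            voxel_spacing_mm=0.5,
            seed=int(rng.integers(2**31 - 1)),
        ),
    }.items():
        ser = phantoms.generate_cine_series(spec)
        save_volume(
            Volume3D(ser.magnitude, (1.0, spec.voxel_spacing_mm, spec.voxel_spacing_mm)),
            out / f"cine_{site}_mag.nii",
        )
        save_volume(
            Volume3D(ser.velocity_cms, (1.0, spec.voxel_spacing_mm, spec.voxel_spacing_mm)),
            out / f"cine_{site}_vel.nii",
        )
        save_json(
            {
                "venc_cms": spec.venc_cms,
                "cycle_ms": spec.cycle_ms,
                "pixel_area_mm2": spec.voxel_spacing_mm**2,
                "seed_pixel": ser.meta["seed_pixel"],
                "positive_direction_label": "fourth-to-third-ventricle"
                if site == "aq"
                else "caudo-cranial",
                "ground_truth": {
                    "sv_mm3": ser.meta["sv_mm3"],
                    "background_offset_cms": spec.background_offset_cms,
                },
            },
            out / f"cine_{site}.json",
        )

    return {"id": subject_id, "sex": sex, "age_years": round(age, 1), "path": str(out)}


def _scaled(fn, scale: float):
    def wrapped(s: float) -> float:
        return fn(s) * scale

    return wrapped


def make_phantom_cohort(
    out_dir: str | Path,
    n_per_group: int = 5,
    seed: int = 0,
    n_mismatch: int = 0,
    n_resistance_outliers: int = 0,
) -> pd.DataFrame:
    """Write a whole phantom cohort and its manifest CSV.

    The last ``n_mismatch`` subjects get a planted >10% cardiac-cycle
    mismatch and the ``n_resistance_outliers`` before them get a planted
    high-resistance aqueduct, for exercising the exclusion cascade.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    total = 2 * n_per_group
    for i in range(total):
        sex = "male" if i < n_per_group else "female"
        k = total - i  # countdown: plant on the tail of the cohort
        mismatch = 14.0 if k <= n_mismatch else 0.0
        rscale = 5.0 if (n_mismatch < k <= n_mismatch + n_resistance_outliers) else 1.0
        rows.append(
            make_phantom_subject(
                out,
                f"sub{i + 1:03d}",
                sex,
                seed=int(rng.integers(2**31 - 1)),
                cycle_mismatch_pct=mismatch,
                resistance_scale=rscale,
            )
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


# --------------------------------------------------------------------------
# Running subjects and cohorts
# --------------------------------------------------------------------------


def _load_cine(subj: Path, site: str) -> tuple[phantoms.CinePCSeries, tuple[int, int]]:
    meta = load_json(subj / f"cine_{site}.json")
    mag = load_volume(subj / f"cine_{site}_mag.nii").data
    vel = load_volume(subj / f"cine_{site}_vel.nii").data
    ser = phantoms.CinePCSeries(
        mag,
        vel,
        float(meta["venc_cms"]),
        float(meta["cycle_ms"]),
        float(meta["pixel_area_mm2"]),
        meta.get("positive_direction_label", ""),
        meta,
    )
    return ser, tuple(int(v) for v in meta["seed_pixel"])


def run_subject(record: SubjectRecord, config: RunConfig) -> dict:
    """Process one subject through all three pipelines.

    Any stage failure marks the row ``failed`` with the stage name and the
    cohort run continues with the next subject.
    """
    row: dict = {"id": record.id, "sex": record.sex, "age_years": record.age_years}
    subj = Path(record.path)
    stage = "morphometry"
    try:
        t1 = load_volume(subj / "t1.nii")
        rois = load_json(subj / "t1_rois.json")["slices"]
        per_slice = {int(k): v for k, v in rois.items()}
        k, res = morphometry.select_max_ratio_slice(
            t1, per_slice, config.morph_target_spacing_mm
        )
        row.update(
            {
                "slice_index": k,
                "area_vent_mm2": res.area_vent_mm2,
                "area_brain_mm2": res.area_brain_mm2,
                "ratio_area": res.ratio_area * 100.0,
                "morph_threshold": res.threshold_used,
            }
        )

        stage = "aqueduct"
        bffe = load_volume(subj / "bffe.nii")
        lm = load_json(subj / "bffe_landmarks.json")
        profile, summary = aqueduct.run_aqueduct(
            bffe,
            tuple(lm["slab"]),
            np.asarray(lm["line"], dtype=float),
            tuple(lm["start"]),
            tuple(lm["end"]),
            config.resistance,
        )
        row.update(
            {
                "resistance": summary["resistance_mPa_s_mm3"],
                "user_length_mm": summary["user_length_mm"],
                "effective_length_mm": summary["effective_length_mm"],
                "d_mean_mm": summary["d_mean_mm"],
                "d_min_mm": summary["d_min_mm"],
            }
        )

        stage = "flow"
        ser_aq, seed_aq = _load_cine(subj, "aq")
        ser_cv, seed_cv = _load_cine(subj, "cv")
        res_aq = flow.process_cine(ser_aq, seed_aq, config.flow)
        res_cv = flow.process_cine(ser_cv, seed_cv, config.flow)
        rsv = flow.ratio_sv(
            res_aq["sv"],
            res_cv["sv"],
            res_aq["cycle_ms"],
            res_cv["cycle_ms"],
            config.mismatch_limit_pct,
        )
        row.update(
            {
                "sv_aq_mm3": rsv.sv_aq_mm3,
                "sv_cv_mm3": rsv.sv_cv_mm3,
                "ratio_sv": rsv.ratio_pct,
                "cycle_ms": 0.5 * (res_aq["cycle_ms"] + res_cv["cycle_ms"]),
                "cycle_mismatch_pct": rsv.cycle_mismatch_pct,
                "mismatch_flag": rsv.flagged,
                "offset_aq_cms": res_aq["background_offset_cms"],
                "offset_cv_cms": res_cv["background_offset_cms"],
            }
        )
        row["failed"] = False
        row["failed_stage"] = ""
    except Exception as exc:  # noqa: BLE001 - per-subject fault isolation
        log.warning("subject %s failed at stage %s: %s", record.id, stage, exc)
        row["failed"] = True
        row["failed_stage"] = stage
        row["error"] = str(exc)
    return row


def run_cohort(
    manifest: pd.DataFrame,
    config: RunConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Per-subject processing + exclusion cascade + cohort statistics.

    Exclusion order (fixed): imaging/stage failure, then cardiac-cycle
    mismatch QC, then one-pass 3xIQR screening on the core parameters.
    Returns a dict with the subject table, exclusion log, Table-1-style
    report, and Spearman matrices; optionally writes everything to
    ``out_dir``.
    """
    rows = [run_subject(SubjectRecord.from_row(r), config) for _, r in manifest.iterrows()]
    table = pd.DataFrame(rows)
    exclusions: list[dict] = []

    ok = table[~table["failed"]].copy()
    for _, r in table[table["failed"]].iterrows():
        exclusions.append({"id": r["id"], "reason": f"stage_failure:{r['failed_stage']}"})

    if "mismatch_flag" in ok.columns:
        for _, r in ok[ok["mismatch_flag"].astype(bool)].iterrows():
            exclusions.append(
                {"id": r["id"], "reason": f"cycle_mismatch:{r['cycle_mismatch_pct']:.1f}%"}
            )
        ok = ok[~ok["mismatch_flag"].astype(bool)]

    if len(ok):
        kept, iqr_log = cohort_stats.exclude_outliers(ok, config.outlier_rule)
        for e in iqr_log:
            exclusions.append(
                {"id": e["id"], "reason": f"iqr_outlier:{e['column']}={e['value']:.3g}"}
            )
    else:
        kept = ok

    result: dict = {
        "subjects": table,
        "analyzed": kept,
        "exclusions": exclusions,
        "n_analyzed": int(len(kept)),
    }
    if len(kept) >= 4:
        cols = [c for c in REPORT_COLUMNS if c in kept.columns]
        result["report"] = cohort_stats.cohort_report(kept, cols)
        mcols = [c for c in MATRIX_COLUMNS if c in kept.columns]
        rho, pmat, stars = cohort_stats.correlation_matrix(kept, mcols)
        result["correlation"] = {"rho": rho, "p": pmat, "stars": stars}
    else:
        cols = [c for c in REPORT_COLUMNS if c in kept.columns]
        result["report"] = {
            "n_total": int(len(kept)),
            "parameters": {
                c: {"total": cohort_stats.summarize(kept[c]).rounded()}
                for c in cols
                if kept[c].notna().sum() >= 2
            },
            "tests_suppressed": True,
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "subjects.csv", index=False)
        kept.to_csv(out / "analyzed.csv", index=False)
        save_json({"exclusions": exclusions, "report": result["report"]}, out / "report.json")
        if "correlation" in result:
            result["correlation"]["rho"].to_csv(out / "correlation_rho.csv")
            result["correlation"]["p"].to_csv(out / "correlation_p.csv")
        with open(out / "run.log", "w") as fh:
            for e in exclusions:
                fh.write(f"excluded {e['id']}: {e['reason']}\n")
            fh.write(f"analyzed {len(kept)} subjects\n")
    return result
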