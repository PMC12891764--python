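"""Shared phantom fixtures.

Expensive phantom-pipeline runs are session-scoped so the same computation
backs both the unit tests and the end-to-end recovery checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from csfquant import aqueduct, phantoms
from csfquant.core import mm_to_px

PAD_MM = 2.0
SECTION_MM = 15.0


def tube_landmarks(vol):
    """Start/end/narrowest-line pixel landmarks for a padded tube phantom."""
    sp = vol.plane_spacing_mm
    start = mm_to_px(phantoms.tube_point_mm(vol, PAD_MM), sp)[0]
    end = mm_to_px(phantoms.tube_point_mm(vol, PAD_MM + SECTION_MM), sp)[0]
    mid = phantoms.tube_point_mm(vol, PAD_MM + 0.1 * SECTION_MM)
    line = mm_to_px(np.array([mid + [-2.5, 0.25], mid + [2.5, -0.25]]), sp)
    return line, tuple(start), tuple(end)


def run_tube(vol, params=None):
    params = params or aqueduct.ResistanceParams()
    line, start, end = tube_landmarks(vol)
    return aqueduct.run_aqueduct(vol, (0, vol.shape[0]), line, start, end, params)


@pytest.fixture(scope="session")
def cylinder_volume():
    """Uniform tube D=2 mm over a 19 mm lumen (15 mm measured section)."""
    spec = phantoms.TubePhantomSpec(
        length_mm=PAD_MM + SECTION_MM + PAD_MM,
        diameter_fn=lambda s: 2.0,
        tilt_deg=7.0,
        voxel_spacing_mm=0.15,
    )
    return phantoms.generate_tube_volume(spec)


@pytest.fixture(scope="session")
def cylinder_run(cylinder_volume):
    return run_tube(cylinder_volume)


def taper_diameter(arc_mm: float) -> float:
    """D = 1 + 0.5 u over the measured section, clamped in the end pads."""
    return 1.0 + 0.5 * float(np.clip((arc_mm - PAD_MM) / SECTION_MM, 0.0, 1.0))


@pytest.fixture(scope="session")
def taper_volume():
    total = PAD_MM + SECTION_MM + PAD_MM
    spec = phantoms.TubePhantomSpec(
        length_mm=total,
        diameter_fn=lambda s: taper_diameter(s * total),
        tilt_deg=7.0,
        voxel_spacing_mm=0.15,
    )
    return phantoms.generate_tube_volume(spec)


@pytest.fixture(scope="session")
def taper_run(taper_volume):
    return run_tube(taper_volume)


@pytest.fixture(scope="session")
def brain_phantom():
    spec = phantoms.BrainPhantomSpec(vent_axes_mm=(10.0, 4.0), vent_offset_mm=(0.0, 7.0))
    return spec, phantoms.generate_brain_slice(spec)


@pytest.fixture(scope="session")
def cine_clean():
    """Noisy but unaliased aqueduct-like series with a known 0.5 cm/s offset."""
    spec = phantoms.CinePhantomSpec(
        lumen_radius_mm=2.0,
        waveform=phantoms.sine_waveform(2.5),
        cycle_ms=800.0,
        background_offset_cms=0.5,
        noise_sd_cms=0.2,
        seed=7,
    )
    return spec, phantoms.generate_cine_series(spec)
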