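"""Shared phantom fixtures.

Volumes are generated at reduced axial/lateral sampling but with the real
temporal protocol: 5 repeats per slow position and a 6.4 ms frame interval
(512 A-scans at 80 kHz, absorbed into duty_cycle), so phase dynamics and
heart-rate recovery run under the study's timing.
"""

import numpy as np
import pytest

from retipulse import (
    VesselSpec,
    compensate_bulk,
    estimate_heart_rate,
    frame_phase_difference,
    generate_phantom,
    phase_to_displacement,
    segment_volume,
)
from retipulse.pipeline import small_test_geometry, small_test_phantom


@pytest.fixture(scope="session")
def geo_small():
    return small_test_geometry()


@pytest.fixture(scope="session")
def static_phantom():
    """Noiseless, motionless phantom: every inter-repeat phase difference is 0."""
    cfg = small_test_phantom(
        small_test_geometry(n_slow_positions=8),
        snr_db=np.inf,
        pulsation_amplitude_ilm_nm=0.0,
        seed=0,
    )
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def pulsatile_chain():
    """A 150-position pulsating phantom processed through the phase chain."""
    g = small_test_geometry(n_slow_positions=150)
    cfg = small_test_phantom(g, heart_rate_bpm=480.0, bulk_motion_sd=0.3, seed=5)
    vol, truth = generate_phantom(cfg)
    seg = segment_volume(vol)
    comp = compensate_bulk(frame_phase_difference(vol), seg)
    hr = estimate_heart_rate(comp, seg)
    ds = phase_to_displacement(comp, g.lambda0_nm, g.refractive_index)
    return {"volume": vol, "truth": truth, "seg": seg, "comp": comp, "hr": hr, "ds": ds}


VESSELS = (
    VesselSpec(center_slow=14.0, center_fast=20.0, radius_um=100.0, thickness_bump_um=4.65),
    VesselSpec(center_slow=30.0, center_fast=44.0, radius_um=80.0, thickness_bump_um=3.10),
)


@pytest.fixture(scope="session")
def vessel_chain():
    """A 48x64 phantom with two superficial vessels, segmented."""
    g = small_test_geometry(n_slow_positions=48, n_fast=64)
    cfg = small_test_phantom(g, vessels=VESSELS, seed=7)
    vol, truth = generate_phantom(cfg)
    seg = segment_volume(vol)
    return {"volume": vol, "truth": truth, "seg": seg, "geometry": g}
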