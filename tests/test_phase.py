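"""Phase dynamics: differencing, bulk referencing, displacement, HR, MAV."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retipulse import (
    OCTVolume,
    compensate_bulk,
    compute_mav,
    estimate_heart_rate,
    frame_phase_difference,
    generate_phantom,
    intensity_mask,
    mav_enface_at_surface,
    phase_to_displacement,
    segment_volume,
)
from retipulse.phase import _rpe_baseline
from retipulse.pipeline import small_test_geometry, small_test_phantom
from retipulse.volume import AcquisitionGeometry


def test_static_noiseless_phase_difference_is_exactly_zero(static_phantom):
    vol, _ = static_phantom
    pds = frame_phase_difference(vol)
    np.testing.assert_array_equal(pds.dphi, 0.0)


def test_uniform_displacement_matches_closed_form_phase():
    """A hand-built two-frame volume with uniform displacement d gives
    dphi = 4*pi*n*d/lambda0 everywhere (mod 2*pi)."""
    g = AcquisitionGeometry(
        n_slow_positions=1, n_repeats=2, n_fast=24, n_depth=40, lambda0_nm=840.0
    )
    rng = np.random.default_rng(0)
    d_nm = 30.0
    k = 4 * np.pi * g.refractive_index / g.lambda0_nm
    phi0 = rng.uniform(-np.pi, np.pi, (g.n_depth, g.n_fast))
    c1 = np.exp(1j * phi0)
    c2 = np.exp(1j * (phi0 + k * d_nm))
    vol = OCTVolume(
        co=np.stack([c1, c2]).astype(np.complex128),
        cross=np.stack([c1, c2]).astype(np.complex128) * 0.05,
        geometry=g,
    )
    pds = frame_phase_difference(vol)
    np.testing.assert_allclose(pds.dphi, k * d_nm, atol=1e-6)


def test_single_repeat_volume_rejected():
    g = AcquisitionGeometry(n_slow_positions=2, n_repeats=1, n_fast=4, n_depth=8)
    z = np.zeros((g.n_frames, g.n_depth, g.n_fast), dtype=np.complex64)
    with pytest.raises(ValueError, match="repeat"):
        frame_phase_difference(OCTVolume(co=z, cross=z, geometry=g))


def test_phasor_smoothing_reduces_circular_variance():
    cfg = small_test_phantom(small_test_geometry(n_slow_positions=4), snr_db=15.0, seed=2)
    vol, truth = generate_phantom(cfg)
    r = vol.geometry.n_repeats
    block = vol.co[:r].astype(np.complex128)
    herm = block[1:] * np.conj(block[:-1])
    pds = frame_phase_difference(vol)
    tissue = slice(int(truth.ilm[0, 0]) + 5, int(truth.isos[0, 0]) - 5)

    def circ_var(ph):
        return 1.0 - np.abs(np.exp(1j * ph).mean())

    naive = circ_var(np.angle(herm[0, tissue]))
    smoothed = circ_var(pds.dphi[0, 0, tissue])
    assert smoothed < naive


def test_bulk_phase_injection_leaves_compensated_phase_invariant():
    """Arbitrary per-frame global phase changes nothing after RPE referencing."""
    g = small_test_geometry(n_slow_positions=10)
    cfg = small_test_phantom(g, seed=5)
    vol, _ = generate_phantom(cfg)
    rng = np.random.default_rng(99)
    beta = np.exp(1j * rng.uniform(-np.pi, np.pi, g.n_frames))
    vol2 = OCTVolume(
        co=(vol.co.astype(np.complex128) * beta[:, None, None]).astype(vol.co.dtype),
        cross=(vol.cross.astype(np.complex128) * beta[:, None, None]).astype(vol.cross.dtype),
        geometry=g,
    )
    seg1, seg2 = segment_volume(vol), segment_volume(vol2)
    c1 = compensate_bulk(frame_phase_difference(vol), seg1)
    c2 = compensate_bulk(frame_phase_difference(vol2), seg2)
    rel = np.linalg.norm(c1.dphi - c2.dphi) / np.linalg.norm(c1.dphi)
    assert rel < 1e-6


def test_bulk_motion_compensated_to_zero_on_static_phantom():
    """On a motionless phantom with strong bulk phase jitter, compensation
    leaves only the SNR-determined phase-noise residual: the same level as a
    bulk-free twin, and small in absolute terms."""
    residuals = []
    for bulk_sd in (0.8, 0.0):
        cfg = small_test_phantom(
            small_test_geometry(n_slow_positions=6),
            pulsation_amplitude_ilm_nm=0.0,
            bulk_motion_sd=bulk_sd,
            seed=6,
        )
        vol, truth = generate_phantom(cfg)
        seg = segment_volume(vol)
        comp = compensate_bulk(frame_phase_difference(vol), seg)
        band = slice(int(truth.ilm[0, 0]), int(truth.rpe[0, 0]))
        residuals.append(np.abs(comp.dphi[:, :, band, :]).mean())
    with_bulk, without_bulk = residuals
    assert with_bulk < 0.05  # rad; ~2.5 nm at 840 nm / n = 1.35
    assert with_bulk == pytest.approx(without_bulk, rel=0.15)


def test_compensated_rpe_baseline_is_zero_by_construction(pulsatile_chain):
    comp, seg = pulsatile_chain["comp"], pulsatile_chain["seg"]
    for s in (0, comp.n_slow // 2):
        baseline = _rpe_baseline(comp.raw_products[s], seg.rpe[s])
        np.testing.assert_allclose(np.angle(baseline), 0.0, atol=1e-9)


@pytest.mark.filterwarnings("ignore::RuntimeWarning")  # pi is at the wrap limit
def test_displacement_printed_constants():
    """dphi = pi, lambda0 = 840 nm, n = 1.35 -> dd = 840/(4*1.35) nm."""
    ds = phase_to_displacement(np.array([np.pi]), 840.0, 1.35)
    assert ds.dd_nm[0] == pytest.approx(840.0 / (4 * 1.35), rel=1e-12)
    assert phase_to_displacement(np.array([0.0]), 840.0, 1.35).dd_nm[0] == 0.0


@settings(max_examples=50, derandomize=True)
@given(
    phi=st.floats(-np.pi / 2, np.pi / 2),
    a=st.floats(0.1, 2.0),
)
def test_displacement_linearity(phi, a):
    if abs(a * phi) > np.pi:
        return
    one = phase_to_displacement(np.array([phi]), 840.0, 1.35).dd_nm[0]
    scaled = phase_to_displacement(np.array([a * phi]), 840.0, 1.35).dd_nm[0]
    assert scaled == pytest.approx(a * one, rel=1e-12, abs=1e-15)


def test_displacement_rejects_bad_constants():
    with pytest.raises(ValueError):
        phase_to_displacement(np.array([0.1]), -1.0, 1.35)
    with pytest.raises(ValueError):
        phase_to_displacement(np.array([0.1]), 840.0, 0.5)


def test_heart_rate_recovery(pulsatile_chain):
    hr, truth = pulsatile_chain["hr"], pulsatile_chain["truth"]
    assert not hr.low_confidence
    assert hr.heart_rate_bpm == pytest.approx(truth.heart_rate_bpm, abs=5.0)
    assert hr.heart_rate_bpm == pytest.approx(60.0 * hr.peak_freq_hz, rel=1e-12)


def test_heart_rate_monotone_discrimination():
    ests = []
    for bpm in (300.0, 550.0):
        cfg = small_test_phantom(
            small_test_geometry(n_slow_positions=80), heart_rate_bpm=bpm, seed=8
        )
        vol, _ = generate_phantom(cfg)
        seg = segment_volume(vol)
        comp = compensate_bulk(frame_phase_difference(vol), seg)
        ests.append(estimate_heart_rate(comp, seg).heart_rate_bpm)
    assert ests[0] < ests[1]


def test_pure_noise_series_flagged_low_confidence():
    cfg = small_test_phantom(
        small_test_geometry(n_slow_positions=60),
        pulsation_amplitude_ilm_nm=0.0,
        snr_db=25.0,
        seed=9,
    )
    vol, _ = generate_phantom(cfg)
    seg = segment_volume(vol)
    comp = compensate_bulk(frame_phase_difference(vol), seg)
    assert estimate_heart_rate(comp, seg).low_confidence


def test_heart_rate_needs_two_cycles():
    cfg = small_test_phantom(small_test_geometry(n_slow_positions=10), seed=1)
    vol, _ = generate_phantom(cfg)
    seg = segment_volume(vol)
    comp = compensate_bulk(frame_phase_difference(vol), seg)
    with pytest.raises(ValueError, match="cycle"):
        estimate_heart_rate(comp, seg, band_hz=(0.1, 12.0))


def test_intensity_mask_matches_brute_force(pulsatile_chain):
    """Mask equals an independently coded two-rule filter: depth in
    [ILM-10, RPE] and intensity >= 0.95 x B-scan mean."""
    vol, seg = pulsatile_chain["volume"], pulsatile_chain["seg"]
    for s in (0, 3):
        bscan = vol.mean_intensity_bscan(s)
        mask = intensity_mask(bscan, seg.ilm[s], seg.rpe[s])
        mean = bscan.mean()
        brute = np.zeros_like(mask)
        for z in range(bscan.shape[0]):
            for a in range(bscan.shape[1]):
                in_band = (z >= seg.ilm[s, a] - 10) and (z <= seg.rpe[s, a])
                brute[z, a] = in_band and bscan[z, a] >= 0.95 * mean
        np.testing.assert_array_equal(mask, brute)


def test_intensity_mask_trivial_rules():
    bscan = np.full((30, 4), 7.0)
    ilm, rpe = np.full(4, 12), np.full(4, 20)
    mask = intensity_mask(bscan, ilm, rpe)
    assert mask[25].sum() == 0  # below RPE masked regardless of intensity
    assert mask[2:12].all()  # uniform image: all in-band pixels pass


def test_mav_static_phantom_exactly_zero(static_phantom):
    vol, _ = static_phantom
    g = vol.geometry
    seg = segment_volume(vol)
    comp = compensate_bulk(frame_phase_difference(vol), seg)
    ds = phase_to_displacement(comp, g.lambda0_nm, g.refractive_index)
    mav = compute_mav(ds, 480.0)
    np.testing.assert_array_equal(mav, 0.0)


def test_mav_oracle_and_rpe_reference(pulsatile_chain):
    """En-face MAV at the ILM within 10% of brute-force averaging of the
    truth displacement series; MAV at the RPE ~ 0 (reference layer)."""
    ds, hr, seg, truth = (
        pulsatile_chain["ds"],
        pulsatile_chain["hr"],
        pulsatile_chain["seg"],
        pulsatile_chain["truth"],
    )
    mav = compute_mav(ds, hr)
    m_ilm = mav_enface_at_surface(mav, seg, "ILM")
    measured = np.nanmean(m_ilm.values)
    assert measured == pytest.approx(truth.expected_mav_nm_per_ms["ILM"], rel=0.10)
    # continuum oracle: mean |velocity| of a sinusoid = 4 f A
    f = truth.heart_rate_bpm / 60.0
    assert truth.expected_mav_nm_per_ms["ILM"] == pytest.approx(
        4 * f * 50.0 * 1e-3, rel=0.05
    )
    # displacement at the reference layer is ~0 up to the leakage the axial
    # smoothing kernel smears into the band from the moving tissue above it
    rpe_rows = ds.dd_nm[:, :, int(truth.rpe[0, 0]) + 1 : int(truth.rpe[0, 0]) + 3, :]
    ilm_rows = ds.dd_nm[:, :, int(truth.ilm[0, 0]) : int(truth.ilm[0, 0]) + 2, :]
    assert np.abs(rpe_rows).mean() < 0.15 * np.abs(ilm_rows).mean()


def test_mav_ilm_isos_ratio_matches_pulsation_profile(pulsatile_chain):
    """ILM amplitude = 2 x IS/OS amplitude -> en-face MAV ratio ~ 2 (15%)."""
    ds, hr, seg = pulsatile_chain["ds"], pulsatile_chain["hr"], pulsatile_chain["seg"]
    mav = compute_mav(ds, hr)
    r = np.nanmean(mav_enface_at_surface(mav, seg, "ILM").values) / np.nanmean(
        mav_enface_at_surface(mav, seg, "IS/OS").values
    )
    assert r == pytest.approx(2.0, rel=0.15)


def test_mav_doubles_with_amplitude():
    vals = []
    for amp in (25.0, 50.0):
        g = small_test_geometry(n_slow_positions=40)
        cfg = small_test_phantom(g, pulsation_amplitude_ilm_nm=amp, seed=12)
        vol, truth = generate_phantom(cfg)
        seg = segment_volume(vol)
        comp = compensate_bulk(frame_phase_difference(vol), seg)
        ds = phase_to_displacement(comp, g.lambda0_nm, g.refractive_index)
        mav = compute_mav(ds, truth.heart_rate_bpm)
        vals.append(np.nanmean(mav_enface_at_surface(mav, seg, "ILM").values))
    assert vals[1] / vals[0] == pytest.approx(2.0, rel=0.05)


def test_wrapped_phase_sets_saturation_flag():
    """Per-pair displacement beyond lambda0/(4n) wraps; the converter flags it."""
    g = small_test_geometry(n_slow_positions=8)
    cfg = small_test_phantom(g, pulsation_amplitude_ilm_nm=800.0, seed=1)
    vol, _ = generate_phantom(cfg)
    seg = segment_volume(vol)
    comp = compensate_bulk(frame_phase_difference(vol), seg)
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        ds = phase_to_displacement(comp, g.lambda0_nm, g.refractive_index)
    assert ds.saturated
    assert any("wrap" in str(x.message) for x in w)


def test_mav_surface_name_rejected(pulsatile_chain):
    ds, hr, seg = pulsatile_chain["ds"], pulsatile_chain["hr"], pulsatile_chain["seg"]
    mav = compute_mav(ds, hr)
    with pytest.raises(ValueError, match="surface"):
        mav_enface_at_surface(mav, seg, "RPE")


def test_mav_masked_rows_marked_invalid(pulsatile_chain):
    ds, hr, seg = pulsatile_chain["ds"], pulsatile_chain["hr"], pulsatile_chain["seg"]
    n_slow, _, n_depth, n_fast = ds.dd_nm.shape
    mask = np.ones((n_slow, n_depth, n_fast), dtype=bool)
    mask[2] = False  # fully masked B-scan
    mav = compute_mav(ds, hr, mask)
    m = mav_enface_at_surface(mav, seg, "ILM")
    assert m.invalid[2].all()


def test_mav_errors_when_cycle_not_covered():
    cfg = small_test_phantom(small_test_geometry(n_slow_positions=2), seed=0)
    g = cfg.geometry
    vol, truth = generate_phantom(cfg)
    seg = segment_volume(vol)
    comp = compensate_bulk(frame_phase_difference(vol), seg)
    ds = phase_to_displacement(comp, g.lambda0_nm, g.refractive_index)
    with pytest.raises(ValueError, match="cycle"):
        compute_mav(ds, 60.0)  # 1 s cycle >> 8 available pairs
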