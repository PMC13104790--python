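"""Phantom generator: determinism, phase encoding, noise calibration, truth."""

import numpy as np
import pytest

from retipulse import VesselSpec, generate_phantom
from retipulse.pipeline import small_test_geometry, small_test_phantom


def test_same_seed_reproduces_bit_for_bit():
    cfg = small_test_phantom(small_test_geometry(n_slow_positions=4), seed=42)
    v1, t1 = generate_phantom(cfg)
    v2, t2 = generate_phantom(cfg)
    np.testing.assert_array_equal(v1.co, v2.co)
    np.testing.assert_array_equal(v1.cross, v2.cross)
    np.testing.assert_array_equal(t1.ilm, t2.ilm)
    np.testing.assert_array_equal(
        t1.displacement_nm["ILM"], t2.displacement_nm["ILM"]
    )


def test_static_noiseless_phantom_has_zero_phase_differences(static_phantom):
    from retipulse.phase import hermitian_product

    vol, _ = static_phantom
    r = vol.geometry.n_repeats
    for s in range(vol.geometry.n_slow_positions):
        block = vol.co[s * r : (s + 1) * r]
        # repeats are bit-identical, so every inter-repeat phase is exactly 0
        for rep in range(1, r):
            np.testing.assert_array_equal(block[rep], block[0])
        dphi = np.angle(hermitian_product(block[1:], block[:-1]))
        np.testing.assert_array_equal(dphi, 0.0)


def test_flat_layer_truth_thickness():
    g = small_test_geometry(n_slow_positions=2, n_depth=200, axial_pixel_tissue_um=3.0)
    cfg = small_test_phantom(g, ilm_depth=100.0, isos_depth=162.0, rpe_depth=170.0)
    _, truth = generate_phantom(cfg)
    np.testing.assert_allclose(truth.rt_um(3.0), 210.0)


def test_truth_displacement_spectrum_peaks_at_heart_rate():
    """480 bpm at a 6.4 ms frame interval puts the spectral peak at 8.0 Hz."""
    g = small_test_geometry(n_slow_positions=100)
    assert g.frame_interval_s == pytest.approx(6.4e-3)
    cfg = small_test_phantom(g, heart_rate_bpm=480.0)
    _, truth = generate_phantom(cfg)
    series = truth.displacement_nm["ILM"]
    nfft = 1 << 16
    spectrum = np.abs(np.fft.rfft(series, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=g.frame_interval_s)
    assert freqs[np.argmax(spectrum)] == pytest.approx(8.0, abs=0.05)


def test_phase_encodes_displacement_closed_form():
    """Noiseless, bulk-free: inter-repeat phase at the ILM equals
    4*pi*n*dd/lambda0 to 1e-9 rad (full-precision phantom)."""
    g = small_test_geometry(n_slow_positions=6)
    cfg = small_test_phantom(g, snr_db=np.inf, seed=3, dtype=np.complex128)
    vol, truth = generate_phantom(cfg)
    k = 4.0 * np.pi * g.refractive_index / g.lambda0_nm
    r = g.n_repeats
    ilm = int(truth.ilm[0, 0])
    d = truth.displacement_nm["ILM"]
    for s in range(g.n_slow_positions):
        block = vol.co[s * r : (s + 1) * r]
        dphi = np.angle(block[1:, ilm, :] * np.conj(block[:-1, ilm, :]))
        expected = np.broadcast_to(
            (k * np.diff(d[s * r : (s + 1) * r]))[:, None], dphi.shape
        )
        np.testing.assert_allclose(dphi, expected, atol=1e-9)


@pytest.mark.parametrize("snr_db", [15.0, 25.0, 40.0])
def test_noise_calibration_within_1_db(snr_db):
    g = small_test_geometry(n_slow_positions=8)
    cfg = small_test_phantom(g, snr_db=snr_db, seed=1)
    vol, truth = generate_phantom(cfg)
    intensity = np.abs(vol.co) ** 2
    # plain tissue rows away from the bright surface bands, vs vitreous
    tissue = intensity[:, 30:130, :].mean()
    vitreous = intensity[:, :10, :].mean()
    measured = 10 * np.log10((tissue - vitreous) / vitreous)
    assert measured == pytest.approx(snr_db, abs=1.0)


def test_expected_mav_zero_at_rpe_and_positive_at_ilm():
    cfg = small_test_phantom(small_test_geometry(n_slow_positions=4))
    _, truth = generate_phantom(cfg)
    assert truth.expected_mav_nm_per_ms["RPE"] == 0.0
    assert truth.expected_mav_nm_per_ms["ILM"] > 0.0
    assert truth.vessel_mask.shape == (4, cfg.geometry.n_fast)


def test_vessel_bump_thickens_retina_only_inside_footprint():
    g = small_test_geometry(n_slow_positions=16, n_fast=32)
    bump = 3 * g.axial_pixel_tissue_um  # exactly 3 pixels
    cfg = small_test_phantom(
        g, vessels=(VesselSpec(center_slow=8.0, center_fast=16.0, radius_um=120.0,
                               thickness_bump_um=bump),)
    )
    _, truth = generate_phantom(cfg)
    rt = truth.rt_um(g.axial_pixel_tissue_um)
    base = rt[~truth.vessel_mask][0]
    assert truth.vessel_mask.any()
    np.testing.assert_allclose(rt[truth.vessel_mask], base + bump)
    np.testing.assert_allclose(rt[~truth.vessel_mask], base)


def test_invalid_configs_rejected():
    g = small_test_geometry()
    with pytest.raises(ValueError, match="n_depth"):
        generate_phantom(small_test_phantom(g, rpe_depth=float(g.n_depth)))
    with pytest.raises(ValueError, match="ordering"):
        generate_phantom(small_test_phantom(g, ilm_depth=150.0, isos_depth=100.0))
    with pytest.raises(ValueError, match="outside"):
        generate_phantom(
            small_test_phantom(
                g, vessels=(VesselSpec(center_slow=-5.0, center_fast=0.0, radius_um=50.0),)
            )
        )


def test_truth_json_roundtrip(tmp_path):
    cfg = small_test_phantom(small_test_geometry(n_slow_positions=3), seed=9)
    _, truth = generate_phantom(cfg)
    p = tmp_path / "truth.json"
    truth.save(p)
    from retipulse.phantom import PhantomTruth

    back = PhantomTruth.load(p)
    np.testing.assert_array_equal(back.ilm, truth.ilm)
    np.testing.assert_array_equal(back.vessel_mask, truth.vessel_mask)
    assert back.heart_rate_bpm == truth.heart_rate_bpm
    np.testing.assert_allclose(back.displacement_nm["ISOS"], truth.displacement_nm["ISOS"])
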