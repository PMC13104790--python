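"""Complex OCTA, noise floor, SVP threshold rule, vessel density."""

import numpy as np
import pytest

from retipulse import OCTVolume, compute_octa, estimate_noise_floor, generate_phantom, segment_svp, segment_volume, svp_density
from retipulse.angiography import OCTAMap
from retipulse.pipeline import small_test_geometry, small_test_phantom
from retipulse.thickness import AnnulusSpec, annulus_mask


def _spec48():
    return AnnulusSpec(center=(24.0, 32.0), slow_pixel_mm=1 / 48, fast_pixel_mm=1 / 64)


@pytest.fixture(scope="module")
def octa_chain(vessel_chain):
    vol, seg = vessel_chain["volume"], vessel_chain["seg"]
    octa = compute_octa(vol, seg)
    octa.noise_floor = estimate_noise_floor(octa, seg)
    return {**vessel_chain, "octa": octa}


def test_static_noiseless_octa_is_zero(static_phantom):
    vol, _ = static_phantom
    seg = segment_volume(vol)
    octa = compute_octa(vol, seg)
    assert np.nanmax(octa.enface) < 1e-9
    # noiseless floor ~ 0: segmentation falls back to the absolute minimum
    floor = estimate_noise_floor(octa, seg)
    mask = segment_svp(octa, noise_floor=floor)
    assert mask.threshold > 0
    assert not mask.mask.any()


def test_vessel_contrast_over_static_tissue():
    """Decorrelating vessel pixels light up >= 10x over motionless tissue."""
    from retipulse import VesselSpec

    g = small_test_geometry(n_slow_positions=48, n_fast=64)
    vessels = (VesselSpec(center_slow=14.0, center_fast=20.0, radius_um=100.0),)
    cfg = small_test_phantom(g, vessels=vessels, pulsation_amplitude_ilm_nm=0.0, seed=7)
    vol, truth = generate_phantom(cfg)
    seg = segment_volume(vol)
    octa = compute_octa(vol, seg)
    vm = truth.vessel_mask
    vessel = np.nanmean(octa.enface[vm])
    tissue = np.nanmean(octa.enface[~vm])
    assert vessel >= 10 * tissue


def test_octa_bulk_phase_invariance(octa_chain):
    vol, seg = octa_chain["volume"], octa_chain["seg"]
    g = vol.geometry
    rng = np.random.default_rng(3)
    beta = np.exp(1j * rng.uniform(-np.pi, np.pi, g.n_frames))
    vol2 = OCTVolume(
        co=(vol.co.astype(np.complex128) * beta[:, None, None]).astype(vol.co.dtype),
        cross=(vol.cross.astype(np.complex128) * beta[:, None, None]).astype(vol.cross.dtype),
        geometry=g,
    )
    a1 = compute_octa(vol, seg).enface
    a2 = compute_octa(vol2, segment_volume(vol2)).enface
    rel = np.linalg.norm(np.nan_to_num(a1 - a2)) / np.linalg.norm(np.nan_to_num(a1))
    assert rel < 1e-6


def test_noise_floor_matches_monte_carlo_oracle(octa_chain):
    """The vitreous median should match the same statistic simulated directly
    from the injected complex-noise model (independent Monte-Carlo oracle)."""
    octa, truth, seg = octa_chain["octa"], octa_chain["truth"], octa_chain["seg"]
    measured = estimate_noise_floor(octa, seg)
    rng = np.random.default_rng(0)
    sigma = truth.noise_amplitude / np.sqrt(2.0)
    n_pairs = octa_chain["geometry"].n_repeats - 1
    n1 = sigma * (rng.standard_normal((200_000, n_pairs)) + 1j * rng.standard_normal((200_000, n_pairs)))
    n2 = sigma * (rng.standard_normal((200_000, n_pairs)) + 1j * rng.standard_normal((200_000, n_pairs)))
    oracle = np.median(np.abs(n2 - n1).mean(axis=1))
    assert measured == pytest.approx(oracle, rel=0.10)


def test_noise_floor_invariant_to_vessels(octa_chain):
    """Vitreous-only statistic: a vessel-free phantom with the same seed and
    noise gives the same floor within sampling error."""
    g = octa_chain["geometry"]
    cfg = small_test_phantom(g, seed=7)  # same conditions, no vessels
    vol, _ = generate_phantom(cfg)
    seg = segment_volume(vol)
    octa = compute_octa(vol, seg)
    floor = estimate_noise_floor(octa, seg)
    assert floor == pytest.approx(octa_chain["octa"].noise_floor, rel=0.05)


def test_svp_dice_and_density_recovery(octa_chain):
    octa, truth, seg = octa_chain["octa"], octa_chain["truth"], octa_chain["seg"]
    mask = segment_svp(octa).mask
    tm = truth.vessel_mask
    dice = 2 * (mask & tm).sum() / (mask.sum() + tm.sum())
    assert dice >= 0.8
    spec = _spec48()
    density = svp_density(mask, spec, valid=seg.valid)
    ann = annulus_mask(spec, tm.shape) & seg.valid
    true_density = 100 * (tm & ann).sum() / ann.sum()
    assert abs(density - true_density) <= 2.0


def test_threshold_monotonicity(octa_chain):
    octa = octa_chain["octa"]
    m20 = segment_svp(octa, multiplier=20).mask
    m30 = segment_svp(octa, multiplier=30).mask
    assert not (m30 & ~m20).any()  # raising the multiplier never adds pixels


def test_scale_invariance_of_threshold_rule(octa_chain):
    octa = octa_chain["octa"]
    doubled = OCTAMap(
        enface=2 * octa.enface, tomogram=2 * octa.tomogram,
        slab_um=octa.slab_um, noise_floor=2 * octa.noise_floor,
    )
    np.testing.assert_array_equal(segment_svp(octa).mask, segment_svp(doubled).mask)


def test_density_equals_brute_force_count(octa_chain):
    octa, seg = octa_chain["octa"], octa_chain["seg"]
    mask = segment_svp(octa)
    spec = _spec48()
    density = svp_density(mask, spec, valid=seg.valid)
    ann = annulus_mask(spec, mask.mask.shape)
    num = den = 0
    for s in range(mask.mask.shape[0]):
        for f in range(mask.mask.shape[1]):
            if ann[s, f] and seg.valid[s, f]:
                den += 1
                num += bool(mask.mask[s, f])
    assert density == pytest.approx(100 * num / den, abs=1e-12)


def test_density_trivial_bounds(octa_chain):
    spec = _spec48()
    empty = np.zeros((48, 64), dtype=bool)
    assert svp_density(empty, spec) == 0.0
    assert svp_density(~empty, spec) == 100.0


def test_single_repeat_rejected():
    g = small_test_geometry(n_slow_positions=2, n_repeats=1)
    z = np.zeros((g.n_frames, g.n_depth, g.n_fast), dtype=np.complex64)
    vol = OCTVolume(co=z, cross=z, geometry=g)
    from retipulse.segmentation import LayerSegmentation

    seg = LayerSegmentation(
        ilm=np.full((2, g.n_fast), 20), isos=np.full((2, g.n_fast), 141),
        rpe=np.full((2, g.n_fast), 149), valid=np.ones((2, g.n_fast), dtype=bool),
    )
    with pytest.raises(ValueError, match="repeat"):
        compute_octa(vol, seg)
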