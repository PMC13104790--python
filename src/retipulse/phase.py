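"""Phase-sensitive motion analysis: inter-repeat phase differences, bulk-motion
referencing at the RPE, displacement conversion, heart-rate spectroscopy, and
mean-absolute-velocity (MAV) mapping.

Processing chain
----------------
1. Hermitian products ``C2 * conj(C1)`` between consecutive repeated B-scans,
   complex-phasor-smoothed with a 10 (axial) x 20 (lateral) pixel kernel; the
   argument is the wrapped phase difference, the magnitude its weight.
2. The amplitude-weighted mean phasor in a small depth window at the RPE is
   divided out per A-scan and pair: the RPE is the motion reference, removing
   bulk eye motion.
3. Phase converts to axial displacement via ``dd = lambda0 * dphi / (4*pi*n)``.
4. The heart rate is the dominant spectral peak of the per-pair mean phase
   difference at the ILM.
5. MAV is the per-pixel mean absolute displacement over one heart cycle of
   pairs, divided by the frame interval (nm/ms), sampled en face at a surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import detrend

from .segmentation import LayerSegmentation
from .volume import OCTVolume

__all__ = [
    "PhaseDifferenceSeries",
    "DisplacementSeries",
    "HREstimate",
    "MAVMap",
    "frame_phase_difference",
    "compensate_bulk",
    "phase_to_displacement",
    "estimate_heart_rate",
    "intensity_mask",
    "compute_mav",
    "mav_enface_at_surface",
]

SMOOTH_KERNEL = (10, 20)  # axial x lateral phasor-smoothing window, pixels
RPE_WINDOW = 2  # +/- pixels around the RPE used when sampling maps
RPE_BAND_PX = 4  # depth rows at/below the upper RPE edge used as phase baseline
SURFACE_WINDOW = 2  # +/- pixels when sampling a map at a surface
MASK_DEPTH_ABOVE_ILM = 10  # intensity mask extends this far above the ILM
MASK_INTENSITY_FRACTION = 0.95  # of the B-scan mean intensity
DEFAULT_HR_BAND_HZ = (4.0, 12.0)  # 240-720 bpm search band
WRAP_GUARD = 0.9  # |dphi| beyond this x pi counts as near-wrapped


@dataclass
class PhaseDifferenceSeries:
    """Smoothed Hermitian products per consecutive-repeat pair.

    ``products`` has shape ``(n_slow, n_pairs, n_depth, n_fast)`` with
    ``n_pairs = n_repeats - 1`` (pairs never straddle slow positions).
    """

    products: np.ndarray
    frame_interval_ms: float
    pair_times_s: np.ndarray  # (n_slow, n_pairs), time of the later frame
    n_repeats: int
    raw_products: np.ndarray | None = None  # unsmoothed, for the RPE baseline
    baseline_from_neighbor: np.ndarray | None = None

    @property
    def dphi(self) -> np.ndarray:
        """Wrapped phase difference, radians in (-pi, pi]."""
        return np.angle(self.products)

    @property
    def weight(self) -> np.ndarray:
        return np.abs(self.products)

    @property
    def n_slow(self) -> int:
        return self.products.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.products.shape[1]


@dataclass
class DisplacementSeries:
    """Per-pair axial displacement tomograms relative to the RPE, nanometres."""

    dd_nm: np.ndarray  # (n_slow, n_pairs, n_depth, n_fast), float64
    valid: np.ndarray
    lambda0_nm: float
    refractive_index: float
    frame_interval_ms: float
    saturated: bool = False
    wrapped_fraction: float = 0.0


@dataclass
class HREstimate:
    heart_rate_bpm: float
    peak_freq_hz: float
    freqs_hz: np.ndarray
    magnitude: np.ndarray
    band_hz: tuple[float, float]
    low_confidence: bool = False


@dataclass
class MAVMap:
    """En-face MAV at a named surface, nm/ms; NaN where masked or invalid."""

    values: np.ndarray
    surface: str
    invalid: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.invalid is None:
            self.invalid = ~np.isfinite(self.values)


def hermitian_product(c2: np.ndarray, c1: np.ndarray) -> np.ndarray:
    """``c2 * conj(c1)`` in float64 via separate real multiplies.

    Numpy's fused complex multiply leaves ~1 ulp residual imaginary parts even
    for bit-identical inputs; forming the product from individually rounded
    real products makes the phase difference of identical frames exactly zero,
    which downstream zero-motion contracts rely on.
    """
    r2, i2 = c2.real.astype(np.float64), c2.imag.astype(np.float64)
    r1, i1 = c1.real.astype(np.float64), c1.imag.astype(np.float64)
    out = np.empty(np.broadcast(c2, c1).shape, dtype=np.complex128)
    out.real = r2 * r1 + i2 * i1
    out.imag = i2 * r1 - r2 * i1
    return out


def frame_phase_difference(volume: OCTVolume, channel: str = "co") -> PhaseDifferenceSeries:
    """Phase differences between corresponding pixels of consecutive repeats.

    Hermitian products are summed over a 10 x 20 (axial x lateral) window
    before taking the argument (complex phasor smoothing), which is the
    amplitude-weighted circular mean of the raw phase differences.
    """
    g = volume.geometry
    if g.n_repeats < 2:
        raise ValueError("phase analysis needs repeated B-scans (n_repeats >= 2)")
    data = volume.co if channel == "co" else volume.cross
    n_pairs = g.n_repeats - 1
    products = np.empty(
        (g.n_slow_positions, n_pairs, g.n_depth, g.n_fast), dtype=np.complex128
    )
    raw = np.empty_like(products)
    for s in range(g.n_slow_positions):
        block = data[s * g.n_repeats : (s + 1) * g.n_repeats]
        herm = hermitian_product(block[1:], block[:-1])
        raw[s] = herm
        # box smoothing of the complex products == windowed phasor sum (scaled)
        products[s].real = uniform_filter(herm.real, size=(1, *SMOOTH_KERNEL), mode="nearest")
        products[s].imag = uniform_filter(herm.imag, size=(1, *SMOOTH_KERNEL), mode="nearest")
        # the box filter leaves ~1 ulp residues where the true sum is zero
        # (empty regions); their argument would be meaningless, so zero them
        mag = np.abs(products[s])
        products[s][mag < 1e-12 * mag.max()] = 0.0
    dt = volume.geometry.frame_interval_s
    pair_idx = np.arange(1, g.n_repeats)
    times = (
        np.arange(g.n_slow_positions)[:, None] * g.n_repeats + pair_idx[None, :]
    ) * dt
    return PhaseDifferenceSeries(
        products=products,
        frame_interval_ms=g.frame_interval_ms,
        pair_times_s=times,
        n_repeats=g.n_repeats,
        raw_products=raw,
    )


def _rpe_baseline(raw_products: np.ndarray, rpe_row: np.ndarray) -> np.ndarray:
    """Amplitude-weighted mean phasor inside the RPE band per (pair, A-scan).

    Uses the unsmoothed Hermitian products over the rows at and directly
    below the upper RPE edge: the RPE itself does not move, whereas the
    smoothed products at the edge are contaminated by pulsating tissue just
    above it (the axial smoothing kernel smears motion into the band), which
    would bias the whole compensated tomogram.
    """
    n_pairs, n_depth, n_fast = raw_products.shape
    offsets = np.arange(RPE_BAND_PX)
    zidx = np.clip(rpe_row[None, :] + offsets[:, None], 0, n_depth - 1)  # (w, fast)
    gathered = raw_products[:, zidx, np.arange(n_fast)[None, :]]  # (pairs, w, fast)
    return gathered.sum(axis=1)


def compensate_bulk(
    pds: PhaseDifferenceSeries, seg: LayerSegmentation
) -> PhaseDifferenceSeries:
    """Reference the phase difference to the RPE, removing bulk motion.

    Per A-scan and pair the amplitude-weighted mean phasor over a small depth
    window in the RPE band is computed and its phase divided out of the whole
    A-scan.  A-scans with an invalid RPE borrow the nearest valid A-scan's
    baseline and are flagged.
    """
    if pds.raw_products is None:
        raise ValueError("series lacks raw products; recompute with frame_phase_difference")
    out = np.empty_like(pds.products)
    raw_out = np.empty_like(pds.raw_products)
    from_neighbor = np.zeros((pds.n_slow, seg.shape[1]), dtype=bool)
    for s in range(pds.n_slow):
        rpe_row = seg.rpe[s]
        valid = seg.valid[s]
        baseline = _rpe_baseline(pds.raw_products[s], rpe_row)  # (pairs, fast)
        if not valid.all():
            if not valid.any():
                from_neighbor[s] = True
            else:
                good = np.nonzero(valid)[0]
                bad = np.nonzero(~valid)[0]
                nearest = good[np.argmin(np.abs(bad[:, None] - good[None, :]), axis=1)]
                baseline[:, bad] = baseline[:, nearest]
                from_neighbor[s, bad] = True
        mag = np.abs(baseline)
        unit = np.where(mag > 0, baseline / np.where(mag > 0, mag, 1.0), 1.0)
        out[s] = pds.products[s] * np.conj(unit)[:, None, :]
        raw_out[s] = pds.raw_products[s] * np.conj(unit)[:, None, :]
    return PhaseDifferenceSeries(
        products=out,
        frame_interval_ms=pds.frame_interval_ms,
        pair_times_s=pds.pair_times_s,
        n_repeats=pds.n_repeats,
        raw_products=raw_out,
        baseline_from_neighbor=from_neighbor,
    )


def phase_to_displacement(
    pds: PhaseDifferenceSeries | np.ndarray,
    lambda0_nm: float,
    refractive_index: float,
    frame_interval_ms: float | None = None,
) -> DisplacementSeries:
    """Convert phase difference to axial displacement:
    ``dd = lambda0 * dphi / (4 * pi * n)`` (nanometres).

    Positive displacement is motion toward the instrument (decreasing depth
    index).  Accepts a series or a bare phase array.  If a substantial
    fraction of tissue phase approaches +/-pi the result is flagged
    ``saturated`` (phase wrapping: per-pair displacement beyond
    ``lambda0 / (4 n)`` is not representable).
    """
    if lambda0_nm <= 0:
        raise ValueError("lambda0_nm must be > 0")
    if refractive_index < 1:
        raise ValueError("refractive_index must be >= 1")
    if isinstance(pds, PhaseDifferenceSeries):
        dphi = pds.dphi
        weight = pds.weight
        valid = weight > 0
        interval = pds.frame_interval_ms
    else:
        dphi = np.asarray(pds, dtype=float)
        valid = np.ones_like(dphi, dtype=bool)
        weight = None
        interval = frame_interval_ms if frame_interval_ms is not None else float("nan")
    dd = dphi * (lambda0_nm / (4.0 * np.pi * refractive_index))
    if weight is not None:
        # consider only pixels carrying real signal when judging saturation
        strong = weight > np.median(weight)
        frac = float(np.mean(np.abs(dphi[strong]) > WRAP_GUARD * np.pi)) if strong.any() else 0.0
    else:
        frac = float(np.mean(np.abs(dphi) > WRAP_GUARD * np.pi))
    saturated = frac > 0.01
    if saturated:
        warnings.warn(
            f"{100 * frac:.1f}% of signal-bearing pixels near the phase-wrapping limit; "
            "displacements beyond lambda0/(4n) per pair are aliased",
            RuntimeWarning,
            stacklevel=2,
        )
    return DisplacementSeries(
        dd_nm=dd,
        valid=valid,
        lambda0_nm=lambda0_nm,
        refractive_index=refractive_index,
        frame_interval_ms=interval,
        saturated=saturated,
        wrapped_fraction=frac,
    )


def ilm_phase_series(pds: PhaseDifferenceSeries, seg: LayerSegmentation) -> np.ndarray:
    """Per-pair mean phase difference over a +/-2 px window at the ILM.

    Returns shape ``(n_slow, n_pairs)``; the amplitude-weighted mean phasor's
    argument is used so noisy pixels contribute little.
    """
    n_slow, n_pairs, n_depth, n_fast = pds.products.shape
    series = np.zeros((n_slow, n_pairs))
    offsets = np.arange(-SURFACE_WINDOW, SURFACE_WINDOW + 1)
    for s in range(n_slow):
        valid = seg.valid[s]
        if not valid.any():
            continue
        zidx = np.clip(seg.ilm[s][None, :] + offsets[:, None], 0, n_depth - 1)
        gathered = pds.products[s][:, zidx, np.arange(n_fast)[None, :]]  # (pairs, w, fast)
        phasor = gathered[:, :, valid].sum(axis=(1, 2))
        series[s] = np.angle(phasor)
    return series


def estimate_heart_rate(
    pds: PhaseDifferenceSeries,
    seg: LayerSegmentation,
    band_hz: tuple[float, float] = DEFAULT_HR_BAND_HZ,
    zero_pad_factor: int = 8,
) -> HREstimate:
    """Heart rate from Fourier analysis of the mean phase difference at the ILM.

    The per-pair series is laid onto the uniform frame grid (pairs straddling
    slow positions are missing and contribute zero after linear detrending),
    zero-padded, and the largest in-band spectral peak is refined by local
    quadratic interpolation.  HR = 60 x peak frequency.
    """
    series = ilm_phase_series(pds, seg)  # (n_slow, n_pairs)
    n_slow, n_pairs = series.shape
    n_rep = pds.n_repeats
    dt = pds.frame_interval_ms * 1e-3

    n_slots = n_slow * n_rep - 1  # one slot per consecutive-frame pair
    grid = np.zeros(n_slots)
    have = np.zeros(n_slots, dtype=bool)
    slots = (np.arange(n_slow)[:, None] * n_rep + np.arange(n_pairs)[None, :]).ravel()
    grid[slots] = series.ravel()
    have[slots] = True

    duration = n_slots * dt
    if duration < 2.0 / band_hz[0]:
        raise ValueError(
            f"series spans {duration:.3f}s, need >= two cycles of {band_hz[0]} Hz"
        )

    grid[have] = detrend(grid[have])
    nfft = int(2 ** np.ceil(np.log2(n_slots))) * zero_pad_factor
    spectrum = np.abs(np.fft.rfft(grid, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=dt)

    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    mag_band = spectrum[in_band]
    f_band = freqs[in_band]
    k = int(np.argmax(mag_band))
    low_confidence = mag_band[k] < 3.0 * np.median(mag_band)

    # local quadratic refinement on the full-resolution spectrum
    k_full = np.nonzero(in_band)[0][k]
    if 0 < k_full < len(spectrum) - 1:
        y0, y1, y2 = spectrum[k_full - 1 : k_full + 2]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    peak = f_band[k] + delta * (freqs[1] - freqs[0])
    return HREstimate(
        heart_rate_bpm=60.0 * peak,
        peak_freq_hz=peak,
        freqs_hz=freqs,
        magnitude=spectrum,
        band_hz=band_hz,
        low_confidence=bool(low_confidence),
    )


def intensity_mask(
    intensity_bscan: np.ndarray,
    ilm: np.ndarray,
    rpe: np.ndarray,
    fraction: float = MASK_INTENSITY_FRACTION,
) -> np.ndarray:
    """Display/analysis mask: keep pixels in the depth band
    ``[ILM - 10, RPE]`` whose intensity reaches ``fraction`` x the B-scan
    mean; everything else is masked (black in display).
    """
    n_depth, n_fast = intensity_bscan.shape
    z = np.arange(n_depth)[:, None]
    band = (z >= np.asarray(ilm)[None, :] - MASK_DEPTH_ABOVE_ILM) & (
        z <= np.asarray(rpe)[None, :]
    )
    return band & (intensity_bscan >= fraction * intensity_bscan.mean())


def compute_mav(
    ds: DisplacementSeries,
    hr: HREstimate | float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mean absolute velocity tomogram, nm/ms.

    Per pixel, the absolute displacements of the pairs spanning one heart
    cycle are averaged and divided by the frame interval.  A repeat block
    holds only ``n_repeats - 1`` pairs (~tens of ms), shorter than a murine
    heart cycle, so pairs are pooled from adjacent slow positions until one
    cycle is covered (recorded in the result's provenance downstream).

    ``mask`` (optional) has shape ``(n_slow, n_depth, n_fast)``; False pixels
    become NaN.
    """
    hr_bpm = hr.heart_rate_bpm if isinstance(hr, HREstimate) else float(hr)
    n_slow, n_pairs, n_depth, n_fast = ds.dd_nm.shape
    dt_ms = ds.frame_interval_ms
    cycle_pairs = max(1, round((60_000.0 / hr_bpm) / dt_ms))
    total_pairs = n_slow * n_pairs
    if total_pairs < cycle_pairs:
        raise ValueError(
            f"only {total_pairs} pairs available, one heart cycle needs {cycle_pairs}"
        )
    half = int(np.ceil(max(cycle_pairs - n_pairs, 0) / (2 * n_pairs)))

    abs_dd = np.abs(ds.dd_nm)  # (slow, pairs, depth, fast)
    mav = np.empty((n_slow, n_depth, n_fast))
    for s in range(n_slow):
        lo = max(0, s - half)
        hi = min(n_slow, s + half + 1)
        if hi - lo < 2 * half + 1:  # clamp the window inside the volume
            lo = max(0, hi - (2 * half + 1))
            hi = min(n_slow, lo + (2 * half + 1))
        mav[s] = abs_dd[lo:hi].mean(axis=(0, 1)) / dt_ms
    if mask is not None:
        mav = np.where(mask, mav, np.nan)
    return mav


_SURFACE_ALIASES = {"ILM": "ilm", "ISOS": "isos", "IS/OS": "isos"}


def mav_enface_at_surface(
    mav_tomogram: np.ndarray, seg: LayerSegmentation, surface: str
) -> MAVMap:
    """Sample a MAV tomogram en face at the ILM or IS/OS.

    The value is the mean over a +/-2 px depth window centered at the
    surface; NaN-masked pixels are ignored; invalid A-scans are marked.
    """
    key = _SURFACE_ALIASES.get(surface.upper().replace(" ", ""))
    if key is None:
        raise ValueError(f"surface must be one of {sorted(_SURFACE_ALIASES)}, got {surface!r}")
    depths = getattr(seg, key)
    n_slow, n_depth, n_fast = mav_tomogram.shape
    offsets = np.arange(-SURFACE_WINDOW, SURFACE_WINDOW + 1)
    zidx = np.clip(depths[:, None, :] + offsets[None, :, None], 0, n_depth - 1)
    gathered = np.take_along_axis(mav_tomogram, zidx, axis=1)  # (slow, w, fast)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(gathered, axis=1)
    values = np.where(seg.valid, values, np.nan)
    return MAVMap(values=values, surface=surface, invalid=~np.isfinite(values))
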