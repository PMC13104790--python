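"""Retinal surface segmentation from the two polarization channels.

Three surfaces are located per B-scan: the ILM (innermost surface) by edge
detection in the co-polarized channel, the upper RPE edge by edge detection
in the cross-polarized channel (where the depolarizing RPE dominates), and
the IS/OS junction as the intensity maximum in a 15-pixel slab directly
above the RPE.

Edge operator: axial first difference of log-intensity after a 1.5-px-sigma
axial Gaussian, thresholded adaptively at mean + 2 SD of the vitreous-region
gradient, gated on the post-edge intensity being a substantial fraction of
the B-scan's bright structures (so weak cross-talk edges above the RPE are
skipped), then median-filtered laterally (width 9).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, maximum_filter1d, median_filter

__all__ = [
    "LayerSegmentation",
    "segment_ilm",
    "segment_rpe",
    "segment_isos",
    "segment_volume",
]

_AXIAL_SIGMA = 1.5
_MEDIAN_WIDTH = 9
_PEAK_GATE_FRACTION = 0.25  # post-edge intensity must reach this x P98 of the B-scan
_ISOS_SLAB = 15  # pixels directly above the RPE searched for the IS/OS
_SHADOW_FRACTION = 0.2  # A-scans dimmer than this x median total are interpolated
_LOG_EPS = 1e-12


@dataclass
class LayerSegmentation:
    """Per-(slow, fast) integer depth indices of the three surfaces.

    ``valid`` flags A-scans where all three surfaces were found in order;
    ``interpolated`` marks shadowed A-scans filled from lateral neighbors.
    """

    ilm: np.ndarray
    isos: np.ndarray
    rpe: np.ndarray
    valid: np.ndarray
    interpolated: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.interpolated is None:
            self.interpolated = np.zeros_like(self.valid)

    @property
    def shape(self) -> tuple[int, int]:
        return self.ilm.shape

    def ordering_ok(self) -> np.ndarray:
        return (self.ilm < self.isos) & (self.isos < self.rpe)

    def to_hdf5(self, group) -> None:
        for name in ("ilm", "isos", "rpe", "valid", "interpolated"):
            group.create_dataset(name, data=getattr(self, name))

    @classmethod
    def from_hdf5(cls, group) -> "LayerSegmentation":
        return cls(**{k: group[k][...] for k in ("ilm", "isos", "rpe", "valid", "interpolated")})

    def to_frame(self):
        import pandas as pd

        s, f = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        return pd.DataFrame(
            {
                "slow": s.ravel(),
                "fast": f.ravel(),
                "ilm": self.ilm.ravel(),
                "isos": self.isos.ravel(),
                "rpe": self.rpe.ravel(),
                "valid": self.valid.ravel(),
            }
        )


def _detect_edges(intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shallowest qualifying rising edge per A-scan.

    Detection runs on the axial gradient of log-intensity (floored at 1e-3 of
    the B-scan maximum so empty regions do not produce runaway log slopes),
    thresholded from the vitreous rows and gated on leading into bright
    structure.  The surface is then localized as the largest raw-intensity
    step inside the candidate window, which is pixel-exact on clean data.
    Returns (depth index per A-scan, valid flag per A-scan).
    """
    n_depth, n_fast = intensity.shape
    intensity = intensity.astype(float)
    smoothed = gaussian_filter1d(intensity, _AXIAL_SIGMA, axis=0, mode="nearest")
    floor = 1e-3 * smoothed.max() + _LOG_EPS
    grad = np.diff(np.log(smoothed + floor), axis=0)  # grad[z] = L[z+1] - L[z]

    # adaptive threshold from the shallowest (vitreous) rows
    n_vit = max(8, int(0.1 * n_depth))
    vit = grad[:n_vit]
    thresh = vit.mean() + 2.0 * vit.std()

    # gate: the edge must lead into structure that is bright both relative to
    # the B-scan's brightest features and to the vitreous noise level, so a
    # pure-noise B-scan yields no candidates at all
    p98 = np.percentile(smoothed, 98)
    vit_level = np.median(smoothed[:n_vit])
    gate = max(_PEAK_GATE_FRACTION * p98, 5.0 * vit_level)
    bright_ahead = maximum_filter1d(smoothed, size=5, axis=0, origin=-2) >= gate
    candidate = (grad > thresh) & bright_ahead[1:]

    raw_step = np.diff(intensity, axis=0)
    depth = np.full(n_fast, -1, dtype=int)
    valid = candidate.any(axis=0)
    first = np.argmax(candidate, axis=0)
    for a in np.nonzero(valid)[0]:
        zc = first[a]
        window = raw_step[zc : min(zc + 8, n_depth - 1), a]
        depth[a] = zc + int(np.argmax(window)) + 1
    return depth, valid


def _median_smooth(depth: np.ndarray, valid: np.ndarray) -> np.ndarray:
    if valid.sum() == 0:
        return depth
    filled = depth.astype(float)
    if (~valid).any():
        idx = np.nonzero(valid)[0]
        filled[~valid] = np.interp(np.nonzero(~valid)[0], idx, filled[idx])
    sm = median_filter(filled, size=_MEDIAN_WIDTH, mode="nearest")
    return np.round(sm).astype(int)


def segment_ilm(co_channel_bscan: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ILM depth per A-scan from a co-polarized intensity B-scan.

    Returns ``(depth, valid)``; A-scans with no qualifying edge are flagged
    invalid (an all-noise B-scan yields all-invalid, no exception).
    """
    depth, valid = _detect_edges(co_channel_bscan)
    return _median_smooth(depth, valid), valid


def segment_rpe(cross_channel_bscan: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper RPE edge per A-scan from a cross-polarized intensity B-scan."""
    depth, valid = _detect_edges(cross_channel_bscan)
    return _median_smooth(depth, valid), valid


def segment_isos(
    intensity_bscan: np.ndarray, rpe: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """IS/OS depth: intensity argmax in the 15-pixel slab directly above the RPE.

    The slab is ``[rpe - 15, rpe - 1]``; ties resolve to the shallowest
    maximum (``argmax`` returns the first).  A-scans with ``rpe < 15`` are
    flagged invalid.
    """
    n_depth, n_fast = intensity_bscan.shape
    rpe = np.asarray(rpe)
    depth = np.full(n_fast, -1, dtype=int)
    valid = rpe >= _ISOS_SLAB
    for a in np.nonzero(valid)[0]:
        top = int(rpe[a]) - _ISOS_SLAB
        slab = intensity_bscan[top : int(rpe[a]), a]
        depth[a] = top + int(np.argmax(slab))
    return depth, valid


def _shadowed_ascans(co_intensity: np.ndarray) -> np.ndarray:
    total = co_intensity.sum(axis=0)
    return total < _SHADOW_FRACTION * np.median(total)


def _interp_invalid(depth: np.ndarray, good: np.ndarray) -> np.ndarray:
    if good.all() or not good.any():
        return depth
    out = depth.astype(float)
    idx = np.nonzero(good)[0]
    out[~good] = np.interp(np.nonzero(~good)[0], idx, out[idx])
    return np.round(out).astype(int)


def segment_volume(volume) -> LayerSegmentation:
    """Segment ILM/IS-OS/RPE for every slow position of a volume.

    Repeat-averaged intensity is used per B-scan.  Shadowed A-scans (total
    signal below 20% of the B-scan median) are interpolated from lateral
    neighbors rather than segmented, and marked in ``interpolated``.
    """
    g = volume.geometry
    shape = (g.n_slow_positions, g.n_fast)
    ilm = np.zeros(shape, dtype=int)
    isos = np.zeros(shape, dtype=int)
    rpe = np.zeros(shape, dtype=int)
    valid = np.zeros(shape, dtype=bool)
    interp = np.zeros(shape, dtype=bool)

    for s in range(g.n_slow_positions):
        co_int = volume.mean_intensity_bscan(s, "co")
        cross_int = volume.mean_intensity_bscan(s, "cross")
        shadow = _shadowed_ascans(co_int)

        ilm_s, v_ilm = segment_ilm(co_int)
        rpe_s, v_rpe = segment_rpe(cross_int)
        good = v_ilm & v_rpe & ~shadow
        ilm_s = _interp_invalid(ilm_s, good | (v_ilm & v_rpe))
        rpe_s = _interp_invalid(rpe_s, good | (v_ilm & v_rpe))
        isos_s, v_isos = segment_isos(co_int, rpe_s)

        ok = v_ilm & v_rpe & v_isos
        ordered = (ilm_s < isos_s) & (isos_s < rpe_s)
        ilm[s], isos[s], rpe[s] = ilm_s, isos_s, rpe_s
        valid[s] = ok & ordered
        interp[s] = shadow & ok

    return LayerSegmentation(ilm=ilm, isos=isos, rpe=rpe, valid=valid, interpolated=interp)
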