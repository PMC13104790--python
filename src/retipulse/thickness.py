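"""En-face retinal-thickness maps and annular summaries around the ONH.

Retinal thickness (RT) is the axial ILM-to-RPE distance per A-scan.  The
summary region is an annulus centered at the (manually annotated) optic nerve
head, inner radius 0.2 mm and outer radius 0.4 mm by default, with explicit
anisotropic mm-per-pixel scales.  Three variants are reported: the full
annulus (RT), excluding superficial-plexus vessel pixels (RT-SVP), and
restricted to vessel pixels (RT@SVP); their difference dRT = RT - RT-SVP
isolates the vascular contribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .segmentation import LayerSegmentation

__all__ = [
    "AnnulusSpec",
    "ThicknessMap",
    "AnnulusSummary",
    "compute_rt_map",
    "annulus_mask",
    "annulus_summary",
    "delta_rt",
    "suggest_onh_center",
]


@dataclass(frozen=True)
class AnnulusSpec:
    """Annular evaluation region in physical units.

    ``center`` is (slow, fast) in pixels; radii in mm; per-axis pixel scales
    in mm/pixel.  Membership is tested at pixel centers, both radii
    inclusive, so pixel counts are exactly reproducible.
    """

    center: tuple[float, float]
    slow_pixel_mm: float
    fast_pixel_mm: float
    r_inner_mm: float = 0.2
    r_outer_mm: float = 0.4

    def __post_init__(self) -> None:
        if not (0 <= self.r_inner_mm < self.r_outer_mm):
            raise ValueError("need 0 <= r_inner < r_outer")
        if self.slow_pixel_mm <= 0 or self.fast_pixel_mm <= 0:
            raise ValueError("pixel scales must be positive")


@dataclass
class AnnulusSummary:
    mean: float
    sd: float
    n: int
    variant: str = "full"


@dataclass
class ThicknessMap:
    """RT per (slow, fast) in micrometres; NaN at invalid A-scans."""

    values_um: np.ndarray
    variant: str = "full"
    axial_pixel_tissue_um: float = float("nan")


def compute_rt_map(seg: LayerSegmentation, axial_pixel_tissue_um: float) -> ThicknessMap:
    """RT = (RPE - ILM) x axial pixel pitch, per A-scan; invalid ones -> NaN."""
    rt = (seg.rpe - seg.ilm).astype(float) * axial_pixel_tissue_um
    rt[~seg.valid] = np.nan
    return ThicknessMap(values_um=rt, variant="full", axial_pixel_tissue_um=axial_pixel_tissue_um)


def annulus_mask(spec: AnnulusSpec, shape: tuple[int, int]) -> np.ndarray:
    """Boolean en-face mask of the annulus on a (n_slow, n_fast) grid.

    Physical distances use the per-axis scales.  An annulus entirely outside
    the grid raises; a partially clipped one warns and reports the clipped
    fraction.
    """
    n_slow, n_fast = shape
    ss, ff = np.mgrid[0:n_slow, 0:n_fast]
    d = np.hypot(
        (ss - spec.center[0]) * spec.slow_pixel_mm,
        (ff - spec.center[1]) * spec.fast_pixel_mm,
    )
    mask = (d >= spec.r_inner_mm) & (d <= spec.r_outer_mm)
    if not mask.any():
        raise ValueError("annulus lies entirely outside the en-face grid")
    # estimate clipping by comparing to the analytic annulus area
    area_px = mask.sum() * spec.slow_pixel_mm * spec.fast_pixel_mm
    area_true = np.pi * (spec.r_outer_mm**2 - spec.r_inner_mm**2)
    if area_px < 0.9 * area_true:
        warnings.warn(
            f"annulus clipped by the grid: covered area {area_px:.4f} mm^2 of "
            f"{area_true:.4f} mm^2",
            stacklevel=2,
        )
    return mask


def annulus_summary(
    values: np.ndarray,
    spec: AnnulusSpec,
    exclude: np.ndarray | None = None,
    restrict_to: np.ndarray | None = None,
    variant: str | None = None,
) -> AnnulusSummary:
    """Mean/SD/count over annulus pixels of an en-face map.

    ``exclude`` removes pixels (e.g. vessel pixels -> RT-SVP);
    ``restrict_to`` keeps only those pixels (-> RT@SVP).  Exactly one of the
    two may be given.  NaN pixels are always excluded.  Sample (n-1) SD; a
    single pixel reports SD 0 by convention.
    """
    if exclude is not None and restrict_to is not None:
        raise ValueError("set at most one of exclude / restrict_to")
    sel = annulus_mask(spec, values.shape) & np.isfinite(values)
    if exclude is not None:
        sel &= ~exclude
        variant = variant or "minus_svp"
    elif restrict_to is not None:
        sel &= restrict_to
        variant = variant or "at_svp"
    else:
        variant = variant or "full"
    n = int(sel.sum())
    if n == 0:
        cause = (
            "all annulus pixels excluded" if exclude is not None
            else "no annulus pixel inside restrict_to" if restrict_to is not None
            else "no valid annulus pixels"
        )
        raise ValueError(f"empty selection for annulus summary: {cause}")
    vals = values[sel]
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return AnnulusSummary(mean=float(vals.mean()), sd=sd, n=n, variant=variant)


def delta_rt(rt_full: AnnulusSummary, rt_minus_svp: AnnulusSummary) -> float:
    """dRT = RT - RT-SVP (micrometres); positive when vessels thicken the retina."""
    if rt_full.variant != "full" or rt_minus_svp.variant != "minus_svp":
        raise ValueError(
            f"expected variants full / minus_svp, got {rt_full.variant} / {rt_minus_svp.variant}"
        )
    return rt_full.mean - rt_minus_svp.mean


def suggest_onh_center(rt_map: ThicknessMap) -> tuple[float, float]:
    """Propose an ONH center as the centroid of the lowest-thickness depression.

    A helper only: the ONH center is a required manual input to the annulus;
    this suggestion never overrides it silently.
    """
    vals = rt_map.values_um
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("no valid thickness pixels")
    thr = np.nanpercentile(vals, 5)
    low = finite & (vals <= thr)
    ss, ff = np.nonzero(low)
    return float(ss.mean()), float(ff.mean())
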