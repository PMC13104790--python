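"""Complex OCT volume container and HDF5/NPZ round-trip I/O.

The pipeline's single input type is a dual-channel (co-/cross-polarized)
complex tomogram stack acquired as repeated B-scans: at each of
``n_slow_positions`` locations along the slow axis, ``n_repeats`` B-scans of
``n_fast`` A-scans are recorded back to back.  Frames are stored slow-major,
i.e. frame index ``f = slow * n_repeats + repeat``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "AcquisitionGeometry",
    "OCTVolume",
    "VolumeFormatError",
    "read_volume",
    "write_volume",
]


class VolumeFormatError(ValueError):
    """Raised when a stored volume is missing required metadata."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Scan protocol and optical metadata of an acquisition.

    Defaults follow the small-animal retinal protocol this package targets:
    400 B-scan locations, each repeated 5 times, 512 A-scans per B-scan at an
    80 kHz A-scan rate, 840 nm central wavelength, a ~1 mm x 1 mm field and
    tissue refractive index 1.35.  ``duty_cycle`` is the fraction of the
    B-scan period spent acquiring; the inter-frame interval is
    ``n_fast / (ascan_rate * duty_cycle)``.
    """

    n_slow_positions: int = 400
    n_repeats: int = 5
    n_fast: int = 512
    n_depth: int = 1024
    ascan_rate: float = 80_000.0
    duty_cycle: float = 1.0
    lambda0_nm: float = 840.0
    axial_pixel_tissue_um: float = 1.55
    lateral_extent_fast_mm: float = 1.0
    lateral_extent_slow_mm: float = 1.0
    refractive_index: float = 1.35

    def __post_init__(self) -> None:
        for name in ("n_slow_positions", "n_repeats", "n_fast", "n_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.ascan_rate <= 0:
            raise ValueError("ascan_rate must be > 0")
        if not (0.0 < self.duty_cycle <= 1.0):
            raise ValueError("duty_cycle must be in (0, 1]")
        if self.lambda0_nm <= 0:
            raise ValueError("lambda0_nm must be > 0")
        if self.refractive_index < 1.0:
            raise ValueError("refractive_index must be >= 1")

    @property
    def n_frames(self) -> int:
        return self.n_slow_positions * self.n_repeats

    @property
    def frame_interval_s(self) -> float:
        """Time between consecutive B-scan frames, seconds (strictly > 0)."""
        return self.n_fast / (self.ascan_rate * self.duty_cycle)

    @property
    def frame_interval_ms(self) -> float:
        return 1e3 * self.frame_interval_s

    @property
    def fast_pixel_mm(self) -> float:
        return self.lateral_extent_fast_mm / self.n_fast

    @property
    def slow_pixel_mm(self) -> float:
        return self.lateral_extent_slow_mm / self.n_slow_positions

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        return cls(**d)


#: geometry fields that must be present in stored metadata
_REQUIRED_FIELDS = tuple(f.name for f in dataclasses.fields(AcquisitionGeometry))


@dataclass
class OCTVolume:
    """Dual-channel complex tomogram stack.

    ``co`` and ``cross`` have shape ``(n_frames, n_depth, n_fast)`` with
    frames ordered slow-major (all repeats of a slow position are
    contiguous).
    """

    co: np.ndarray
    cross: np.ndarray
    geometry: AcquisitionGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (self.geometry.n_frames, self.geometry.n_depth, self.geometry.n_fast)
        for name, arr in (("co", self.co), ("cross", self.cross)):
            if arr.shape != expected:
                raise ValueError(
                    f"channel {name!r} has shape {arr.shape}, geometry implies {expected}"
                )
            if not np.iscomplexobj(arr):
                raise ValueError(f"channel {name!r} must be complex-valued")

    # -- frame indexing -------------------------------------------------
    def frame_index(self, slow: int, repeat: int) -> int:
        return slow * self.geometry.n_repeats + repeat

    def repeats_at(self, slow: int, channel: str = "co") -> np.ndarray:
        """All repeated frames at one slow position, shape (n_repeats, depth, fast)."""
        r = self.geometry.n_repeats
        data = self.co if channel == "co" else self.cross
        return data[slow * r : (slow + 1) * r]

    def mean_intensity_bscan(self, slow: int, channel: str = "co") -> np.ndarray:
        """Repeat-averaged intensity |C|^2 B-scan at one slow position."""
        frames = self.repeats_at(slow, channel)
        return np.mean(np.abs(frames) ** 2, axis=0)


def write_volume(volume: OCTVolume, path: str | Path) -> Path:
    """Write a volume to HDF5 (default) or NPZ (``.npz`` suffix).

    All geometry fields are stored as attributes (HDF5) or a JSON sidecar
    entry (NPZ) so that ``read_volume(write_volume(v))`` reproduces the
    volume and metadata exactly.
    """
    path = Path(path)
    geo = volume.geometry.to_dict()
    if path.suffix == ".npz":
        np.savez(
            path,
            co=volume.co,
            cross=volume.cross,
            geometry_json=np.bytes_(json.dumps(geo).encode()),
        )
    else:
        with h5py.File(path, "w") as f:
            f.create_dataset("co", data=volume.co)
            f.create_dataset("cross", data=volume.cross)
            for k, v in geo.items():
                f.attrs[k] = v
            for k, v in volume.meta.items():
                f.attrs[f"meta_{k}"] = v
    return path


def _geometry_from_mapping(attrs, path: Path) -> AcquisitionGeometry:
    missing = [k for k in _REQUIRED_FIELDS if k not in attrs]
    if missing:
        raise VolumeFormatError(
            f"{path}: missing required metadata field(s): {', '.join(missing)}"
        )
    kwargs = {k: attrs[k] for k in _REQUIRED_FIELDS}
    for k in ("n_slow_positions", "n_repeats", "n_fast", "n_depth"):
        kwargs[k] = int(kwargs[k])
    for k in set(_REQUIRED_FIELDS) - {"n_slow_positions", "n_repeats", "n_fast", "n_depth"}:
        kwargs[k] = float(kwargs[k])
    return AcquisitionGeometry(**kwargs)


def read_volume(path: str | Path) -> OCTVolume:
    """Read a volume written by :func:`write_volume`."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            if "geometry_json" not in z:
                raise VolumeFormatError(f"{path}: missing required metadata field(s): geometry_json")
            geo_map = json.loads(bytes(z["geometry_json"]).decode())
            geometry = _geometry_from_mapping(geo_map, path)
            return OCTVolume(co=z["co"], cross=z["cross"], geometry=geometry)
    with h5py.File(path, "r") as f:
        for ds in ("co", "cross"):
            if ds not in f:
                raise VolumeFormatError(f"{path}: missing dataset {ds!r}")
        geometry = _geometry_from_mapping(dict(f.attrs), path)
        meta = {
            k[len("meta_"):]: v for k, v in f.attrs.items() if k.startswith("meta_")
        }
        return OCTVolume(co=f["co"][...], cross=f["cross"][...], geometry=geometry, meta=meta)
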