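"""Read/write multi-channel 3D stacks with physical voxel spacing.

In-memory convention: voxel data is a numpy array of shape (C, Z, Y, X)
and voxel spacing is a (z, y, x) tuple in micrometers.  Volumes are
stored as plain TIFF with a JSON sidecar (``<file>.json``) recording
spacing, channel roles and sample metadata; OME-TIFF pixel-size
metadata is honoured on read when no sidecar is present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ConfocalVolume", "read_volume", "write_volume", "CHANNEL_ROLES"]

CHANNEL_ROLES = ("nuclear", "ar", "myosin", "other")


@dataclass
class ConfocalVolume:
    """A validated multi-channel confocal volume.

    ``data``: (C, Z, Y, X) non-negative intensities, arbitrary units.
    ``channel_roles``: one role per channel; exactly one "nuclear",
    at most one "ar".
    ``spacing_um``: (z, y, x) voxel spacing in micrometers.
    """

    data: np.ndarray
    channel_roles: tuple[str, ...]
    spacing_um: tuple[float, float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"expected (C, Z, Y, X) data, got shape {self.data.shape}")
        self.channel_roles = tuple(self.channel_roles)
        if len(self.channel_roles) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_roles)} channel roles given for "
                f"{self.data.shape[0]} channels"
            )
        for role in self.channel_roles:
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
        if self.channel_roles.count("nuclear") != 1:
            raise ValueError("exactly one channel must have the 'nuclear' role")
        if self.channel_roles.count("ar") > 1:
            raise ValueError("at most one channel may have the 'ar' role")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError(
                f"voxel spacing must be 3 strictly positive values (z, y, x), "
                f"got {self.spacing_um}"
            )
        if np.issubdtype(self.data.dtype, np.number) and self.data.size:
            if float(self.data.min()) < 0:
                raise ValueError("intensities must be non-negative")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[1:])

    def channel(self, role: str) -> np.ndarray:
        """Return the (Z, Y, X) data of the unique channel with ``role``."""
        idx = [i for i, r in enumerate(self.channel_roles) if r == role]
        if not idx:
            raise KeyError(f"no channel with role {role!r}")
        if len(idx) > 1:
            raise KeyError(f"{len(idx)} channels with role {role!r}; ambiguous")
        return self.data[idx[0]]

    def with_metadata(self, **kwargs) -> "ConfocalVolume":
        return replace(self, metadata={**self.metadata, **kwargs})


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_volume(volume: ConfocalVolume, path) -> Path:
    """Write a volume as plain TIFF plus a JSON sidecar; returns the TIFF path.

    Roundtrip is lossless for integer data (dtype preserved).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, volume.data, photometric="minisblack", metadata={"axes": "CZYX"}
    )
    sidecar = {
        "spacing_um": list(volume.spacing_um),
        "channels": list(volume.channel_roles),
        "metadata": volume.metadata,
        "axes": "CZYX",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def _ome_spacing(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Best-effort (z, y, x) spacing from OME metadata, in micrometers."""
    try:
        ome = tif.ome_metadata
    except Exception:  # pragma: no cover - tifffile internals
        return None
    if not ome:
        return None
    import re

    def grab(attr: str) -> float | None:
        m = re.search(rf'{attr}="([\d.eE+-]+)"', ome)
        return float(m.group(1)) if m else None

    z, y, x = grab("PhysicalSizeZ"), grab("PhysicalSizeY"), grab("PhysicalSizeX")
    if z is None or y is None or x is None:
        return None
    return (z, y, x)


def read_volume(
    path,
    channel_roles: tuple[str, ...] | list[str] | None = None,
    spacing_um: tuple[float, float, float] | None = None,
    metadata: dict | None = None,
) -> ConfocalVolume:
    """Read a TIFF stack into a validated :class:`ConfocalVolume`.

    Spacing and channel roles come from the JSON sidecar when present;
    OME pixel sizes are used as a fallback for spacing.  Explicit
    ``spacing_um`` / ``channel_roles`` arguments override both.  Missing
    spacing with no override is a hard error because all downstream
    physical-unit kernels would be undefined.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = None
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        ome_spacing = _ome_spacing(tif)
    if data.ndim == 2:
        data = data[np.newaxis, np.newaxis]
    elif data.ndim == 3:
        data = data[np.newaxis]
    elif data.ndim != 4:
        raise ValueError(f"cannot interpret TIFF with shape {data.shape} as (C, Z, Y, X)")

    roles = channel_roles
    if roles is None and sidecar is not None:
        roles = sidecar.get("channels")
    if roles is None:
        if data.shape[0] == 1:
            roles = ("nuclear",)
        else:
            raise ValueError(
                "channel roles not given and no sidecar found for a "
                f"{data.shape[0]}-channel file"
            )
    if len(roles) != data.shape[0]:
        raise ValueError(
            f"role map names {len(roles)} channels but file has {data.shape[0]}"
        )

    spacing = spacing_um
    if spacing is None and sidecar is not None:
        spacing = sidecar.get("spacing_um")
    if spacing is None:
        spacing = ome_spacing
    if spacing is None:
        raise ValueError(
            f"{path}: no voxel spacing in metadata; pass spacing_um explicitly "
            "(physical-unit processing is undefined without it)"
        )

    meta = dict(sidecar.get("metadata", {})) if sidecar else {}
    if metadata:
        meta.update(metadata)
    return ConfocalVolume(
        data=data,
        channel_roles=tuple(roles),
        spacing_um=tuple(spacing),
        metadata=meta,
    )


def write_labels(labels: np.ndarray, path, spacing_um=None) -> Path:
    """Write an integer label/mask grid as an unsigned-integer TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(labels)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    tifffile.imwrite(path, arr, photometric="minisblack")
    if spacing_um is not None:
        _sidecar_path(path).write_text(
            json.dumps({"spacing_um": list(spacing_um)}, indent=2)
        )
    return path


def read_labels(path) -> np.ndarray:
    """Read a label/mask TIFF as an integer array."""
    return tifffile.imread(Path(path))
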