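"""Organ segmentation from the nuclear counterstain channel.

Pipeline (all kernel sizes given in micrometers and converted per axis
using the volume's voxel spacing):

1. 3D median filter, anisotropic kernel (default 3.3 x 3.3 x 4.3 um).
2. Plane-by-plane rolling-ball background subtraction (default radius
   66.4 um); a switch retains the estimated background instead, since
   either component may be fed forward.
3. Grayscale morphological closing with an ellipsoidal structuring
   element (default radius 20 um) to fill inter-nuclear gaps.
4. Hysteresis thresholding: voxels at or above the high threshold seed
   the mask; voxels at or above the low threshold are kept iff
   26-connected to a seed.  Defaults: high = Otsu of the enhanced
   volume, low = 0.5 * high; both overridable.

An optional manual-exclusion mask (e.g. abdominal-wall tissue traced by
an observer) is zeroed out before thresholding and can never appear in
the output mask.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import block_reduce
from skimage.restoration import rolling_ball
from skimage.transform import resize

from .volume_io import ConfocalVolume

__all__ = [
    "SegmentationParams",
    "OrganMask",
    "enhance_nuclear_channel",
    "segment_organ",
    "um_to_odd_voxels",
    "um_to_voxel_radius",
    "ellipsoid_footprint",
]

logger = logging.getLogger(__name__)


@dataclass
class SegmentationParams:
    """Physical-unit parameters of the segmentation pipeline.

    Kernel/radius fields are micrometers; thresholds are absolute
    intensities on the enhanced volume, or None for the automatic rule.
    """

    median_kernel_um: tuple[float, float, float] = (4.3, 3.3, 3.3)  # (z, y, x)
    rolling_ball_radius_um: float = 66.4
    closing_radius_um: float = 20.0
    low_threshold: float | None = None
    high_threshold: float | None = None
    low_fraction: float = 0.5  # low = low_fraction * high under the Otsu rule
    subtract_background: bool = True  # False: feed the background estimate forward
    exclusion_mask: np.ndarray | None = None
    max_footprint_elements: int = 2000  # decompose closing SE beyond this

    def __post_init__(self) -> None:
        if len(self.median_kernel_um) != 3 or any(
            k <= 0 for k in self.median_kernel_um
        ):
            raise ValueError("median kernel must be 3 positive extents (z, y, x) um")
        if self.rolling_ball_radius_um <= 0 or self.closing_radius_um <= 0:
            raise ValueError("physical radii must be > 0")
        if not (0.0 < self.low_fraction <= 1.0):
            raise ValueError("low_fraction must be in (0, 1]")
        if (
            self.low_threshold is not None
            and self.high_threshold is not None
            and self.low_threshold > self.high_threshold
        ):
            raise ValueError("low threshold must be <= high threshold")


@dataclass
class OrganMask:
    """Boolean organ mask with the resolved parameters that produced it."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("organ mask must be 3D (z, y, x)")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def um_to_odd_voxels(extent_um: float, spacing_um: float) -> int:
    """Nearest odd voxel count >= 1 for a physical kernel extent (ties round up)."""
    v = extent_um / spacing_um
    return max(1, 2 * math.floor(v / 2.0) + 1)


def um_to_voxel_radius(radius_um: float, spacing_um: float) -> int:
    """Nearest integer voxel radius >= 1 for a physical radius."""
    return max(1, round(radius_um / spacing_um))


def ellipsoid_footprint(rz: int, ry: int, rx: int) -> np.ndarray:
    """Boolean ellipsoidal structuring element with the given voxel radii."""
    zz, yy, xx = np.ogrid[-rz : rz + 1, -ry : ry + 1, -rx : rx + 1]
    return (
        (zz / max(rz, 0.5)) ** 2
        + (yy / max(ry, 0.5)) ** 2
        + (xx / max(rx, 0.5)) ** 2
    ) <= 1.0 + 1e-9


def _decompose_radii(rz: int, ry: int, rx: int, max_elements: int) -> list[tuple[int, int, int]]:
    """Split ellipsoid radii into a sequence whose Minkowski sum has the target radii.

    Iterated dilation with the small elements approximates dilation with
    the full ellipsoid at a fraction of the cost; radii add exactly per
    axis, the digital boundary is approximated.
    """
    full = ellipsoid_footprint(rz, ry, rx)
    if full.sum() <= max_elements:
        return [(rz, ry, rx)]
    k = 2
    while True:
        step = (math.ceil(rz / k), math.ceil(ry / k), math.ceil(rx / k))
        if ellipsoid_footprint(*step).sum() <= max_elements:
            break
        k += 1
    seq = []
    rem = [rz, ry, rx]
    while any(rem):
        cur = tuple(min(s, r) for s, r in zip(step, rem))
        cur = tuple(max(c, 0) for c in cur)
        seq.append(cur)
        rem = [r - c for r, c in zip(rem, cur)]
    return seq


def _grey_closing_ellipsoid(
    image: np.ndarray, radii_vox: tuple[int, int, int], max_elements: int
) -> np.ndarray:
    seq = _decompose_radii(*radii_vox, max_elements=max_elements)
    out = image
    for radii in seq:
        fp = ellipsoid_footprint(*radii)
        out = ndi.grey_dilation(out, footprint=fp)
    for radii in reversed(seq):
        fp = ellipsoid_footprint(*radii)
        out = ndi.grey_erosion(out, footprint=fp)
    return out


def _rolling_ball_plane(
    plane: np.ndarray, radius_px: float, max_direct_radius: float = 16.0
) -> np.ndarray:
    """Rolling-ball background estimate of one z-plane.

    Large radii use the standard shrink trick: block-minimum downscale,
    roll a proportionally smaller ball, bilinear upscale, clip under the
    image.
    """
    plane = plane.astype(np.float64, copy=False)
    if radius_px <= max_direct_radius:
        return rolling_ball(plane, radius=radius_px)
    shrink = int(np.ceil(radius_px / max_direct_radius))
    # partial edge blocks must not see the pad value: pad with +inf for a min
    small = block_reduce(plane, (shrink, shrink), np.min, cval=np.inf)
    bg_small = rolling_ball(small, radius=radius_px / shrink)
    bg = resize(bg_small, plane.shape, order=1, anti_aliasing=False)
    return np.minimum(bg, plane)


def enhance_nuclear_channel(
    volume: ConfocalVolume, params: SegmentationParams | None = None
) -> np.ndarray:
    """Median -> per-plane rolling ball -> grayscale closing on the nuclear channel.

    Returns a float (Z, Y, X) grid.  Also attaches the resolved
    voxel-unit parameters to ``volume.metadata['enhancement']``.
    """
    params = params or SegmentationParams()
    nuclear = volume.channel("nuclear").astype(np.float64)
    sz, sy, sx = volume.spacing_um

    kz, ky, kx = params.median_kernel_um
    kernel = (
        um_to_odd_voxels(kz, sz),
        um_to_odd_voxels(ky, sy),
        um_to_odd_voxels(kx, sx),
    )
    if kernel == (1, 1, 1):
        warnings.warn(
            "median kernel resolves to a single voxel on every axis; "
            "median step is the identity",
            stacklevel=2,
        )
        filtered = nuclear
    else:
        filtered = ndi.median_filter(nuclear, size=kernel)

    # in-plane (y, x) pixel scale for the per-plane rolling ball
    inplane = math.sqrt(sy * sx)
    radius_px = params.rolling_ball_radius_um / inplane
    out = np.empty_like(filtered)
    for z in range(filtered.shape[0]):
        bg = _rolling_ball_plane(filtered[z], radius_px)
        out[z] = (filtered[z] - bg) if params.subtract_background else bg

    radii = (
        um_to_voxel_radius(params.closing_radius_um, sz),
        um_to_voxel_radius(params.closing_radius_um, sy),
        um_to_voxel_radius(params.closing_radius_um, sx),
    )
    closed = _grey_closing_ellipsoid(out, radii, params.max_footprint_elements)
    volume.metadata.setdefault("enhancement", {}).update(
        {
            "median_kernel_vox": list(kernel),
            "rolling_ball_radius_px": radius_px,
            "closing_radii_vox": list(radii),
            "subtract_background": params.subtract_background,
        }
    )
    return closed


def _hysteresis(enhanced: np.ndarray, low: float, high: float) -> np.ndarray:
    """Keep low-threshold voxels 26-connected to a high-threshold seed."""
    mask_low = enhanced >= low
    mask_high = enhanced >= high
    if not mask_high.any():
        return np.zeros_like(mask_low)
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, _ = ndi.label(mask_low, structure=structure)
    seed_labels = np.unique(labels[mask_high])
    seed_labels = seed_labels[seed_labels > 0]
    return np.isin(labels, seed_labels)


def segment_organ(
    volume: ConfocalVolume, params: SegmentationParams | None = None
) -> OrganMask:
    """Full organ segmentation: enhance, exclude, hysteresis-threshold."""
    params = params or SegmentationParams()
    enhanced = enhance_nuclear_channel(volume, params)
    if params.exclusion_mask is not None:
        excl = np.asarray(params.exclusion_mask, dtype=bool)
        if excl.shape != enhanced.shape:
            raise ValueError(
                f"exclusion mask shape {excl.shape} != volume shape {enhanced.shape}"
            )
        enhanced = enhanced.copy()
        enhanced[excl] = 0.0

    high = params.high_threshold
    if high is None:
        if np.ptp(enhanced) == 0:
            high = float(enhanced.flat[0]) + 1.0  # constant volume: nothing to seed
        else:
            high = float(threshold_otsu(enhanced))
    low = params.low_threshold
    if low is None:
        low = params.low_fraction * high
    if low > high:
        raise ValueError(f"low threshold {low} exceeds high threshold {high}")

    mask = _hysteresis(enhanced, low, high)
    if not mask.any():
        logger.warning("no voxel reached the high threshold (%.4g); empty mask", high)
    if params.exclusion_mask is not None:
        mask &= ~np.asarray(params.exclusion_mask, dtype=bool)
    return OrganMask(
        mask=mask,
        provenance={
            "low_threshold": float(low),
            "high_threshold": float(high),
            "specimen_id": volume.metadata.get("specimen_id", ""),
            **volume.metadata.get("enhancement", {}),
        },
    )
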