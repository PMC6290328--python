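"""Tip/core partition of the segmented organ and regional AR-intensity summaries.

The organ mask is split into a "tip" region (between the cord and the
dense muscular layer, normally traced by a masked observer and supplied
as a mask file) and a "core" region (everything else in the organ).
Regional means are always computed on the RAW AR channel, never the
enhanced one.  A geometric stand-in for the observer
(:func:`default_tip_partition`) cuts the organ at a fraction of its
extent along the principal axis nearest a cord landmark, for fully
synthetic pipelines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .group_stats import (
    DEFAULT_ALPHA,
    GroupComparisonResult,
    paired_sign_flip,
    paired_t,
)
from .organ_segmentation import OrganMask
from .volume_io import ConfocalVolume

__all__ = [
    "RegionLabels",
    "RegionIntensitySummary",
    "LABEL_OUTSIDE",
    "LABEL_CORE",
    "LABEL_TIP",
    "load_region_labels",
    "default_tip_partition",
    "summarize_regions",
    "compare_regions",
]

LABEL_OUTSIDE = 0
LABEL_CORE = 1
LABEL_TIP = 2


@dataclass
class RegionLabels:
    """Integer label grid: 0 outside organ, 1 core, 2 tip."""

    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("region labels must be 3D (z, y, x)")
        bad = set(np.unique(self.labels)) - {LABEL_OUTSIDE, LABEL_CORE, LABEL_TIP}
        if bad:
            raise ValueError(f"unexpected label values {sorted(bad)}")

    @property
    def organ_mask(self) -> np.ndarray:
        return self.labels != LABEL_OUTSIDE

    @property
    def tip_mask(self) -> np.ndarray:
        return self.labels == LABEL_TIP

    @property
    def core_mask(self) -> np.ndarray:
        return self.labels == LABEL_CORE


@dataclass(frozen=True)
class RegionIntensitySummary:
    """Per-specimen regional means of the raw AR channel."""

    specimen_id: str
    strain: str
    day: str
    tip_mean: float  # nan when the region is empty
    core_mean: float
    tip_voxels: int
    core_voxels: int

    @property
    def ratio(self) -> float:
        """tip mean / core mean; nan (undefined) when core is empty."""
        if self.core_voxels == 0 or math.isnan(self.core_mean):
            return math.nan
        return self.tip_mean / self.core_mean


def load_region_labels(
    mask: OrganMask, tip_mask: np.ndarray, provenance: dict | None = None
) -> RegionLabels:
    """Combine an organ mask with an observer-supplied tip mask.

    Labels are tip where the tip mask intersects the organ, core on the
    rest of the organ.  A tip mask that misses the organ entirely is an
    observer/grid mismatch and raises.
    """
    tip = np.asarray(tip_mask, dtype=bool)
    if tip.shape != mask.mask.shape:
        raise ValueError(
            f"tip mask shape {tip.shape} != organ mask shape {mask.mask.shape}"
        )
    tip_in_organ = tip & mask.mask
    if mask.mask.any() and not tip_in_organ.any():
        raise ValueError(
            "tip mask does not intersect the organ mask; check observer input/grid"
        )
    labels = np.zeros(mask.mask.shape, dtype=np.uint8)
    labels[mask.mask] = LABEL_CORE
    labels[tip_in_organ] = LABEL_TIP
    if not (labels[mask.mask] != LABEL_OUTSIDE).all():  # defensive, by construction
        raise AssertionError("partition must cover the organ mask")
    return RegionLabels(labels=labels, provenance=provenance or {"source": "observer"})


def default_tip_partition(
    mask: OrganMask,
    landmark_zyx_um: tuple[float, float, float],
    tip_fraction: float,
    spacing_um: tuple[float, float, float],
    max_landmark_distance_um: float = 60.0,
) -> RegionLabels:
    """Geometric stand-in for the manual tip tracing.

    The organ's principal axis is found by PCA of its voxel coordinates
    (in micrometers), oriented toward the cord landmark; the tip is the
    ``tip_fraction`` of the organ extent nearest the landmark along that
    axis.
    """
    if not (0.0 < tip_fraction < 1.0):
        raise ValueError(f"tip fraction must be in (0, 1), got {tip_fraction}")
    if not mask.mask.any():
        raise ValueError("cannot partition an empty organ mask")
    coords_vox = np.argwhere(mask.mask).astype(float)
    coords = coords_vox * np.asarray(spacing_um, dtype=float)
    landmark = np.asarray(landmark_zyx_um, dtype=float)
    nearest = float(np.sqrt(((coords - landmark) ** 2).sum(axis=1)).min())
    if nearest > max_landmark_distance_um:
        raise ValueError(
            f"cord landmark is {nearest:.1f} um from the organ "
            f"(limit {max_landmark_distance_um} um); wrong grid or landmark?"
        )
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / len(centered)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, np.argmax(eigvals)]
    if axis @ (landmark - centroid) < 0:
        axis = -axis
    proj = centered @ axis
    lo, hi = float(proj.min()), float(proj.max())
    cut = hi - tip_fraction * (hi - lo)
    labels = np.zeros(mask.mask.shape, dtype=np.uint8)
    flat_idx = tuple(coords_vox.astype(int).T)
    labels[flat_idx] = np.where(proj >= cut, LABEL_TIP, LABEL_CORE)
    return RegionLabels(
        labels=labels,
        provenance={
            "source": "synthetic",
            "landmark_zyx_um": list(map(float, landmark_zyx_um)),
            "tip_fraction": float(tip_fraction),
        },
    )


def summarize_regions(
    volume: ConfocalVolume, labels: RegionLabels
) -> RegionIntensitySummary:
    """Mean raw AR intensity over the tip and core regions.

    Empty regions yield nan means (undefined), never zero.
    """
    ar = volume.channel("ar").astype(np.float64)
    if ar.shape != labels.labels.shape:
        raise ValueError(
            f"AR channel shape {ar.shape} != label grid shape {labels.labels.shape}"
        )

    def region_mean(region: np.ndarray) -> tuple[float, int]:
        n = int(region.sum())
        if n == 0:
            return math.nan, 0
        return float(ar[region].sum() / n), n

    tip_mean, tip_n = region_mean(labels.tip_mask)
    core_mean, core_n = region_mean(labels.core_mask)
    if core_n == 0:
        warnings.warn("core region is empty; tip:core ratio undefined", stacklevel=2)
    return RegionIntensitySummary(
        specimen_id=str(volume.metadata.get("specimen_id", "")),
        strain=str(volume.metadata.get("strain", "")),
        day=str(volume.metadata.get("day", "")),
        tip_mean=tip_mean,
        core_mean=core_mean,
        tip_voxels=tip_n,
        core_voxels=core_n,
    )


def compare_regions(
    summaries,
    method: str = "paired_t",
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, GroupComparisonResult]:
    """Tip-vs-core comparison within each (strain, day) group.

    ``method``: "paired_t" (default, two-sided) or "permutation" (exact
    sign-flip on per-specimen differences).  Groups with fewer than two
    specimens are skipped with a warning.
    """
    if method not in ("paired_t", "permutation"):
        raise ValueError("method must be 'paired_t' or 'permutation'")
    by_group: dict[tuple[str, str], list[RegionIntensitySummary]] = {}
    for s in summaries:
        if math.isnan(s.tip_mean) or math.isnan(s.core_mean):
            warnings.warn(
                f"specimen {s.specimen_id!r} has an empty region; excluded",
                stacklevel=2,
            )
            continue
        by_group.setdefault((s.strain, s.day), []).append(s)
    results: dict[str, GroupComparisonResult] = {}
    for (strain, day), group in sorted(by_group.items()):
        if len(group) < 2:
            warnings.warn(
                f"group strain={strain!r} day={day!r} has n < 2; skipped",
                stacklevel=2,
            )
            continue
        tips = [s.tip_mean for s in group]
        cores = [s.core_mean for s in group]
        if method == "paired_t":
            res = paired_t(tips, cores, alpha=alpha)
        else:
            res = paired_sign_flip(tips, cores, alpha=alpha)
        results[f"{strain}|{day}"] = res
    return results
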