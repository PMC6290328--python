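"""Muscle-fiber morphometry: object measurement, background filtering, summaries.

Objects are measured from an integer-labeled 2D mask: area from pixel
counts, feret diameters by rotating calipers over the convex hull of
pixel extents, aspect as feret max / feret min.  The background filter
deletes records failing the aspect/area cutoffs (defaults: aspect < 5
or area < 500 um^2 deleted); group summaries are geometric (log-scale)
statistics with cross-group tests on log values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .group_stats import DEFAULT_ALPHA, one_way_anova, two_sample_t

__all__ = [
    "FiberRecord",
    "measure_objects",
    "filter_fibers",
    "summarize_morphology",
    "records_to_frame",
    "frame_to_records",
]

AREA_CUTOFF_UM2 = 500.0
ASPECT_CUTOFF = 5.0


@dataclass(frozen=True)
class FiberRecord:
    """One measured object from the muscle-outgrowth assay."""

    object_id: int
    area_um2: float
    feret_min_um: float
    feret_max_um: float
    aspect: float
    strain: str = ""
    treatment: str = ""
    true_class: str | None = None  # generator-only ground truth, hidden downstream

    def __post_init__(self) -> None:
        if not (self.area_um2 > 0):
            raise ValueError(f"area must be > 0, got {self.area_um2}")
        if not (self.feret_max_um >= self.feret_min_um > 0):
            raise ValueError(
                f"need feret max >= feret min > 0, got "
                f"({self.feret_min_um}, {self.feret_max_um})"
            )
        if self.aspect < 1.0 - 1e-9:
            raise ValueError(f"aspect must be >= 1, got {self.aspect}")


def _caliper_widths(points: np.ndarray) -> tuple[float, float]:
    """(min, max) caliper width of a planar point set, in point units.

    Max width is the hull diameter; min width is the smallest distance
    between parallel supporting lines, attained on a hull edge.
    Degenerate sets (single point / collinear) fall back to the segment
    length and zero thickness.
    """
    pts = np.unique(points, axis=0)
    if len(pts) == 1:
        return 0.0, 0.0
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except QhullError:  # collinear
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        return 0.0, float(d.max())
    diffs = verts[:, None] - verts[None, :]
    fmax = float(np.sqrt((diffs**2).sum(axis=-1)).max())
    fmin = math.inf
    n = len(verts)
    for i in range(n):
        edge = verts[(i + 1) % n] - verts[i]
        length = np.linalg.norm(edge)
        if length == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / length
        width = float(np.abs((verts - verts[i]) @ normal).max())
        fmin = min(fmin, width)
    return fmin, fmax


def measure_objects(
    labels: np.ndarray,
    pixel_um: float,
    strain: str = "",
    treatment: str = "",
) -> list[FiberRecord]:
    """Measure every labeled object in a 2D integer mask.

    Area is pixel count times pixel area.  Feret diameters are caliper
    widths of the pixel-center hull plus one pixel (accounting for the
    unit extent of each pixel), so a single pixel measures one pixel
    across in every direction and an axis-aligned w x h rectangle
    measures feret min = min(w, h).
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("measure_objects expects a 2D labeled mask")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("labeled mask must have an integer dtype")
    if not (pixel_um > 0):
        raise ValueError(f"pixel size must be > 0, got {pixel_um}")
    records = []
    for obj_id in np.unique(labels):
        if obj_id == 0:
            continue
        rr, cc = np.nonzero(labels == obj_id)
        pts = np.column_stack([rr, cc]).astype(float)
        fmin, fmax = _caliper_widths(pts)
        feret_min = (fmin + 1.0) * pixel_um
        feret_max = (fmax + 1.0) * pixel_um
        records.append(
            FiberRecord(
                object_id=int(obj_id),
                area_um2=float(len(pts)) * pixel_um**2,
                feret_min_um=feret_min,
                feret_max_um=feret_max,
                aspect=feret_max / feret_min,
                strain=strain,
                treatment=treatment,
            )
        )
    return records


def filter_fibers(
    records: Iterable[FiberRecord],
    area_cutoff: float = AREA_CUTOFF_UM2,
    aspect_cutoff: float = ASPECT_CUTOFF,
    combine: str = "all",
) -> list[FiberRecord]:
    """Delete background objects below the morphometric cutoffs.

    Default (``combine="all"``): a record is retained iff
    aspect >= aspect_cutoff AND area >= area_cutoff; values exactly at a
    cutoff are retained (the deletion rule is strict "<").
    ``combine="any"`` retains records passing either cutoff (delete only
    when both fail).  Order-preserving and idempotent.
    """
    if combine not in ("all", "any"):
        raise ValueError("combine must be 'all' or 'any'")
    out = []
    for r in records:
        pass_aspect = r.aspect >= aspect_cutoff
        pass_area = r.area_um2 >= area_cutoff
        keep = (pass_aspect and pass_area) if combine == "all" else (pass_aspect or pass_area)
        if keep:
            out.append(r)
    return out


def _geometric_stats(values: Sequence[float]) -> dict:
    logs = np.log(np.asarray(values, dtype=float))
    return {
        "n": int(logs.size),
        "geometric_mean": float(np.exp(logs.mean())),
        "geometric_sd": float(np.exp(logs.std(ddof=1))) if logs.size > 1 else math.nan,
    }


METRICS = {
    "area": lambda r: r.area_um2,
    "length": lambda r: r.feret_max_um,
    "aspect": lambda r: r.aspect,
}


def summarize_morphology(
    grouped: dict[str, Sequence[FiberRecord]],
    alpha: float = DEFAULT_ALPHA,
    test: str = "anova",
) -> dict:
    """Per-group geometric summaries of area, length and aspect, plus tests.

    Cross-group tests run on log-transformed values (one-way ANOVA for
    >= 3 groups, pooled t for 2) and require every group to contribute
    at least 2 records; otherwise tests are skipped with a note.
    """
    groups = {k: list(v) for k, v in grouped.items() if len(v) > 0}
    empty = [k for k, v in grouped.items() if len(v) == 0]
    if empty:
        warnings.warn(f"empty groups excluded from summaries: {empty}", stacklevel=2)
    summary: dict = {"groups": {}, "tests": {}, "excluded_empty_groups": empty}
    for key, recs in groups.items():
        summary["groups"][key] = {
            m: _geometric_stats([f(r) for r in recs]) for m, f in METRICS.items()
        }
    testable = len(groups) >= 2 and all(len(v) >= 2 for v in groups.values())
    if not testable:
        summary["tests"] = {"note": "skipped: need >= 2 groups with n >= 2 each"}
        return summary
    keys = sorted(groups)
    for metric, f in METRICS.items():
        samples = [np.log([f(r) for r in groups[k]]) for k in keys]
        if len(samples) == 2:
            res = two_sample_t(samples[0], samples[1], alpha=alpha)
        else:
            res = one_way_anova(samples, alpha=alpha)
        summary["tests"][metric] = res
    summary["n_tests"] = len(METRICS)
    return summary


def records_to_frame(records: Sequence[FiberRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "object_id": [r.object_id for r in records],
            "area_um2": [r.area_um2 for r in records],
            "feret_min_um": [r.feret_min_um for r in records],
            "feret_max_um": [r.feret_max_um for r in records],
            "aspect": [r.aspect for r in records],
            "strain": [r.strain for r in records],
            "treatment": [r.treatment for r in records],
            "true_class": [r.true_class for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[FiberRecord]:
    records = []
    for _, row in df.iterrows():
        records.append(
            FiberRecord(
                object_id=int(row.get("object_id", 0)),
                area_um2=float(row["area_um2"]),
                feret_min_um=float(row["feret_min_um"]),
                feret_max_um=float(row["feret_max_um"]),
                aspect=float(row["aspect"]),
                strain=str(row.get("strain", "") or ""),
                treatment=str(row.get("treatment", "") or ""),
                true_class=(
                    None
                    if "true_class" not in row or pd.isna(row["true_class"])
                    else str(row["true_class"])
                ),
            )
        )
    return records
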