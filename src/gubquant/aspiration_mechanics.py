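"""Micropipette-aspiration mechanics: apparent elastic modulus of soft tissue.

The elastic half-space model gives the apparent modulus of aspirated
tissue as

    E_app = 3 a dp / (2 pi L Phi(a, w))

with ``a`` the pipette inner radius, ``dp`` the magnitude of the applied
suction pressure, ``L`` the aspirated length, and ``Phi`` a
dimensionless wall function of the pipette geometry.  Two published
algebraic readings of the wall function are provided (see
:func:`wall_function`); the product form is the default.

Pressures are handled as positive magnitudes throughout: a suction of
-70 kPa enters as ``dp = 70``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .group_stats import (
    DEFAULT_ALPHA,
    GroupComparisonResult,
    mann_whitney_u,
    one_way_anova,
    two_sample_t,
    welch_pair_detail,
)

__all__ = [
    "AspirationMeasurement",
    "ModulusResult",
    "PHI_FORMS",
    "wall_function",
    "apparent_modulus",
    "assign_position",
    "regional_analysis",
    "load_measurements",
    "moduli_table",
]

#: canonical anatomic position labels along the organ's outer curvature
POSITIONS = ("base", "midportion", "tip")

#: height-fraction bands defining each position (inclusive bounds)
POSITION_BANDS = {
    "base": (0.0, 0.25),
    "midportion": (0.40, 0.60),
    "tip": (0.75, 1.0),
}

PHI_FORMS = ("product", "ratio")


@dataclass(frozen=True)
class AspirationMeasurement:
    """One aspiration record: pipette geometry, pressure, response, context."""

    a_um: float
    w_um: float
    dp_kpa: float
    L_um: float
    position: str | None = None
    height_fraction: float | None = None
    strain: str = ""
    day: str = ""
    specimen_id: str = ""

    def __post_init__(self) -> None:
        for name in ("a_um", "w_um", "dp_kpa", "L_um"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.height_fraction is not None and not (
            0.0 <= self.height_fraction <= 1.0
        ):
            raise ValueError(
                f"height_fraction must be in [0, 1], got {self.height_fraction}"
            )

    def resolved_position(self) -> str | None:
        if self.position is not None:
            return self.position
        if self.height_fraction is not None:
            return assign_position(self.height_fraction)
        return None


@dataclass(frozen=True)
class ModulusResult:
    """Apparent modulus for one measurement, with provenance."""

    e_app_kpa: float
    phi: float
    position: str | None
    strain: str = ""
    day: str = ""
    specimen_id: str = ""
    measurement: AspirationMeasurement | None = field(default=None, repr=False)


def wall_function(a: float, w: float, form: str = "product") -> float:
    """Dimensionless pipette wall function Phi(a, w).

    ``form="product"`` (default):
        Phi = 1/2 * (1 + w/a) * (1 + w/(2a)) * ln(8a/w)
    ``form="ratio"`` (alternative reading):
        Phi = (1 + w/(2a)) * ln(8a/w) / (2 * (1 + w/a))

    Both depend only on w/a and require 0 < w < 8a so the logarithm is
    positive.
    """
    if form not in PHI_FORMS:
        raise ValueError(f"unknown wall-function form {form!r}; use one of {PHI_FORMS}")
    if not (a > 0 and w > 0):
        raise ValueError(f"pipette radius and wall thickness must be > 0 (a={a}, w={w})")
    if w >= 8.0 * a:
        raise ValueError(
            f"wall thickness w={w} must be < 8a={8.0 * a} for a positive logarithm"
        )
    r = w / a
    log_term = math.log(8.0 / r)
    if form == "product":
        return 0.5 * (1.0 + r) * (1.0 + 0.5 * r) * log_term
    return (1.0 + 0.5 * r) * log_term / (2.0 * (1.0 + r))


def apparent_modulus(
    m: AspirationMeasurement, phi_form: str = "product"
) -> ModulusResult:
    """E_app = 3 a dp / (2 pi L Phi), in kPa for micrometer lengths and kPa pressure."""
    phi = wall_function(m.a_um, m.w_um, form=phi_form)
    e_app = 3.0 * m.a_um * m.dp_kpa / (2.0 * math.pi * m.L_um * phi)
    return ModulusResult(
        e_app_kpa=e_app,
        phi=phi,
        position=m.resolved_position(),
        strain=m.strain,
        day=m.day,
        specimen_id=m.specimen_id,
        measurement=m,
    )


def assign_position(height_fraction: float) -> str | None:
    """Map a height fraction (0 = pelvic floor, 1 = cord) to an anatomic band.

    <= 0.25 is base, [0.40, 0.60] is midportion, >= 0.75 is tip; fractions
    between the bands are unassigned (None) and excluded from analysis.
    """
    h = float(height_fraction)
    if not (0.0 <= h <= 1.0):
        raise ValueError(f"height fraction must be in [0, 1], got {h}")
    for label, (lo, hi) in POSITION_BANDS.items():
        if lo <= h <= hi:
            return label
    return None


def regional_analysis(
    results: Iterable[ModulusResult],
    day_test: str = "t",
    alpha: float = DEFAULT_ALPHA,
) -> dict:
    """Regional and gestational comparisons of apparent moduli.

    Per (strain, day): one-way ANOVA of E_app across the three anatomic
    positions, followed by descriptive unadjusted pairwise contrasts.
    Per (strain, position): two-sample comparison across gestational
    days (``day_test`` = "t" for pooled t, "mannwhitney" for
    Mann-Whitney U).  Contrasts lacking two groups of n >= 2 are skipped
    with a warning.
    """
    if day_test not in ("t", "mannwhitney"):
        raise ValueError("day_test must be 't' or 'mannwhitney'")
    kept = [r for r in results if r.position in POSITIONS]
    by_strain_day: dict[tuple[str, str], dict[str, list[float]]] = {}
    by_strain_pos: dict[tuple[str, str], dict[str, list[float]]] = {}
    for r in kept:
        by_strain_day.setdefault((r.strain, r.day), {}).setdefault(
            r.position, []
        ).append(r.e_app_kpa)
        by_strain_pos.setdefault((r.strain, r.position), {}).setdefault(
            r.day, []
        ).append(r.e_app_kpa)

    report: dict = {"position_effects": {}, "day_effects": {}, "n_tests": 0}
    for (strain, day), groups in sorted(by_strain_day.items()):
        usable = {p: v for p, v in groups.items() if len(v) >= 2}
        if len(usable) < 2:
            warnings.warn(
                f"skipping position contrast for strain={strain!r} day={day!r}: "
                "fewer than 2 positions with n >= 2",
                stacklevel=2,
            )
            continue
        ordered = [p for p in POSITIONS if p in usable]
        anova = one_way_anova([usable[p] for p in ordered], alpha=alpha)
        pairwise = {}
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                pa, pb = ordered[i], ordered[j]
                pairwise[f"{pa}_vs_{pb}"] = welch_pair_detail(
                    usable[pa], usable[pb], alpha=alpha
                )
        report["position_effects"][f"{strain}|{day}"] = {
            "anova": anova,
            "group_means": {p: float(np.mean(usable[p])) for p in ordered},
            "pairwise_descriptive": pairwise,
        }
        report["n_tests"] += 1
    for (strain, pos), by_day in sorted(by_strain_pos.items()):
        days = sorted(by_day)
        if len(days) != 2 or any(len(by_day[d]) < 2 for d in days):
            warnings.warn(
                f"skipping day contrast for strain={strain!r} position={pos!r}: "
                "need exactly 2 days with n >= 2",
                stacklevel=2,
            )
            continue
        x, y = by_day[days[0]], by_day[days[1]]
        if day_test == "t":
            res = two_sample_t(x, y, equal_var=True, alpha=alpha)
        else:
            res = mann_whitney_u(x, y, alpha=alpha)
        report["day_effects"][f"{strain}|{pos}|{days[0]}_vs_{days[1]}"] = res
        report["n_tests"] += 1
    return report


# ---------------------------------------------------------------------------
# tabular I/O

CSV_COLUMNS = [
    "specimen_id",
    "strain",
    "day",
    "position",
    "height_fraction",
    "a_um",
    "w_um",
    "dp_kpa",
    "L_um",
]


def load_measurements(path) -> list[AspirationMeasurement]:
    """Read aspiration records from CSV (columns as in :data:`CSV_COLUMNS`).

    Either ``position`` or ``height_fraction`` must be present per row.
    """
    df = pd.read_csv(path)
    required = {"a_um", "w_um", "dp_kpa", "L_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        pos = row.get("position")
        pos = None if pd.isna(pos) else str(pos)
        hf = row.get("height_fraction")
        hf = None if hf is None or pd.isna(hf) else float(hf)
        if pos is None and hf is None:
            raise ValueError("each row needs a position or a height_fraction")
        out.append(
            AspirationMeasurement(
                a_um=float(row["a_um"]),
                w_um=float(row["w_um"]),
                dp_kpa=float(row["dp_kpa"]),
                L_um=float(row["L_um"]),
                position=pos,
                height_fraction=hf,
                strain=str(row.get("strain", "")),
                day=str(row.get("day", "")),
                specimen_id=str(row.get("specimen_id", "")),
            )
        )
    return out


def moduli_table(results: Sequence[ModulusResult]) -> pd.DataFrame:
    """Flatten modulus results to a tidy frame (one row per measurement)."""
    return pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in results],
            "strain": [r.strain for r in results],
            "day": [r.day for r in results],
            "position": [r.position for r in results],
            "e_app_kpa": [r.e_app_kpa for r in results],
            "phi": [r.phi for r in results],
        }
    )
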