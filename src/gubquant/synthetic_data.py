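"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators, each a pure function of (spec, seed):

* :func:`generate_confocal_volume` — an organ-shaped phantom (ellipsoid
  body plus a cylindrical cord appendage) filled with spherical nuclei.
  The nuclear channel carries bright blobs at the nucleus positions; the
  AR channel carries, at each nucleus, the generative mean of its region
  (tip, core, or muscle shell — shell nuclei are AR-poor).  Voxel-exact
  organ and tip/core ground truth is returned alongside.
* :func:`generate_aspiration_cohort` — aspiration records drawn through
  the forward half-space model: L = 3 a dp / (2 pi E Phi(a, w)) with
  region- and day-dependent true moduli, then multiplicative
  measurement noise on L.
* :func:`generate_fiber_table` — fiber/debris morphometry tables with a
  hidden true-class column for testing the background filter.

A lightweight summary-level cohort simulator
(:func:`simulate_intensity_cohort`) supports power/type-I experiments
on the regional-intensity comparison without rendering volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .aspiration_mechanics import AspirationMeasurement, wall_function
from .fiber_morphometry import FiberRecord
from .organ_segmentation import OrganMask
from .region_quantification import (
    LABEL_CORE,
    LABEL_TIP,
    RegionIntensitySummary,
    RegionLabels,
)
from .volume_io import ConfocalVolume

__all__ = [
    "VolumePhantomSpec",
    "AspirationCohortSpec",
    "FiberTableSpec",
    "generate_confocal_volume",
    "generate_aspiration_cohort",
    "generate_fiber_table",
    "simulate_intensity_cohort",
]


# ---------------------------------------------------------------------------
# confocal phantom


@dataclass
class VolumePhantomSpec:
    """Geometry, intensity and noise model of the organ phantom.

    All physical quantities are micrometers; axis order is (z, y, x).
    The organ is an ellipsoid (body) with a cylindrical cord appendage
    extending along +z from the ellipsoid top; the tip is the
    ``tip_fraction`` of the organ's z-extent adjacent to the cord; the
    muscle shell is the outer layer of the ellipsoid body.
    """

    shape: tuple[int, int, int] = (64, 128, 128)
    spacing_um: tuple[float, float, float] = (2.15, 1.1, 1.1)
    semi_axes_um: tuple[float, float, float] = (48.0, 40.0, 40.0)
    center_um: tuple[float, float, float] | None = None  # default: fitted near grid center
    cord_length_um: float = 25.0
    cord_radius_um: float = 10.0
    tip_fraction: float = 0.25
    nuclear_density_per_1000um3: float = 8.0
    nucleus_radius_um: float = 4.0
    nucleus_profile: str = "solid"  # or "gaussian"
    nuclear_peak: float = 1000.0
    ar_core_mean: float = 200.0
    ar_tip_mean: float = 300.0
    ar_muscle_mean: float = 20.0
    background_mean: float = 10.0
    cytoplasmic_fraction: float = 0.0
    muscle_shell_um: float = 8.0
    noise_sigma: float = 10.0
    poisson_scale: float | None = None
    include_myosin: bool = False
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        self.semi_axes_um = tuple(float(s) for s in self.semi_axes_um)
        if self.center_um is not None:
            self.center_um = tuple(float(c) for c in self.center_um)
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be 3 positive ints (z, y, x), got {self.shape}")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("voxel spacing must be strictly positive per axis")
        if not (0.0 < self.tip_fraction < 1.0):
            raise ValueError(f"tip fraction must be in (0, 1), got {self.tip_fraction}")
        for name in ("ar_core_mean", "ar_tip_mean", "ar_muscle_mean", "background_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("cord_length_um", "cord_radius_um", "nucleus_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.muscle_shell_um < 0:
            raise ValueError("muscle shell thickness must be >= 0 (0 disables the shell)")
        if any(s <= 0 for s in self.semi_axes_um):
            raise ValueError("ellipsoid semi-axes must be > 0")
        if self.nuclear_density_per_1000um3 < 0:
            raise ValueError("nuclear density must be >= 0")
        if self.nucleus_profile not in ("solid", "gaussian"):
            raise ValueError("nucleus_profile must be 'solid' or 'gaussian'")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        self._validate_fit()

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing_um))

    def resolved_center_um(self) -> np.ndarray:
        if self.center_um is not None:
            return np.asarray(self.center_um, dtype=float)
        ez, ey, ex = self.extent_um
        # push the body down in z so the cord fits above it
        cz = (ez - self.cord_length_um) / 2.0
        return np.array([cz, ey / 2.0, ex / 2.0])

    def _validate_fit(self) -> None:
        center = self.resolved_center_um()
        names = ("z", "y", "x")
        for i, name in enumerate(names):
            lo = center[i] - self.semi_axes_um[i]
            hi = center[i] + self.semi_axes_um[i]
            if i == 0:
                hi = max(hi, center[0] + self.semi_axes_um[0] + self.cord_length_um)
            if lo < 0 or hi > self.extent_um[i]:
                raise ValueError(
                    f"organ exceeds the grid on the {name} axis: "
                    f"[{lo:.1f}, {hi:.1f}] um outside [0, {self.extent_um[i]:.1f}] um"
                )


def _organ_geometry(spec: VolumePhantomSpec):
    """Voxel-center masks of body, cord and the full organ, plus z landmarks."""
    center = spec.resolved_center_um()
    axes_um = [
        (np.arange(n) + 0.5) * s for n, s in zip(spec.shape, spec.spacing_um)
    ]
    zz = axes_um[0][:, None, None]
    yy = axes_um[1][None, :, None]
    xx = axes_um[2][None, None, :]
    az, ay, ax = spec.semi_axes_um
    q = (
        ((zz - center[0]) / az) ** 2
        + ((yy - center[1]) / ay) ** 2
        + ((xx - center[2]) / ax) ** 2
    )
    body = q <= 1.0
    body_top = center[0] + az
    cord = (
        (zz >= body_top - 1e-9)
        & (zz <= body_top + spec.cord_length_um)
        & (((yy - center[1]) ** 2 + (xx - center[2]) ** 2) <= spec.cord_radius_um**2)
    )
    organ = body | cord
    return center, (zz, yy, xx), q, body, cord, organ


def _point_in_organ(p: np.ndarray, spec: VolumePhantomSpec, center: np.ndarray) -> bool:
    az, ay, ax = spec.semi_axes_um
    q = (
        ((p[0] - center[0]) / az) ** 2
        + ((p[1] - center[1]) / ay) ** 2
        + ((p[2] - center[2]) / ax) ** 2
    )
    if q <= 1.0:
        return True
    body_top = center[0] + az
    return (
        body_top - 1e-9 <= p[0] <= body_top + spec.cord_length_um
        and (p[1] - center[1]) ** 2 + (p[2] - center[2]) ** 2 <= spec.cord_radius_um**2
    )


def _in_muscle_shell(p: np.ndarray, spec: VolumePhantomSpec, center: np.ndarray) -> bool:
    """Shell test on the ellipsoid body: within the outer normalized layer."""
    az, ay, ax = spec.semi_axes_um
    q = math.sqrt(
        ((p[0] - center[0]) / az) ** 2
        + ((p[1] - center[1]) / ay) ** 2
        + ((p[2] - center[2]) / ax) ** 2
    )
    if q > 1.0 or spec.muscle_shell_um == 0:
        return False  # cord or shell disabled
    # normalized shell thickness taken against the smallest semi-axis
    t = spec.muscle_shell_um / min(az, ay, ax)
    return q >= 1.0 - t


def generate_confocal_volume(
    spec: VolumePhantomSpec,
) -> tuple[ConfocalVolume, OrganMask, RegionLabels]:
    """Render the phantom; returns (volume, ground-truth mask, ground-truth labels).

    Deterministic: identical spec (including seed) reproduces the
    identical volume bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    center, (zz, yy, xx), q, body, cord, organ = _organ_geometry(spec)
    nz, ny, nx = spec.shape
    sz, sy, sx = spec.spacing_um
    voxel_vol = sz * sy * sx

    # ground truth: tip = top tip_fraction of the organ z-extent (cord included)
    organ_z = zz * np.ones_like(organ, dtype=float)
    z_vals = organ_z[organ]
    z_lo, z_hi = float(z_vals.min()), float(z_vals.max())
    tip_cut = z_hi - spec.tip_fraction * (z_hi - z_lo)
    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[organ] = LABEL_CORE
    labels[organ & (organ_z >= tip_cut)] = LABEL_TIP

    n_channels = 3 if spec.include_myosin else 2
    data = np.full((n_channels,) + spec.shape, spec.background_mean, dtype=np.float64)

    organ_volume_um3 = float(organ.sum()) * voxel_vol
    n_nuclei = int(round(spec.nuclear_density_per_1000um3 * organ_volume_um3 / 1000.0))

    # rejection-sample nucleus centers uniformly inside the organ
    centers = []
    lo = center - np.array([spec.semi_axes_um[0], spec.semi_axes_um[1], spec.semi_axes_um[2]])
    hi = center + np.array(
        [
            spec.semi_axes_um[0] + spec.cord_length_um,
            spec.semi_axes_um[1],
            spec.semi_axes_um[2],
        ]
    )
    while len(centers) < n_nuclei:
        p = rng.uniform(lo, hi)
        if _point_in_organ(p, spec, center):
            centers.append(p)

    r = spec.nucleus_radius_um
    spacing = np.array([sz, sy, sx])
    for p in centers:
        if _in_muscle_shell(p, spec, center):
            ar_value = spec.ar_muscle_mean
            is_muscle = True
        else:
            ar_value = spec.ar_tip_mean if p[0] >= tip_cut else spec.ar_core_mean
            is_muscle = False
        # local bounding box in voxels
        lo_v = np.maximum(np.floor((p - r) / spacing - 0.5).astype(int), 0)
        hi_v = np.minimum(
            np.ceil((p + r) / spacing - 0.5).astype(int) + 1, np.array(spec.shape)
        )
        if np.any(lo_v >= hi_v):
            continue
        sl = tuple(slice(a, b) for a, b in zip(lo_v, hi_v))
        local = [
            (np.arange(a, b) + 0.5) * s for a, b, s in zip(lo_v, hi_v, spacing)
        ]
        d2 = (
            ((local[0] - p[0]) ** 2)[:, None, None]
            + ((local[1] - p[1]) ** 2)[None, :, None]
            + ((local[2] - p[2]) ** 2)[None, None, :]
        )
        if spec.nucleus_profile == "solid":
            blob = (d2 <= r * r).astype(np.float64)
        else:
            blob = np.exp(-d2 / (2.0 * (r / 2.0) ** 2))
        region = data[0][sl]
        np.maximum(region, spec.background_mean + blob * spec.nuclear_peak, out=region)
        ar_region = data[1][sl]
        np.maximum(ar_region, spec.background_mean + blob * ar_value, out=ar_region)
        if spec.include_myosin and is_muscle:
            myo = data[2][sl]
            np.maximum(myo, spec.background_mean + blob * spec.nuclear_peak, out=myo)

    if spec.cytoplasmic_fraction > 0:
        # diffuse AR at a fraction of the regional mean across the organ
        diffuse = np.where(
            labels == LABEL_TIP,
            spec.ar_tip_mean,
            np.where(labels == LABEL_CORE, spec.ar_core_mean, 0.0),
        )
        np.maximum(
            data[1],
            spec.background_mean + spec.cytoplasmic_fraction * diffuse,
            out=data[1],
        )

    if spec.poisson_scale:
        data = rng.poisson(np.maximum(data, 0.0) / spec.poisson_scale) * float(
            spec.poisson_scale
        )
        data = data.astype(np.float64)
    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
    np.clip(data, 0.0, None, out=data)

    roles = ("nuclear", "ar", "myosin")[:n_channels]
    volume = ConfocalVolume(
        data=data,
        channel_roles=roles,
        spacing_um=spec.spacing_um,
        metadata={
            "specimen_id": f"phantom-{spec.seed}",
            "cord_landmark_zyx_um": [
                float(center[0] + spec.semi_axes_um[0] + spec.cord_length_um),
                float(center[1]),
                float(center[2]),
            ],
            "tip_fraction": spec.tip_fraction,
            "n_nuclei": n_nuclei,
            **spec.metadata,
        },
    )
    mask = OrganMask(mask=organ, provenance={"source": "phantom", "seed": spec.seed})
    region_labels = RegionLabels(
        labels=labels, provenance={"source": "phantom", "tip_cut_z_um": tip_cut}
    )
    return volume, mask, region_labels


# ---------------------------------------------------------------------------
# aspiration cohorts


@dataclass
class AspirationCohortSpec:
    """Forward-model cohort: true moduli per (strain, day, position) in kPa."""

    moduli_kpa: dict = field(
        default_factory=lambda: {
            ("LE/wt", "E19", "base"): 2.0,
            ("LE/wt", "E19", "midportion"): 3.0,
            ("LE/wt", "E19", "tip"): 2.0,
        }
    )
    n_per_group: int = 15
    pipette_radius_mean_um: float = 40.0
    pipette_radius_sd_um: float = 2.0
    wall_thickness_um: float = 8.0
    pressure_kpa: float = 70.0  # magnitude of the applied suction
    noise_rel: float = 0.15  # relative sd on aspirated length
    phi_form: str = "product"
    seed: int = 0

    def __post_init__(self) -> None:
        moduli = {}
        for key, e in self.moduli_kpa.items():
            if not (e > 0):
                raise ValueError(f"true modulus for {key} must be > 0, got {e}")
            moduli[tuple(key)] = float(e)
        self.moduli_kpa = moduli
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.pressure_kpa <= 0:
            raise ValueError("pressure magnitude must be > 0")
        if self.pipette_radius_mean_um <= 0 or self.wall_thickness_um <= 0:
            raise ValueError("pipette geometry must be > 0")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be >= 0")


def generate_aspiration_cohort(spec: AspirationCohortSpec) -> list[AspirationMeasurement]:
    """Draw aspiration records through the forward elastic model.

    For each specimen: L = 3 a dp / (2 pi E_true Phi(a, w)), then a
    multiplicative Gaussian perturbation of relative sd ``noise_rel``
    (redrawn in the vanishing-probability event of a non-positive L).
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for (strain, day, position), e_true in sorted(spec.moduli_kpa.items()):
        for i in range(spec.n_per_group):
            a = float(
                rng.normal(spec.pipette_radius_mean_um, spec.pipette_radius_sd_um)
            )
            a = max(a, 0.1 * spec.pipette_radius_mean_um)
            phi = wall_function(a, spec.wall_thickness_um, form=spec.phi_form)
            L0 = 3.0 * a * spec.pressure_kpa / (2.0 * math.pi * e_true * phi)
            L = L0
            if spec.noise_rel > 0:
                L = L0 * (1.0 + spec.noise_rel * float(rng.standard_normal()))
                while L <= 0:
                    L = L0 * (1.0 + spec.noise_rel * float(rng.standard_normal()))
            records.append(
                AspirationMeasurement(
                    a_um=a,
                    w_um=spec.wall_thickness_um,
                    dp_kpa=spec.pressure_kpa,
                    L_um=L,
                    position=position,
                    strain=strain,
                    day=day,
                    specimen_id=f"{strain}-{day}-{position}-{i}",
                )
            )
    return records


# ---------------------------------------------------------------------------
# fiber tables


@dataclass
class FiberTableSpec:
    """Fiber/debris mixture with known class labels.

    Fiber areas are log-normal (parameters on the log scale, um^2);
    fiber aspects sit at or above the retention cutoff; debris
    distributions straddle the cutoffs so the filter has work to do.
    """

    n_fibers: int = 50
    n_debris: int = 50
    fiber_area_log_mean: float = math.log(2000.0)
    fiber_area_log_sd: float = 0.4
    fiber_aspect_min: float = 5.0
    fiber_aspect_spread: float = 4.0  # mean excess above the minimum
    debris_area_log_mean: float = math.log(400.0)
    debris_area_log_sd: float = 0.8
    debris_aspect_mean: float = 3.0
    debris_aspect_sd: float = 2.0
    strain: str = ""
    treatment: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers < 0 or self.n_debris < 0:
            raise ValueError("object counts must be >= 0")
        if self.fiber_aspect_min < 1.0:
            raise ValueError("fiber aspect support must be >= 1")


def _record_from_area_aspect(
    obj_id: int, area: float, aspect: float, spec: FiberTableSpec, true_class: str
) -> FiberRecord:
    # ellipse model: area = pi/4 * fmax * fmin, aspect = fmax / fmin
    fmin = math.sqrt(4.0 * area / (math.pi * aspect))
    fmax = aspect * fmin
    return FiberRecord(
        object_id=obj_id,
        area_um2=area,
        feret_min_um=fmin,
        feret_max_um=fmax,
        aspect=aspect,
        strain=spec.strain,
        treatment=spec.treatment,
        true_class=true_class,
    )


def generate_fiber_table(spec: FiberTableSpec) -> list[FiberRecord]:
    """Fiber rows first, then debris rows, each tagged with its true class."""
    rng = np.random.default_rng(spec.seed)
    records = []
    obj_id = 1
    for _ in range(spec.n_fibers):
        area = float(rng.lognormal(spec.fiber_area_log_mean, spec.fiber_area_log_sd))
        aspect = spec.fiber_aspect_min + float(
            rng.exponential(spec.fiber_aspect_spread)
        )
        records.append(_record_from_area_aspect(obj_id, area, aspect, spec, "fiber"))
        obj_id += 1
    for _ in range(spec.n_debris):
        area = float(rng.lognormal(spec.debris_area_log_mean, spec.debris_area_log_sd))
        aspect = max(
            1.0, float(rng.normal(spec.debris_aspect_mean, spec.debris_aspect_sd))
        )
        records.append(_record_from_area_aspect(obj_id, area, aspect, spec, "debris"))
        obj_id += 1
    return records


# ---------------------------------------------------------------------------
# summary-level intensity cohorts (power / type-I experiments)


def simulate_intensity_cohort(
    n_specimens: int,
    tip_core_ratio: float,
    noise_rel: float,
    core_mean: float = 200.0,
    strain: str = "LE/wt",
    day: str = "E21",
    seed: int = 0,
) -> list[RegionIntensitySummary]:
    """Per-specimen tip/core mean pairs around a generative contrast.

    Measured regional means are Gaussian around the generative values
    with relative sd ``noise_rel``, emulating the specimen-to-specimen
    variability of the volumetric pipeline without rendering volumes.
    """
    if n_specimens < 1:
        raise ValueError("n_specimens must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_specimens):
        core = float(rng.normal(core_mean, noise_rel * core_mean))
        tip = float(
            rng.normal(tip_core_ratio * core_mean, noise_rel * tip_core_ratio * core_mean)
        )
        out.append(
            RegionIntensitySummary(
                specimen_id=f"sim-{seed}-{i}",
                strain=strain,
                day=day,
                tip_mean=max(tip, 1e-9),
                core_mean=max(core, 1e-9),
                tip_voxels=1000,
                core_voxels=3000,
            )
        )
    return out
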