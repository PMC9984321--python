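"""Synthetic CT: thorax phantom, acquisition degradation, patient-like cohort.

No public coronary-calcium CT dataset pairs an ECG-gated calcium-scoring scan
(CSCT) with the non-gated low-dose CT (LDCT) acquired for PET attenuation
correction, so this module manufactures both from known ground truth:

* an anthropomorphic thorax-phantom section (soft-tissue body, two lungs,
  spine, and a 200 mg/cm^3 hydroxyapatite calibration rod) used to calibrate
  the tube-voltage-adapted detection threshold;
* a cohort of cardiac patches carrying spherical coronary calcifications with
  analytically known Agatston ground truth, imaged under both protocols.

The image-formation model is deliberately simple and stated in full:

* **HU model** — material HU at 120 kVp is linear in hydroxyapatite density
  through (0 mg/cm^3 -> soft tissue) and (200 mg/cm^3 -> 269 HU), the rod
  value measured at 120 kVp. Each rendered voxel also records its
  calcium-attributable HU in a separate channel; at 130 kVp that component is
  multiplied by the calcium contrast ratio (default 249/269, the rod values
  measured at the two voltages), while non-calcium tissue is kVp-invariant.
* **Partial volume** — primitives are rendered on a supersampled lattice
  (>= 4 sub-samples per axis by default) and box-averaged to the target grid.
* **Acquisition** — in order: calcium-contrast rescaling (130 kVp only),
  isotropic Gaussian motion blur (sd in mm; 0 for gated scans), slab
  averaging to the protocol slice thickness sampled every increment mm plus
  in-plane box down-sampling, then seeded additive Gaussian noise in HU.
  No projection-domain physics, beam hardening, or cardiac-phase model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume import HU_MAX, HU_MIN, VoxelGrid, save_volume

__all__ = [
    "SOFT_TISSUE_HU",
    "HU_CAHA200_120KVP",
    "HU_CAHA200_130KVP",
    "AcquisitionProtocol",
    "GATED_PROTOCOL",
    "LDCT_PROTOCOL",
    "PhantomSpec",
    "LesionSpec",
    "CohortSpec",
    "SubjectRecord",
    "VESSEL_LABELS",
    "hu_from_density",
    "rasterize_phantom",
    "simulate_acquisition",
    "category_counts",
    "generate_cohort",
    "write_cohort",
]

# Reference HU of the 200 mg/cm^3 hydroxyapatite calibration rod at the two
# tube voltages (phantom measurement), anchoring the density->HU line and the
# default calcium contrast ratio.
HU_CAHA200_120KVP = 269.0
HU_CAHA200_130KVP = 249.0
SOFT_TISSUE_HU = 35.0
AIR_HU = -1000.0


def hu_from_density(density: float) -> float:
    """HU at 120 kVp of hydroxyapatite-loaded tissue of the given density.

    Linear through (0, soft tissue) and (200 mg/cm^3, 269 HU).
    """
    return SOFT_TISSUE_HU + density * (HU_CAHA200_120KVP - SOFT_TISSUE_HU) / 200.0


def density_from_hu(hu: float) -> float:
    """Inverse of :func:`hu_from_density`."""
    return (hu - SOFT_TISSUE_HU) * 200.0 / (HU_CAHA200_120KVP - SOFT_TISSUE_HU)


# ---------------------------------------------------------------------------
# Acquisition protocols
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Reconstruction geometry and degradation level of one CT protocol.

    ``calcium_hu_ratio`` scales the calcium-attributable HU component and is
    1.0 at 120 kVp; at 130 kVp it defaults to 249/269, the measured drop of
    the calibration rod. ``motion_sd`` is the standard deviation (mm) of the
    isotropic Gaussian blur standing in for uncontrolled cardiac/respiratory
    motion; 0 means ECG-gated breath-hold.
    """

    name: str
    kvp: int
    slice_thickness: float = 3.0
    increment: float = 3.0
    pixel_mm: float = 1.0
    noise_sd: float = 0.0
    motion_sd: float = 0.0
    calcium_hu_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.kvp not in (120, 130):
            raise ValueError(f"tube voltage must be 120 or 130 kVp, got {self.kvp}")
        if self.slice_thickness <= 0 or self.increment <= 0 or self.pixel_mm <= 0:
            raise ValueError("slice_thickness, increment and pixel_mm must be positive")
        if self.noise_sd < 0 or self.motion_sd < 0:
            raise ValueError("noise_sd and motion_sd must be non-negative")
        if not 0 < self.calcium_hu_ratio <= 2:
            raise ValueError("calcium_hu_ratio must lie in (0, 2]")


#: Dedicated calcium-scoring CT: 120 kVp, ECG-gated breath-hold, 3 mm slices
#: reconstructed every 1.5 mm (overlapping). Pixel 0.5 mm approximates a
#: 228 mm cardiac field of view on a 512 matrix; noise is low (80 ref. mAs).
GATED_PROTOCOL = AcquisitionProtocol(
    name="csct", kvp=120, slice_thickness=3.0, increment=1.5,
    pixel_mm=0.5, noise_sd=5.0, motion_sd=0.0, calcium_hu_ratio=1.0,
)

#: Attenuation-correction low-dose CT: 130 kVp, free-breathing and non-gated,
#: 3 mm slices every 3 mm. Pixel 1.0 mm approximates a 500 mm field of view
#: on a 512 matrix; 25 ref. mAs brings higher noise, and residual motion is
#: modelled as a 1.5 mm Gaussian blur.
LDCT_PROTOCOL = AcquisitionProtocol(
    name="ldct", kvp=130, slice_thickness=3.0, increment=3.0,
    pixel_mm=1.0, noise_sd=12.0, motion_sd=1.5,
    calcium_hu_ratio=HU_CAHA200_130KVP / HU_CAHA200_120KVP,
)


# ---------------------------------------------------------------------------
# Geometric primitives (world coordinates, mm; z = slice axis)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Primitive:
    hu: float
    is_calcium: bool = False

    def __post_init__(self) -> None:
        if not HU_MIN <= self.hu <= HU_MAX:
            raise ValueError(f"non-physical HU assignment: {self.hu}")

    def mask(self, z: float, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass(frozen=True)
class EllipseCylinder(_Primitive):
    """Ellipse in-plane, extruded along z over [z_min, z_max]."""

    center_xy: tuple[float, float] = (0.0, 0.0)
    semi_axes: tuple[float, float] = (1.0, 1.0)  # (ax, ay)
    z_range: tuple[float, float] = (-math.inf, math.inf)

    def mask(self, z, yy, xx):
        if not self.z_range[0] <= z <= self.z_range[1]:
            return np.zeros(yy.shape, bool)
        u = (xx - self.center_xy[0]) / self.semi_axes[0]
        v = (yy - self.center_xy[1]) / self.semi_axes[1]
        return u * u + v * v <= 1.0


@dataclass(frozen=True)
class Cylinder(_Primitive):
    """Circular cylinder with axis parallel to z."""

    center_xy: tuple[float, float] = (0.0, 0.0)
    diameter: float = 1.0
    z_range: tuple[float, float] = (-math.inf, math.inf)

    def mask(self, z, yy, xx):
        if not self.z_range[0] <= z <= self.z_range[1]:
            return np.zeros(yy.shape, bool)
        r = self.diameter / 2.0
        return (xx - self.center_xy[0]) ** 2 + (yy - self.center_xy[1]) ** 2 <= r * r


@dataclass(frozen=True)
class Sphere(_Primitive):
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (z, y, x)
    diameter: float = 1.0

    def mask(self, z, yy, xx):
        r = self.diameter / 2.0
        dz2 = (z - self.center[0]) ** 2
        if dz2 > r * r:
            return np.zeros(yy.shape, bool)
        d2 = dz2 + (yy - self.center[1]) ** 2 + (xx - self.center[2]) ** 2
        return d2 <= r * r


# ---------------------------------------------------------------------------
# Phantom and lesion specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Thorax-phantom section: body, lungs, spine, hydroxyapatite rod.

    Default geometry approximates an anthropomorphic thorax phantom with a
    large central calibration insert of 200 mg/cm^3 hydroxyapatite. All
    coordinates in mm; the section is extruded over ``z_extent``.
    """

    body_semi_axes: tuple[float, float] = (150.0, 100.0)
    soft_tissue_hu: float = SOFT_TISSUE_HU
    lung_centers: tuple[tuple[float, float], ...] = ((-65.0, 10.0), (65.0, 10.0))
    lung_semi_axes: tuple[float, float] = (48.0, 62.0)
    lung_hu: float = -800.0
    spine_center: tuple[float, float] = (0.0, -72.0)
    spine_semi_axes: tuple[float, float] = (22.0, 18.0)
    spine_hu: float = 300.0
    insert_center_xy: tuple[float, float] = (0.0, 0.0)
    insert_diameter: float = 25.0
    insert_density: float = 200.0
    z_extent: float = 12.0
    lesions: tuple["LesionSpec", ...] = ()

    def __post_init__(self) -> None:
        if self.insert_density <= 0:
            raise ValueError("calibration-insert density must be positive")
        cx, cy = self.insert_center_xy
        ax, ay = self.body_semi_axes
        r = self.insert_diameter / 2.0
        if (cx / (ax - r)) ** 2 + (cy / (ay - r)) ** 2 > 1.0:
            raise ValueError("calibration insert must lie inside the body outline")

    @property
    def insert_hu(self) -> float:
        return hu_from_density(self.insert_density)

    def primitives(self) -> list[_Primitive]:
        """Render order; overlapping primitives resolve last-listed-wins."""
        prims: list[_Primitive] = [
            EllipseCylinder(self.soft_tissue_hu, False, (0.0, 0.0), self.body_semi_axes),
        ]
        for c in self.lung_centers:
            prims.append(EllipseCylinder(self.lung_hu, False, c, self.lung_semi_axes))
        prims.append(EllipseCylinder(self.spine_hu, True, self.spine_center, self.spine_semi_axes))
        prims.append(Cylinder(self.insert_hu, True, self.insert_center_xy, self.insert_diameter))
        for les in self.lesions:
            prims.append(Sphere(hu_from_density(les.density), True, les.center, les.diameter))
        return prims


VESSEL_LABELS = {1: "LM", 2: "LAD", 3: "LCx", 4: "RCA"}
_LABEL_OF_VESSEL = {v: k for k, v in VESSEL_LABELS.items()}


@dataclass(frozen=True)
class LesionSpec:
    """One spherical coronary calcification: where, how big, how dense."""

    center: tuple[float, float, float]  # (z, y, x) mm
    diameter: float
    density: float  # hydroxyapatite mg/cm^3
    vessel: str = "LAD"

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.density <= 0:
            raise ValueError("lesion diameter and density must be positive")
        if self.vessel not in _LABEL_OF_VESSEL:
            raise ValueError(f"vessel must be one of {sorted(_LABEL_OF_VESSEL)}")


# ---------------------------------------------------------------------------
# Rasterization (partial-volume rendering)
# ---------------------------------------------------------------------------


def _rasterize(
    primitives: list[_Primitive],
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    slice_thickness: float,
    supersample: int,
    background_hu: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Render primitives with ``supersample`` sub-samples per axis.

    Returns ``(values, calcium)`` at 120 kVp reference contrast; ``calcium``
    is the calcium-attributable HU per voxel (full material HU weighted by
    occupancy of calcium primitives).
    """
    nz, ny, nx = shape
    s = int(supersample)
    if s < 1:
        raise ValueError("supersample must be >= 1")
    dz, dy, dx = spacing
    # fine in-plane lattice of sub-sample centres, shared by all slices
    fy = origin[1] + dy * (np.arange(ny * s) + 0.5) / s - dy / 2.0
    fx = origin[2] + dx * (np.arange(nx * s) + 0.5) / s - dx / 2.0
    yy, xx = np.meshgrid(fy, fx, indexing="ij")
    values = np.empty(shape, np.float64)
    calcium = np.empty(shape, np.float64)
    # Extruded primitives render identically at every z where they are
    # active, so cache the in-plane pass per activity pattern; only spheres
    # vary continuously with z and are composited on top.
    extruded = [p for p in primitives if not isinstance(p, Sphere)]
    spheres = [p for p in primitives if isinstance(p, Sphere)]
    cache: dict[tuple[bool, ...], tuple[np.ndarray, np.ndarray]] = {}

    def base_render(z: float) -> tuple[np.ndarray, np.ndarray]:
        key = tuple(p.z_range[0] <= z <= p.z_range[1] for p in extruded)
        if key not in cache:
            hu = np.full(yy.shape, background_hu)
            ca = np.zeros(yy.shape)
            for prim, active in zip(extruded, key):
                if active:
                    m = prim.mask(z, yy, xx)
                    hu[m] = prim.hu
                    ca[m] = prim.hu if prim.is_calcium else 0.0
            cache[key] = (hu, ca)
        return cache[key]

    for k in range(nz):
        z_lo = origin[0] + k * dz - slice_thickness / 2.0
        sub_z = z_lo + slice_thickness * (np.arange(s) + 0.5) / s
        acc_hu = np.zeros(yy.shape, np.float64)
        acc_ca = np.zeros(yy.shape, np.float64)
        for z in sub_z:
            hu_fine, ca_fine = base_render(z)
            live = [sp for sp in spheres if abs(z - sp.center[0]) <= sp.diameter / 2.0]
            if live:
                hu_fine, ca_fine = hu_fine.copy(), ca_fine.copy()
                for sp in live:
                    m = sp.mask(z, yy, xx)
                    hu_fine[m] = sp.hu
                    ca_fine[m] = sp.hu if sp.is_calcium else 0.0
            acc_hu += hu_fine
            acc_ca += ca_fine
        acc_hu /= s
        acc_ca /= s
        values[k] = acc_hu.reshape(ny, s, nx, s).mean(axis=(1, 3))
        calcium[k] = acc_ca.reshape(ny, s, nx, s).mean(axis=(1, 3))
    return values, calcium


def rasterize_phantom(
    spec: PhantomSpec,
    protocol: AcquisitionProtocol,
    seed: int = 0,
    supersample: int = 4,
    fov_margin: float = 10.0,
) -> VoxelGrid:
    """Render the phantom as scanned under one protocol.

    Geometry is supersampled ``supersample`` times per axis and box-averaged
    to the protocol grid (partial-volume model). At 130 kVp the
    calcium-attributable HU is scaled by the protocol's contrast ratio, then
    seeded Gaussian noise of the protocol's sd is added. The phantom is
    static, so no motion blur applies regardless of ``motion_sd``.
    """
    ax, ay = spec.body_semi_axes
    px = protocol.pixel_mm
    nx = int(math.ceil(2 * (ax + fov_margin) / px))
    ny = int(math.ceil(2 * (ay + fov_margin) / px))
    t, inc = protocol.slice_thickness, protocol.increment
    nz = max(1, int(math.floor((spec.z_extent - t) / inc)) + 1)
    origin = (t / 2.0, -(ny * px) / 2.0 + px / 2.0, -(nx * px) / 2.0 + px / 2.0)
    spacing = (inc, px, px)
    prims = spec.primitives()
    # confine primitives to the phantom's z extent
    prims = [
        replace(p, z_range=(0.0, spec.z_extent)) if hasattr(p, "z_range") else p
        for p in prims
    ]
    values, calcium = _rasterize(
        prims, (nz, ny, nx), spacing, origin, t, supersample, AIR_HU
    )
    if protocol.calcium_hu_ratio != 1.0:
        values = values + calcium * (protocol.calcium_hu_ratio - 1.0)
    if protocol.noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, protocol.noise_sd, values.shape)
    np.clip(values, HU_MIN, HU_MAX, out=values)
    return VoxelGrid(values, spacing, origin, slice_thickness=t, calcium=calcium)


# ---------------------------------------------------------------------------
# Acquisition simulation
# ---------------------------------------------------------------------------


def simulate_acquisition(
    truth: VoxelGrid, protocol: AcquisitionProtocol, seed: int = 0
) -> VoxelGrid:
    """Degrade a fine ground-truth volume into one protocol's reconstruction.

    Applies, in order: calcium-contrast rescaling (when the protocol ratio
    differs from 1 and the truth carries a calcium channel), Gaussian motion
    blur of ``motion_sd`` mm, slab averaging to ``slice_thickness`` sampled
    every ``increment`` mm with in-plane box down-sampling to ``pixel_mm``,
    and seeded additive Gaussian noise. The truth grid must be at least as
    fine as the protocol grid on every axis, the protocol pixel and slab
    geometry must be integer multiples of the truth spacing, and an increment
    exceeding twice the slice thickness is rejected as unsupported geometry.
    """
    t, inc, px = protocol.slice_thickness, protocol.increment, protocol.pixel_mm
    if inc > 2.0 * t:
        raise ValueError(
            f"increment {inc} mm exceeds twice the slice thickness {t} mm; "
            "such gapped geometries are not supported"
        )
    dz, dy, dx = truth.spacing
    if dz > t + 1e-9 or dy > px + 1e-9 or dx > px + 1e-9:
        raise ValueError("truth grid must be at least as fine as the protocol grid")

    def _factor(a: float, b: float, what: str) -> int:
        f = a / b
        if abs(f - round(f)) > 1e-6:
            raise ValueError(f"{what} ({a} mm) must be an integer multiple of the truth spacing ({b} mm)")
        return int(round(f))

    fy = _factor(px, dy, "protocol pixel")
    fx = _factor(px, dx, "protocol pixel")
    f_t = _factor(t, dz, "slice thickness")
    f_inc = _factor(inc, dz, "increment")

    values = truth.values.astype(np.float64, copy=True)
    if protocol.calcium_hu_ratio != 1.0:
        if truth.calcium is not None:
            values += truth.calcium * (protocol.calcium_hu_ratio - 1.0)
    if protocol.motion_sd > 0:
        sigma = tuple(protocol.motion_sd / s for s in truth.spacing)
        values = gaussian_filter(values, sigma=sigma, mode="nearest")

    nz, ny, nx = values.shape
    n_out = max(1, (nz - f_t) // f_inc + 1)
    ny_out, nx_out = ny // fy, nx // fx
    out = np.empty((n_out, ny_out, nx_out), np.float64)
    for k in range(n_out):
        slab = values[k * f_inc : k * f_inc + f_t].mean(axis=0)
        out[k] = slab[: ny_out * fy, : nx_out * fx].reshape(ny_out, fy, nx_out, fx).mean(axis=(1, 3))

    if protocol.noise_sd > 0:
        rng = np.random.default_rng(seed)
        out += rng.normal(0.0, protocol.noise_sd, out.shape)
    np.clip(out, HU_MIN, HU_MAX, out=out)

    z0 = truth.origin[0] + (f_t - 1) * dz / 2.0  # centre of the first slab
    oy = truth.origin[1] + (fy - 1) * dy / 2.0
    ox = truth.origin[2] + (fx - 1) * dx / 2.0
    return VoxelGrid(out, (inc, px, px), (z0, oy, ox), slice_thickness=t)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Per-category count proportions of the reference cohort (n = 213):
#: 12, 9, 27, 34, 69, 62 subjects in risk categories 0..5.
DEFAULT_CATEGORY_PROPORTIONS = (12 / 213, 9 / 213, 27 / 213, 34 / 213, 69 / 213, 62 / 213)

# Agatston target windows per category, inset from the interval edges so that
# partial-volume and noise differences between grids rarely flip a category.
_CATEGORY_TARGETS = {
    1: (2.0, 9.0),
    2: (15.0, 90.0),
    3: (120.0, 380.0),
    4: (450.0, 950.0),
    5: (1100.0, 2600.0),
}

# Cardiac patch geometry (mm): vessel anchor points (y, x) in a 72 mm square
# patch, z in [0, 30). Lesions scatter within _LESION_JITTER of an anchor and
# the vessel mask is a 10 mm-radius cylinder around it.
_PATCH_XY = 72.0
_PATCH_Z = 30.0
_TRUTH_SPACING = (0.5, 0.25, 0.25)
_VESSEL_ANCHORS = {"LM": (30.0, 30.0), "LAD": (48.0, 26.0), "LCx": (44.0, 50.0), "RCA": (24.0, 48.0)}
_VESSEL_RADIUS = 10.0
_LESION_JITTER = 6.0
# Nominal lesion peak HU sits mid-bin of the Agatston density weights so that
# grid-dependent partial volume rarely changes a lesion's weight.
_LESION_PEAK_HU = (165.0, 250.0, 350.0, 550.0, 800.0)
_LESION_PEAK_P = (0.1, 0.2, 0.25, 0.25, 0.2)


@dataclass(frozen=True)
class CohortSpec:
    """Size, composition and sampling ranges of a synthetic cohort."""

    n_subjects: int = 213
    category_proportions: tuple[float, ...] = DEFAULT_CATEGORY_PROPORTIONS
    lesion_diameter_range: tuple[float, float] = (3.0, 9.0)
    small_lesion_diameter_range: tuple[float, float] = (2.5, 5.0)
    max_retries: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        if len(self.category_proportions) != 6:
            raise ValueError("need six category proportions")
        if abs(sum(self.category_proportions) - 1.0) > 1e-9:
            raise ValueError("category proportions must sum to 1")


def category_counts(proportions: tuple[float, ...], n: int) -> np.ndarray:
    """Apportion ``n`` subjects to categories by largest remainder.

    Exact whenever ``proportions`` are themselves counts over ``n``.
    """
    raw = np.asarray(proportions, float) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


@dataclass
class SubjectRecord:
    """One simulated subject: ground truth plus both reconstructions."""

    subject_id: str
    category: int
    true_total: float
    true_per_vessel: dict[str, float]
    lesions: tuple[LesionSpec, ...]
    gated: VoxelGrid
    ldct: VoxelGrid
    gated_mask: np.ndarray
    ldct_mask: np.ndarray


def _render_lesions(lesions: tuple[LesionSpec, ...], supersample: int = 2) -> VoxelGrid:
    """Ground-truth patch: soft-tissue background plus calcified spheres.

    Rendered on the fine truth grid (0.5 x 0.25 x 0.25 mm) with supersampled
    partial volume; spheres are rasterized only inside their bounding boxes.
    """
    dz, dy, dx = _TRUTH_SPACING
    nz = int(round(_PATCH_Z / dz))
    ny = nx = int(round(_PATCH_XY / dy))
    values = np.full((nz, ny, nx), SOFT_TISSUE_HU, np.float64)
    calcium = np.zeros((nz, ny, nx), np.float64)
    s = supersample
    for les in lesions:
        hu = hu_from_density(les.density)
        cz, cy, cx = les.center
        r = les.diameter / 2.0
        k0 = max(0, int((cz - r) / dz) - 1)
        k1 = min(nz, int((cz + r) / dz) + 2)
        j0 = max(0, int((cy - r) / dy) - 1)
        j1 = min(ny, int((cy + r) / dy) + 2)
        i0 = max(0, int((cx - r) / dx) - 1)
        i1 = min(nx, int((cx + r) / dx) + 2)
        if k0 >= k1 or j0 >= j1 or i0 >= i1:
            continue
        # occupancy fraction per voxel from s^3 sub-samples
        zz = (np.arange(k0 * s, k1 * s) + 0.5) * dz / s
        yy = (np.arange(j0 * s, j1 * s) + 0.5) * dy / s
        xx = (np.arange(i0 * s, i1 * s) + 0.5) * dx / s
        d2 = (
            ((zz - cz) ** 2)[:, None, None]
            + ((yy - cy) ** 2)[None, :, None]
            + ((xx - cx) ** 2)[None, None, :]
        )
        occ = (d2 <= r * r).reshape(k1 - k0, s, j1 - j0, s, i1 - i0, s).mean(axis=(1, 3, 5))
        sub_v = values[k0:k1, j0:j1, i0:i1]
        sub_c = calcium[k0:k1, j0:j1, i0:i1]
        # occupancy composition; overlapping lesions: later listed wins where present
        np.copyto(sub_v, occ * hu + (1 - occ) * sub_v, where=occ > 0)
        np.copyto(sub_c, occ * hu, where=occ > 0)
    return VoxelGrid(values, _TRUTH_SPACING, (dz / 2.0, dy / 2.0, dx / 2.0),
                     slice_thickness=dz, calcium=calcium)


def _vessel_mask(grid: VoxelGrid) -> np.ndarray:
    """Vessel label map on a scan grid: 10 mm cylinders around the anchors."""
    y = grid.axis_coords(1)
    x = grid.axis_coords(2)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    plane = np.zeros(yy.shape, np.uint8)
    for name, (ay, axx) in _VESSEL_ANCHORS.items():
        m = (yy - ay) ** 2 + (xx - axx) ** 2 <= _VESSEL_RADIUS**2
        plane[m] = _LABEL_OF_VESSEL[name]
    return np.broadcast_to(plane, grid.shape).copy()


_TRUTH_SCORING_PROTOCOL = AcquisitionProtocol(
    name="truth", kvp=120, slice_thickness=3.0, increment=3.0,
    pixel_mm=_TRUTH_SPACING[1], noise_sd=0.0, motion_sd=0.0,
)


def _truth_score(truth: VoxelGrid):
    """Analytic ground-truth Agatston result of a lesion patch.

    Noise-free slab averaging of the fine rendering to the 3 mm scoring
    partition at full in-plane resolution, then standard scoring at 130 HU.
    """
    from .scoring import ScoringConfig, total_score

    slabs = simulate_acquisition(truth, _TRUTH_SCORING_PROTOCOL, seed=0)
    return total_score(slabs, ScoringConfig(), mask=_vessel_mask(slabs))


def _sample_lesions(category: int, target: float, spec: CohortSpec, rng) -> tuple[LesionSpec, ...]:
    """Draw a lesion set whose rough score estimate reaches ``target``."""
    vessels = list(_VESSEL_ANCHORS)
    lesions: list[LesionSpec] = []
    est = 0.0
    d_rng = spec.small_lesion_diameter_range if category == 1 else spec.lesion_diameter_range
    while est < target and len(lesions) < 40:
        d = rng.uniform(*d_rng)
        peak = rng.choice(_LESION_PEAK_HU, p=_LESION_PEAK_P)
        if category == 1:
            peak = _LESION_PEAK_HU[int(rng.integers(0, 2))]  # small, lighter lesions
        vessel = vessels[int(rng.integers(0, 4))]
        ay, ax = _VESSEL_ANCHORS[vessel]
        ang = rng.uniform(0, 2 * math.pi)
        rad = rng.uniform(0, _LESION_JITTER)
        cy, cx = ay + rad * math.sin(ang), ax + rad * math.cos(ang)
        cz = rng.uniform(3.0 + d / 2, _PATCH_Z - 3.0 - d / 2)
        w = 1 if peak < 200 else 2 if peak < 300 else 3 if peak < 400 else 4
        # total cross-area over 3 mm slabs ~ sphere volume / 3 mm, trimmed for
        # the rim lost to thresholding
        est_lesion = w * 0.8 * (math.pi / 6.0) * d**3 / 3.0
        lesions.append(LesionSpec((cz, cy, cx), d, density_from_hu(peak), vessel))
        est += est_lesion
    return tuple(lesions)


def _rescale_lesions(lesions: tuple[LesionSpec, ...], factor: float, d_max: float) -> tuple[LesionSpec, ...]:
    return tuple(
        replace(les, diameter=float(np.clip(les.diameter * factor, 1.5, d_max * 1.3)))
        for les in lesions
    )


def _make_subject(idx: int, category: int, spec: CohortSpec,
                  gated: AcquisitionProtocol, ldct: AcquisitionProtocol,
                  rng: np.random.Generator) -> SubjectRecord:
    from .risk import categorize
    from .scoring import ScoringConfig, total_score

    last_err = "no attempt"
    for _attempt in range(spec.max_retries):
        if category == 0:
            lesions: tuple[LesionSpec, ...] = ()
            truth = _render_lesions(lesions)
            result = _truth_score(truth)
        else:
            lo, hi = _CATEGORY_TARGETS[category]
            target = rng.uniform(lo, hi)
            lesions = _sample_lesions(category, target, spec, rng)
            truth = _render_lesions(lesions)
            result = _truth_score(truth)
            # one corrective resize towards the target, then re-check
            for _ in range(6):
                if lo <= result.total <= hi:
                    break
                if result.total <= 0:
                    break
                factor = float(np.clip((target / result.total) ** 0.4, 0.6, 1.6))
                lesions = _rescale_lesions(lesions, factor, spec.lesion_diameter_range[1])
                truth = _render_lesions(lesions)
                result = _truth_score(truth)
            if not lo <= result.total <= hi:
                last_err = f"truth score {result.total:.1f} outside window [{lo}, {hi}]"
                continue
        gated_seed = int(rng.integers(0, 2**31 - 1))
        ldct_seed = int(rng.integers(0, 2**31 - 1))
        gated_vol = simulate_acquisition(truth, gated, seed=gated_seed)
        ldct_vol = simulate_acquisition(truth, ldct, seed=ldct_seed)
        gated_mask = _vessel_mask(gated_vol)
        gated_result = total_score(gated_vol, ScoringConfig(), mask=gated_mask)
        if categorize(gated_result.total) != category:
            last_err = (
                f"gated score {gated_result.total:.1f} lands in category "
                f"{categorize(gated_result.total)}, wanted {category}"
            )
            continue
        return SubjectRecord(
            subject_id=f"S{idx:04d}",
            category=category,
            true_total=result.total,
            true_per_vessel=dict(result.per_vessel),
            lesions=lesions,
            gated=gated_vol,
            ldct=ldct_vol,
            gated_mask=gated_mask,
            ldct_mask=_vessel_mask(ldct_vol),
        )
    raise RuntimeError(
        f"subject {idx}: risk category {category} unreachable with the configured "
        f"sampling ranges after {spec.max_retries} attempts ({last_err})"
    )


def generate_cohort(
    spec: CohortSpec,
    gated: AcquisitionProtocol = GATED_PROTOCOL,
    ldct: AcquisitionProtocol = LDCT_PROTOCOL,
) -> list[SubjectRecord]:
    """Simulate a paired-scan cohort with known Agatston ground truth.

    Subjects are apportioned to the six risk categories by
    ``spec.category_proportions`` (largest remainder, so proportions stated
    as counts reproduce those counts exactly). Each subject's lesion set is
    sampled, verified against its analytically scored ground truth, and
    re-sampled until the rendered gated scan also scores inside the assigned
    category; both reconstructions and their vessel masks are returned.
    Fixed ``spec.seed`` reproduces the cohort bit-identically.
    """
    counts = category_counts(spec.category_proportions, spec.n_subjects)
    categories = np.repeat(np.arange(6), counts)
    root = np.random.SeedSequence(spec.seed)
    records = []
    for idx, (category, child) in enumerate(zip(categories, root.spawn(len(categories)))):
        rng = np.random.default_rng(child)
        records.append(_make_subject(idx, int(category), spec, gated, ldct, rng))
    return records


def write_cohort(records: list[SubjectRecord], out_dir: str | Path) -> Path:
    """Write cohort volumes, masks and a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if not records:
        return manifest_path
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        paths = {
            "gated_path": f"{rec.subject_id}_gated.nii.gz",
            "ldct_path": f"{rec.subject_id}_ldct.nii.gz",
            "gated_mask_path": f"{rec.subject_id}_gated_mask.nii.gz",
            "ldct_mask_path": f"{rec.subject_id}_ldct_mask.nii.gz",
        }
        save_volume(rec.gated, out_dir / paths["gated_path"])
        save_volume(rec.ldct, out_dir / paths["ldct_path"])
        for key, grid in (("gated_mask_path", rec.gated), ("ldct_mask_path", rec.ldct)):
            mask = rec.gated_mask if key == "gated_mask_path" else rec.ldct_mask
            save_volume(
                VoxelGrid(mask.astype(np.int16), grid.spacing, grid.origin,
                          slice_thickness=grid.slice_thickness),
                out_dir / paths[key],
            )
        rows.append({
            "subject_id": rec.subject_id,
            "true_total": rec.true_total,
            "true_category": rec.category,
            **paths,
        })
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path
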