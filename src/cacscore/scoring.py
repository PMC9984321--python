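"""Agatston coronary-calcium scoring with a voltage-adapted threshold.

The Agatston score is computed slice-wise on contiguous 3 mm slices: pixels
at or above the detection threshold (130 HU at 120 kVp) are grouped into
in-plane connected components, components smaller than 1 mm^2 are discarded,
and each remaining lesion contributes ``area (mm^2) x density weight``,
where the weight is 1/2/3/4 for a peak HU in [threshold, 200), [200, 300),
[300, 400), [400, inf). The per-scan score is the sum over slices; lesions
are attributed to a coronary artery (LM, LAD, LCx, RCA) by majority vote of
a co-registered label mask, with LM and LAD also reported combined.

At 130 kVp calcium attenuates less, so the fixed 130 HU cut-off under-detects;
the adapted threshold rescales it by the ratio of the calibration-rod HU at
the target voltage to its HU at 120 kVp::

    t_target = 130 HU * HU_CaHA@target / HU_CaHA@120kVp

Only the detection threshold is adapted — the density-weight bin edges stay
at 200/300/400 HU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import VoxelGrid

__all__ = [
    "ScoringConfig",
    "ThresholdCalibration",
    "LesionMeasurement",
    "AgatstonResult",
    "adapted_threshold",
    "mean_roi_hu",
    "density_weight",
    "score_slice",
    "total_score",
    "cac_positive",
]

AGATSTON_THRESHOLD_HU = 130.0
WEIGHT_BIN_EDGES = (200.0, 300.0, 400.0)
VESSELS = ("LM", "LAD", "LCx", "RCA")

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass(frozen=True)
class ScoringConfig:
    """Detection and grouping parameters of the Agatston computation."""

    threshold_hu: float = AGATSTON_THRESHOLD_HU
    min_area_mm2: float = 1.0
    connectivity: int = 8  # in-plane: 4 or 8
    slab_mm: float = 3.0  # non-overlapping scoring partition

    def __post_init__(self) -> None:
        if self.threshold_hu <= 0:
            raise ValueError("detection threshold must be positive")
        if self.min_area_mm2 <= 0:
            raise ValueError("minimum lesion area must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def adapted_threshold(hu_target: float, hu_120: float) -> float:
    """Detection threshold rescaled to another tube voltage.

    ``130 * hu_target / hu_120``, where the two inputs are the calibration
    rod's mean HU at the target voltage and at 120 kVp. Returned unrounded.
    """
    if hu_target <= 0 or hu_120 <= 0:
        raise ValueError("calibration HU values must be positive")
    return AGATSTON_THRESHOLD_HU * hu_target / hu_120


@dataclass(frozen=True)
class ThresholdCalibration:
    """Calibration-rod HU pair and the detection threshold derived from it."""

    hu_target_kvp: float
    hu_120kvp: float
    threshold_hu: float

    def __post_init__(self) -> None:
        if self.hu_target_kvp <= 0 or self.hu_120kvp <= 0 or self.threshold_hu <= 0:
            raise ValueError("calibration values must be positive")

    @classmethod
    def from_rod_hu(cls, hu_target_kvp: float, hu_120kvp: float) -> "ThresholdCalibration":
        return cls(hu_target_kvp, hu_120kvp, adapted_threshold(hu_target_kvp, hu_120kvp))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ThresholdCalibration":
        return cls(**json.loads(Path(path).read_text()))


def mean_roi_hu(
    volume: VoxelGrid,
    center_xy: tuple[float, float],
    diameter: float,
    slice_index: int | None = None,
) -> float:
    """Mean HU over a circular ROI on one slice (central slice by default).

    ``center_xy`` is the world (y, x) position in mm; the ROI is the set of
    pixels whose centres fall within ``diameter / 2`` of it.
    """
    if slice_index is None:
        slice_index = volume.shape[0] // 2
    if not 0 <= slice_index < volume.shape[0]:
        raise ValueError(f"slice index {slice_index} outside volume")
    y = volume.axis_coords(1)
    x = volume.axis_coords(2)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    m = (yy - center_xy[0]) ** 2 + (xx - center_xy[1]) ** 2 <= (diameter / 2.0) ** 2
    if not m.any():
        raise ValueError("ROI contains no voxels")
    return float(volume.values[slice_index][m].mean())


@dataclass(frozen=True)
class LesionMeasurement:
    """One connected calcified component on one scored slice."""

    slice_index: int
    pixel_count: int
    area_mm2: float
    peak_hu: float
    weight: int
    score: float
    vessel: str | None = None


def density_weight(peak_hu: float) -> int:
    """Agatston density weight of a lesion from its peak HU."""
    return 1 + int(np.searchsorted(WEIGHT_BIN_EDGES, peak_hu, side="right"))


def score_slice(
    slice_hu: np.ndarray,
    pixel_area_mm2: float,
    config: ScoringConfig = ScoringConfig(),
    vessel_labels: np.ndarray | None = None,
    slice_index: int = 0,
) -> list[LesionMeasurement]:
    """Agatston lesions of a single 2-D slice.

    Thresholds at ``config.threshold_hu``, groups pixels under the configured
    in-plane connectivity, drops components below the minimum area, and
    scores each remaining component as area times density weight.
    """
    slice_hu = np.asarray(slice_hu)
    if slice_hu.ndim != 2:
        raise ValueError("score_slice expects a 2-D slice")
    if pixel_area_mm2 <= 0:
        raise ValueError("pixel area must be positive")
    mask = slice_hu >= config.threshold_hu
    if not mask.any():
        return []
    labels, n = ndimage.label(mask, structure=_STRUCTURES[config.connectivity])
    lesions = []
    for obj_slice, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        comp = labels[obj_slice] == lab
        npix = int(comp.sum())
        area = npix * pixel_area_mm2
        if area < config.min_area_mm2:
            continue
        peak = float(slice_hu[obj_slice][comp].max())
        weight = density_weight(peak)
        vessel = None
        if vessel_labels is not None:
            votes = np.bincount(vessel_labels[obj_slice][comp].astype(int).ravel())
            top = int(votes.argmax())
            if top > 0:
                vessel = VESSELS[top - 1]
        lesions.append(
            LesionMeasurement(slice_index, npix, area, peak, weight, area * weight, vessel)
        )
    return lesions


@dataclass
class AgatstonResult:
    """Total and per-vessel Agatston scores of one scan."""

    total: float
    per_vessel: dict[str, float]
    unassigned: float
    lesions: list[LesionMeasurement] = field(default_factory=list)

    @property
    def lm_lad(self) -> float:
        """LM and LAD combined, reported as one vessel."""
        return self.per_vessel["LM"] + self.per_vessel["LAD"]

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "per_vessel": dict(self.per_vessel),
            "lm_lad": self.lm_lad,
            "unassigned": self.unassigned,
            "lesions": [asdict(les) for les in self.lesions],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _scoring_slices(volume: VoxelGrid, slab_mm: float) -> list[int]:
    """Indices of a non-overlapping slab partition, phase-locked to slice 0.

    Overlapping reconstructions (increment < thickness) are scored on every
    ``thickness / increment``-th slice; contiguous volumes score every slice.
    """
    dz = volume.spacing[0]
    thickness = volume.slice_thickness
    if thickness <= dz * (1 + 1e-9):
        return list(range(volume.shape[0]))
    stride = thickness / dz
    if abs(stride - round(stride)) > 1e-6:
        raise ValueError(
            f"slice thickness {thickness} mm is not an integer multiple of the "
            f"increment {dz} mm; no non-overlapping partition exists"
        )
    return list(range(0, volume.shape[0], int(round(stride))))


def total_score(
    volume: VoxelGrid,
    config: ScoringConfig = ScoringConfig(),
    mask: np.ndarray | None = None,
) -> AgatstonResult:
    """Agatston total and per-vessel scores of a CT volume.

    ``mask`` is an optional vessel label map on the scan grid (0 background,
    1..4 = LM/LAD/LCx/RCA); each lesion is attributed by majority label among
    its pixels, and unlabeled lesions still count toward the total.
    """
    if mask is not None and mask.shape != volume.shape:
        raise ValueError(f"vessel mask shape {mask.shape} != volume shape {volume.shape}")
    lesions: list[LesionMeasurement] = []
    for k in _scoring_slices(volume, config.slab_mm):
        lesions.extend(
            score_slice(
                volume.values[k],
                volume.pixel_area,
                config,
                vessel_labels=None if mask is None else mask[k],
                slice_index=k,
            )
        )
    per_vessel = {v: 0.0 for v in VESSELS}
    unassigned = 0.0
    for les in lesions:
        if les.vessel is None:
            unassigned += les.score
        else:
            per_vessel[les.vessel] += les.score
    total = sum(les.score for les in lesions)
    return AgatstonResult(total, per_vessel, unassigned, lesions)


def cac_positive(result: AgatstonResult | float) -> bool:
    """Coronary calcium present: total Agatston score of at least 1."""
    total = result.total if isinstance(result, AgatstonResult) else float(result)
    return total >= 1.0
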