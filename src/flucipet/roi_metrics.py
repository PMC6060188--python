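"""ROI construction and semiquantitative uptake metrics.

Implements the measurement conventions of threshold-based amino-acid PET
tumor quantification: a spherical search ROI over the lesion, a 15-mm
spherical background ROI mirrored to the contralateral hemisphere, and
"metabolically active tumor" segmentation at minimum thresholds of k times
the contralateral background SUV_mean (k = 1.3, 1.6, 1.9 by default).  From
these it derives, per frame:

* ``SUV_max``   — hottest voxel in the search region,
* ``SUV_mean_k`` — mean SUV over voxels at or above ``k * background``,
* ``TB_max = SUV_max / background_mean``,
* ``TB_mean_k = SUV_mean_k / background_mean``,
* segmented volume (mL) at each threshold.

Empty threshold masks yield missing values (NaN), never zeros, so downstream
statistics can exclude them explicitly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .phantom import DynamicImage, voxel_center_coords

__all__ = [
    "SphereROI",
    "VoxelMask",
    "UptakeMetrics",
    "DEFAULT_THRESHOLDS",
    "BACKGROUND_SPHERE_DIAMETER_MM",
    "sphere_mask",
    "mirror_contralateral",
    "background_mean",
    "threshold_segment",
    "lesion_metrics",
    "metrics_table",
]

#: Minimum thresholds (multiples of contralateral background SUV_mean).
DEFAULT_THRESHOLDS: tuple[float, ...] = (1.3, 1.6, 1.9)

#: Background sphere size, read as 15-mm *diameter* (PET convention).
BACKGROUND_SPHERE_DIAMETER_MM = 15.0


@dataclass(frozen=True)
class SphereROI:
    """A spherical region in world coordinates (mm)."""

    center_mm: tuple[float, float, float]
    diameter_mm: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be > 0")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass(frozen=True)
class VoxelMask:
    """A boolean volume on an image grid, with its voxel size for volumetrics."""

    mask: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 3:
            raise ValueError("mask must be 3-D")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_ml(self) -> float:
        return self.count * self.voxel_size_mm**3 / 1000.0

    def __and__(self, other: "VoxelMask") -> "VoxelMask":
        return VoxelMask(self.mask & other.mask, self.voxel_size_mm)

    def minus(self, other: "VoxelMask | None") -> "VoxelMask":
        if other is None:
            return self
        return VoxelMask(self.mask & ~other.mask, self.voxel_size_mm)


@dataclass(frozen=True)
class UptakeMetrics:
    """Per-lesion, per-frame semiquantitative metrics.

    ``suv_mean``, ``tb_mean`` and ``segmented_volume_ml`` are keyed by
    threshold ratio k; missing (empty-mask) entries hold NaN with volume 0.
    """

    lesion_id: str
    frame_index: int
    frame_mid_time_min: float
    background_mean: float
    suv_max: float
    tb_max: float
    suv_mean: dict[float, float]
    tb_mean: dict[float, float]
    segmented_volume_ml: dict[float, float]


def sphere_mask(
    roi: SphereROI,
    shape: tuple[int, int, int],
    voxel_size_mm: float,
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> VoxelMask:
    """Voxels whose centers lie within the sphere (center-in convention).

    A sphere entirely outside the grid yields an empty mask with a warning,
    not an error.
    """
    xs, ys, zs = voxel_center_coords(shape, voxel_size_mm, origin_mm)
    cx, cy, cz = roi.center_mm
    d2 = (
        (xs - cx)[:, None, None] ** 2
        + (ys - cy)[None, :, None] ** 2
        + (zs - cz)[None, None, :] ** 2
    )
    mask = d2 <= roi.radius_mm**2
    if not mask.any():
        warnings.warn("sphere ROI does not cover any voxel center; mask is empty")
    return VoxelMask(mask, voxel_size_mm)


def mirror_contralateral(
    point_mm: tuple[float, float, float], midsagittal_plane_x_mm: float
) -> tuple[float, float, float]:
    """Reflect a world point across the midsagittal plane x = const.

    Used to place the contralateral normal-brain background sphere; applying
    it twice is the identity.
    """
    x, y, z = point_mm
    return (2.0 * midsagittal_plane_x_mm - x, y, z)


def background_mean(frame: np.ndarray, mask: VoxelMask) -> float:
    """Arithmetic mean SUV over the (nonempty) background mask."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != mask.mask.shape:
        raise ValueError("frame and mask shapes differ")
    if mask.count == 0:
        raise ValueError("background mask is empty; background SUV_mean undefined")
    return float(frame[mask.mask].mean())


def threshold_segment(
    frame: np.ndarray,
    search: VoxelMask,
    bg: float,
    k: float,
    exclude: VoxelMask | None = None,
) -> VoxelMask:
    """Metabolically active tumor: search-ROI voxels at or above ``k * bg``.

    ``exclude`` removes blood-pool / choroid-plexus voxels from consideration.
    The comparison is >= — a *minimum* threshold includes boundary voxels.
    """
    frame = np.asarray(frame, dtype=float)
    if bg <= 0:
        raise ValueError("background SUV_mean must be > 0")
    if search.count == 0:
        raise ValueError("search ROI is empty")
    eligible = search.minus(exclude)
    return VoxelMask(eligible.mask & (frame >= k * bg), search.voxel_size_mm)


def lesion_metrics(
    frame: np.ndarray,
    search: VoxelMask,
    bg: float,
    ks: tuple[float, ...] = DEFAULT_THRESHOLDS,
    exclude: VoxelMask | None = None,
    lesion_id: str = "",
    frame_index: int = 0,
    frame_mid_time_min: float = float("nan"),
) -> UptakeMetrics:
    """All per-frame uptake metrics for one lesion search region."""
    frame = np.asarray(frame, dtype=float)
    eligible = search.minus(exclude)
    if eligible.count == 0:
        raise ValueError("search ROI (minus exclusions) is empty")
    suv_max = float(frame[eligible.mask].max())
    suv_mean: dict[float, float] = {}
    tb_mean: dict[float, float] = {}
    seg_vol: dict[float, float] = {}
    for k in ks:
        seg = threshold_segment(frame, search, bg, k, exclude)
        seg_vol[k] = seg.volume_ml
        if seg.count == 0:
            suv_mean[k] = math.nan
            tb_mean[k] = math.nan
        else:
            m = float(frame[seg.mask].mean())
            suv_mean[k] = m
            tb_mean[k] = m / bg
    return UptakeMetrics(
        lesion_id=lesion_id,
        frame_index=frame_index,
        frame_mid_time_min=frame_mid_time_min,
        background_mean=bg,
        suv_max=suv_max,
        tb_max=suv_max / bg,
        suv_mean=suv_mean,
        tb_mean=tb_mean,
        segmented_volume_ml=seg_vol,
    )


def metrics_table(
    img: DynamicImage,
    searches: dict[str, VoxelMask],
    bg_mask: VoxelMask,
    ks: tuple[float, ...] = DEFAULT_THRESHOLDS,
    excludes: dict[str, VoxelMask] | None = None,
):
    """Per-lesion x per-frame metrics as a tidy DataFrame.

    One row per (lesion, frame); threshold-keyed metrics become columns
    ``suv_mean_1.3``, ``tb_mean_1.3``, ``volume_ml_1.3`` etc.  The background
    sphere is fixed across frames; each frame's own background mean normalizes
    that frame's ratios.
    """
    import pandas as pd

    mids = img.schedule.frame_mid_times_min
    rows = []
    for lesion_id, search in searches.items():
        excl = (excludes or {}).get(lesion_id)
        for f in range(img.schedule.n_frames):
            frame = img.frame(f)
            bg = background_mean(frame, bg_mask)
            if bg <= 0:
                # pre-uptake frame: background SUV ~ 0, ratios undefined
                eligible = search.minus(excl)
                row = {
                    "lesion_id": lesion_id,
                    "frame_index": f,
                    "time_min": float(mids[f]),
                    "background_mean": bg,
                    "suv_max": float(frame[eligible.mask].max()),
                    "tb_max": math.nan,
                }
                for k in ks:
                    row[f"suv_mean_{k:g}"] = math.nan
                    row[f"tb_mean_{k:g}"] = math.nan
                    row[f"volume_ml_{k:g}"] = 0.0
                rows.append(row)
                continue
            m = lesion_metrics(
                frame, search, bg, ks, excl,
                lesion_id=lesion_id, frame_index=f, frame_mid_time_min=float(mids[f]),
            )
            row = {
                "lesion_id": m.lesion_id,
                "frame_index": m.frame_index,
                "time_min": m.frame_mid_time_min,
                "background_mean": m.background_mean,
                "suv_max": m.suv_max,
                "tb_max": m.tb_max,
            }
            for k in ks:
                row[f"suv_mean_{k:g}"] = m.suv_mean[k]
                row[f"tb_mean_{k:g}"] = m.tb_mean[k]
                row[f"volume_ml_{k:g}"] = m.segmented_volume_ml[k]
            rows.append(row)
    return pd.DataFrame(rows)
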