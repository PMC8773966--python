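"""Iterative global-maximum lesion extraction from SUV volumes.

The extraction loop mirrors how hot bone lesions are enumerated on a
quantitative workstation: pick the hottest voxel of the volume, grow a
volume of interest (VOI) around it, exclude that region, and repeat until
the desired number of lesions (at most five per category) is reached or
the remaining maximum sinks into background.

The VOI is grown by fixed-fraction thresholding: the 26-connected component
of voxels above ``frac`` times the seed SUV, clipped to a ball of
``radius_mm`` around the seed.  Vendor VOI tools are proprietary; this is
the standard fixed-threshold construction and all three knobs are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import ndimage

from .quantification import SUVVolume

__all__ = [
    "Region",
    "Category",
    "Voi",
    "Lesion",
    "VolumeExhaustedError",
    "global_maximum",
    "grow_voi",
    "extract_lesions",
    "top_k_per_category",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class Region(str, Enum):
    LUMBAR = "L"
    THORACIC = "T"
    PELVIC = "P"
    OTHER = "O"


class Category(str, Enum):
    METASTATIC = "metastatic"
    DEGENERATIVE = "degenerative"


class VolumeExhaustedError(RuntimeError):
    """Raised when every voxel of a volume has been excluded."""


@dataclass
class Voi:
    """A grown volume of interest: seed voxel, member voxels, peak SUV."""

    seed_voxel: tuple[int, int, int]
    mask: np.ndarray              # boolean grid, same shape as the volume
    suv_max: float
    centroid_mm: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class Lesion:
    lesion_id: str
    patient_id: str
    category: Category
    region: Region
    suv_max: float
    voi: Voi | None = None


def global_maximum(vol: SUVVolume,
                   excluded: np.ndarray | None = None
                   ) -> tuple[tuple[int, int, int], float]:
    """Hottest non-excluded voxel; ties broken by smallest (i, j, k).

    ``excluded`` is a boolean mask of voxels to ignore.
    """
    grid = vol.grid
    if excluded is not None:
        if excluded.all():
            raise VolumeExhaustedError("all voxels excluded")
        work = np.where(excluded, -np.inf, grid)
    else:
        work = grid
    flat = int(np.argmax(work))  # first occurrence in C order = lexicographic
    idx = np.unravel_index(flat, grid.shape)
    return tuple(int(i) for i in idx), float(grid[idx])


def _ball_mask(shape: tuple[int, ...], center: tuple[int, int, int],
               radius_mm: float, spacing: tuple[float, float, float]
               ) -> np.ndarray:
    axes = [(np.arange(n) - c) * s
            for n, c, s in zip(shape, center, spacing)]
    d2 = (axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2
          + axes[2][None, None, :] ** 2)
    return d2 <= radius_mm ** 2


def grow_voi(vol: SUVVolume, seed: tuple[int, int, int],
             frac: float = 0.40, radius_mm: float = 15.0) -> Voi:
    """Fixed-fraction threshold VOI around ``seed``.

    Mask = 26-connected component containing the seed among voxels with
    SUV >= frac * SUV(seed), intersected with a ball of ``radius_mm``.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    grid = vol.grid
    if any(not 0 <= s < n for s, n in zip(seed, grid.shape)):
        raise ValueError(f"seed {seed} outside grid of shape {grid.shape}")
    seed = tuple(int(s) for s in seed)
    seed_val = float(grid[seed])
    above = grid >= frac * seed_val
    above &= _ball_mask(grid.shape, seed, radius_mm, vol.voxel_spacing_mm)
    labels, _ = ndimage.label(above, structure=_STRUCT_26)
    mask = labels == labels[seed]
    coords = np.argwhere(mask)
    centroid = tuple(
        float(np.mean(coords[:, a]) * vol.voxel_spacing_mm[a]
              + vol.origin_mm[a]) for a in range(3))
    return Voi(seed_voxel=seed, mask=mask, suv_max=seed_val,
               centroid_mm=centroid)


def extract_lesions(vol: SUVVolume, k_max: int = 5, frac: float = 0.40,
                    radius_mm: float = 15.0,
                    floor: float | None = None) -> list[Voi]:
    """Extract up to ``k_max`` VOIs by iterated global-maximum selection.

    Stops early when the next maximum falls below ``floor`` (default:
    twice the median of the nonzero voxels, a background proxy that makes
    the operator's stopping choice deterministic).  Returned VOIs are
    pairwise disjoint and sorted by decreasing SUVmax.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    grid = vol.grid
    nonzero = grid[grid > 0]
    if nonzero.size == 0:
        return []
    if floor is None:
        floor = 2.0 * float(np.median(nonzero))
    excluded = np.zeros(grid.shape, dtype=bool)
    vois: list[Voi] = []
    while len(vois) < k_max:
        try:
            seed, value = global_maximum(vol, excluded)
        except VolumeExhaustedError:
            break
        if value < floor or value <= 0:
            break
        voi = grow_voi(vol, seed, frac=frac, radius_mm=radius_mm)
        voi.mask &= ~excluded  # keep VOIs pairwise disjoint
        excluded |= voi.mask
        excluded |= _ball_mask(grid.shape, seed, radius_mm,
                               vol.voxel_spacing_mm)
        # consume the whole connected hot region, not just the ball-clipped
        # VOI, so an extended lesion is never re-selected from its far side
        labels, _ = ndimage.label(grid >= frac * value, structure=_STRUCT_26)
        excluded |= labels == labels[seed]
        vois.append(voi)
    vois.sort(key=lambda v: -v.suv_max)
    return vois


def top_k_per_category(table: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Keep the k highest distinct SUVmax per patient and category.

    Equal SUVmax values within a patient/category are deduplicated (first
    by lesion_id kept) before truncation, so the survivors carry distinct
    values; every patient keeps at least one lesion of each category it had.
    """
    required = {"patient_id", "category", "suv_max"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")

    if "lesion_id" in table.columns:
        out = table.sort_values(["suv_max", "lesion_id"],
                                ascending=[False, True], kind="stable")
    else:
        out = table.sort_values("suv_max", ascending=False, kind="stable")
    out = out.drop_duplicates(subset=["patient_id", "category", "suv_max"],
                              keep="first")
    rank = out.groupby(["patient_id", "category"], observed=True).cumcount()
    return out[rank < k].reset_index(drop=True)
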