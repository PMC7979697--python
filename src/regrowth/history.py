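"""Per-pixel forest-history reconstruction from annual land-cover stacks.

A pixel's annual series of {forest=1, anthropic=0} determines, in the
final year of the stack:

* its class — *old-growth* (forest in every year), *secondary*
  (forest in the final year after at least one anthropic year),
  *anthropic* (non-forest in the final year; any earlier secondary
  episode is disregarded), or *nodata*;
* its age — the length of the uninterrupted forest run ending at the
  final layer (1 = regrew in the final year); with an n-year stack ages
  span 1..n−1;
* its deforestation count — the number of forest→anthropic conversions
  before the most recent regrowth onset (1 = only the original
  conversion; pixels already anthropic in the first year are counted as
  1, their conversion predating the observation window).

Secondary pixels are grouped into connected patches; only patches of at
least 9000 m² (10 Landsat pixels, ≈ one cell of the coarse biomass
product) are retained for analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import Grid, NODATA

__all__ = [
    "CLASS_NODATA",
    "CLASS_OLD_GROWTH",
    "CLASS_SECONDARY",
    "CLASS_ANTHROPIC",
    "CLASS_EXCLUDED",
    "ForestHistoryMap",
    "PatchSet",
    "classify_history",
    "count_repeated_deforestations",
    "apply_exclusion_masks",
    "flag_burned",
    "label_patches",
]

CLASS_NODATA = 0
CLASS_OLD_GROWTH = 1
CLASS_SECONDARY = 2
CLASS_ANTHROPIC = 3
CLASS_EXCLUDED = 4

CLASS_NAMES = {
    CLASS_NODATA: "nodata",
    CLASS_OLD_GROWTH: "old_growth",
    CLASS_SECONDARY: "secondary",
    CLASS_ANTHROPIC: "anthropic",
    CLASS_EXCLUDED: "excluded",
}


@dataclass
class ForestHistoryMap:
    """Final-year forest history: class, age, deforestation count, burned flag.

    ``age`` and ``deforestation_count`` are −1 where undefined (only
    secondary pixels carry them); ``burned`` is filled by
    :func:`flag_burned` once burned-area masks are available.
    """

    class_map: np.ndarray
    age: np.ndarray
    deforestation_count: np.ndarray
    burned: np.ndarray
    grid: Grid

    @property
    def secondary(self) -> np.ndarray:
        return self.class_map == CLASS_SECONDARY

    @property
    def old_growth(self) -> np.ndarray:
        return self.class_map == CLASS_OLD_GROWTH

    def class_names(self) -> np.ndarray:
        out = np.empty(self.class_map.shape, dtype=object)
        for code, name in CLASS_NAMES.items():
            out[self.class_map == code] = name
        return out


def _validate_stack(stack: np.ndarray) -> np.ndarray:
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_years, rows, cols)")
    if stack.shape[0] < 2:
        raise ValueError("need at least two annual layers")
    bad = ~np.isin(stack, (0, 1, NODATA))
    if bad.any():
        raise ValueError("land-cover stack must contain only {0, 1, nodata}")
    return stack


def classify_history(stack: np.ndarray, grid: Grid | None = None) -> ForestHistoryMap:
    """Reconstruct class/age/deforestation-count from an annual binary stack."""
    stack = _validate_stack(stack)
    n_years, rows, cols = stack.shape
    if grid is None:
        grid = Grid(rows, cols)
    elif grid.shape != (rows, cols):
        raise ValueError("grid shape does not match stack layers")

    nodata_any = (stack == NODATA).any(axis=0)
    forest = stack == 1

    all_forest = forest.all(axis=0)
    final_forest = forest[-1]
    # length of the trailing run of forest years
    trailing = np.cumprod(forest[::-1], axis=0).sum(axis=0)
    # forest→anthropic transitions over the whole series; for a pixel
    # forested in the final year these all precede the regrowth onset
    clearings = (forest[:-1] & ~forest[1:]).sum(axis=0)

    class_map = np.full((rows, cols), CLASS_ANTHROPIC, dtype=np.uint8)
    class_map[final_forest] = CLASS_SECONDARY
    class_map[all_forest] = CLASS_OLD_GROWTH
    class_map[nodata_any] = CLASS_NODATA

    secondary = class_map == CLASS_SECONDARY
    age = np.where(secondary, trailing, -1).astype(np.int32)
    count = np.where(secondary, np.maximum(clearings, 1), -1).astype(np.int32)

    burned = np.zeros((rows, cols), dtype=bool)
    return ForestHistoryMap(class_map, age, count, burned, grid)


def count_repeated_deforestations(series) -> int:
    """Number of forest→anthropic transitions in one pixel's annual series.

    Returns the raw transition count at or before the onset of the final
    forest run (0 for an all-forest, old-growth series).
    """
    series = np.asarray(series)
    if series.ndim != 1 or series.size < 2:
        raise ValueError("series must be one-dimensional with length ≥ 2")
    if not np.isin(series, (0, 1)).all():
        raise ValueError("series must be binary")
    forest = series == 1
    return int((forest[:-1] & ~forest[1:]).sum())


def apply_exclusion_masks(
    history: ForestHistoryMap,
    masks: list[np.ndarray] | None = None,
    buffers: list[tuple[tuple[float, float], float]] | None = None,
) -> ForestHistoryMap:
    """Mark pixels under any mask, or within a buffer radius of a point, excluded.

    ``buffers`` are ((x, y), radius) pairs in grid coordinates (metres);
    a pixel is excluded when its centre lies within the radius. Used to
    drop plantation misclassifications and field-site surroundings.
    """
    excluded = np.zeros(history.class_map.shape, dtype=bool)
    for mask in masks or []:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != history.class_map.shape:
            raise ValueError("exclusion mask shape does not match history grid")
        excluded |= mask
    if buffers:
        xs, ys = history.grid.cell_centers()
        for (px, py), radius in buffers:
            excluded |= (xs - px) ** 2 + (ys - py) ** 2 <= radius ** 2

    class_map = history.class_map.copy()
    class_map[excluded & (class_map != CLASS_NODATA)] = CLASS_EXCLUDED
    secondary = class_map == CLASS_SECONDARY
    age = np.where(secondary, history.age, -1).astype(np.int32)
    count = np.where(secondary, history.deforestation_count, -1).astype(np.int32)
    burned = history.burned & secondary
    return ForestHistoryMap(class_map, age, count, burned, history.grid)


def flag_burned(history: ForestHistoryMap, burned_masks: np.ndarray) -> ForestHistoryMap:
    """Set the burned flag where any annual burned-area mask touches a pixel."""
    burned_masks = np.asarray(burned_masks, dtype=bool)
    if burned_masks.ndim == 2:
        burned_masks = burned_masks[None]
    if burned_masks.shape[-2:] != history.class_map.shape:
        raise ValueError("burned masks do not match history grid")
    burned = burned_masks.any(axis=0) & history.secondary
    return ForestHistoryMap(
        history.class_map, history.age, history.deforestation_count, burned, history.grid
    )


@dataclass
class PatchSet:
    """Connected secondary-forest patches above the minimum mapping unit.

    ``labels`` holds the patch id per pixel (0 = background, including
    secondary pixels of dropped sub-threshold components); ``table`` has
    one row per retained patch with its representative age (modal over
    member pixels, ties toward the smaller value), deforestation and
    burned classes.
    """

    labels: np.ndarray
    table: pd.DataFrame
    min_area_m2: float
    connectivity: int = 8

    def __len__(self) -> int:
        return len(self.table)


def _mode_smallest(values: np.ndarray) -> int:
    vals, counts = np.unique(values, return_counts=True)
    return int(vals[np.argmax(counts)])  # np.unique sorts → first max = smallest


def label_patches(
    history: ForestHistoryMap,
    min_area_m2: float = 9000.0,
    connectivity: int = 8,
) -> PatchSet:
    """Delineate secondary patches and drop those below ``min_area_m2`` (≥ rule)."""
    if min_area_m2 <= 0:
        raise ValueError("min_area_m2 must be positive")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    raw_labels, n_raw = ndimage.label(history.secondary, structure=structure)

    area = history.grid.pixel_area_m2
    counts = np.bincount(raw_labels.ravel(), minlength=n_raw + 1)
    keep = np.flatnonzero(counts * area >= min_area_m2)
    keep = keep[keep != 0]

    relabel = np.zeros(n_raw + 1, dtype=np.int32)
    relabel[keep] = np.arange(1, len(keep) + 1)
    labels = relabel[raw_labels]

    rows = []
    for new_id, old_id in enumerate(keep, start=1):
        sel = raw_labels == old_id
        ages = history.age[sel]
        defs = history.deforestation_count[sel]
        age = _mode_smallest(ages)
        n_def = _mode_smallest(defs)
        burned = bool(history.burned[sel].any())
        repeated = n_def >= 2
        rows.append(
            {
                "patch_id": new_id,
                "n_pixels": int(sel.sum()),
                "area_m2": float(sel.sum() * area),
                "age": age,
                "deforestation_count": n_def,
                "repeated": repeated,
                "burned": burned,
                "dist_class": (
                    ("repeated_" if repeated else "single_")
                    + ("burnt" if burned else "not_burnt")
                ),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "patch_id",
            "n_pixels",
            "area_m2",
            "age",
            "deforestation_count",
            "repeated",
            "burned",
            "dist_class",
        ],
    )
    return PatchSet(labels, table, min_area_m2, connectivity)
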