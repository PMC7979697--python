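"""Attach carbon and driver values to patches; build age–AGC tables.

This is the space-for-time substitution step: instead of following any
single stand through time, the single-epoch carbon map is summarised
per patch (modal AGC, since a patch of secondary forest overlies a
handful of coarse biomass cells), the patch values are grouped by stand
age, and the per-age medians form the chronosequence the growth curve
is fitted to. Biomass is converted to carbon at the conventional 2:1
ratio (AGC = AGB / 2).

A bias correction subtracts the smallest per-age median from every
median, shifting each group's chronosequence to start at or near zero
for a one-year-old stand; the same offset must be applied to that
group's old-growth asymptote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import NODATA
from .history import PatchSet

__all__ = [
    "agb_to_agc",
    "zonal_modal_agc",
    "zonal_mean_driver",
    "build_patch_records",
    "AgeAGCTable",
    "build_age_table",
]


def agb_to_agc(agb):
    """Convert aboveground biomass (Mg ha⁻¹) to carbon (Mg C ha⁻¹): AGC = AGB/2."""
    agb = np.asarray(agb, dtype=float)
    if (agb[np.isfinite(agb)] < 0).any():
        raise ValueError("biomass must be non-negative")
    return agb / 2.0


def _patch_values(labels: np.ndarray, patch_id: int, raster: np.ndarray) -> np.ndarray:
    sel = labels == patch_id
    if not sel.any():
        raise ValueError(f"patch {patch_id} has no pixels")
    vals = np.asarray(raster, dtype=float)[sel]
    vals = vals[np.isfinite(vals) & (vals != NODATA)]
    if vals.size == 0:
        raise ValueError(f"patch {patch_id} has no valid overlapping cells")
    return vals


def zonal_modal_agc(
    labels: np.ndarray,
    patch_id: int,
    agc_raster: np.ndarray,
    bin_width: float = 1.0,
) -> float:
    """Modal AGC of a patch (Mg C ha⁻¹).

    Continuous carbon values are binned to ``bin_width`` before taking
    the mode (a raw mode on near-continuous rasters is degenerate); ties
    go to the smaller bin, and the returned value is the median of the
    raw values inside the modal bin, so a patch over a constant surface
    returns that constant exactly.
    """
    vals = _patch_values(labels, patch_id, agc_raster)
    bins = np.floor(vals / bin_width).astype(np.int64)
    uniq, counts = np.unique(bins, return_counts=True)
    modal_bin = uniq[np.argmax(counts)]  # unique is sorted → ties pick smaller
    return float(np.median(vals[bins == modal_bin]))


def zonal_mean_driver(labels: np.ndarray, patch_id: int, driver_raster: np.ndarray) -> float:
    """Arithmetic mean of a driver over the patch's valid cells."""
    return float(_patch_values(labels, patch_id, driver_raster).mean())


def build_patch_records(
    patches: PatchSet,
    agc_raster: np.ndarray,
    driver_rasters: dict[str, np.ndarray] | None = None,
    region_raster: np.ndarray | None = None,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """One record per patch: age, modal AGC, per-driver means, region id.

    Vectorised over patches with pandas groupby; semantics match the
    per-patch :func:`zonal_modal_agc` / :func:`zonal_mean_driver` ops.
    """
    labels = patches.labels
    sel = labels > 0
    pid = labels[sel]
    agc = np.asarray(agc_raster, dtype=float)[sel]

    df = pd.DataFrame({"patch_id": pid, "agc_raw": agc})
    df["bin"] = np.floor(df["agc_raw"] / bin_width).astype(np.int64)
    # modal bin per patch (ties → smaller bin), then median raw value within it
    counts = (
        df.groupby(["patch_id", "bin"]).size().rename("n").reset_index()
        .sort_values(["patch_id", "n", "bin"], ascending=[True, False, True])
    )
    modal = counts.drop_duplicates("patch_id").set_index("patch_id")["bin"]
    df = df.merge(modal.rename("modal_bin"), on="patch_id")
    agc_mode = (
        df[df["bin"] == df["modal_bin"]].groupby("patch_id")["agc_raw"].median().rename("agc")
    )

    records = patches.table.set_index("patch_id").join(agc_mode)
    for name, raster in (driver_rasters or {}).items():
        vals = np.asarray(raster, dtype=float)[sel]
        records[name] = pd.Series(vals).groupby(pd.Series(pid)).mean().values
    if region_raster is not None:
        reg = pd.Series(np.asarray(region_raster)[sel])
        mode_reg = (
            reg.groupby(pd.Series(pid)).agg(lambda s: s.value_counts().sort_index().idxmax())
        )
        records["region_id"] = mode_reg.values
    return records.reset_index()


@dataclass
class AgeAGCTable:
    """Bias-corrected median AGC per stand age for one group.

    ``table`` columns: ``age``, ``median_agc_raw``, ``median_agc``
    (corrected), ``n_patches``. ``bias_offset`` is the smallest raw
    median; subtracting it everywhere makes ``min(median_agc) == 0``
    while preserving between-age differences exactly.
    """

    table: pd.DataFrame
    bias_offset: float
    group: str = ""

    @property
    def ages(self) -> np.ndarray:
        return self.table["age"].to_numpy()

    @property
    def medians(self) -> np.ndarray:
        return self.table["median_agc"].to_numpy()

    @property
    def n_ages(self) -> int:
        return len(self.table)


def build_age_table(
    records: pd.DataFrame,
    group: str = "",
    value_col: str = "agc",
    age_col: str = "age",
) -> AgeAGCTable:
    """Median AGC by age, bias-corrected to start at zero.

    Requires at least three distinct ages (a two-parameter curve cannot
    be identified from fewer points).
    """
    if len(records) == 0:
        raise ValueError(f"empty record group {group!r}")
    grouped = records.groupby(age_col)[value_col]
    table = grouped.median().rename("median_agc_raw").reset_index()
    table["n_patches"] = grouped.size().values
    table = table.rename(columns={age_col: "age"}).sort_values("age").reset_index(drop=True)
    if table["age"].nunique() < 3:
        raise ValueError(
            f"group {group!r} has {table['age'].nunique()} distinct ages; need ≥3"
        )
    offset = float(table["median_agc_raw"].min())
    table["median_agc"] = table["median_agc_raw"] - offset
    return AgeAGCTable(table[["age", "median_agc_raw", "median_agc", "n_patches"]], offset, group)
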