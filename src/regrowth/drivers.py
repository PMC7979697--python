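"""Climate and soil driver processing.

Computes the Maximum Cumulative Water Deficit (MCWD) from monthly
precipitation, brings coarser driver rasters onto the 30 m analysis
grid, and bins continuous drivers into the categorical levels used for
grouped growth modelling.

MCWD
----
Within each year the water deficit is accumulated month by month
against a fixed evapotranspiration demand of 100 mm month⁻¹::

    CWD_1 = min(0, P_1 − 100)
    CWD_n = min(0, CWD_{n−1} + P_n − 100)

The year's MCWD is the most negative CWD of its twelve months, and the
driver surface is the mean of the annual MCWDs over the study period.
MCWD is never positive; a month with ≥ 100 mm rainfall can only relax
the deficit, never deepen it. By default years are calendar years reset
each January; a hydrological anchor month is available because the
windowing convention is a genuine free choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid

__all__ = ["DriverSurface", "compute_mcwd", "resample_to_grid", "bin_driver"]

#: Fixed monthly evapotranspiration demand, mm month⁻¹.
EVAPOTRANSPIRATION = 100.0

DRIVER_UNITS = {
    "sw_radiation": "W m-2",
    "precipitation": "mm yr-1",
    "mcwd": "mm yr-1",
    "scc": "cmol(+) kg-1",
    "burn_count": "count",
    "deforestation_count": "count",
}


@dataclass
class DriverSurface:
    """A named driver raster with units and measurement kind."""

    name: str
    values: np.ndarray
    units: str = ""
    kind: str = "continuous"

    def __post_init__(self) -> None:
        if not self.units:
            self.units = DRIVER_UNITS.get(self.name, "")


def compute_mcwd(
    monthly_precip: np.ndarray,
    anchor_month: int = 1,
) -> np.ndarray:
    """Mean annual MCWD (mm yr⁻¹, ≤ 0) from a monthly precipitation series.

    Parameters
    ----------
    monthly_precip
        Array of shape (n_years, 12, ...) or (n_months, ...) with
        n_months divisible by 12. Trailing dimensions are spatial.
    anchor_month
        1-based month at which the yearly deficit window resets
        (1 = calendar years).
    """
    p = np.asarray(monthly_precip, dtype=float)
    if p.ndim >= 2 and p.shape[1] == 12 and p.ndim >= 3:
        pass  # already (n_years, 12, ...)
    else:
        if p.shape[0] % 12:
            raise ValueError("need complete years of monthly precipitation")
        p = p.reshape((p.shape[0] // 12, 12) + p.shape[1:])
    if (p < 0).any():
        raise ValueError("precipitation must be non-negative")
    if not 1 <= anchor_month <= 12:
        raise ValueError("anchor_month must be in 1..12")
    if anchor_month != 1:
        flat = p.reshape((-1,) + p.shape[2:])
        flat = flat[anchor_month - 1 : flat.shape[0] - (12 - anchor_month + 1) or None]
        n_full = flat.shape[0] // 12
        if n_full < 1:
            raise ValueError("no complete window after anchoring")
        p = flat[: n_full * 12].reshape((n_full, 12) + flat.shape[1:])

    n_years = p.shape[0]
    spatial = p.shape[2:]
    mcwd_years = np.zeros((n_years,) + spatial)
    for y in range(n_years):
        cwd = np.zeros(spatial)
        mcwd = np.zeros(spatial)
        for m in range(12):
            cwd = np.minimum(0.0, cwd + p[y, m] - EVAPOTRANSPIRATION)
            mcwd = np.minimum(mcwd, cwd)
        mcwd_years[y] = mcwd
    return mcwd_years.mean(axis=0)


def resample_to_grid(
    values: np.ndarray,
    src_grid: Grid,
    dst_grid: Grid,
) -> np.ndarray:
    """Nearest-neighbour resampling of ``values`` onto ``dst_grid``.

    Each destination pixel takes the value of the source pixel whose
    cell contains the destination pixel's centre; values are replicated
    or subset, never interpolated (safe for categorical layers).
    """
    values = np.asarray(values)
    if values.shape[-2:] != src_grid.shape:
        raise ValueError("values shape does not match source grid")
    xs = dst_grid.x0 + (np.arange(dst_grid.n_cols) + 0.5) * dst_grid.pixel_size
    ys = dst_grid.y0 - (np.arange(dst_grid.n_rows) + 0.5) * dst_grid.pixel_size
    ci = np.floor((xs - src_grid.x0) / src_grid.pixel_size).astype(int)
    ri = np.floor((src_grid.y0 - ys) / src_grid.pixel_size).astype(int)
    if (ci < 0).all() or (ci >= src_grid.n_cols).all() or (ri < 0).all() or (
        ri >= src_grid.n_rows
    ).all():
        raise ValueError("source and target grids do not overlap")
    ci = np.clip(ci, 0, src_grid.n_cols - 1)
    ri = np.clip(ri, 0, src_grid.n_rows - 1)
    return values[..., ri[:, None], ci[None, :]]


#: Category labels for 4- and 3-level binnings, ordered low → high driver value.
BIN_LABELS = {
    4: ("very_low", "low", "moderate", "high"),
    3: ("low", "moderate", "high"),
    2: ("low", "high"),
}


def bin_driver(
    values: np.ndarray,
    breaks: np.ndarray | list | None = None,
    percentiles: tuple = (25, 50, 75),
    labels: tuple | None = None,
):
    """Bin continuous driver values into ordered categories.

    Intervals are half-open ``[b_i, b_{i+1})``; values below the first
    break fall in the first class, values at or above the last break in
    the last class. When ``breaks`` is None they are the given
    percentiles of the finite values (linear interpolation — the patch
    set is the analysis unit, one value per patch).

    Returns ``(labels_array, thresholds)``.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if breaks is None:
        if np.unique(finite).size < 4:
            raise ValueError("need ≥4 distinct values for percentile breaks")
        breaks = np.percentile(finite, percentiles)
    breaks = np.asarray(breaks, dtype=float)
    if (np.diff(breaks) < 0).any():
        raise ValueError("breaks must be sorted ascending")
    n_classes = len(breaks) + 1
    if labels is None:
        labels = BIN_LABELS.get(n_classes, tuple(f"class_{i}" for i in range(n_classes)))
    if len(labels) != n_classes:
        raise ValueError("need one label per interval")
    idx = np.digitize(values, breaks, right=False)
    out = np.asarray(labels, dtype=object)[idx]
    return out, breaks
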