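"""Minimal raster-grid plumbing shared by all stages.

Rasters are plain numpy arrays in row-major order, pixel-centre
registered. A :class:`Grid` carries the affine information (origin of
the top-left pixel corner, square pixel size) in arbitrary projected
units — metres for the 30 m analysis grid. All stages require
co-registered grids; only :func:`regrowth.drivers.resample_to_grid`
moves values between grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Conventional GeoTIFF nodata marker used throughout.
NODATA = -9999


@dataclass(frozen=True)
class Grid:
    """Affine description of a raster: shape + top-left origin + pixel size."""

    n_rows: int
    n_cols: int
    pixel_size: float = 30.0
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def pixel_area_m2(self) -> float:
        return self.pixel_size ** 2

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_area_m2 / 10_000.0

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate arrays of pixel centres, shape (n_rows, n_cols).

        y decreases with row index (north-up convention).
        """
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.pixel_size
        ys = self.y0 - (np.arange(self.n_rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def same_shape(self, arr: np.ndarray) -> bool:
        return arr.shape[-2:] == self.shape
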