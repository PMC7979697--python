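"""Secondary-forest carbon-stock accounting.

Stocks are computed pixel by pixel: each secondary pixel contributes the
growth-curve prediction at its own age, scaled by pixel area,

    stock [Tg C] = Σ_pixels Y_model(age) · area_ha · 10⁻⁶,

with the model chosen by the pixel's patch (climate region ×
disturbance class). The annual ledger between two consecutive years
books

* gains — growth of persisting secondary forest, Y(age+1) − Y(age),
  plus recruitment of new secondary forest at Y(1);
* losses — the modelled stock of secondary pixels deforested between
  the two years;

so that ``stock_end = stock_start + gains − losses`` holds exactly.
A no-disturbance counterfactual rescores every pixel with its region's
single-deforestation/not-burnt curve at the observed age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Grid
from .growth import ChapmanRichardsResults
from .history import ForestHistoryMap, PatchSet

__all__ = [
    "StockLedger",
    "model_id_rasters",
    "total_stock",
    "annual_net_change",
    "potential_stock_no_disturbance",
    "grid_aggregate",
    "percent_reduction",
]

MG_PER_TG = 1e6


@dataclass
class StockLedger:
    """Gains, losses and stock totals (Tg C) for one accounting step."""

    gains_TgC: float
    losses_TgC: float
    stock_start_TgC: float
    stock_end_TgC: float
    grids: dict = field(default_factory=dict)

    @property
    def net_TgC(self) -> float:
        return self.gains_TgC - self.losses_TgC

    def __post_init__(self) -> None:
        if self.gains_TgC < 0 or self.losses_TgC < 0:
            raise ValueError("gains and losses must be non-negative")
        closure = self.stock_end_TgC - self.stock_start_TgC - self.net_TgC
        if abs(closure) > 1e-6:
            raise ValueError(f"ledger does not close: residual {closure:.3e} Tg C")


def model_id_rasters(
    patches: PatchSet,
    region_raster: np.ndarray,
    fits: dict[tuple[int, str], ChapmanRichardsResults],
    strict: bool = True,
):
    """Per-pixel model index for every pixel of a retained patch.

    Returns ``(model_id, fit_list)`` where ``model_id`` is −1 outside
    retained patches and otherwise indexes ``fit_list``. A patch whose
    (region, class) has no fit raises KeyError when ``strict``,
    otherwise drops to −1 (excluded from model-based accounting).
    """
    keys = sorted(fits)
    key_index = {key: i for i, key in enumerate(keys)}
    fit_list = [fits[key] for key in keys]

    table = patches.table
    if "region_id" not in table.columns:
        raise ValueError("patch table lacks region_id; run regionalization first")
    max_id = int(table["patch_id"].max()) if len(table) else 0
    patch_key = np.full(max_id + 1, -1, dtype=np.int32)
    missing = set()
    for row in table.itertuples(index=False):
        key = (int(row.region_id), row.dist_class)
        if key not in key_index:
            missing.add(key)
            continue
        patch_key[row.patch_id] = key_index[key]
    if missing and strict:
        raise KeyError(f"no growth fit for (region, class): {sorted(missing)}")
    model_id = np.where(patches.labels > 0, patch_key[patches.labels], -1)
    return model_id, fit_list


def _stock_per_pixel(
    age: np.ndarray,
    model_id: np.ndarray,
    fit_list: list[ChapmanRichardsResults],
    age_shift: int = 0,
) -> np.ndarray:
    """Mg C per pixel-ha: Y(age + shift) evaluated with each pixel's model."""
    out = np.zeros(age.shape, dtype=float)
    for mid, fit in enumerate(fit_list):
        sel = model_id == mid
        if sel.any():
            out[sel] = fit.predict(age[sel] + age_shift)
    return out


def total_stock(
    age: np.ndarray,
    model_id: np.ndarray,
    fit_list: list[ChapmanRichardsResults],
    pixel_area_ha: float,
) -> float:
    """Total modelled secondary-forest stock in Tg C."""
    secondary = model_id >= 0
    if secondary.any() and (age[secondary] < 1).any():
        raise ValueError("every accounted pixel needs age ≥ 1")
    dens = _stock_per_pixel(age, model_id, fit_list)
    return float(dens[secondary].sum() * pixel_area_ha / MG_PER_TG)


def annual_net_change(
    history_a: ForestHistoryMap,
    history_b: ForestHistoryMap,
    model_id_a: np.ndarray,
    model_id_b: np.ndarray,
    fit_list: list[ChapmanRichardsResults],
    keep_grids: bool = False,
) -> StockLedger:
    """Carbon ledger between two consecutive annual histories.

    ``model_id_a``/``model_id_b`` give each accounted pixel's model in
    the earlier and later year (−1 = not accounted). Losses use the
    model-predicted stock of the deforested pixels (consistent with the
    gains side of the ledger).
    """
    if history_a.class_map.shape != history_b.class_map.shape:
        raise ValueError("histories are not co-registered")
    area_ha = history_a.grid.pixel_area_ha

    sec_a = model_id_a >= 0
    sec_b = model_id_b >= 0
    persisting = sec_a & sec_b
    recruited = sec_b & ~sec_a
    deforested = sec_a & ~sec_b

    bad = persisting & (history_b.age != history_a.age + 1)
    if bad.any():
        raise ValueError(f"{bad.sum()} persisting pixels do not age by exactly one year")
    # true recruits were anthropic the year before and enter at age 1;
    # pixels secondary in both years may enter the accounted set late
    # when their patch first crosses the minimum mapping unit
    from .history import CLASS_ANTHROPIC  # local import avoids cycle at module load

    new_regrowth = recruited & (history_a.class_map == CLASS_ANTHROPIC)
    if (new_regrowth & (history_b.age != 1)).any():
        raise ValueError("pixels regrowing from anthropic land must enter at age 1")
    og_to_sec = recruited & history_a.old_growth
    if og_to_sec.any():
        raise ValueError("old-growth pixels cannot recruit as secondary without clearing")

    dens_a = _stock_per_pixel(history_a.age, model_id_a, fit_list)
    dens_a1 = _stock_per_pixel(history_a.age, model_id_a, fit_list, age_shift=1)
    dens_b = _stock_per_pixel(history_b.age, model_id_b, fit_list)

    growth = np.where(persisting, dens_a1 - dens_a, 0.0)
    recruit = np.where(recruited, dens_b, 0.0)
    loss = np.where(deforested, dens_a, 0.0)

    gains = float((growth.sum() + recruit.sum()) * area_ha / MG_PER_TG)
    losses = float(loss.sum() * area_ha / MG_PER_TG)
    stock_a = float(dens_a[sec_a].sum() * area_ha / MG_PER_TG)

    # independent end-of-year summation (persisting pixels keep their
    # year-a model, so growth and stock sides agree); the StockLedger
    # constructor re-checks the conservation identity
    stock_b = float(
        (np.where(persisting, dens_a1, 0.0).sum() + recruit.sum()) * area_ha / MG_PER_TG
    )
    grids = {}
    if keep_grids:
        grids = {
            "gains_Mg": (growth + recruit) * area_ha,
            "losses_Mg": loss * area_ha,
            "net_Mg": (growth + recruit - loss) * area_ha,
        }
    return StockLedger(gains, losses, stock_a, stock_b, grids)


def potential_stock_no_disturbance(
    age: np.ndarray,
    model_id: np.ndarray,
    region_raster: np.ndarray,
    fits: dict[tuple[int, str], ChapmanRichardsResults],
    pixel_area_ha: float,
    missing: str = "raise",
) -> float:
    """Counterfactual stock with every pixel on its region's no-disturbance curve.

    Observed ages are kept (the counterfactual does not rewind repeated
    clearing to make stands older), so the estimate is conservative.
    ``missing`` controls regions without a no-disturbance fit:
    ``"raise"`` (default) or ``"skip"`` (their pixels are left out, as
    they are on the actual-stock side when their group has no fit).
    """
    secondary = model_id >= 0
    total = 0.0
    for region in np.unique(region_raster[secondary]):
        key = (int(region), "single_not_burnt")
        if key not in fits:
            if missing == "skip":
                continue
            raise KeyError(f"missing no-disturbance fit for region {region}")
        sel = secondary & (region_raster == region)
        total += fits[key].predict(age[sel]).sum()
    return float(total * pixel_area_ha / MG_PER_TG)


def grid_aggregate(
    values: np.ndarray,
    grid: Grid,
    cell_size: float,
    x_origin: float | None = None,
    y_origin: float | None = None,
) -> np.ndarray:
    """Sum per-pixel values onto a coarse grid (default aligned to the raster).

    Every pixel is counted in exactly one coarse cell (centre-point
    rule), so cell sums re-add to the raster total exactly.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values shape does not match grid")
    if cell_size <= 0:
        raise ValueError("cell size must be positive")
    xs, ys = grid.cell_centers()
    x0 = grid.x0 if x_origin is None else x_origin
    y0 = grid.y0 if y_origin is None else y_origin
    ci = np.floor((xs - x0) / cell_size).astype(int)
    ri = np.floor((y0 - ys) / cell_size).astype(int)
    out = np.zeros((ri.max() + 1, ci.max() + 1))
    np.add.at(out, (ri, ci), values)
    return out


def percent_reduction(actual: float, potential: float) -> float:
    """Reduction of the actual stock relative to the potential, in percent."""
    if potential <= 0:
        raise ValueError("potential stock must be positive")
    return 100.0 * (potential - actual) / potential
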