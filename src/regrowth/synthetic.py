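"""Synthetic landscapes with known ground truth.

Emulates the statistical structure of the real inputs — an annual binary
land-cover stack (forest=1 / anthropic=0), climate and soil driver
surfaces, and a single-epoch aboveground-biomass map — so that every
downstream stage (history reconstruction, driver attribution, growth
fitting, regionalization, carbon accounting, scenario projection) can be
tested against exactly known truth without any satellite downloads.

Design in brief
---------------
* The landscape is tiled with *management units*: clearable cores of
  ``unit_rows × unit_cols`` pixels (default 2×5 = 9000 m² at 30 m)
  separated by a permanent-forest margin (default 1 pixel). Clearing,
  abandonment, re-clearing and fire events are drawn per unit-year from
  a Markov chain (forest → anthropic at ``clearing_rate``; anthropic →
  secondary forest at ``abandonment_rate``; secondary → anthropic at
  ``reclearing_rate``). Unit-level events mimic real clearing polygons:
  each regrowing unit is an isolated even-aged patch that exactly meets
  the 9000 m² minimum mapping unit, and the margins keep neighbouring
  patches from merging into unrealistic percolation clusters.
* Four climate regions occupy the grid quadrants. Each region carries a
  planted mean shortwave radiation, annual precipitation, water-deficit
  level and an old-growth carbon asymptote; each (region, disturbance
  class) pair carries a true Chapman–Richards curve ``(A, k, c)``.
* AGC of a secondary pixel of age ``a`` is ``Y(a) = A(1 − e^{−k a})^c``
  plus noise drawn once per management unit (the coarse biomass
  product's error is spatially correlated) plus a small per-pixel
  jitter. Old-growth pixels sit at the regional asymptote plus noise;
  anthropic pixels carry low uniform background biomass. The written
  map is biomass, AGB = 2 × AGC.

Everything is reproducible: the same seed and config give byte-identical
stacks, ledgers and rasters, and the event uniforms are drawn with a
rate-independent stream so that raising ``clearing_rate`` (same seed)
can only add clearing events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .grid import Grid, NODATA

__all__ = [
    "DISTURBANCE_CLASSES",
    "SyntheticConfig",
    "SyntheticScene",
    "default_true_models",
    "chapman_richards",
    "solve_rate_coefficient",
    "monthly_profile",
    "generate_landcover_stack",
    "generate_driver_surfaces",
    "generate_agc_map",
    "simulate_scene",
    "replay_ledger",
]

#: The four disturbance classes of the 16-model regional set.
DISTURBANCE_CLASSES = (
    "single_not_burnt",
    "single_burnt",
    "repeated_not_burnt",
    "repeated_burnt",
)

# Planted regional climatology. Regions are ordered by ascending mean
# shortwave radiation so that region 1 is the wet, low-radiation
# north-west-like corner and region 4 the dry, high-radiation
# north-east-like corner. Values echo published regional means for the
# Brazilian Amazon (e.g. 163.6 W m⁻² and 2049 mm yr⁻¹ in the north-west,
# a 135.5 Mg C ha⁻¹ old-growth asymptote in the north-east).
REGION_CLIMATE = pd.DataFrame(
    {
        "region": [1, 2, 3, 4],
        "sw_radiation": [163.6, 172.0, 181.7, 190.0],
        "precipitation": [2049.0, 2150.0, 1913.0, 1850.0],
        "mcwd": [-64.4, -150.0, -325.5, -390.0],
        "asymptote": [120.0, 128.0, 112.0, 135.5],
        # no-disturbance mean regrowth rate over the first 20 years,
        # Mg C ha⁻¹ yr⁻¹ (3.0 west … 1.3 east)
        "rate20": [3.0, 2.4, 1.8, 1.3],
    }
).set_index("region")

# Multiplier applied to the 20-year accumulation of each disturbance
# class relative to the undisturbed curve (fire and repeated clearing
# reduce regrowth by roughly 20–50%).
CLASS_RATE_FACTOR = {
    "single_not_burnt": 1.0,
    "single_burnt": 0.80,
    "repeated_not_burnt": 0.70,
    "repeated_burnt": 0.50,
}
CLASS_SHAPE = {
    "single_not_burnt": 1.8,
    "single_burnt": 1.7,
    "repeated_not_burnt": 1.7,
    "repeated_burnt": 1.6,
}


def chapman_richards(t, A, k, c):
    """Chapman–Richards curve Y(t) = A·(1 − e^(−k t))^c."""
    t = np.asarray(t, dtype=float)
    return A * np.power(-np.expm1(-k * t), c)


def solve_rate_coefficient(A: float, y20: float, c: float, horizon: int = 20) -> float:
    """Rate coefficient k such that Y(horizon) = y20 for given A and c."""
    frac = y20 / A
    if not 0 < frac < 1:
        raise ValueError("target accumulation must lie strictly below the asymptote")
    return -math.log(1.0 - frac ** (1.0 / c)) / horizon


def default_true_models() -> dict[tuple[int, str], tuple[float, float, float]]:
    """True (A, k, c) per (region, disturbance class).

    k is solved so the 20-year accumulation matches the planted regional
    rate scaled by the disturbance-class factor.
    """
    models: dict[tuple[int, str], tuple[float, float, float]] = {}
    for region, row in REGION_CLIMATE.iterrows():
        for cls in DISTURBANCE_CLASSES:
            c = CLASS_SHAPE[cls]
            y20 = row["rate20"] * 20.0 * CLASS_RATE_FACTOR[cls]
            k = solve_rate_coefficient(row["asymptote"], y20, c)
            models[(int(region), cls)] = (float(row["asymptote"]), k, c)
    return models


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth configuration of a synthetic landscape.

    Rates are probabilities per management-unit-year; the fire process
    starts in ``fire_start_year`` (burned-area products begin in 2001).
    """

    grid_rows: int = 100
    grid_cols: int = 100
    pixel_size_m: float = 30.0
    year_start: int = 1985
    year_end: int = 2017
    clearing_rate: float = 0.03
    abandonment_rate: float = 0.15
    reclearing_rate: float = 0.04
    fire_rate: float = 0.02
    fire_start_year: int = 2001
    unit_rows: int = 2
    unit_cols: int = 5
    unit_margin: int = 1
    true_models: Mapping[tuple[int, str], tuple[float, float, float]] = field(
        default_factory=default_true_models
    )
    noise_sd: float = 5.0
    pixel_noise_sd: float = 0.5
    background_agb_max: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.year_end <= self.year_start:
            raise ValueError("year range must contain at least two years")
        for name in ("clearing_rate", "abandonment_rate", "reclearing_rate", "fire_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0 or self.pixel_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.unit_rows <= 0 or self.unit_cols <= 0 or self.unit_margin < 0:
            raise ValueError("unit shape must be positive, margin non-negative")
        for key, (A, k, c) in self.true_models.items():
            if min(A, k, c) <= 0:
                raise ValueError(f"true model {key} must have A, k, c > 0")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1

    @property
    def grid(self) -> Grid:
        return Grid(self.grid_rows, self.grid_cols, self.pixel_size_m)

    @property
    def burn_years(self) -> np.ndarray:
        return np.arange(max(self.fire_start_year, self.year_start), self.year_end + 1)


# ---------------------------------------------------------------------------
# unit bookkeeping


def _unit_map(config: SyntheticConfig) -> np.ndarray:
    """Management-unit id per pixel, −1 on the permanent-forest margins.

    The grid is tiled with (unit_rows+margin) × (unit_cols+margin)
    tiles; the clearable core occupies the tile's top-left
    unit_rows × unit_cols pixels. Partial tiles at the grid edge are
    margin. Unit ids are renumbered contiguously 0..n_units−1.
    """
    tr = config.unit_rows + config.unit_margin
    tc = config.unit_cols + config.unit_margin
    r = np.arange(config.grid_rows)
    c = np.arange(config.grid_cols)
    core_r = (r % tr < config.unit_rows) & (r + (config.unit_rows - r % tr) <= config.grid_rows)
    core_c = (c % tc < config.unit_cols) & (c + (config.unit_cols - c % tc) <= config.grid_cols)
    n_tcols = (config.grid_cols + tc - 1) // tc
    tile_id = (r[:, None] // tr) * n_tcols + (c[None, :] // tc)
    units = np.where(core_r[:, None] & core_c[None, :], tile_id, -1)
    # renumber occurring tiles contiguously
    occurring = np.unique(units[units >= 0])
    remap = np.full(int(units.max()) + 1 if units.max() >= 0 else 1, -1, dtype=np.int64)
    remap[occurring] = np.arange(occurring.size)
    return np.where(units >= 0, remap[units.clip(0)], -1)


def region_map(config: SyntheticConfig) -> np.ndarray:
    """True climate-region id (1..4) per pixel: the four grid quadrants."""
    half_r = config.grid_rows // 2
    half_c = config.grid_cols // 2
    reg = np.empty((config.grid_rows, config.grid_cols), dtype=np.int16)
    reg[:half_r, :half_c] = 1
    reg[:half_r, half_c:] = 2
    reg[half_r:, :half_c] = 3
    reg[half_r:, half_c:] = 4
    return reg


# ---------------------------------------------------------------------------
# land-cover stack + truth ledger


def generate_landcover_stack(config: SyntheticConfig):
    """Simulate the annual land-cover stack and its truth ledger.

    Returns
    -------
    stack : (n_years, rows, cols) int8 array of {0, 1}
        1 = forest (old-growth or secondary), 0 = anthropic.
    ledger : pandas.DataFrame
        One row per management-unit event: columns ``unit``, ``year``,
        ``event`` ∈ {clear, abandon, burn}. Replaying the ledger
        (:func:`replay_ledger`) reproduces the final-year class, age and
        deforestation count of every pixel exactly.
    """
    rng = np.random.default_rng(config.seed)
    units = _unit_map(config)
    core = units >= 0
    n_units = int(units.max()) + 1

    # unit states: 0 forest (never cleared), 1 anthropic, 2 secondary
    state = np.zeros(n_units, dtype=np.int8)
    unit_forest = np.ones((config.n_years, n_units), dtype=np.int8)
    records: list[tuple[int, int, str]] = []

    for ti, year in enumerate(config.years[1:], start=1):
        # rate-independent uniform streams → common random numbers
        u_clear = rng.random(n_units)
        u_abandon = rng.random(n_units)
        u_fire = rng.random(n_units)

        forested = state != 1
        clear_p = np.where(state == 0, config.clearing_rate, config.reclearing_rate)
        cleared = forested & (u_clear < clear_p)
        abandoned = (state == 1) & (u_abandon < config.abandonment_rate)

        for u in np.flatnonzero(cleared):
            records.append((int(u), int(year), "clear"))
        for u in np.flatnonzero(abandoned):
            records.append((int(u), int(year), "abandon"))

        state[cleared] = 1
        state[abandoned] = 2

        if year >= config.fire_start_year:
            burnt = (state == 2) & (u_fire < config.fire_rate)
            for u in np.flatnonzero(burnt):
                records.append((int(u), int(year), "burn"))

        unit_forest[ti] = (state != 1).astype(np.int8)

    stack = np.where(core[None, :, :], unit_forest[:, units.clip(0)], np.int8(1))
    ledger = pd.DataFrame(records, columns=["unit", "year", "event"])
    return stack.astype(np.int8), ledger


def replay_ledger(ledger: pd.DataFrame, config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Independent per-unit replay of the event ledger.

    Derives, for the final year, the class of every pixel
    (``old_growth`` / ``secondary`` / ``anthropic``), its age, its
    deforestation count and whether it burned during the current or any
    regrowth episode — without looking at the raster stack. Used as the
    truth oracle for the history-reconstruction stage.

    Returns a dict of per-pixel arrays: ``class_name`` (object),
    ``age`` (int, -1 undefined), ``n_clearings`` (int), ``burned`` (bool),
    ``dist_class`` (object, '' where not secondary).
    """
    units = _unit_map(config)
    core = units >= 0
    n_units = int(units.max()) + 1

    cls = np.full(n_units, "old_growth", dtype=object)
    age = np.full(n_units, -1, dtype=np.int64)
    n_clear = np.zeros(n_units, dtype=np.int64)
    burned = np.zeros(n_units, dtype=bool)

    last_event_year = np.full(n_units, config.year_start, dtype=np.int64)
    last_event = np.full(n_units, "", dtype=object)
    for row in ledger.itertuples(index=False):
        if row.event == "clear":
            n_clear[row.unit] += 1
            last_event[row.unit] = "clear"
            last_event_year[row.unit] = row.year
        elif row.event == "abandon":
            last_event[row.unit] = "abandon"
            last_event_year[row.unit] = row.year
        elif row.event == "burn":
            burned[row.unit] = True

    secondary = last_event == "abandon"
    anthropic = last_event == "clear"
    cls[secondary] = "secondary"
    cls[anthropic] = "anthropic"
    # age 1 in the year of abandonment itself (first forest year)
    age[secondary] = config.year_end - last_event_year[secondary] + 1

    dist = np.full(n_units, "", dtype=object)
    rep = n_clear >= 2
    dist[secondary & rep & burned] = "repeated_burnt"
    dist[secondary & rep & ~burned] = "repeated_not_burnt"
    dist[secondary & ~rep & burned] = "single_burnt"
    dist[secondary & ~rep & ~burned] = "single_not_burnt"

    uidx = units.clip(0)
    return {
        "class_name": np.where(core, cls[uidx], "old_growth"),
        "age": np.where(core, age[uidx], -1),
        "n_clearings": np.where(core, n_clear[uidx], 0),
        "burned": np.where(core, (burned & secondary)[uidx], False),
        "dist_class": np.where(core, dist[uidx], ""),
        "unit": units,
    }


# ---------------------------------------------------------------------------
# driver surfaces


def monthly_profile(annual_precip: float, target_mcwd: float) -> np.ndarray:
    """12 monthly precipitation values with a planted annual MCWD.

    Builds a simple seasonal cycle: ``n_dry`` consecutive months below
    the 100 mm month⁻¹ evapotranspiration demand accumulate exactly
    ``target_mcwd`` of deficit, the remaining wet months share the rest
    of the annual total evenly (each ≥ 100 mm so the deficit resets).
    """
    if target_mcwd > 0:
        raise ValueError("MCWD target must be ≤ 0")
    deficit = -target_mcwd
    if deficit == 0:
        return np.full(12, annual_precip / 12.0)
    # each dry month can contribute at most 100 mm of deficit
    n_dry = max(1, math.ceil(deficit / 100.0))
    if n_dry > 11:
        raise ValueError("MCWD target deeper than 11 dry months can produce")
    dry_value = 100.0 - deficit / n_dry
    wet_total = annual_precip - n_dry * dry_value
    n_wet = 12 - n_dry
    wet_value = wet_total / n_wet
    if wet_value < 100.0:
        raise ValueError("annual precipitation too low for the requested MCWD")
    profile = np.full(12, wet_value)
    # dry season mid-year (months 6..6+n_dry)
    profile[6 : 6 + n_dry] = dry_value
    return profile


def generate_driver_surfaces(config: SyntheticConfig, ledger: pd.DataFrame | None = None):
    """Generate driver surfaces on the analysis grid.

    Returns a dict with:

    * ``sw_radiation`` — (rows, cols), W m⁻², regional mean + smooth
      within-region gradient + pixel noise
    * ``precip_monthly`` — (12, rows, cols), mm month⁻¹, a seasonal
      profile per region whose annual MCWD equals the planted value
    * ``scc`` — (rows, cols), cmol(+) kg⁻¹, smooth soil-fertility field
    * ``burned`` — (n_burn_years, rows, cols) bool masks for years ≥
      ``fire_start_year`` (all False when no ledger is given)
    * ``region`` — true region-id raster (for truth checks)

    The random stream is independent of the land-cover stream, so driver
    surfaces are reproducible for a given config regardless of whether
    the stack was generated first.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    reg = region_map(config)
    rows, cols = config.grid_rows, config.grid_cols

    yy, xx = np.mgrid[0:rows, 0:cols]
    gradient = (xx / max(cols - 1, 1) + yy / max(rows - 1, 1) - 1.0)  # in [-1, 1]

    sw = np.zeros((rows, cols))
    precip_monthly = np.zeros((12, rows, cols))
    for region, row in REGION_CLIMATE.iterrows():
        mask = reg == region
        sw[mask] = row["sw_radiation"]
        profile = monthly_profile(row["precipitation"], row["mcwd"])
        for m in range(12):
            precip_monthly[m][mask] = profile[m]
    sw = sw + 1.5 * gradient + rng.normal(0.0, 0.8, size=sw.shape)
    # small wet-month jitter; dry months left exact so the planted MCWD holds
    wet = precip_monthly >= 100.0
    jitter = rng.normal(0.0, 3.0, size=precip_monthly.shape)
    precip_monthly = np.where(wet, np.maximum(precip_monthly + jitter, 100.0), precip_monthly)

    scc = 0.3 + 0.45 * (1.0 + np.sin(3.0 * np.pi * xx / max(cols - 1, 1))) / 2.0
    scc = scc + rng.normal(0.0, 0.02, size=scc.shape)
    scc = np.clip(scc, 0.01, None)

    burn_years = config.burn_years
    burned = np.zeros((len(burn_years), rows, cols), dtype=bool)
    if ledger is not None and len(ledger):
        units = _unit_map(config)
        burns = ledger[ledger["event"] == "burn"]
        year_index = {int(y): i for i, y in enumerate(burn_years)}
        for row_ in burns.itertuples(index=False):
            bi = year_index.get(int(row_.year))
            if bi is not None:
                burned[bi][units == row_.unit] = True
        burned &= (units >= 0)[None, :, :]

    return {
        "sw_radiation": sw,
        "precip_monthly": precip_monthly,
        "scc": scc,
        "burned": burned,
        "burn_years": burn_years,
        "region": reg,
    }


# ---------------------------------------------------------------------------
# AGC / AGB map


def generate_agc_map(truth: dict[str, np.ndarray], config: SyntheticConfig) -> np.ndarray:
    """Aboveground-biomass raster (Mg ha⁻¹) from the truth ledger replay.

    Secondary pixels carry 2·(Y(age) + ε), with Y the true
    Chapman–Richards curve of the pixel's (region, disturbance class)
    and ε unit-level noise N(0, noise_sd) plus per-pixel jitter.
    Old-growth pixels carry 2·(A_region + ε); anthropic pixels carry low
    Uniform(0, background_agb_max) clutter. Values are clipped at 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    reg = region_map(config)
    units = truth["unit"]
    core = units >= 0
    n_units = int(units.max()) + 1

    agc = np.zeros(config.grid.shape, dtype=float)
    cls = truth["class_name"]
    age = truth["age"]
    dist = truth["dist_class"]

    secondary = cls == "secondary"
    for region in np.unique(reg):
        A_region = float(REGION_CLIMATE.loc[int(region), "asymptote"])
        og = (cls == "old_growth") & (reg == region)
        agc[og] = A_region
        for dcls in DISTURBANCE_CLASSES:
            sel = secondary & (reg == region) & (dist == dcls)
            if not sel.any():
                continue
            key = (int(region), dcls)
            if key not in config.true_models:
                raise KeyError(f"no true model for (region, class) = {key}")
            A, k, c = config.true_models[key]
            agc[sel] = chapman_richards(age[sel], A, k, c)

    unit_noise = rng.normal(0.0, config.noise_sd, size=n_units)
    margin_noise = rng.normal(0.0, config.noise_sd, size=agc.shape)
    pixel_noise = rng.normal(0.0, config.pixel_noise_sd, size=agc.shape)
    background = rng.uniform(0.0, config.background_agb_max, size=agc.shape)

    spatial_noise = np.where(core, unit_noise[units.clip(0)], margin_noise)
    forested = secondary | (cls == "old_growth")
    agc = np.where(forested, agc + spatial_noise + pixel_noise, 0.0)
    agc = np.clip(agc, 0.0, None)

    agb = 2.0 * agc
    agb[~forested] = background[~forested]
    return agb


# ---------------------------------------------------------------------------
# one-call scene


@dataclass
class SyntheticScene:
    """Everything one simulated landscape provides, truth included."""

    config: SyntheticConfig
    stack: np.ndarray
    ledger: pd.DataFrame
    truth: dict[str, np.ndarray]
    drivers: dict[str, np.ndarray]
    agb: np.ndarray

    @property
    def grid(self) -> Grid:
        return self.config.grid


def simulate_scene(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticScene:
    """Simulate stack, ledger, truth replay, drivers and biomass in one call."""
    if config is None:
        config = SyntheticConfig()
    if seed is not None:
        config = SyntheticConfig(**{**config.__dict__, "seed": seed})
    stack, ledger = generate_landcover_stack(config)
    truth = replay_ledger(ledger, config)
    drivers = generate_driver_surfaces(config, ledger)
    agb = generate_agc_map(truth, config)
    return SyntheticScene(config, stack, ledger, truth, drivers, agb)
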