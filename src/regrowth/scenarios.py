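"""Preservation scenarios and NDC arithmetic.

The secondary forest standing in the reference year (2017) is aged
forward year by year to a horizon (2030). A preservation scenario keeps
only stands at or above an age threshold (``all``, ``age5plus`` …
``age20plus``); preserved pixels accrue carbon along their growth
curves, non-preserved pixels are removed from the projection ledger
(their standing stock is excluded, not booked as an emission). The
headline statistic is the mean annual accumulation over the horizon,
``(stock(2030) − stock(2017)) / 13`` — the yearly series itself declines
because Chapman–Richards increments shrink with age.

NDC arithmetic converts Brazil's pledged net-emission reductions
(37% by 2025, 43% by 2030, against a 2.1 GtCO₂e yr⁻¹ 2005 baseline)
into Tg C yr⁻¹ (×1000 Tg/Gt × 12/44 C/CO₂), and expresses the projected
accumulation as a percentage of those targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accounting import MG_PER_TG, _stock_per_pixel
from .growth import ChapmanRichardsResults, chapman_richards

__all__ = [
    "SCENARIOS",
    "ScenarioProjection",
    "project",
    "ndc_target",
    "contribution_percent",
    "relative_difference_percent",
]

#: scenario label → minimum preserved age in the reference year
SCENARIOS = {"all": 0, "age5plus": 5, "age10plus": 10, "age15plus": 15, "age20plus": 20}

C_PER_CO2 = 12.0 / 44.0


@dataclass
class ScenarioProjection:
    """Projected stock and accumulation for one preservation scenario."""

    scenario: str
    preserved_area_ha: float
    years: np.ndarray
    stock_TgC: np.ndarray
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def accumulation_TgC_yr(self) -> np.ndarray:
        """Year-on-year accumulation (first horizon year onwards)."""
        return np.diff(self.stock_TgC)

    @property
    def mean_annual_accumulation(self) -> float:
        span = self.years[-1] - self.years[0]
        return float((self.stock_TgC[-1] - self.stock_TgC[0]) / span)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"year": self.years, "stock_TgC": self.stock_TgC})
        if self.ci_lower is not None:
            df["stock_ci95_lower"] = self.ci_lower
            df["stock_ci95_upper"] = self.ci_upper
        return df


def project(
    age: np.ndarray,
    model_id: np.ndarray,
    fit_list: list[ChapmanRichardsResults],
    pixel_area_ha: float,
    scenario: str = "all",
    start_year: int = 2017,
    horizon_end: int = 2030,
    ci: bool = False,
    n_draws: int = 200,
    seed: int | None = None,
) -> ScenarioProjection:
    """Age the preserved secondary forest forward under one scenario.

    ``age``/``model_id`` describe the landscape in ``start_year``; the
    CI band (optional) propagates growth-parameter uncertainty by
    evaluating the projection at parameter draws per fit.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; pick from {sorted(SCENARIOS)}")
    if horizon_end <= start_year:
        raise ValueError("horizon must extend beyond the start year")
    preserved = (model_id >= 0) & (age >= max(SCENARIOS[scenario], 1))
    model_id = np.where(preserved, model_id, -1)

    years = np.arange(start_year, horizon_end + 1)
    stock = np.empty(years.size)
    for i, _ in enumerate(years):
        dens = _stock_per_pixel(age, model_id, fit_list, age_shift=i)
        stock[i] = dens[preserved].sum() * pixel_area_ha / MG_PER_TG

    lo = hi = None
    if ci:
        rng = np.random.default_rng(seed)
        draws = np.empty((n_draws, years.size))
        ages_by_model = [age[model_id == mid] for mid in range(len(fit_list))]
        param_draws = []
        for fit in fit_list:
            if fit.boot_params is not None and len(fit.boot_params) >= n_draws:
                idx = rng.choice(len(fit.boot_params), size=n_draws, replace=False)
                param_draws.append(fit.boot_params[idx])
            else:
                d = rng.multivariate_normal([fit.k, fit.c], fit.cov, size=n_draws)
                param_draws.append(np.clip(d, 1e-8, None))
        for b in range(n_draws):
            for i, _ in enumerate(years):
                total = 0.0
                for mid, fit in enumerate(fit_list):
                    a = ages_by_model[mid]
                    if a.size == 0:
                        continue
                    kk, cc = param_draws[mid][b]
                    total += chapman_richards(a + i, fit.asymptote, kk, cc).sum()
                draws[b, i] = total * pixel_area_ha / MG_PER_TG
        lo = np.percentile(draws, 2.5, axis=0)
        hi = np.percentile(draws, 97.5, axis=0)

    return ScenarioProjection(
        scenario=scenario,
        preserved_area_ha=float(preserved.sum() * pixel_area_ha),
        years=years,
        stock_TgC=stock,
        ci_lower=lo,
        ci_upper=hi,
        meta={"start_year": start_year, "horizon_end": horizon_end},
    )


def ndc_target(
    baseline_GtCO2e: float = 2.1,
    reduction_fraction: float = 0.43,
    ndigits: int | None = 0,
) -> float:
    """Pledged net-emission level in Tg C yr⁻¹.

    ``baseline × (1 − reduction) × 1000 Tg/Gt × 12/44``; rounded to
    ``ndigits`` (None = unrounded). The 37% / 43% pledges against the
    2.1 GtCO₂e baseline give 361 and 326 Tg C yr⁻¹.
    """
    if not 0 <= reduction_fraction < 1:
        raise ValueError("reduction fraction must be in [0, 1)")
    value = baseline_GtCO2e * (1.0 - reduction_fraction) * 1000.0 * C_PER_CO2
    return round(value, ndigits) if ndigits is not None else value


def contribution_percent(accumulation_TgC_yr: float, target_TgC_yr: float) -> float:
    """Accumulation as a percentage of an emissions target."""
    if target_TgC_yr <= 0:
        raise ValueError("target must be positive")
    return 100.0 * accumulation_TgC_yr / target_TgC_yr


def relative_difference_percent(reference: float, other: float) -> float:
    """100 × (reference − other) / reference."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (reference - other) / reference
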