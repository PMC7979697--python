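"""End-to-end orchestration of the regrowth analysis.

:func:`run_synthetic_pipeline` executes every stage in dependency order
on one simulated landscape and returns all intermediate and final
products; :func:`run_pipeline` drives it from a config mapping (or YAML
file via the CLI), writes tables, fitted models, ledgers and a run
manifest (parameters, seeds, artifact checksums) to a run directory.

Stage order: simulate → history → drivers → regions → attribution →
growth fits → (importance) → accounting → scenario projection.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import accounting, attribution, drivers, history, regions, scenarios
from .growth import ChapmanRichardsModel, ChapmanRichardsResults, old_growth_asymptote
from .importance import ImportanceResult, rank_importance
from .synthetic import SyntheticConfig, SyntheticScene, simulate_scene

log = logging.getLogger("regrowth")

__all__ = ["PipelineResult", "run_synthetic_pipeline", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    scene: SyntheticScene
    history_final: history.ForestHistoryMap
    history_prev: history.ForestHistoryMap
    patches: history.PatchSet
    driver_surfaces: dict[str, np.ndarray]
    records: pd.DataFrame
    model_set: regions.RegionalModelSet
    skipped_groups: list[tuple[int, str]]
    stock_TgC: float
    potential_stock_TgC: float
    ledger: accounting.StockLedger
    projections: dict[str, scenarios.ScenarioProjection]
    importance: ImportanceResult | None = None
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def fits(self) -> dict[tuple[int, str], ChapmanRichardsResults]:
        return self.model_set.fits

    def summary(self) -> str:
        lines = [
            "Secondary-forest regrowth pipeline",
            "=" * 50,
            f"secondary patches retained       {len(self.patches):8d}",
            f"2017 carbon stock                {self.stock_TgC:12.6f} Tg C",
            f"potential (no-disturbance) stock {self.potential_stock_TgC:12.6f} Tg C",
            f"disturbance reduction            {accounting.percent_reduction(self.stock_TgC, self.potential_stock_TgC):8.1f} %",
            f"annual gains                     {self.ledger.gains_TgC:12.6f} Tg C/yr",
            f"annual losses                    {self.ledger.losses_TgC:12.6f} Tg C/yr",
            f"net sink                         {self.ledger.net_TgC:12.6f} Tg C/yr",
        ]
        for name, proj in self.projections.items():
            lines.append(
                f"scenario {name:<10} mean accumulation {proj.mean_annual_accumulation:10.6f} Tg C/yr"
            )
        return "\n".join(lines)


def _fit_regional_models(
    patches: history.PatchSet,
    records: pd.DataFrame,
    agc_raster: np.ndarray,
    hist: history.ForestHistoryMap,
    region_raster: np.ndarray,
    summaries: pd.DataFrame,
    min_ages: int = 3,
) -> tuple[regions.RegionalModelSet, list[tuple[int, str]]]:
    """Fit the 16 (region × disturbance class) growth curves.

    Groups with fewer than ``min_ages`` distinct stand ages cannot
    identify (k, c) and are skipped (their patches drop out of the
    model-based accounting).
    """
    fits: dict[tuple[int, str], ChapmanRichardsResults] = {}
    asymptotes: dict[tuple[int, str], float] = {}
    offsets: dict[tuple[int, str], float] = {}
    skipped: list[tuple[int, str]] = []
    for (region, cls), grp in records.groupby(["region_id", "dist_class"], observed=True):
        key = (int(region), str(cls))
        if grp["age"].nunique() < min_ages:
            skipped.append(key)
            continue
        table = attribution.build_age_table(grp, group=f"region{region}.{cls}")
        A = old_growth_asymptote(
            agc_raster,
            hist.old_growth,
            group_mask=region_raster == region,
            bias_offset=table.bias_offset,
        )
        model = ChapmanRichardsModel.from_age_table(table, asymptote=A)
        try:
            fits[key] = model.fit()
        except RuntimeError as exc:  # flagged non-convergent group
            log.warning("growth fit for %s did not converge: %s", key, exc)
            skipped.append(key)
            continue
        asymptotes[key] = A
        offsets[key] = table.bias_offset
    model_set = regions.RegionalModelSet(region_raster, summaries, fits, asymptotes, offsets)
    return model_set, skipped


def run_synthetic_pipeline(
    config: SyntheticConfig | None = None,
    seed: int | None = None,
    k_regions: int = 4,
    min_area_m2: float = 9000.0,
    connectivity: int = 8,
    run_importance: bool = False,
    importance_kwargs: dict | None = None,
    project_ci: bool = False,
) -> PipelineResult:
    """Run every stage on one simulated landscape."""
    timings: dict[str, float] = {}

    def tic(stage):
        timings[stage] = time.perf_counter()

    def toc(stage):
        timings[stage] = time.perf_counter() - timings[stage]
        log.info("stage %-12s %.2fs", stage, timings[stage])

    tic("simulate")
    scene = simulate_scene(config, seed=seed)
    cfg = scene.config
    toc("simulate")

    tic("history")
    hist = history.classify_history(scene.stack, grid=scene.grid)
    hist = history.flag_burned(hist, scene.drivers["burned"])
    hist_prev = history.classify_history(scene.stack[:-1], grid=scene.grid)
    # burn flags for the previous year use masks up to that year only
    burn_years = scene.drivers["burn_years"]
    prev_masks = scene.drivers["burned"][burn_years <= cfg.year_end - 1]
    if prev_masks.size:
        hist_prev = history.flag_burned(hist_prev, prev_masks)
    patches = history.label_patches(hist, min_area_m2, connectivity)
    patches_prev = history.label_patches(hist_prev, min_area_m2, connectivity)
    toc("history")

    tic("drivers")
    mcwd = drivers.compute_mcwd(scene.drivers["precip_monthly"])
    annual_precip = scene.drivers["precip_monthly"].sum(axis=0)
    driver_surfaces = {
        "sw_radiation": scene.drivers["sw_radiation"],
        "precipitation": annual_precip,
        "mcwd": mcwd,
        "scc": scene.drivers["scc"],
        "burn_count": scene.drivers["burned"].sum(axis=0).astype(float),
        "deforestation_count": np.maximum(hist.deforestation_count, 0).astype(float),
    }
    toc("drivers")

    tic("regions")
    region_raster, summaries = regions.kmeans_regions(
        driver_surfaces, mask=hist.secondary, k=k_regions, seed=cfg.seed if seed is None else seed
    )
    toc("regions")

    tic("attribution")
    agc = attribution.agb_to_agc(scene.agb)
    records = attribution.build_patch_records(
        patches, agc, driver_surfaces, region_raster=region_raster
    )
    records_prev = attribution.build_patch_records(
        patches_prev, agc, region_raster=region_raster
    )
    toc("attribution")

    tic("fit")
    model_set, skipped = _fit_regional_models(
        patches, records, agc, hist, region_raster, summaries
    )
    toc("fit")

    imp = None
    if run_importance:
        tic("importance")
        kwargs = dict(importance_kwargs or {})
        kwargs.setdefault("seed", cfg.seed if seed is None else seed)
        kwargs.setdefault("sample_n", min(2500, len(records)))
        predictors = [
            "age", "sw_radiation", "precipitation", "mcwd", "scc",
            "burn_count", "deforestation_count",
        ]
        imp = rank_importance(records, predictors=predictors, **kwargs)
        toc("importance")

    tic("accounting")
    patches.table = records  # records carry region_id for model lookup
    patches_prev.table = records_prev
    model_id, fit_list = accounting.model_id_rasters(
        patches, region_raster, model_set.fits, strict=False
    )
    model_id_prev, _ = accounting.model_id_rasters(
        patches_prev, region_raster, model_set.fits, strict=False
    )
    area_ha = scene.grid.pixel_area_ha
    stock = accounting.total_stock(hist.age, model_id, fit_list, area_ha)
    potential = accounting.potential_stock_no_disturbance(
        hist.age, model_id, region_raster, model_set.fits, area_ha, missing="skip"
    )
    ledger = accounting.annual_net_change(hist_prev, hist, model_id_prev, model_id, fit_list)
    toc("accounting")

    tic("project")
    projections = {
        name: scenarios.project(
            hist.age, model_id, fit_list, area_ha,
            scenario=name, start_year=cfg.year_end, horizon_end=cfg.year_end + 13,
            ci=project_ci, seed=cfg.seed,
        )
        for name in scenarios.SCENARIOS
    }
    toc("project")

    return PipelineResult(
        scene=scene,
        history_final=hist,
        history_prev=hist_prev,
        patches=patches,
        driver_surfaces=driver_surfaces,
        records=records,
        model_set=model_set,
        skipped_groups=skipped,
        stock_TgC=stock,
        potential_stock_TgC=potential,
        ledger=ledger,
        projections=projections,
        importance=imp,
        timings=timings,
    )


# ---------------------------------------------------------------------------
# config-driven run with artifacts


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> PipelineResult:
    """Run the pipeline from a flat config mapping and write artifacts.

    Recognised sections: ``synthetic`` (SyntheticConfig fields),
    ``history`` (min_area_m2, connectivity), ``regions`` (k),
    ``importance`` (enabled + rank_importance kwargs), ``seed``.
    Writes patch records, age-group fits, the accounting ledger,
    scenario projections and a manifest with parameters, seeds and
    artifact checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    syn = SyntheticConfig(**{**config.get("synthetic", {}), "seed": seed})
    hist_cfg = config.get("history", {})
    imp_cfg = dict(config.get("importance", {}))
    run_imp = bool(imp_cfg.pop("enabled", False))

    result = run_synthetic_pipeline(
        syn,
        k_regions=int(config.get("regions", {}).get("k", 4)),
        min_area_m2=float(hist_cfg.get("min_area_m2", 9000.0)),
        connectivity=int(hist_cfg.get("connectivity", 8)),
        run_importance=run_imp,
        importance_kwargs=imp_cfg,
    )

    artifacts: dict[str, str] = {}

    def write_df(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        artifacts[name] = _sha256(path)

    write_df(result.records, "patch_records.csv")
    write_df(result.model_set.fit_table(), "growth_fits.csv")
    write_df(result.model_set.summaries.reset_index(), "region_summaries.csv")
    write_df(regions.class_prevalence(result.records).reset_index(), "class_prevalence.csv")
    ledger = result.ledger
    write_df(
        pd.DataFrame(
            [
                {
                    "gains_TgC": ledger.gains_TgC,
                    "losses_TgC": ledger.losses_TgC,
                    "net_TgC": ledger.net_TgC,
                    "stock_start_TgC": ledger.stock_start_TgC,
                    "stock_end_TgC": ledger.stock_end_TgC,
                    "potential_stock_TgC": result.potential_stock_TgC,
                }
            ]
        ),
        "stock_ledger.csv",
    )
    proj = pd.concat(
        [p.to_frame().assign(scenario=name) for name, p in result.projections.items()]
    )
    write_df(proj, "scenario_projections.csv")
    if result.importance is not None:
        write_df(result.importance.summary().reset_index(names="variable"), "importance.csv")

    manifest = {
        "seed": seed,
        "config": {
            "synthetic": {
                k: v for k, v in syn.__dict__.items() if k != "true_models"
            },
            "history": hist_cfg,
            "regions": config.get("regions", {}),
            "importance": {"enabled": run_imp, **imp_cfg},
        },
        "skipped_groups": [list(g) for g in result.skipped_groups],
        "timings_s": {k: round(v, 3) for k, v in result.timings.items()},
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
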