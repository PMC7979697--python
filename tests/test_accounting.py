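"""Carbon-stock accounting: unit arithmetic, conservation, gridding."""

import numpy as np
import pytest

from regrowth import (
    SyntheticConfig,
    agb_to_agc,
    annual_net_change,
    classify_history,
    grid_aggregate,
    label_patches,
    model_id_rasters,
    percent_reduction,
    potential_stock_no_disturbance,
    simulate_scene,
    total_stock,
)
from regrowth.accounting import StockLedger
from regrowth.attribution import build_patch_records
from regrowth.grid import Grid
from regrowth.history import ForestHistoryMap
from regrowth.synthetic import region_map


def single_pixel_setup(results_from_params, age_val, k=0.1):
    fit = results_from_params(100.0, k, 1.0)
    age = np.array([[age_val]])
    model_id = np.array([[0]])
    return age, model_id, [fit]


def test_single_pixel_stock_arithmetic(results_from_params):
    # Y(5) of A=100, k=... chosen so Y(5)=40 → use direct closed form instead:
    fit = results_from_params(100.0, 0.1, 1.0)
    age = np.array([[5]])
    stock = total_stock(age, np.array([[0]]), [fit], pixel_area_ha=0.09)
    expected_Mg = 100 * (1 - np.exp(-0.5)) * 0.09
    assert stock == pytest.approx(expected_Mg * 1e-6)


def test_stock_is_additive(results_from_params):
    fit = results_from_params(100.0, 0.1, 1.0)
    age = np.array([[5, 5]])
    doubled = total_stock(age, np.zeros((1, 2), int), [fit], 0.09)
    single = total_stock(age[:, :1], np.zeros((1, 1), int), [fit], 0.09)
    assert doubled == pytest.approx(2 * single)
    assert total_stock(age, np.full((1, 2), -1), [fit], 0.09) == 0.0


def hist_from(series_grid):
    stack = np.asarray(series_grid).transpose(2, 0, 1).astype(np.int8)
    return classify_history(stack)


def test_annual_ledger_closed_forms(results_from_params):
    fit = results_from_params(100.0, 0.1, 1.0)
    # pixel ages 5 → 6 between the two years
    series = [[[1, 0, 1, 1, 1, 1, 1, 1]]]  # cleared year 2, regrew year 3
    hist_a = hist_from([[s[:-1] for s in row] for row in series])
    hist_b = hist_from(series)
    assert hist_a.age[0, 0] == 5 and hist_b.age[0, 0] == 6
    ledger = annual_net_change(
        hist_a, hist_b, np.array([[0]]), np.array([[0]]), [fit]
    )
    expected = 100 * (np.exp(-0.5) - np.exp(-0.6)) * 0.09
    assert ledger.gains_TgC * 1e6 == pytest.approx(expected, abs=1e-4)
    assert ledger.losses_TgC == 0.0

    # pixel of age 4 deforested
    series_d = [[[1, 0, 1, 1, 1, 1, 0]]]
    hist_a = hist_from([[s[:-1] for s in row] for row in series_d])
    hist_b = hist_from(series_d)
    ledger = annual_net_change(
        hist_a, hist_b, np.array([[0]]), np.array([[-1]]), [fit]
    )
    expected_loss = 100 * (1 - np.exp(-0.4)) * 0.09
    assert ledger.losses_TgC * 1e6 == pytest.approx(expected_loss, abs=1e-4)
    assert ledger.gains_TgC == 0.0
    assert ledger.stock_end_TgC == pytest.approx(0.0)


def test_recruitment_enters_at_year_one(results_from_params):
    fit = results_from_params(100.0, 0.1, 1.0)
    series = [[[1, 0, 0, 0, 1]]]  # regrows in the final year
    hist_a = hist_from([[s[:-1] for s in row] for row in series])
    hist_b = hist_from(series)
    ledger = annual_net_change(hist_a, hist_b, np.array([[-1]]), np.array([[0]]), [fit])
    expected = 100 * (1 - np.exp(-0.1)) * 0.09
    assert ledger.gains_TgC * 1e6 == pytest.approx(expected, abs=1e-4)
    assert ledger.stock_start_TgC == 0.0


def test_empty_landscape_gives_zero_ledger(results_from_params):
    fit = results_from_params(100.0, 0.1, 1.0)
    stack = np.ones((4, 3, 3), dtype=np.int8)
    hist = classify_history(stack)
    ledger = annual_net_change(
        hist, hist, np.full((3, 3), -1), np.full((3, 3), -1), [fit]
    )
    assert ledger.gains_TgC == ledger.losses_TgC == ledger.net_TgC == 0.0


def test_ledger_conservation_on_random_landscapes():
    """stock_end = stock_start + gains − losses on many random landscapes."""
    from regrowth.pipeline import run_synthetic_pipeline

    for seed in range(25):
        cfg = SyntheticConfig(grid_rows=42, grid_cols=42, seed=seed)
        res = run_synthetic_pipeline(cfg)
        led = res.ledger
        residual = led.stock_end_TgC - led.stock_start_TgC - led.gains_TgC + led.losses_TgC
        assert abs(residual) < 1e-6
        assert led.gains_TgC >= 0 and led.losses_TgC >= 0


def test_ledger_validates_conservation():
    with pytest.raises(ValueError):
        StockLedger(gains_TgC=1.0, losses_TgC=0.0, stock_start_TgC=0.0, stock_end_TgC=5.0)
    with pytest.raises(ValueError):
        StockLedger(gains_TgC=-1.0, losses_TgC=0.0, stock_start_TgC=0.0, stock_end_TgC=-1.0)


def test_potential_stock_dominates_actual(pipeline_result):
    res = pipeline_result
    model_id, fit_list = model_id_rasters(
        res.patches, res.model_set.region_raster, res.fits, strict=False
    )
    hist = res.history_final
    # dominance premise: no-disturbance curve above each disturbed curve
    ages = np.arange(1, 33)
    dominated = True
    for region in res.model_set.regions:
        base = res.fits[(region, "single_not_burnt")].predict(ages)
        for cls in ("single_burnt", "repeated_not_burnt", "repeated_burnt"):
            fit = res.fits.get((region, cls))
            if fit is not None and not (base >= fit.predict(ages) - 1e-9).all():
                dominated = False
    actual = total_stock(hist.age, model_id, fit_list, hist.grid.pixel_area_ha)
    potential = potential_stock_no_disturbance(
        hist.age, model_id, res.model_set.region_raster, res.fits, hist.grid.pixel_area_ha
    )
    if dominated:
        assert potential >= actual
    assert res.stock_TgC == pytest.approx(actual)


def test_counterfactual_equals_actual_without_disturbance(results_from_params):
    fit = results_from_params(100.0, 0.1, 1.0)
    age = np.array([[3, 7], [12, 20]])
    model_id = np.zeros((2, 2), int)
    region = np.ones((2, 2), int)
    fits = {(1, "single_not_burnt"): fit}
    actual = total_stock(age, model_id, [fit], 0.09)
    potential = potential_stock_no_disturbance(age, model_id, region, fits, 0.09)
    assert potential == pytest.approx(actual)


def test_printed_stock_reduction_is_8_percent():
    assert round(percent_reduction(293.7, 319.7)) == 8


# -- coarse gridding -------------------------------------------------------


def test_grid_aggregate_conserves_totals():
    rng = np.random.default_rng(6)
    grid = Grid(40, 40, pixel_size=30.0)
    vals = rng.uniform(0, 5, size=grid.shape)
    coarse = grid_aggregate(vals, grid, cell_size=300.0)
    assert coarse.shape == (4, 4)
    assert coarse.sum() == pytest.approx(vals.sum(), abs=1e-9)
    # flat-loop binning oracle
    oracle = np.zeros_like(coarse)
    for r in range(40):
        for c in range(40):
            oracle[r // 10, c // 10] += vals[r, c]
    assert np.allclose(coarse, oracle)


def test_single_coarse_cell_collects_everything():
    grid = Grid(8, 8, pixel_size=30.0)
    vals = np.ones(grid.shape)
    coarse = grid_aggregate(vals, grid, cell_size=10_000.0)
    assert coarse.shape == (1, 1)
    assert coarse[0, 0] == 64.0


def test_grid_aggregate_validation():
    grid = Grid(4, 4)
    with pytest.raises(ValueError):
        grid_aggregate(np.ones((3, 3)), grid, 100.0)
    with pytest.raises(ValueError):
        grid_aggregate(np.ones((4, 4)), grid, -1.0)
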