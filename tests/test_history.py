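"""History reconstruction against an independent per-pixel replay oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regrowth import (
    apply_exclusion_masks,
    classify_history,
    count_repeated_deforestations,
    flag_burned,
    label_patches,
    replay_ledger,
)
from regrowth.grid import Grid, NODATA
from regrowth.history import CLASS_EXCLUDED


def oracle(series):
    """Straightforward per-pixel scan: (class, age, deforestation_count)."""
    series = list(series)
    if any(v not in (0, 1) for v in series):
        return ("nodata", -1, -1)
    if all(v == 1 for v in series):
        return ("old_growth", -1, -1)
    if series[-1] == 0:
        return ("anthropic", -1, -1)
    age = 0
    for v in reversed(series):
        if v == 1:
            age += 1
        else:
            break
    clearings = sum(
        1 for a, b in zip(series[:-1], series[1:]) if a == 1 and b == 0
    )
    return ("secondary", age, max(clearings, 1))


def as_stack(series_list):
    """Stack of shape (T, n, 1) from a list of equal-length pixel series."""
    arr = np.asarray(series_list).T
    return arr[:, :, None]


@pytest.mark.parametrize(
    "series, expected",
    [
        ([1, 1, 1, 1, 1, 1, 1], ("old_growth", -1, -1)),
        ([1, 1, 0, 0, 1, 1, 1], ("secondary", 3, 1)),
        ([1, 0, 1, 0, 1, 1, 0], ("anthropic", -1, -1)),
        ([0, 1, 1, 1], ("secondary", 3, 1)),  # converted before the window
        ([1, 0, 1, 0, 1, 1], ("secondary", 2, 2)),
    ],
)
def test_classification_examples(series, expected):
    hist = classify_history(as_stack([series]))
    cls, age, count = expected
    assert hist.class_names()[0, 0] == cls
    assert hist.age[0, 0] == age
    assert hist.deforestation_count[0, 0] == count


def test_oracle_equivalence_on_random_series():
    rng = np.random.default_rng(123)
    n, T = 10_000, 33
    series = (rng.random((n, T)) < rng.uniform(0.2, 0.9, size=(n, 1))).astype(np.int8)
    hist = classify_history(as_stack(series))
    names = hist.class_names()
    for i in range(n):
        cls, age, count = oracle(series[i])
        assert names[i, 0] == cls
        assert hist.age[i, 0] == age
        assert hist.deforestation_count[i, 0] == count


def test_ledger_replay_matches_classification(default_scene):
    hist = classify_history(default_scene.stack, grid=default_scene.grid)
    truth = default_scene.truth
    assert (hist.class_names() == truth["class_name"]).all()
    sec = truth["class_name"] == "secondary"
    assert np.array_equal(hist.age[sec], truth["age"][sec])
    assert np.array_equal(hist.deforestation_count[sec], truth["n_clearings"][sec])
    burned = flag_burned(hist, default_scene.drivers["burned"])
    assert np.array_equal(burned.burned, truth["burned"])


@given(
    st.lists(st.integers(0, 1), min_size=2, max_size=40).filter(lambda s: s[-1] == 1)
)
@settings(max_examples=200, derandomize=True)
def test_appending_a_forest_year_increments_age_only(series):
    cls, age, count = oracle(series)
    cls2, age2, count2 = oracle(series + [1])
    if cls == "secondary":
        assert (cls2, age2, count2) == ("secondary", age + 1, count)
    else:
        assert cls == cls2 == "old_growth"


@given(
    st.lists(st.integers(0, 1), min_size=2, max_size=40).filter(lambda s: s[0] == 1)
)
@settings(max_examples=200, derandomize=True)
def test_old_growth_iff_no_transitions(series):
    hist = classify_history(as_stack([series]))
    transitions = count_repeated_deforestations(series) + sum(
        1 for a, b in zip(series[:-1], series[1:]) if a == 0 and b == 1
    )
    assert (hist.class_names()[0, 0] == "old_growth") == (transitions == 0)


@pytest.mark.parametrize(
    "series, expected",
    [([1, 1, 0, 1, 1], 1), ([1, 0, 1, 0, 1, 1], 2), ([1, 1, 1, 1], 0)],
)
def test_repeated_deforestation_count(series, expected):
    assert count_repeated_deforestations(series) == expected


def test_count_rejects_bad_series():
    with pytest.raises(ValueError):
        count_repeated_deforestations([1])
    with pytest.raises(ValueError):
        count_repeated_deforestations([1, 2, 0])


def test_nodata_anywhere_makes_pixel_nodata():
    hist = classify_history(as_stack([[1, NODATA, 1, 1]]))
    assert hist.class_names()[0, 0] == "nodata"


def test_stack_validation():
    with pytest.raises(ValueError):
        classify_history(np.ones((1, 4, 4), dtype=np.int8))
    with pytest.raises(ValueError):
        classify_history(np.full((3, 4, 4), 2, dtype=np.int8))


# -- exclusion masking -----------------------------------------------------


def test_empty_masks_are_identity(default_scene):
    hist = classify_history(default_scene.stack, grid=default_scene.grid)
    out = apply_exclusion_masks(hist, masks=[], buffers=[])
    assert np.array_equal(out.class_map, hist.class_map)


def test_full_mask_removes_all_secondary(default_scene):
    hist = classify_history(default_scene.stack, grid=default_scene.grid)
    out = apply_exclusion_masks(hist, masks=[np.ones(hist.class_map.shape, bool)])
    assert not out.secondary.any()
    assert (out.class_map == CLASS_EXCLUDED).any()


def test_buffer_exclusion_matches_distance_scan():
    stack = np.zeros((3, 40, 40), dtype=np.int8)
    stack[-1] = 1  # every pixel secondary (anthropic years before)
    hist = classify_history(stack)
    point, radius = (600.0, -450.0), 300.0
    out = apply_exclusion_masks(hist, buffers=[(point, radius)])
    xs, ys = hist.grid.cell_centers()
    expected = (xs - point[0]) ** 2 + (ys - point[1]) ** 2 <= radius ** 2
    assert np.array_equal(out.class_map == CLASS_EXCLUDED, expected)
    assert expected.sum() > 0


# -- patch labelling -------------------------------------------------------


def secondary_history(mask):
    """History where exactly ``mask`` pixels are secondary (age 2)."""
    mask = np.asarray(mask, dtype=bool)
    stack = np.ones((4, *mask.shape), dtype=np.int8)
    stack[1][mask] = 0  # cleared once, then regrew
    return classify_history(stack)


def test_minimum_mapping_unit_is_inclusive_at_9000_m2():
    mask = np.zeros((20, 20), bool)
    mask[2, 2:11] = True  # 9 pixels = 8100 m² → dropped
    mask[10, 5:15] = True  # 10 pixels = 9000 m² → retained
    patches = label_patches(secondary_history(mask))
    assert len(patches) == 1
    assert patches.table.loc[0, "area_m2"] == pytest.approx(9000.0)
    assert patches.table.loc[0, "n_pixels"] == 10


def test_no_secondary_gives_empty_patchset():
    hist = classify_history(np.ones((3, 8, 8), dtype=np.int8))
    patches = label_patches(hist)
    assert len(patches) == 0
    assert (patches.labels == 0).all()


def test_connectivity_option_splits_diagonal_patches():
    mask = np.zeros((30, 30), bool)
    mask[0:5, 0:2] = True          # 10 pixels
    mask[5:10, 2:4] = True         # diagonal corner contact with the first
    hist = secondary_history(mask)
    assert len(label_patches(hist, connectivity=8)) == 1
    assert len(label_patches(hist, connectivity=4)) == 2


def test_patch_tags_follow_member_pixels(default_scene):
    hist = classify_history(default_scene.stack, grid=default_scene.grid)
    hist = flag_burned(hist, default_scene.drivers["burned"])
    patches = label_patches(hist)
    assert len(patches) > 0
    for row in patches.table.itertuples(index=False):
        sel = patches.labels == row.patch_id
        assert row.burned == bool(hist.burned[sel].any())
        assert row.repeated == (row.deforestation_count >= 2)
        assert row.area_m2 >= patches.min_area_m2
    # patches are disjoint secondary pixels
    assert ((patches.labels > 0) & ~hist.secondary).sum() == 0


def test_min_area_must_be_positive(default_scene):
    hist = classify_history(default_scene.stack)
    with pytest.raises(ValueError):
        label_patches(hist, min_area_m2=0)
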