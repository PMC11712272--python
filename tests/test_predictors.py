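import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import lifescore as ls
from lifescore import landcover as lc
from lifescore.curves import CurveSpec
from lifescore.grid import aggregate_fine_to_coarse, fine_area_raster
from lifescore.pipeline import life_score_map
from lifescore.predictors import (
    endemism_map,
    habitat_loss_map,
    predictor_layers,
    regression_table,
    richness_map,
)
from lifescore.scenarios import conversion
from lifescore.species import RangeComponent, SpeciesRecord

from conftest import make_uniform_world


def _species(sid, mask, prefs=None, taxon="bird"):
    return SpeciesRecord(
        species_id=sid, taxon_group=taxon,
        components=[RangeComponent(mask)],
        preferences={"resident": frozenset(prefs or {lc.FOREST_MOIST})},
        elevation_unbounded=True,
    )


def test_richness_counts_range_overlap():
    world = make_uniform_world(n_cols=6)
    full = _species("everywhere", np.ones(world.grid.fine_shape, dtype=bool))
    r = richness_map([full], world)
    assert (r == 1).all()

    m1 = np.zeros(world.grid.fine_shape, dtype=bool); m1[0, 0] = True
    m2 = np.zeros(world.grid.fine_shape, dtype=bool); m2[0, 4] = True
    r = richness_map([_species("a", m1), _species("b", m2)], world)
    assert r[0, 0] == 1 and r[0, 4] == 1 and r.sum() == 2


def test_richness_uses_range_not_habitat():
    world = make_uniform_world(n_cols=3, natural=False)  # all arable
    full = _species("x", np.ones(world.grid.fine_shape, dtype=bool))
    assert (richness_map([full], world) == 1).all()  # zero AOH, still counted


def test_richness_matches_brute_force_on_random_world(prepared):
    world, included, _ = prepared
    r = richness_map(included, world)
    f = world.grid.fine_factor
    from lifescore.predictors import _current_range_union
    for cell in [(0, 0), (2, 3), (5, 5)]:
        count = sum(
            1 for rec in included
            if _current_range_union(rec)[
                cell[0] * f:(cell[0] + 1) * f, cell[1] * f:(cell[1] + 1) * f
            ].any()
        )
        assert r[cell] == count


def test_endemism_of_single_cell_species_is_one():
    world = make_uniform_world(n_cols=5)
    m = np.zeros(world.grid.fine_shape, dtype=bool); m[0, 2] = True
    e = endemism_map([_species("solo", m)], world)
    assert e[0, 2] == pytest.approx(1.0)
    assert e.sum() == pytest.approx(1.0)


def test_endemism_of_evenly_spread_species_is_one_over_k():
    world = make_uniform_world(n_cols=8)  # single row: equal-area cells
    full = _species("even", np.ones(world.grid.fine_shape, dtype=bool))
    e = endemism_map([full], world)
    assert e == pytest.approx(np.full(world.grid.coarse_shape, 1 / 8), rel=1e-12)


def test_endemism_matches_brute_force(prepared):
    world, included, _ = prepared
    e = endemism_map(included, world)
    f = world.grid.fine_factor
    areas = fine_area_raster(world.grid)
    from lifescore.predictors import _current_aoh_mask_and_area
    cell = (3, 2)
    shares, n = 0.0, 0
    for rec in included:
        mask, tot = _current_aoh_mask_and_area(rec, world)
        if tot <= 0:
            continue
        sub = mask[cell[0] * f:(cell[0] + 1) * f, cell[1] * f:(cell[1] + 1) * f]
        if sub.any():
            cell_area = areas[
                cell[0] * f:(cell[0] + 1) * f, cell[1] * f:(cell[1] + 1) * f
            ][sub].sum()
            shares += cell_area / tot
            n += 1
    expected = shares / n if n else 0.0
    assert e[cell] == pytest.approx(expected, rel=1e-12)


def test_habitat_loss_zero_on_untouched_world():
    world = make_uniform_world(n_cols=4)
    full = _species("u", np.ones(world.grid.fine_shape, dtype=bool))
    table = ls.aoh_table([full], world)
    hl = habitat_loss_map([full], world, table)
    assert hl == pytest.approx(np.zeros(world.grid.coarse_shape), abs=1e-15)


def test_habitat_loss_is_whole_range_loss_share(fig1):
    world, (a, b, c), _ = fig1
    table = ls.aoh_table([a], world)
    hl = habitat_loss_map([a], world, table)
    # A retains 1/3 of original AOH -> loss 2/3 wherever A has current AOH
    assert hl[0, 0] == pytest.approx(2 / 3, rel=1e-12)
    assert hl[0, 5] == 0.0  # no current AOH there


def test_species_with_gained_habitat_contributes_zero_loss():
    world = make_uniform_world(n_cols=4, natural=False)
    world.current_lc[0, 0] = lc.FOREST_MOIST
    mask = np.ones(world.grid.fine_shape, dtype=bool)
    gainer = _species("g", mask, prefs={lc.FOREST_MOIST, lc.ARABLE})
    table = ls.aoh_table([gainer], world)
    assert table["fraction_remaining"].iloc[0] == pytest.approx(1.0)
    world.current_lc[0, 1] = lc.FOREST_MOIST  # fraction now > 1? keep simple: >= 1
    hl = habitat_loss_map([gainer], world, ls.aoh_table([gainer], world))
    assert (hl == 0).all()


def test_regression_table_reproducible_and_standardized(prepared):
    world, included, table = prepared
    layers = predictor_layers(included, world, table)
    life = life_score_map(world, included, conversion(), CurveSpec())
    t1 = regression_table(life, layers, n_cells=20, n_runs=3, seed=42)
    t2 = regression_table(life, layers, n_cells=20, n_runs=3, seed=42)
    pd.testing.assert_frame_equal(t1, t2)
    assert set(t1["run_id"]) == {0, 1, 2}
    for _, run in t1.groupby("run_id"):
        for c in ["log_score", "log_richness", "log_endemism", "log_loss"]:
            assert abs(run[c].mean()) < 1e-12
            assert run[c].std(ddof=0) == pytest.approx(1.0, abs=1e-12)


def test_sign_filter_keeps_all_positive_conversion_cells(prepared):
    world, included, table = prepared
    layers = predictor_layers(included, world, table)
    life = life_score_map(world, included, conversion(), CurveSpec())
    pos = (life.values > 0) & np.isfinite(life.values)
    big = regression_table(life, layers, n_cells=10**6, n_runs=1, seed=0)
    # every sampled cell is a positive-score cell
    assert len(big) <= pos.sum()
    assert (big[["row", "col"]].apply(tuple, axis=1).map(
        lambda rc: pos[rc]
    )).all()


def test_score_magnitude_rank_correlates_with_endemism_and_loss_gradients():
    """On a world built with endemism and habitat-loss gradients, |score|
    rises with both predictor layers."""
    cfg = ls.WorldConfig(
        seed=17, endemism_gradient=True, placement_rule="gradient",
        lat_min=-0.3, lat_max=0.3, lon_min=0.0, lon_max=0.6,
        n_species={"amphibian": 15, "reptile": 15, "bird": 15, "mammal": 15},
    )
    world = ls.generate_world(cfg)
    records = ls.generate_species(cfg, world)
    included, _ = ls.filter_species(records)
    table = ls.aoh_table(included, world)
    included, _ = ls.apply_no_aoh_filter(included, table)
    layers = predictor_layers(included, world, table)
    life = life_score_map(world, included, conversion(), CurveSpec())
    valid = np.isfinite(life.values) & (np.abs(life.values) > 0)
    scores = np.abs(life.values[valid])
    rho_e, _ = spearmanr(scores, layers.endemism[valid])
    rho_l, _ = spearmanr(scores, layers.habitat_loss[valid])
    assert rho_e > 0
    assert rho_l > 0
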