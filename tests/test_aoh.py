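import numpy as np
import pandas as pd
import pytest

import lifescore as ls
from lifescore import landcover as lc
from lifescore.aoh import (
    compute_aoh,
    species_aoh,
    suitability_mask,
    summarize_aoh_distribution,
)
from lifescore.grid import GridSpec, fine_area_raster
from lifescore.species import RangeComponent, SpeciesRecord
from lifescore.worlds import RegistrationError, WorldLayers

from conftest import make_uniform_world


def build_4x4_world():
    grid = GridSpec(lat_min=0, lat_max=4 / 60, lon_min=0, lon_max=4 / 60,
                    coarse_res=4.0, fine_factor=4)
    pnv = np.full((4, 4), lc.FOREST, dtype=np.int16)
    current = np.full((4, 4), lc.FOREST_MOIST, dtype=np.int16)
    current[2:, :] = lc.ARABLE
    dem = np.zeros((4, 4))
    dem[:, 3] = 2000.0  # east column too high
    return WorldLayers(grid=grid, current_lc=current, pnv=pnv, dem=dem)


def test_hand_counted_suitable_pixels_on_4x4_world():
    """Range of 8 pixels, 3 of which match both habitat and elevation."""
    world = build_4x4_world()
    range_mask = np.zeros((4, 4), dtype=bool)
    range_mask[:2, :] = True  # 8 pixels, all forest_moist, col 3 too high
    area, mask = compute_aoh(
        range_mask, world.current_lc, world.dem, {lc.FOREST_MOIST},
        (0.0, 1000.0), world.grid, matching="mixed",
    )
    assert mask.sum() == 6
    # convert the second row: exactly 3 matching pixels remain
    world.current_lc[1, :] = lc.ARABLE
    area, mask = compute_aoh(
        range_mask, world.current_lc, world.dem, {lc.FOREST_MOIST},
        (0.0, 1000.0), world.grid, matching="mixed",
    )
    assert mask.sum() == 3
    expected = fine_area_raster(world.grid)[mask].sum()
    assert area == pytest.approx(expected, rel=1e-15)


def test_universal_preferences_and_elevation_recover_range_area():
    world = build_4x4_world()
    range_mask = np.ones((4, 4), dtype=bool)
    area, mask = compute_aoh(
        range_mask, world.current_lc, world.dem, set(lc.ALL_CODES),
        (-np.inf, np.inf), world.grid, matching="mixed",
    )
    assert mask.all()
    assert area == pytest.approx(fine_area_raster(world.grid).sum(), rel=1e-15)


def test_level2_natural_preference_matches_level1_pnv_layer():
    """A forest subtype preference still matches the coarser PNV forest class."""
    world = build_4x4_world()
    rng = np.ones((4, 4), dtype=bool)
    m = suitability_mask(rng, world.pnv, world.dem, {lc.FOREST_DRY},
                         (-np.inf, np.inf), matching="level1")
    assert m.all()
    m2 = suitability_mask(rng, world.pnv, world.dem, {lc.FOREST_DRY},
                          (-np.inf, np.inf), matching="level2")
    assert not m2.any()


def test_mixed_matching_collapses_natural_but_not_artificial_classes():
    world = build_4x4_world()
    rng = np.ones((4, 4), dtype=bool)
    # natural at level 1: forest_dry preference matches forest_moist pixels
    m = suitability_mask(rng, world.current_lc, world.dem, {lc.FOREST_DRY},
                         (-np.inf, np.inf), matching="mixed")
    assert m[:2, :].all() and not m[2:, :].any()
    # artificial at level 2: pasture preference does not match arable pixels
    m = suitability_mask(rng, world.current_lc, world.dem, {lc.PASTURE},
                         (-np.inf, np.inf), matching="mixed")
    assert not m.any()
    m = suitability_mask(rng, world.current_lc, world.dem, {lc.ARABLE},
                         (-np.inf, np.inf), matching="mixed")
    assert m[2:, :].all()


def test_elevation_bounds_inclusive_at_both_ends():
    world = build_4x4_world()
    rng = np.ones((4, 4), dtype=bool)
    m = suitability_mask(rng, world.current_lc, world.dem, {lc.FOREST_MOIST},
                         (0.0, 2000.0), matching="mixed")
    assert m[0, 3] and m[0, 0]


def test_misregistered_rasters_raise():
    world = build_4x4_world()
    with pytest.raises(RegistrationError):
        suitability_mask(
            np.ones((3, 4), dtype=bool), world.current_lc, world.dem,
            {lc.FOREST_MOIST}, (0, 1), matching="mixed",
        )


def test_fig1_species_fractions(fig1):
    world, (a, b, c), _ = fig1
    fa = species_aoh(a, world)[0]
    assert fa.fraction_remaining == pytest.approx(1 / 3, rel=1e-12)
    assert species_aoh(b, world)[0].fraction_remaining == pytest.approx(0.25)
    assert species_aoh(c, world)[0].fraction_remaining == pytest.approx(0.5)


def test_fraction_above_one_for_arable_beneficiary():
    """A species tolerant only of arable in a fully converted world."""
    world = make_uniform_world(n_cols=6, natural=False)  # all arable, PNV forest
    mask = np.ones(world.grid.fine_shape, dtype=bool)
    rec = SpeciesRecord(
        species_id="x", taxon_group="bird",
        components=[RangeComponent(mask)],
        preferences={"resident": frozenset({lc.ARABLE, lc.FOREST_MOIST})},
        elevation_unbounded=True,
    )
    s = species_aoh(rec, world)[0]
    assert s.current_km2 == pytest.approx(s.original_km2, rel=1e-12)
    # restrict natural preference away: original shrinks to zero suitability
    rec2 = SpeciesRecord(
        species_id="y", taxon_group="bird",
        components=[RangeComponent(mask)],
        preferences={"resident": frozenset({lc.ARABLE, lc.WETLAND_L2})},
        elevation_unbounded=True,
    )
    s2 = species_aoh(rec2, world)[0]
    assert s2.current_km2 > 0 and s2.original_km2 == 0
    assert np.isnan(s2.fraction_remaining)


def test_pristine_world_gives_equal_current_and_original_aoh():
    cfg = ls.WorldConfig(seed=11, placement_rule="none", urban_fraction=0.0)
    world = ls.generate_world(cfg)
    records = ls.generate_species(cfg, world)
    table = ls.aoh_table(records, world)
    ok = table.dropna(subset=["fraction_remaining"])
    assert np.allclose(ok["current_km2"], ok["original_km2"], rtol=1e-12)


def test_enlarging_preferences_never_decreases_aoh(small_world):
    _, world, records = small_world
    rng = np.random.default_rng(5)
    for rec in records[:8]:
        season = next(iter(rec.preferences))
        prefs = set(rec.preferences[season])
        mask = rec.components[0].mask
        a1, _ = compute_aoh(mask, world.current_lc, world.dem, prefs,
                            rec.elevation_bounds, world.grid, "mixed")
        extra = set(rng.choice(list(lc.NATURAL_L2 + lc.ARTIFICIAL), 2))
        a2, _ = compute_aoh(mask, world.current_lc, world.dem, prefs | extra,
                            rec.elevation_bounds, world.grid, "mixed")
        assert a2 >= a1
        lo, hi = rec.elevation_bounds
        mid = (lo + hi) / 2
        a3, _ = compute_aoh(mask, world.current_lc, world.dem, prefs,
                            (lo, mid), world.grid, "mixed")
        assert a3 <= a1


def test_level1_matching_admits_at_least_level2_pixels(small_world):
    _, world, records = small_world
    for rec in records[:8]:
        season = next(iter(rec.preferences))
        prefs = {p for p in rec.preferences[season]
                 if lc.DEFAULT_CROSSWALK[p] is lc.Role.NATURAL}
        if not prefs:
            continue
        mask = rec.components[0].mask
        a1, _ = compute_aoh(mask, world.current_lc, world.dem, prefs,
                            rec.elevation_bounds, world.grid, "level1")
        a2, _ = compute_aoh(mask, world.current_lc, world.dem, prefs,
                            rec.elevation_bounds, world.grid, "level2")
        assert a1 >= a2


def _table(rows):
    return pd.DataFrame(
        rows, columns=["species_id", "season", "current_km2", "original_km2",
                       "fraction_remaining"],
    )


def test_summary_statistics_of_fraction_distribution():
    rows = [
        ("a", "resident", 2.5, 10.0, 0.25),
        ("b", "resident", 10.0, 10.0, 1.0),
    ]
    out = summarize_aoh_distribution(_table(rows))
    assert out["geometric_mean_all"] == pytest.approx(0.5, rel=1e-12)
    assert out["proportion_above_one"] == 0.0

    rows = [
        ("a", "resident", 10.0, 10.0, 1.0),
        ("b", "breeding", 8.0, 10.0, 0.8),
        ("b", "non-breeding", 2.0, 10.0, 0.2),  # migrant: lower season counts
        ("c", "resident", 0.0, 10.0, 0.0),      # zero current: excluded from GM
        ("d", "resident", 30.0, 10.0, 3.0),
    ]
    out = summarize_aoh_distribution(_table(rows))
    assert out["n_zero_fraction"] == 1
    assert out["geometric_mean_all"] == pytest.approx(
        np.exp(np.mean(np.log([1.0, 0.2, 3.0]))), rel=1e-12
    )
    assert out["geometric_mean_lost"] == pytest.approx(0.2, rel=1e-12)
    assert out["proportion_above_one"] == pytest.approx(0.25)


def test_unchanged_world_summary_is_unity(fig1):
    world, species, _ = fig1
    pristine = WorldLayers(
        grid=world.grid,
        current_lc=np.full(world.grid.fine_shape, lc.FOREST_MOIST, np.int16),
        pnv=world.pnv, dem=world.dem,
    )
    table = ls.aoh_table(species, pristine)
    out = summarize_aoh_distribution(table)
    assert out["geometric_mean_all"] == pytest.approx(1.0, rel=1e-12)
    assert out["proportion_above_one"] == 0.0
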