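import numpy as np
import pytest

import lifescore as ls
from lifescore.curves import CurveSpec
from lifescore.grid import fine_area_raster
from lifescore.scalability import (
    RegionProfile,
    deviation_table,
    geometric_size_grid,
    region_profile_from_world,
    simulate_large_actions,
    simulate_subcell_actions,
)

Z025 = CurveSpec("power", z=0.25)
Z1 = CurveSpec("power", z=1.0)


def make_profile(n=12, cell=3.4, seed=0, frac_lo=0.2, frac_hi=0.7):
    """Profile with ample AOH so losses never clamp to zero."""
    rng = np.random.default_rng(seed)
    a_orig = rng.uniform(5e4, 5e5, n)
    frac = rng.uniform(frac_lo, frac_hi, n)
    a_now = a_orig * frac
    return RegionProfile(
        name="synthetic", region_area_km2=1e6, cell_area_km2=cell,
        species_ids=[f"s{i}" for i in range(n)],
        a_now=a_now, a_orig=a_orig,
        occupancy=rng.uniform(0.05, 0.9, n),
    )


def test_profile_occupancy_examples(fig1):
    world, (a, b, c), _ = fig1
    table = ls.aoh_table([a, b, c], world)
    region = np.ones(world.grid.fine_shape, dtype=bool)
    prof = region_profile_from_world(world, [a, b, c], region, table)
    areas = fine_area_raster(world.grid)
    region_area = areas.sum()
    # A's current AOH covers cells 0-3 of the 12-cell region
    i = prof.species_ids.index("A")
    assert prof.occupancy[i] == pytest.approx(
        areas[0, :4].sum() / region_area, rel=1e-12
    )
    # full-region synthetic species would give occupancy 1
    full = ls.SpeciesRecord(
        species_id="full", taxon_group="bird",
        components=[ls.RangeComponent(np.ones(world.grid.fine_shape, bool))],
        preferences={"resident": frozenset({10, 60})},  # forest_moist + arable
        elevation_unbounded=True,
    )
    t2 = ls.aoh_table([a, full], world)
    p2 = region_profile_from_world(world, [a, full], region, t2)
    assert p2.occupancy[p2.species_ids.index("full")] == pytest.approx(1.0)


def test_empty_region_rejected(fig1):
    world, species, _ = fig1
    with pytest.raises(ValueError):
        region_profile_from_world(
            world, species, np.zeros(world.grid.fine_shape, bool),
            ls.aoh_table(species, world),
        )


def test_single_cell_actions_have_zero_deviation():
    prof = make_profile()
    res = simulate_large_actions(prof, Z025, np.array([prof.cell_area_km2]),
                                 reps=50, seed=1)
    assert np.all(res[0].deviations == 0)


def test_linear_curve_gives_zero_deviation_at_every_size():
    """z = 1 below the cap makes marginal sums exact for both simulations."""
    prof = make_profile()
    sizes = geometric_size_grid(prof.cell_area_km2, 1e4, 6)
    for r in simulate_large_actions(prof, Z1, sizes, reps=40, seed=2):
        assert np.all(np.abs(r.deviations) < 1e-9)
    sides = np.array([0.05, 0.2, 1.0])
    for r in simulate_subcell_actions(prof, Z1, sides, reps=40, seed=3):
        assert np.all(np.abs(r.deviations) < 1e-9)


def test_full_cell_subcell_action_has_zero_deviation():
    prof = make_profile()
    res = simulate_subcell_actions(prof, Z025, np.array([1.0]), reps=50, seed=4)
    assert np.all(res[0].deviations == 0)


def test_marginal_sums_understate_true_losses_for_concave_curves():
    """Signed per-replicate deviation: approx <= true for pure-loss actions."""
    prof = make_profile()
    sizes = geometric_size_grid(10 * prof.cell_area_km2, 1e4, 4)
    for r in simulate_large_actions(prof, Z025, sizes, reps=60, seed=5):
        assert np.all(r.summed_relative <= 1e-12)


def test_mean_deviation_grows_with_action_size():
    prof = make_profile()
    sizes = geometric_size_grid(prof.cell_area_km2, 3e4, 8)
    res = simulate_large_actions(prof, Z025, sizes, reps=200, seed=6)
    means = [r.mean for r in res]
    assert np.all(np.diff(means) >= -1e-12)
    assert means[-1] > means[0]


def test_oversized_actions_skipped_with_empty_result():
    prof = make_profile()
    res = simulate_large_actions(
        prof, Z025, np.array([10 * prof.region_area_km2]), reps=5, seed=0
    )
    assert res[0].deviations.size == 0
    assert deviation_table(res, "aggregate_ratio").empty


def test_simulations_reproducible_for_identical_seeds():
    prof = make_profile()
    sizes = geometric_size_grid(prof.cell_area_km2, 1e4, 4)
    a = simulate_large_actions(prof, Z025, sizes, reps=30, seed=9)
    b = simulate_large_actions(prof, Z025, sizes, reps=30, seed=9)
    for ra, rb in zip(a, b):
        np.testing.assert_array_equal(ra.deviations, rb.deviations)
    sa = simulate_subcell_actions(prof, Z025, np.array([0.3]), reps=30, seed=9)
    sb = simulate_subcell_actions(prof, Z025, np.array([0.3]), reps=30, seed=9)
    np.testing.assert_array_equal(sa[0].deviations, sb[0].deviations)


def test_invalid_profile_and_sides_rejected():
    with pytest.raises(ValueError):
        RegionProfile("bad", 100.0, 3.4, ["s"], np.array([1.0]),
                      np.array([0.0]), np.array([0.5]))
    prof = make_profile()
    with pytest.raises(ValueError):
        simulate_subcell_actions(prof, Z025, np.array([1.5]), reps=5, seed=0)


def test_deviation_table_columns():
    prof = make_profile()
    res = simulate_large_actions(prof, Z025,
                                 np.array([prof.cell_area_km2, 500.0]),
                                 reps=20, seed=11)
    tbl = deviation_table(res, "aggregate_ratio")
    assert list(tbl.columns) == [
        "size", "mean_deviation", "se_deviation",
        "mean_summed_relative", "statistic_variant",
    ]
    assert len(tbl) == 2 and (tbl["statistic_variant"] == "aggregate_ratio").all()
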