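import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

import lifescore as ls


@pytest.fixture(scope="session")
def fig1():
    """The canonical three-species worked example (world, [A, B, C], focal cell)."""
    return ls.fig1_fixture()


@pytest.fixture(scope="session")
def small_world():
    """Seeded 24x24-fine-pixel world with 30 species, agriculture gradient."""
    cfg = ls.WorldConfig(seed=7)
    world = ls.generate_world(cfg)
    records = ls.generate_species(cfg, world)
    return cfg, world, records


@pytest.fixture(scope="session")
def prepared(small_world):
    """(world, included records, AOH table) after both filter passes."""
    _, world, records = small_world
    included, _ = ls.filter_species(records)
    table = ls.aoh_table(included, world)
    included, _ = ls.apply_no_aoh_filter(included, table)
    ids = {r.species_id for r in included}
    table = table[table["species_id"].isin(ids)].reset_index(drop=True)
    return world, included, table


def make_antisymmetric_pair():
    """A pristine world, its fully-converted twin, and per-cell species.

    Each species is confined to a single coarse cell (plus an extinct-coded
    historic component elsewhere, so remaining fractions sit below 1), which
    makes converting a cell of the pristine world and restoring the same
    cell of the converted twin exactly opposite changes for every species.
    """
    from lifescore import landcover as lc
    from lifescore.grid import GridSpec
    from lifescore.species import RangeComponent, SpeciesRecord
    from lifescore.worlds import WorldLayers

    grid = GridSpec(lat_min=0.0, lat_max=3 / 60, lon_min=0.0, lon_max=3 / 60,
                    coarse_res=1.0, fine_factor=2)
    shape = grid.fine_shape  # 6x6
    pnv = np.full(shape, lc.FOREST, dtype=np.int16)
    dem = np.zeros(shape)
    pristine = WorldLayers(
        grid=grid, pnv=pnv, dem=dem,
        current_lc=np.full(shape, lc.FOREST_MOIST, dtype=np.int16),
    )
    converted = WorldLayers(
        grid=grid, pnv=pnv, dem=dem,
        current_lc=np.full(shape, lc.ARABLE, dtype=np.int16),
    )
    species = []
    for ci in range(3):
        for cj in range(3):
            mask = np.zeros(shape, dtype=bool)
            r0, c0 = 2 * ci, 2 * cj
            pixels = [(r0, c0), (r0, c0 + 1), (r0 + 1, c0)][: 1 + (ci + cj) % 3]
            for p in pixels:
                mask[p] = True
            emask = np.zeros(shape, dtype=bool)
            er, ec = 2 * ((ci + 1) % 3), 2 * ((cj + 1) % 3)
            emask[er + 1, ec + 1] = True
            species.append(
                SpeciesRecord(
                    species_id=f"s{ci}{cj}", taxon_group="bird",
                    components=[
                        RangeComponent(mask),
                        RangeComponent(emask, presence="extinct"),
                    ],
                    preferences={"resident": frozenset({lc.FOREST_MOIST})},
                    elevation_unbounded=True,
                )
            )
    return pristine, converted, species


def make_uniform_world(n_cols=8, natural=True, fine_factor=1, n_rows=1):
    """Single-latitude-band world of equal-area cells (helper for hand counts)."""
    from lifescore import landcover as lc
    from lifescore.grid import GridSpec
    from lifescore.worlds import WorldLayers

    grid = GridSpec(
        lat_min=0.0, lat_max=n_rows / 60, lon_min=0.0, lon_max=n_cols / 60,
        coarse_res=1.0, fine_factor=fine_factor,
    )
    shape = grid.fine_shape
    pnv = np.full(shape, lc.FOREST, dtype=np.int16)
    code = lc.FOREST_MOIST if natural else lc.ARABLE
    current = np.full(shape, code, dtype=np.int16)
    dem = np.zeros(shape)
    return WorldLayers(grid=grid, current_lc=current, pnv=pnv, dem=dem)
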