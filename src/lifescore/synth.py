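"""Seeded synthetic worlds and species sets.

The generator emulates the statistical structure the scoring pipeline
assumes — a potential-natural-vegetation layer, a current land-cover layer
derived from it by a known conversion history, an elevation model, and
species with contiguous ranges, habitat preferences, elevation limits and
(optionally) seasonal migration — so every downstream stage is testable
without any external dataset. Everything is a pure function of
(configuration, seed).

Ranges are generated directly as fine-grid masks (rasterized ellipses); the
polygon reading path lives in :mod:`lifescore.rasters` and is exercised
separately. Habitat-loss-to-date is known by construction: the current
layer is the PNV layer with agriculture painted over it according to a
configurable placement rule, so each species' "original" state is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import landcover as lc
from .grid import GridSpec, fine_area_raster
from .species import RangeComponent, SpeciesRecord
from .worlds import WorldLayers

PLACEMENT_RULES = ("none", "all_arable", "gradient", "random")

#: level-1 PNV class -> representative level-2 subtypes in the current layer
_L2_SUBTYPES = {
    lc.FOREST: (lc.FOREST_MOIST, lc.FOREST_DRY),
    lc.SHRUBLAND: (lc.SHRUBLAND_L2,),
    lc.GRASSLAND: (lc.GRASSLAND_NATURAL,),
    lc.WETLAND: (lc.WETLAND_L2,),
    lc.DESERT: (lc.DESERT_L2,),
}


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic world.

    ``placement_rule`` controls where agriculture replaces natural
    vegetation and therefore the habitat-loss-to-date pattern:
    ``none`` (pristine), ``all_arable``, ``random`` (uniform probability
    ``agriculture_intensity``), or ``gradient`` (probability rising from 0
    in the west to ``agriculture_intensity`` in the east, giving a built-in
    loss gradient). ``endemism_gradient`` shrinks range sizes toward the
    north, giving a built-in endemism gradient on the other grid axis.
    """

    lat_min: float = -0.2
    lat_max: float = 0.2
    lon_min: float = 0.0
    lon_max: float = 0.4
    coarse_res: float = 4.0  # arc-minutes
    fine_factor: int = 4
    n_species: dict[str, int] = field(
        default_factory=lambda: {
            "amphibian": 8, "reptile": 7, "bird": 8, "mammal": 7
        }
    )
    range_px_min: int = 8
    range_px_max: int = 200
    fraction_migratory: float = 0.2
    habitat_breadth: int = 2
    fraction_arable_tolerant: float = 0.15
    placement_rule: str = "gradient"
    agriculture_intensity: float = 0.7
    pasture_share: float = 0.3
    urban_fraction: float = 0.02
    relief_m: float = 1500.0
    endemism_gradient: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.placement_rule not in PLACEMENT_RULES:
            raise ValueError(f"unknown placement rule {self.placement_rule!r}")
        if any(n < 0 for n in self.n_species.values()):
            raise ValueError("species counts must be non-negative")
        if self.range_px_min < 1 or self.range_px_max < self.range_px_min:
            raise ValueError("invalid range-size span")

    def grid(self) -> GridSpec:
        return GridSpec(
            lat_min=self.lat_min, lat_max=self.lat_max,
            lon_min=self.lon_min, lon_max=self.lon_max,
            coarse_res=self.coarse_res, fine_factor=self.fine_factor,
        )


def generate_world(cfg: WorldConfig) -> WorldLayers:
    """Build co-registered PNV / current land cover / DEM rasters.

    The PNV layer is assigned from elevation and latitude bands; the
    current layer carries level-2 subtypes of the PNV classes with
    agriculture (arable/pasture) and a sprinkling of urban painted over
    them per the placement rule.
    """
    grid = cfg.grid()
    rows, cols = grid.fine_shape
    if rows == 0 or cols == 0:
        raise ValueError("degenerate grid: zero cells")
    rng = np.random.default_rng([cfg.seed, 0])

    # smooth elevation surface: a few random low-frequency bumps
    rr, cc = np.meshgrid(
        np.linspace(0, 1, rows), np.linspace(0, 1, cols), indexing="ij"
    )
    dem = np.zeros((rows, cols))
    for _ in range(4):
        fy, fx = rng.uniform(0.5, 2.5, size=2)
        py, px = rng.uniform(0, 2 * np.pi, size=2)
        dem += rng.uniform(0.2, 1.0) * np.sin(2 * np.pi * fy * rr + py) * np.sin(
            2 * np.pi * fx * cc + px
        )
    dem -= dem.min()
    if dem.max() > 0:
        dem *= cfg.relief_m / dem.max()

    # PNV from elevation terciles and a latitudinal band
    q1, q2 = np.quantile(dem, [0.4, 0.8])
    pnv = np.full((rows, cols), lc.FOREST, dtype=np.int16)
    pnv[dem > q1] = lc.SHRUBLAND
    pnv[dem > q2] = lc.GRASSLAND
    wet = (dem < np.quantile(dem, 0.08))
    pnv[wet] = lc.WETLAND
    dry_band = rr > 0.85
    pnv[dry_band & (dem <= q1)] = lc.DESERT

    # current layer: level-2 subtypes of PNV
    current = np.empty_like(pnv)
    subtype_coin = rng.random((rows, cols))
    for l1, subs in _L2_SUBTYPES.items():
        sel = pnv == l1
        if len(subs) == 1:
            current[sel] = subs[0]
        else:
            current[sel] = np.where(subtype_coin[sel] < 0.5, subs[0], subs[1])

    # agriculture placement
    u = rng.random((rows, cols))
    if cfg.placement_rule == "none":
        converted = np.zeros((rows, cols), dtype=bool)
    elif cfg.placement_rule == "all_arable":
        converted = np.ones((rows, cols), dtype=bool)
    elif cfg.placement_rule == "random":
        converted = u < cfg.agriculture_intensity
    else:  # gradient: none in the west, intensity in the east
        p = cfg.agriculture_intensity * cc
        converted = u < p
    ag_coin = rng.random((rows, cols))
    current[converted] = np.where(
        ag_coin[converted] < cfg.pasture_share, lc.PASTURE, lc.ARABLE
    )
    if cfg.placement_rule == "all_arable":
        current[:] = lc.ARABLE

    urban = rng.random((rows, cols)) < cfg.urban_fraction
    current[urban] = lc.URBAN

    return WorldLayers(grid=grid, current_lc=current, pnv=pnv, dem=dem)


def _ellipse_mask(shape, center, area_px, aspect, angle, rng) -> np.ndarray:
    """Rasterize an ellipse of roughly the requested pixel area."""
    rows, cols = shape
    ry = max(0.6, np.sqrt(area_px * aspect / np.pi))
    rx = max(0.6, area_px / (np.pi * ry))
    yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dy + sa * dx
    v = -sa * dy + ca * dx
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def generate_species(
    cfg: WorldConfig, world: WorldLayers, return_bookkeeping: bool = False
):
    """Generate species with ranges, preferences and elevation limits.

    Each species receives a contiguous elliptical range, ``habitat_breadth``
    natural habitat classes sampled from those present inside the range
    (some species additionally tolerate arable land), elevation limits
    bracketing the range's terrain, and — for a ``fraction_migratory``
    subset — disjoint breeding and non-breeding ranges.

    With ``return_bookkeeping=True`` also returns the generator's own
    pixel-count record of each species-season's current and original AOH
    (computed here from the construction, used to cross-check the AOH
    engine).
    """
    rng = np.random.default_rng([cfg.seed, 1])
    grid = world.grid
    rows, cols = grid.fine_shape
    areas = fine_area_raster(grid)
    pnv_l1 = world.pnv
    cur_l1 = lc.to_level1_array(world.current_lc)
    cur_is_artificial = np.isin(world.current_lc, list(lc.ARTIFICIAL))

    records: list[SpeciesRecord] = []
    book_rows: list[dict] = []
    idx = 0
    for taxon in sorted(cfg.n_species):
        for _ in range(cfg.n_species[taxon]):
            sid = f"{taxon[:3]}_{idx:04d}"
            idx += 1
            center = (rng.uniform(0, rows - 1), rng.uniform(0, cols - 1))
            log_area = rng.uniform(
                np.log(cfg.range_px_min), np.log(cfg.range_px_max)
            )
            area_px = float(np.exp(log_area))
            if cfg.endemism_gradient:
                # smaller ranges toward the north, larger toward the south
                area_px *= 10.0 ** (-0.5 + center[0] / max(rows - 1, 1))
            aspect = rng.uniform(0.5, 2.0)
            angle = rng.uniform(0, np.pi)
            mask = _ellipse_mask((rows, cols), center, area_px, aspect, angle, rng)
            if not mask.any():
                mask[int(round(center[0])), int(round(center[1]))] = True

            # preferences: natural level-2 classes whose parents occur in-range
            present_l1 = np.unique(pnv_l1[mask])
            candidates = [
                c for c in lc.NATURAL_L2 if lc.to_level1(c) in present_l1
            ]
            if not candidates:
                candidates = [lc.FOREST_MOIST]
            k = min(cfg.habitat_breadth, len(candidates))
            prefs = set(
                rng.choice(candidates, size=k, replace=False).tolist()
            )
            if rng.random() < cfg.fraction_arable_tolerant:
                prefs.add(lc.ARABLE)
                if rng.random() < 0.5:
                    prefs.add(lc.PASTURE)

            dem_in = world.dem[mask]
            pad = 0.1 * cfg.relief_m
            elev_lo = float(dem_in.min() - pad)
            elev_hi = float(dem_in.max() + pad)

            migratory = rng.random() < cfg.fraction_migratory
            if migratory and mask.sum() >= 4:
                # split the ellipse into disjoint north/south halves
                split = int(np.clip(round(center[0]), 1, rows - 1))
                b_mask = mask.copy()
                b_mask[split:, :] = False
                n_mask = mask & ~b_mask
                if not b_mask.any() or not n_mask.any():
                    migratory = False
            if migratory:
                comps = [
                    RangeComponent(b_mask, seasonality="breeding"),
                    RangeComponent(n_mask, seasonality="non-breeding"),
                ]
                preferences = {
                    "breeding": frozenset(prefs),
                    "non-breeding": frozenset(prefs),
                }
            else:
                comps = [RangeComponent(mask, seasonality="resident")]
                preferences = {"resident": frozenset(prefs)}

            rec = SpeciesRecord(
                species_id=sid,
                taxon_group=taxon,
                components=comps,
                preferences=preferences,
                elevation_min=elev_lo,
                elevation_max=elev_hi,
            )
            records.append(rec)

            if return_bookkeeping:
                pref_l1 = sorted({lc.to_level1(p) for p in prefs})
                pref_art = sorted(
                    p for p in prefs
                    if lc.DEFAULT_CROSSWALK[p] is not lc.Role.NATURAL
                )
                elev_ok = (world.dem >= elev_lo) & (world.dem <= elev_hi)
                season_masks = (
                    {"breeding": comps[0].mask, "non-breeding": comps[1].mask}
                    if migratory
                    else {"resident": comps[0].mask}
                )
                for season, smask in season_masks.items():
                    base = smask & elev_ok
                    orig = base & np.isin(pnv_l1, pref_l1)
                    cur = base & np.where(
                        cur_is_artificial,
                        np.isin(world.current_lc, pref_art),
                        np.isin(cur_l1, pref_l1),
                    )
                    book_rows.append(
                        {
                            "species_id": sid,
                            "season": season,
                            "current_km2": float(areas[cur].sum()),
                            "original_km2": float(areas[orig].sum()),
                        }
                    )

    if return_bookkeeping:
        return records, pd.DataFrame(book_rows)
    return records


def fig1_fixture():
    """Minimal hand-built world for the canonical worked example.

    A single row of 12 equal-area 1 arc-min cells on the equator; potential
    vegetation is forest everywhere; cells 0-3 are still forest, cells 4-11
    converted to arable. Three forest species, none arable-tolerant:

    * **A** — range covers all 12 cells: original AOH 12 cells, current 4,
      so exactly one-third of its human-absent AOH remains, and converting
      the focal cell (0, 0) removes 25% of its current AOH;
    * **B** — range of 8 cells with only 2 still forested (half of A's
      remaining fraction);
    * **C** — range of 6 cells with 3 forested (a different original AOH).

    Returns ``(world, [A, B, C], focal_cell)`` with ``focal_cell=(0, 0)``.
    """
    grid = GridSpec(
        lat_min=0.0, lat_max=1 / 60, lon_min=0.0, lon_max=12 / 60,
        coarse_res=1.0, fine_factor=1,
    )
    shape = grid.fine_shape  # (1, 12)
    pnv = np.full(shape, lc.FOREST, dtype=np.int16)
    current = np.full(shape, lc.ARABLE, dtype=np.int16)
    current[0, :4] = lc.FOREST_MOIST
    dem = np.zeros(shape)

    world = WorldLayers(grid=grid, current_lc=current, pnv=pnv, dem=dem)

    def make(sid: str, cols: list[int]) -> SpeciesRecord:
        mask = np.zeros(shape, dtype=bool)
        mask[0, cols] = True
        return SpeciesRecord(
            species_id=sid,
            taxon_group="bird",
            components=[RangeComponent(mask)],
            preferences={"resident": frozenset({lc.FOREST_MOIST})},
            elevation_unbounded=True,
        )

    a = make("A", list(range(12)))
    b = make("B", [0, 1, 4, 5, 6, 7, 8, 9])
    c = make("C", [0, 1, 2, 4, 5, 6])
    return world, [a, b, c], (0, 0)
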