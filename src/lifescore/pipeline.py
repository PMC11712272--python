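"""Per-cell marginal LIFE scores.

Each coarse cell is scored under a change to that cell alone (marginality):
the scenario's pixelwise transform is applied inside the cell, every
species' AOH change is evaluated at fine resolution within its current-range
mask, translated through the persistence curve into a change in extinction
probability (geometric-mean seasonal combination for migrants), summed over
species, and divided by the area of land the scenario actually changes in
the cell. Positive scores mean more expected extinctions per km^2 changed;
cells where the scenario changes nothing are nodata (NaN).

Because the pixelwise transform of one cell leaves the rest of the world at
current land cover, a species' AOH under "change cell c only" differs from
its current AOH exactly by the suitability difference inside c — so the
whole map is assembled from one full-world transformed suitability raster
per species-season, without re-running the world per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import landcover as lc
from .aoh import species_aoh, suitability_mask
from .curves import CurveSpec, combine_seasons, persistence
from .grid import aggregate_fine_to_coarse, coarse_cell_fine_slice, fine_area_raster
from .scenarios import ScenarioSpec, changed_mask, transform_raster
from .species import (
    SpeciesRecord,
    season_preferences,
    seasons_of,
    select_range_components,
)
from .worlds import WorldLayers


@dataclass
class LifeMap:
    """Coarse raster of change in expected extinctions per km^2 changed."""

    grid: object
    scenario: str
    curve: CurveSpec
    values: np.ndarray          # float64, NaN where nothing changes
    numerator: np.ndarray       # summed delta extinction probability per cell
    changed_area: np.ndarray    # km^2 changed per cell
    taxon: str | None = None
    skipped_species: list[str] = field(default_factory=list)

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.changed_area <= 0


def _season_delta_aoh_maps(
    record: SpeciesRecord, world: WorldLayers, scen_lc: np.ndarray
) -> dict[str, np.ndarray]:
    """Coarse raster of per-cell AOH change (km^2) for each season.

    Evaluated inside the species' *current-purpose* range mask: gains are
    allowed anywhere in the current range, even outside current AOH.
    """
    areas = fine_area_raster(world.grid)
    out = {}
    for season in seasons_of(record):
        prefs = season_preferences(record, season)
        rng_mask = select_range_components(record, "current", season)
        cur = suitability_mask(
            rng_mask, world.current_lc, world.dem, prefs,
            record.elevation_bounds, matching="mixed",
        )
        scen = suitability_mask(
            rng_mask, scen_lc, world.dem, prefs,
            record.elevation_bounds, matching="mixed",
        )
        diff = (scen.astype(np.float64) - cur.astype(np.float64)) * areas
        out[season] = aggregate_fine_to_coarse(diff, world.grid.fine_factor)
    return out


def species_cell_delta_aoh(
    record: SpeciesRecord,
    world: WorldLayers,
    scenario: ScenarioSpec,
    coarse_cell: tuple[int, int],
) -> dict[str, float]:
    """Per-season AOH change (km^2) for one species from changing one cell."""
    sl = coarse_cell_fine_slice(world.grid, *coarse_cell)
    scen_lc = world.current_lc.copy()
    scen_lc[sl] = transform_raster(
        world.current_lc[sl], world.pnv[sl], scenario
    )
    maps = _season_delta_aoh_maps(record, world, scen_lc)
    r, c = coarse_cell
    return {season: float(m[r, c]) for season, m in maps.items()}


def _species_contribution(
    record: SpeciesRecord,
    world: WorldLayers,
    scen_lc: np.ndarray,
    curve: CurveSpec,
    aoh_by_season: dict[str, tuple[float, float]],
) -> np.ndarray | None:
    """Coarse raster of the species' per-cell change in extinction probability.

    Returns None (caller logs a skip) when any season's original AOH is zero,
    where the remaining fraction is undefined.
    """
    if any(orig <= 0 for (_, orig) in aoh_by_season.values()):
        return None
    delta_maps = _season_delta_aoh_maps(record, world, scen_lc)
    seasons = list(delta_maps)
    if len(seasons) == 1:
        a_now, a_orig = aoh_by_season[seasons[0]]
        d = delta_maps[seasons[0]]
        p_now = persistence(a_now / a_orig, curve)
        x_scen = np.clip(a_now + d, 0.0, None) / a_orig
        return p_now - persistence(x_scen, curve)
    # migratory: geometric-mean combination before and after
    p_now = {}
    p_scen = {}
    for s in seasons:
        a_now, a_orig = aoh_by_season[s]
        p_now[s] = persistence(a_now / a_orig, curve)
        x = np.clip(a_now + delta_maps[s], 0.0, None) / a_orig
        p_scen[s] = persistence(x, curve)
    before = combine_seasons(p_now[seasons[0]], p_now[seasons[1]])
    after = combine_seasons(p_scen[seasons[0]], p_scen[seasons[1]])
    return before - after


def _aoh_by_season(record: SpeciesRecord, world: WorldLayers):
    return {
        s.season: (s.current_km2, s.original_km2)
        for s in species_aoh(record, world)
    }


def life_score_map(
    world: WorldLayers,
    records: list[SpeciesRecord],
    scenario: ScenarioSpec,
    curve: CurveSpec = CurveSpec(),
    taxon: str | None = None,
) -> LifeMap:
    """Compute the LIFE score map for one scenario and curve.

    ``taxon`` restricts the species set to one taxonomic group (the map is
    still normalized by the full changed area, so per-taxon numerators sum
    to the combined numerator cellwise).
    """
    scen_lc = transform_raster(world.current_lc, world.pnv, scenario)
    _, changed = changed_mask(world, scenario)
    subset = [r for r in records if taxon is None or r.taxon_group == taxon]
    contribs = []
    skipped = []
    for rec in subset:
        contrib = _species_contribution(
            rec, world, scen_lc, curve, _aoh_by_season(rec, world)
        )
        if contrib is None:
            skipped.append(rec.species_id)
        else:
            contribs.append(contrib)
    if contribs:
        numerator = np.sum(np.stack(contribs), axis=0)
    else:
        numerator = np.zeros(world.grid.coarse_shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(changed > 0, numerator / changed, np.nan)
    return LifeMap(
        grid=world.grid, scenario=scenario.name, curve=curve,
        values=values, numerator=numerator, changed_area=changed,
        taxon=taxon, skipped_species=skipped,
    )


def disaggregate_by_taxon(
    world: WorldLayers,
    records: list[SpeciesRecord],
    scenario: ScenarioSpec,
    curve: CurveSpec = CurveSpec(),
) -> dict[str, LifeMap]:
    """One LifeMap per taxonomic group present in the species list."""
    taxa = sorted({r.taxon_group for r in records})
    return {
        t: life_score_map(world, records, scenario, curve, taxon=t)
        for t in taxa
    }


@dataclass
class SensitivityResult:
    """Curve-shape sensitivity of the score surface.

    ``relative_spread`` is the across-curve variance of each cell's score
    divided by the squared reference-curve score; ``max_relative_deviation``
    is ``max_c |L_curve - L_ref| / |L_ref|``. ``spread_score_correlation``
    is the Pearson correlation between the relative spread and the
    reference score over valid cells.
    """

    maps: dict[str, LifeMap]
    reference: str
    relative_spread: np.ndarray
    max_relative_deviation: np.ndarray
    spread_score_correlation: float


def curve_sensitivity(
    world: WorldLayers,
    records: list[SpeciesRecord],
    scenario: ScenarioSpec,
    curves: list[CurveSpec],
    reference: CurveSpec = CurveSpec(),
) -> SensitivityResult:
    """Score the world under each curve and quantify per-cell spread."""
    if len(curves) < 2:
        raise ValueError("curve sensitivity needs at least two curves")
    labels = [c.label for c in curves]
    if reference.label not in labels:
        raise ValueError(
            f"reference curve {reference.label} absent from curve list"
        )
    maps = {
        c.label: life_score_map(world, records, scenario, c) for c in curves
    }
    stack = np.stack([maps[l].values for l in labels])
    ref = maps[reference.label].values
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN nodata cells
        spread = np.var(stack, axis=0) / np.square(ref)
        max_dev = np.nanmax(np.abs(stack - ref), axis=0) / np.abs(ref)
    valid = np.isfinite(spread) & np.isfinite(ref)
    if valid.sum() >= 2 and np.std(spread[valid]) > 0 and np.std(ref[valid]) > 0:
        corr = float(np.corrcoef(spread[valid], ref[valid])[0, 1])
    else:
        corr = float("nan")
    return SensitivityResult(
        maps=maps,
        reference=reference.label,
        relative_spread=spread,
        max_relative_deviation=max_dev,
        spread_score_correlation=corr,
    )
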