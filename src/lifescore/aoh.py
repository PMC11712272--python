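"""Area of Habitat (AOH) computation.

A species' AOH is the part of its range whose land cover matches its habitat
preferences and whose elevation lies within its limits. Two AOHs are
computed per species-season:

* **current** — against the present-day land-cover layer, with the range
  restricted to extant / possibly-extinct polygons. Natural habitat
  preferences are matched at IUCN level 1 and artificial ones at level 2
  (the finest matching the paired layers support);
* **original** — against potential natural vegetation (mapped at level 1
  only, so matching is level 1 throughout), with extinct polygons also
  included to capture the historic range.

The ratio current/original is the fraction of human-absent AOH remaining,
the quantity the persistence curves consume. It may exceed 1 for species
whose potential distribution has grown under human land use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import landcover as lc
from .grid import fine_area_raster
from .species import (
    SpeciesRecord,
    season_preferences,
    seasons_of,
    select_range_components,
)
from .worlds import RegistrationError, WorldLayers

MATCHING_MODES = ("level1", "level2", "mixed")


@dataclass(frozen=True)
class SeasonalAOH:
    """Current and original AOH (km^2) of one species in one season."""

    species_id: str
    season: str
    current_km2: float
    original_km2: float

    @property
    def fraction_remaining(self) -> float:
        """current/original; NaN where the original AOH is zero."""
        if self.original_km2 <= 0:
            return float("nan")
        return self.current_km2 / self.original_km2


def suitability_mask(
    range_mask: np.ndarray,
    lc_raster: np.ndarray,
    dem: np.ndarray,
    preference_set,
    elev_bounds: tuple[float, float],
    matching: str = "mixed",
) -> np.ndarray:
    """Boolean mask of pixels suitable for a species.

    A pixel is suitable iff it lies in the range mask, its elevation falls
    within ``elev_bounds`` (inclusive at both ends) and its land-cover class
    matches the preference set under the requested matching level:

    * ``level2`` — exact code comparison;
    * ``level1`` — both pixel codes and preferences collapsed to their
      level-1 parents (used against the PNV layer);
    * ``mixed`` — natural classes compared at level 1, artificial classes
      at level 2 (used against the current layer).
    """
    if matching not in MATCHING_MODES:
        raise ValueError(f"matching must be one of {MATCHING_MODES}")
    if not (range_mask.shape == lc_raster.shape == dem.shape):
        raise RegistrationError(
            "range mask, land cover and DEM must share one grid: "
            f"{range_mask.shape} vs {lc_raster.shape} vs {dem.shape}"
        )
    prefs = set(preference_set)
    lc.validate_codes(prefs)

    lo, hi = elev_bounds
    ok = range_mask & (dem >= lo) & (dem <= hi)

    if matching == "level2":
        class_ok = np.isin(lc_raster, sorted(prefs))
    elif matching == "level1":
        pref_l1 = sorted({lc.to_level1(p) for p in prefs})
        class_ok = np.isin(lc.to_level1_array(lc_raster), pref_l1)
    else:  # mixed
        nat_l1 = sorted(
            {lc.to_level1(p) for p in prefs if lc.DEFAULT_CROSSWALK[p] is lc.Role.NATURAL}
        )
        art = sorted(p for p in prefs if lc.DEFAULT_CROSSWALK[p] is not lc.Role.NATURAL)
        pixel_l1 = lc.to_level1_array(lc_raster)
        pixel_is_artificial = np.isin(lc_raster, list(lc.ARTIFICIAL))
        class_ok = np.where(
            pixel_is_artificial,
            np.isin(lc_raster, art),
            np.isin(pixel_l1, nat_l1),
        )
    return ok & class_ok


def compute_aoh(
    range_mask: np.ndarray,
    lc_raster: np.ndarray,
    dem: np.ndarray,
    preference_set,
    elev_bounds: tuple[float, float],
    grid,
    matching: str = "mixed",
) -> tuple[float, np.ndarray]:
    """AOH area (km^2) and its suitability mask."""
    mask = suitability_mask(
        range_mask, lc_raster, dem, preference_set, elev_bounds, matching
    )
    area = float(fine_area_raster(grid)[mask].sum())
    return area, mask


def species_aoh(record: SpeciesRecord, world: WorldLayers) -> list[SeasonalAOH]:
    """Current and original AOH for each of a species' seasons.

    Migratory species get one entry per breeding / non-breeding season;
    all other species a single resident entry.
    """
    out = []
    for season in seasons_of(record):
        prefs = season_preferences(record, season)
        cur_range = select_range_components(record, "current", season)
        orig_range = select_range_components(record, "original", season)
        cur_area, _ = compute_aoh(
            cur_range, world.current_lc, world.dem, prefs,
            record.elevation_bounds, world.grid, matching="mixed",
        )
        orig_area, _ = compute_aoh(
            orig_range, world.pnv, world.dem, prefs,
            record.elevation_bounds, world.grid, matching="level1",
        )
        out.append(SeasonalAOH(record.species_id, season, cur_area, orig_area))
    return out


def aoh_table(records: list[SpeciesRecord], world: WorldLayers) -> pd.DataFrame:
    """Per-species-season AOH table with columns
    ``species_id, taxon_group, season, current_km2, original_km2,
    fraction_remaining``."""
    rows = []
    for rec in records:
        for s in species_aoh(rec, world):
            rows.append(
                {
                    "species_id": s.species_id,
                    "taxon_group": rec.taxon_group,
                    "season": s.season,
                    "current_km2": s.current_km2,
                    "original_km2": s.original_km2,
                    "fraction_remaining": s.fraction_remaining,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "species_id", "taxon_group", "season",
            "current_km2", "original_km2", "fraction_remaining",
        ],
    )


def summarize_aoh_distribution(table: pd.DataFrame) -> dict:
    """Summary statistics of the fraction-of-AOH-remaining distribution.

    Migratory species contribute the *lower* of their two seasonal
    fractions. Species whose original AOH is zero are dropped (fraction
    undefined); species whose current AOH is zero have fraction 0, which is
    log-undefined, so they are excluded from the geometric means but
    counted and reported. Returns geometric means over all species and
    over the subset with fraction < 1, the proportion with fraction > 1,
    and bookkeeping counts.
    """
    t = table.dropna(subset=["fraction_remaining"])
    per_species = t.groupby("species_id")["fraction_remaining"].min()
    n = len(per_species)
    zeros = int((per_species == 0).sum())
    pos = per_species[per_species > 0]
    lost = pos[pos < 1]
    return {
        "n_species": n,
        "n_zero_fraction": zeros,
        "geometric_mean_all": float(np.exp(np.log(pos).mean())) if len(pos) else float("nan"),
        "geometric_mean_lost": float(np.exp(np.log(lost).mean())) if len(lost) else float("nan"),
        "proportion_above_one": float((per_species > 1).mean()) if n else float("nan"),
    }
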