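"""Species data model and inclusion/exclusion rules.

Species enter the pipeline as :class:`SpeciesRecord` objects carrying
IUCN-style attributes: a taxon group, a "systems" label, habitat preference
sets and elevation limits per season, and one or more range components each
coded with presence / origin / seasonality. The filtering rules implemented
here decide which species and which range components contribute to Area of
Habitat, and every exclusion is logged with a machine-readable reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

TAXON_GROUPS = ("amphibian", "reptile", "bird", "mammal")

#: systems labels that exclude a species outright (non-terrestrial)
EXCLUDED_SYSTEMS = (
    "marine",
    "terrestrial + marine",
    "freshwater",
    "freshwater + marine",
)

# attribute code sets governing range-component selection
PRESENCE_CURRENT = frozenset({"extant", "possibly extinct"})
PRESENCE_ORIGINAL = frozenset({"extant", "possibly extinct", "extinct"})
ORIGIN_ALLOWED = frozenset({"native", "reintroduced", "uncertain"})
SEASONALITY_ALLOWED = frozenset({"resident", "breeding", "non-breeding", "unknown"})

SEASON_RESIDENT = "resident"
SEASON_BREEDING = "breeding"
SEASON_NONBREEDING = "non-breeding"


class ExclusionReason(str, Enum):
    MISSING_DATA = "MISSING_DATA"
    CAVE = "CAVE"
    SYSTEMS = "SYSTEMS"
    NO_AOH = "NO_AOH"


@dataclass
class RangeComponent:
    """One range polygon/mask with its IUCN attribute codes."""

    mask: np.ndarray  # boolean fine-grid mask
    presence: str = "extant"
    origin: str = "native"
    seasonality: str = "resident"


@dataclass
class SpeciesRecord:
    """One species with its ecological preferences and range components.

    ``preferences`` maps a season name to the set of suitable land-cover
    codes.  Non-migratory species use a single ``"resident"`` season.
    ``elevation_min``/``elevation_max`` are metres above sea level, inclusive
    at both ends; ``elevation_unbounded=True`` means the species has no
    mapped elevation limits (and is treated as suitable at any elevation)
    rather than missing data.
    """

    species_id: str
    taxon_group: str
    components: list[RangeComponent]
    preferences: dict[str, frozenset[int]]
    elevation_min: float | None = None
    elevation_max: float | None = None
    elevation_unbounded: bool = False
    systems: str = "terrestrial"
    cave_subterranean: bool = False

    def __post_init__(self) -> None:
        self.preferences = {k: frozenset(v) for k, v in self.preferences.items()}
        if (
            self.elevation_min is not None
            and self.elevation_max is not None
            and self.elevation_min > self.elevation_max
        ):
            raise ValueError(
                f"{self.species_id}: elevation_min exceeds elevation_max"
            )

    @property
    def elevation_bounds(self) -> tuple[float, float]:
        if self.elevation_unbounded:
            return (-np.inf, np.inf)
        return (self.elevation_min, self.elevation_max)


def is_migratory(record: SpeciesRecord) -> bool:
    """True iff the record maps distinct breeding and non-breeding seasons.

    A species qualifies when it has both breeding- and non-breeding-coded
    range components, or distinct preference sets for the two seasons. A
    species with only one mapped season (e.g. breeding-only components)
    is treated as having that single season, resident-like.
    """
    seasonalities = {c.seasonality for c in record.components}
    has_both_ranges = "breeding" in seasonalities and "non-breeding" in seasonalities
    has_both_prefs = (
        SEASON_BREEDING in record.preferences
        and SEASON_NONBREEDING in record.preferences
    )
    return has_both_ranges or has_both_prefs


def seasons_of(record: SpeciesRecord) -> list[str]:
    """Seasons a species' AOH is computed for."""
    if is_migratory(record):
        return [SEASON_BREEDING, SEASON_NONBREEDING]
    return [SEASON_RESIDENT]


def season_preferences(record: SpeciesRecord, season: str) -> frozenset[int]:
    """Preference set for a season, falling back to the resident set."""
    if season in record.preferences:
        return record.preferences[season]
    return record.preferences.get(SEASON_RESIDENT, frozenset())


def select_range_components(
    record: SpeciesRecord, purpose: str, season: str = SEASON_RESIDENT
) -> np.ndarray:
    """Union the record's range components eligible for an AOH purpose.

    ``purpose="current"`` unions components whose presence is extant /
    possibly extinct; ``purpose="original"`` additionally admits extinct
    polygons (historic range). Origin must be native / reintroduced /
    uncertain, and seasonality one of resident / breeding / non-breeding /
    unknown (never "passage" or "introduced" origins).

    For a seasonal request, resident and unknown components count toward
    both seasons; breeding components only toward the breeding season and
    non-breeding only toward non-breeding.

    Returns a boolean mask (empty selection gives an all-False mask, which
    downstream feeds the NO_AOH filter rather than raising).
    """
    if purpose not in ("current", "original"):
        raise ValueError(f"unknown purpose {purpose!r}")
    presence_ok = PRESENCE_ORIGINAL if purpose == "original" else PRESENCE_CURRENT

    if season == SEASON_RESIDENT:
        season_ok = SEASONALITY_ALLOWED
    elif season == SEASON_BREEDING:
        season_ok = frozenset({"resident", "breeding", "unknown"})
    elif season == SEASON_NONBREEDING:
        season_ok = frozenset({"resident", "non-breeding", "unknown"})
    else:
        raise ValueError(f"unknown season {season!r}")

    shape = record.components[0].mask.shape
    out = np.zeros(shape, dtype=bool)
    for comp in record.components:
        if (
            comp.presence in presence_ok
            and comp.origin in ORIGIN_ALLOWED
            and comp.seasonality in season_ok
        ):
            out |= comp.mask
    return out


def _missing_data(record: SpeciesRecord) -> bool:
    if not record.preferences or all(
        len(p) == 0 for p in record.preferences.values()
    ):
        return True
    if record.elevation_unbounded:
        return False
    return record.elevation_min is None or record.elevation_max is None


def filter_species(
    records: list[SpeciesRecord],
) -> tuple[list[SpeciesRecord], pd.DataFrame]:
    """Apply the static inclusion rules; return (included, exclusion log).

    Excludes species with missing preference or elevation data, cave /
    subterranean species, and species whose systems label marks them as
    marine or freshwater. The NO_AOH rule (no measurable AOH either
    currently or originally) needs computed AOH and is applied in a second
    pass by :func:`apply_no_aoh_filter`.

    The log has one row per excluded species with columns
    ``species_id, taxon_group, reason``.
    """
    included: list[SpeciesRecord] = []
    rows: list[dict] = []
    for rec in records:
        reason: ExclusionReason | None = None
        if rec.systems.strip().lower() in EXCLUDED_SYSTEMS:
            reason = ExclusionReason.SYSTEMS
        elif rec.cave_subterranean:
            reason = ExclusionReason.CAVE
        elif _missing_data(rec) or not rec.components:
            reason = ExclusionReason.MISSING_DATA
        if reason is None:
            included.append(rec)
        else:
            rows.append(
                {
                    "species_id": rec.species_id,
                    "taxon_group": rec.taxon_group,
                    "reason": reason.value,
                }
            )
    log = pd.DataFrame(rows, columns=["species_id", "taxon_group", "reason"])
    return included, log


def apply_no_aoh_filter(
    records: list[SpeciesRecord], aoh_table: pd.DataFrame
) -> tuple[list[SpeciesRecord], pd.DataFrame]:
    """Second-pass filter: drop species with zero AOH both now and originally.

    ``aoh_table`` is the per-species-season table from
    :func:`lifescore.aoh.aoh_table` (columns ``species_id, current_km2,
    original_km2``).
    """
    totals = aoh_table.groupby("species_id")[["current_km2", "original_km2"]].sum()
    rows = []
    included = []
    for rec in records:
        if rec.species_id in totals.index:
            cur, orig = totals.loc[rec.species_id]
            measurable = cur > 0 or orig > 0
        else:
            measurable = False
        if measurable:
            included.append(rec)
        else:
            rows.append(
                {
                    "species_id": rec.species_id,
                    "taxon_group": rec.taxon_group,
                    "reason": ExclusionReason.NO_AOH.value,
                }
            )
    log = pd.DataFrame(rows, columns=["species_id", "taxon_group", "reason"])
    return included, log
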