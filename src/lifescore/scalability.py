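"""Scalability simulations: how far per-cell map values can be trusted for
actions larger or smaller than one grid cell.

Because persistence responds non-linearly to habitat loss, the impact of a
multi-cell action is not the sum of the single-cell map values it covers,
and the impact of a sub-cell action is not the cell's per-km^2 score times
its area. Two non-spatial Monte-Carlo simulations quantify the deviation:

* **large actions** — k cells scattered across a region without
  replacement, each independently "hitting" a species with the probability
  given by the species' regional AOH occupancy; the true impact evaluates
  the persistence curve once at the total habitat lost, the approximate
  impact sums the per-cell marginal values;
* **sub-cell actions** — one cell, an action covering a fraction of it;
  the approximate impact multiplies the cell's per-km^2 score by the
  action's area.

The primary deviation statistic per replicate is
``|sum_s approx_s - sum_s true_s| / |sum_s true_s|`` (scale-free across
species counts); the literal per-species summed relative deviation
``sum_s (approx_s - true_s)/true_s`` is also emitted as a secondary column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aoh import suitability_mask
from .curves import CurveSpec, delta_extinction
from .grid import aggregate_fine_to_coarse, fine_area_raster
from .species import (
    SpeciesRecord,
    season_preferences,
    seasons_of,
    select_range_components,
)
from .worlds import WorldLayers


@dataclass
class RegionProfile:
    """Non-spatial summary of a region for the scalability simulations.

    ``occupancy[s]`` is the portion of species ``s``'s current AOH
    overlapping the region, expressed per unit region area — the probability
    that a randomly placed cell of the region contains habitat of the
    species under the homogeneous-random-distribution assumption.
    """

    name: str
    region_area_km2: float
    cell_area_km2: float
    species_ids: list[str]
    a_now: np.ndarray       # global current AOH per species, km^2
    a_orig: np.ndarray      # global original AOH per species, km^2
    occupancy: np.ndarray   # p_s in [0, 1]

    def __post_init__(self) -> None:
        self.a_now = np.asarray(self.a_now, dtype=float)
        self.a_orig = np.asarray(self.a_orig, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if np.any(self.a_orig <= 0):
            raise ValueError("original AOH must be positive for all species")
        if np.any((self.occupancy < 0) | (self.occupancy > 1)):
            raise ValueError("occupancy must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return max(1, round(self.region_area_km2 / self.cell_area_km2))


@dataclass
class DeviationResult:
    """Deviation between true and map-derived impacts at one action size."""

    size: float                      # km^2 (large) or arc-min side (sub-cell)
    deviations: np.ndarray           # primary statistic per replicate
    summed_relative: np.ndarray      # secondary (literal per-species sum)

    @property
    def mean(self) -> float:
        return float(np.mean(self.deviations))

    @property
    def se(self) -> float:
        n = len(self.deviations)
        return float(np.std(self.deviations, ddof=1) / np.sqrt(n)) if n > 1 else 0.0


def region_profile_from_world(
    world: WorldLayers,
    records: list[SpeciesRecord],
    region_mask: np.ndarray,
    aoh_table: pd.DataFrame,
    name: str = "region",
) -> RegionProfile:
    """Profile a region of the world: per-species regional occupancy plus
    global AOH states. Species with zero AOH in the region are excluded."""
    if not region_mask.any():
        raise ValueError("region mask is empty")
    areas = fine_area_raster(world.grid)
    region_area = float(areas[region_mask].sum())
    cell_area = region_area / int(region_mask.sum()) * world.grid.fine_factor**2

    totals = aoh_table.groupby("species_id")[["current_km2", "original_km2"]].sum()
    ids, a_now, a_orig, occ = [], [], [], []
    for rec in records:
        in_region = 0.0
        for season in seasons_of(rec):
            prefs = season_preferences(rec, season)
            rng_mask = select_range_components(rec, "current", season)
            suit = suitability_mask(
                rng_mask, world.current_lc, world.dem, prefs,
                rec.elevation_bounds, matching="mixed",
            )
            in_region = max(in_region, float(areas[suit & region_mask].sum()))
        if in_region <= 0:
            continue
        cur, orig = totals.loc[rec.species_id]
        if orig <= 0:
            continue
        ids.append(rec.species_id)
        a_now.append(cur)
        a_orig.append(orig)
        occ.append(min(1.0, in_region / region_area))
    return RegionProfile(
        name=name, region_area_km2=region_area, cell_area_km2=cell_area,
        species_ids=ids, a_now=np.array(a_now), a_orig=np.array(a_orig),
        occupancy=np.array(occ),
    )


def _deviation_stats(approx: np.ndarray, true: np.ndarray) -> tuple[float, float]:
    total_true = true.sum()
    primary = (
        abs(approx.sum() - total_true) / abs(total_true)
        if total_true != 0 else 0.0
    )
    nz = true != 0
    secondary = float(((approx[nz] - true[nz]) / true[nz]).sum())
    return float(primary), secondary


def geometric_size_grid(
    lo: float, hi: float, n: int = 10
) -> np.ndarray:
    """Geometrically spaced action sizes from ``lo`` to ``hi``."""
    return np.geomspace(lo, hi, n)


def simulate_large_actions(
    profile: RegionProfile,
    curve: CurveSpec,
    sizes: np.ndarray,
    reps: int = 100,
    seed: int = 0,
) -> list[DeviationResult]:
    """Deviation of summed per-cell values from the true impact of losing
    ``size`` km^2 of habitat scattered across the region.

    Per replicate, ``k = round(size / cell_area)`` cells are scattered
    without replacement; each independently hits species ``s`` with
    probability ``p_s``. The true per-species impact evaluates the curve
    once at the total loss ``hits_s * cell_area``; the approximate impact is
    ``hits_s`` times the single-cell marginal impact evaluated at the
    unperturbed current AOH. Sizes needing more cells than the region holds
    are skipped with a warning entry (empty result).
    """
    rng = np.random.default_rng(seed)
    out = []
    cell = profile.cell_area_km2
    p = profile.occupancy
    a_now, a_orig = profile.a_now, profile.a_orig
    marginal = np.array(
        [
            delta_extinction(o, n, max(n - cell, 0.0), curve)
            for n, o in zip(a_now, a_orig)
        ]
    )
    for size in sizes:
        k = max(1, round(size / cell))
        if k > profile.n_cells:
            out.append(DeviationResult(float(size), np.array([]), np.array([])))
            continue
        prim = np.empty(reps)
        sec = np.empty(reps)
        for r in range(reps):
            hits = rng.binomial(k, p)
            loss = np.minimum(hits * cell, a_now)
            true = np.array(
                [
                    delta_extinction(o, n, n - l, curve)
                    for n, o, l in zip(a_now, a_orig, loss)
                ]
            )
            approx = hits * marginal
            prim[r], sec[r] = _deviation_stats(approx, true)
        out.append(DeviationResult(float(size), prim, sec))
    return out


def simulate_subcell_actions(
    profile: RegionProfile,
    curve: CurveSpec,
    sides_arcmin: np.ndarray,
    coarse_res: float = 1.0,
    reps: int = 100,
    seed: int = 0,
) -> list[DeviationResult]:
    """Deviation for actions smaller than one cell.

    Per replicate, one cell is drawn; each species is present with
    probability ``p_s`` (fixed for the whole action). The action covers
    ``(side/coarse_res)^2`` of the cell. The true impact removes exactly
    that area from each present species' AOH; the approximate impact
    multiplies the cell's per-km^2 score (full-cell change divided by cell
    area) by the action area.
    """
    rng = np.random.default_rng(seed)
    cell = profile.cell_area_km2
    p = profile.occupancy
    a_now, a_orig = profile.a_now, profile.a_orig
    full_cell = np.array(
        [
            delta_extinction(o, n, max(n - cell, 0.0), curve)
            for n, o in zip(a_now, a_orig)
        ]
    )
    out = []
    for side in sides_arcmin:
        if not 0 < side <= coarse_res:
            raise ValueError("action side must lie in (0, coarse_res]")
        action_area = (side / coarse_res) ** 2 * cell
        prim = np.empty(reps)
        sec = np.empty(reps)
        for r in range(reps):
            present = rng.random(len(p)) < p
            loss = np.where(present, np.minimum(action_area, a_now), 0.0)
            true = np.array(
                [
                    delta_extinction(o, n, n - l, curve)
                    for n, o, l in zip(a_now, a_orig, loss)
                ]
            )
            approx = present * full_cell / cell * action_area
            prim[r], sec[r] = _deviation_stats(approx, true)
        out.append(DeviationResult(float(side), prim, sec))
    return out


def deviation_table(results: list[DeviationResult], variant: str) -> pd.DataFrame:
    """CSV-ready summary: one row per action size."""
    rows = []
    for res in results:
        if res.deviations.size == 0:
            continue
        rows.append(
            {
                "size": res.size,
                "mean_deviation": res.mean,
                "se_deviation": res.se,
                "mean_summed_relative": float(np.mean(res.summed_relative)),
                "statistic_variant": variant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "size", "mean_deviation", "se_deviation",
            "mean_summed_relative", "statistic_variant",
        ],
    )
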