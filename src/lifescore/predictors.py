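"""Spatial predictor layers and regression-table preparation.

Three coarse layers summarize why a cell scores as it does:

* **richness** — number of species whose current range overlaps the cell;
* **endemism** — mean, over species with current AOH in the cell, of the
  share of their global current AOH the cell holds;
* **habitat loss to date** — mean, over species with current AOH in the
  cell, of the proportion of their original AOH no longer suitable
  (clamped to [0, 1]: species that gained habitat contribute 0).

:func:`regression_table` prepares model-ready samples relating log scores to
the log predictors; fitting (e.g. a GAM with a spatial smoother) is left to
external statistical tooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aoh import suitability_mask
from .grid import aggregate_fine_to_coarse, fine_area_raster
from .pipeline import LifeMap
from .scenarios import CONVERSION
from .species import (
    SpeciesRecord,
    season_preferences,
    seasons_of,
    select_range_components,
)
from .worlds import WorldLayers


@dataclass
class PredictorLayers:
    richness: np.ndarray      # integer counts
    endemism: np.ndarray      # in [0, 1]
    habitat_loss: np.ndarray  # in [0, 1]


def _current_range_union(record: SpeciesRecord) -> np.ndarray:
    masks = [
        select_range_components(record, "current", s) for s in seasons_of(record)
    ]
    out = masks[0]
    for m in masks[1:]:
        out = out | m
    return out


def _current_aoh_mask_and_area(record: SpeciesRecord, world: WorldLayers):
    """Union over seasons of the current suitability mask, plus global area."""
    areas = fine_area_raster(world.grid)
    union = np.zeros(world.grid.fine_shape, dtype=bool)
    for season in seasons_of(record):
        prefs = season_preferences(record, season)
        rng_mask = select_range_components(record, "current", season)
        union |= suitability_mask(
            rng_mask, world.current_lc, world.dem, prefs,
            record.elevation_bounds, matching="mixed",
        )
    return union, float(areas[union].sum())


def richness_map(records: list[SpeciesRecord], world: WorldLayers) -> np.ndarray:
    """Species count per coarse cell, by current-range overlap (range, not AOH)."""
    f = world.grid.fine_factor
    counts = np.zeros(world.grid.coarse_shape, dtype=np.int64)
    for rec in records:
        rng = _current_range_union(rec)
        counts += aggregate_fine_to_coarse(rng.astype(np.int64), f) > 0
    return counts


def endemism_map(records: list[SpeciesRecord], world: WorldLayers) -> np.ndarray:
    """Mean per-species share of global current AOH held by each cell."""
    f = world.grid.fine_factor
    areas = fine_area_raster(world.grid)
    total_share = np.zeros(world.grid.coarse_shape)
    n_present = np.zeros(world.grid.coarse_shape, dtype=np.int64)
    for rec in records:
        mask, global_area = _current_aoh_mask_and_area(rec, world)
        if global_area <= 0:
            continue
        cell_area = aggregate_fine_to_coarse(np.where(mask, areas, 0.0), f)
        present = cell_area > 0
        total_share[present] += cell_area[present] / global_area
        n_present += present
    with np.errstate(invalid="ignore"):
        out = np.where(n_present > 0, total_share / n_present, 0.0)
    return out


def habitat_loss_map(
    records: list[SpeciesRecord], world: WorldLayers, aoh_table: pd.DataFrame
) -> np.ndarray:
    """Mean per-species proportion of original AOH lost, per cell.

    "Species present" means species whose current AOH intersects the cell;
    each contributes ``clamp(1 - fraction_remaining, 0, 1)`` — its whole-
    range loss to date, not the loss within the cell.
    """
    f = world.grid.fine_factor
    fractions = (
        aoh_table.dropna(subset=["fraction_remaining"])
        .groupby("species_id")["fraction_remaining"].min()
    )
    total = np.zeros(world.grid.coarse_shape)
    n_present = np.zeros(world.grid.coarse_shape, dtype=np.int64)
    for rec in records:
        if rec.species_id not in fractions.index:
            continue
        loss = float(np.clip(1.0 - fractions[rec.species_id], 0.0, 1.0))
        mask, global_area = _current_aoh_mask_and_area(rec, world)
        if global_area <= 0:
            continue
        present = aggregate_fine_to_coarse(mask.astype(np.int64), f) > 0
        total[present] += loss
        n_present += present
    with np.errstate(invalid="ignore"):
        return np.where(n_present > 0, total / n_present, 0.0)


def predictor_layers(
    records: list[SpeciesRecord], world: WorldLayers, aoh_table: pd.DataFrame
) -> PredictorLayers:
    return PredictorLayers(
        richness=richness_map(records, world),
        endemism=endemism_map(records, world),
        habitat_loss=habitat_loss_map(records, world, aoh_table),
    )


def regression_table(
    life_map: LifeMap,
    predictors: PredictorLayers,
    n_cells: int,
    n_runs: int,
    seed: int,
) -> pd.DataFrame:
    """Sampled, standardized tables relating log10 score to log10 predictors.

    Keeps only scores with the scenario's predominant sign (positive for
    conversion; the absolute value of negative scores for reversion),
    log10-transforms the response and the three predictors, drops cells
    where any transform is non-finite, then for each of ``n_runs`` runs
    samples ``n_cells`` cells without replacement and standardizes each
    run's columns to zero mean and unit variance. Cell coordinates are kept
    for downstream spatial smoothing. Columns: ``run_id, row, col, lat,
    lon, log_score, log_richness, log_endemism, log_loss``.
    """
    values = life_map.values
    if life_map.scenario == CONVERSION:
        keep = values > 0
        response = values
    else:
        keep = values < 0
        response = -values
    keep = keep & np.isfinite(values)

    rows, cols = np.nonzero(keep)
    with np.errstate(divide="ignore", invalid="ignore"):
        data = pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "lat": np.asarray(life_map.grid.coarse_lat_center(rows), dtype=float),
                "lon": np.asarray(life_map.grid.coarse_lon_center(cols), dtype=float),
                "log_score": np.log10(response[rows, cols]),
                "log_richness": np.log10(
                    predictors.richness[rows, cols].astype(float)
                ),
                "log_endemism": np.log10(predictors.endemism[rows, cols]),
                "log_loss": np.log10(predictors.habitat_loss[rows, cols]),
            }
        )
    log_cols = ["log_score", "log_richness", "log_endemism", "log_loss"]
    data = data[np.isfinite(data[log_cols]).all(axis=1)].reset_index(drop=True)

    rng = np.random.default_rng(seed)
    n_avail = len(data)
    take = min(n_cells, n_avail)
    out = []
    for run in range(n_runs):
        idx = rng.choice(n_avail, size=take, replace=False)
        sample = data.iloc[idx].copy()
        for c in log_cols:
            sd = sample[c].std(ddof=0)
            sample[c] = (sample[c] - sample[c].mean()) / (sd if sd > 0 else 1.0)
        sample.insert(0, "run_id", run)
        out.append(sample)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["run_id", "row", "col", "lat", "lon", *log_cols]
    )
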