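"""Independent, naive recomputation of AOH and cell scores.

Everything here is written from the definitions with explicit per-pixel
loops and its own level-1 crosswalk, spherical-area formula and persistence
evaluation, deliberately sharing no raster code with the package's scoring
path. Only the range-component attribute selection is reused (it is tested
separately on constructed records).
"""

import math

import numpy as np

from lifescore.species import seasons_of, season_preferences, select_range_components

LEVEL1 = {10: 1, 11: 1, 20: 2, 30: 3, 40: 4, 50: 5,
          1: 1, 2: 2, 3: 3, 4: 4, 5: 5, 60: 60, 61: 61, 62: 62}
ARTIFICIAL = {60, 61, 62}
ARABLE, PASTURE, URBAN = 60, 61, 62


def row_area_km2(grid, row):
    d = grid.coarse_res / 60.0 / grid.fine_factor
    s = 2.0 * math.pi * grid.earth_radius * d / 360.0
    lat = grid.lat_max - (row + 0.5) * d
    return s * s * math.cos(math.radians(lat))


def pixel_suitable(code, prefs, matching):
    code = int(code)
    if matching == "level2":
        return code in prefs
    if matching == "level1":
        return LEVEL1[code] in {LEVEL1[p] for p in prefs}
    if code in ARTIFICIAL:
        return code in {p for p in prefs if p in ARTIFICIAL}
    return LEVEL1[code] in {LEVEL1[p] for p in prefs if p not in ARTIFICIAL}


def naive_aoh(grid, range_mask, lc_raster, dem, prefs, bounds, matching):
    lo, hi = bounds
    total = 0.0
    rows, cols = lc_raster.shape
    for i in range(rows):
        a = row_area_km2(grid, i)
        for j in range(cols):
            if not range_mask[i, j]:
                continue
            if not (lo <= dem[i, j] <= hi):
                continue
            if pixel_suitable(lc_raster[i, j], prefs, matching):
                total += a
    return total


def naive_transform(cur, pnv, scenario):
    cur, pnv = int(cur), int(pnv)
    if scenario == "conversion_to_arable":
        return cur if cur == URBAN else ARABLE
    if cur in (ARABLE, PASTURE):
        return pnv
    return cur


def power_persistence(x, z):
    return min(1.0, x ** z)


def naive_cell_score(world, records, scenario_name, coarse_cell, z=0.25):
    """Score one coarse cell by brute force: build the modified land-cover
    raster for that cell alone and recompute every species' AOH from scratch."""
    grid = world.grid
    f = grid.fine_factor
    r0, c0 = coarse_cell[0] * f, coarse_cell[1] * f

    mod = world.current_lc.copy()
    changed_area = 0.0
    for i in range(r0, r0 + f):
        for j in range(c0, c0 + f):
            new = naive_transform(mod[i, j], world.pnv[i, j], scenario_name)
            if new != int(mod[i, j]):
                changed_area += row_area_km2(grid, i)
            mod[i, j] = new
    if changed_area == 0.0:
        return float("nan")

    total = 0.0
    for rec in records:
        # undefined remaining fraction in any season skips the species
        states = []
        for season in seasons_of(rec):
            prefs = set(season_preferences(rec, season))
            cur_rng = select_range_components(rec, "current", season)
            orig_rng = select_range_components(rec, "original", season)
            a_orig = naive_aoh(grid, orig_rng, world.pnv, world.dem, prefs,
                               rec.elevation_bounds, "level1")
            if a_orig <= 0:
                states = None
                break
            a_now = naive_aoh(grid, cur_rng, world.current_lc, world.dem,
                              prefs, rec.elevation_bounds, "mixed")
            a_scen = naive_aoh(grid, cur_rng, mod, world.dem, prefs,
                               rec.elevation_bounds, "mixed")
            states.append((a_now, a_orig, a_scen))
        if states is None:
            continue
        if len(states) == 1:
            a_now, a_orig, a_scen = states[0]
            de = power_persistence(a_now / a_orig, z) - power_persistence(
                a_scen / a_orig, z
            )
        else:
            p_before = [power_persistence(n / o, z) for n, o, _ in states]
            p_after = [power_persistence(s / o, z) for _, o, s in states]
            de = math.sqrt(p_before[0] * p_before[1]) - math.sqrt(
                p_after[0] * p_after[1]
            )
        total += de
    return total / changed_area
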