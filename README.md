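# lifescore

**Map the marginal impact of land-cover change on expected species
extinctions.**

`lifescore` implements a per-grid-cell extinction-risk metric for
conservation macroecology: given species ranges, habitat and elevation
preferences, and paired rasters of current land cover and potential natural
vegetation (PNV), it scores every coarse grid cell with the change in the
expected number of species extinctions per km² of land converted to
agriculture or restored to natural habitat. It is aimed at researchers and
analysts who want to prototype, stress-test or extend persistence-score
pipelines without the multi-terabyte global datasets: a seeded synthetic
world generator stands in for the real inputs, and every stage — Area of
Habitat (AOH) computation, scenario transforms, scoring, predictor layers,
curve-shape sensitivity and scalability simulations — is exercisable and
tested end to end on it.

## The model

For species *s*, let `A_orig` be its AOH under potential natural vegetation
(its habitat in the absence of people) and `A_now` its AOH under current
land cover. Its probability of persisting over the assessment horizon is a
non-decreasing function of the remaining fraction `x = A_now / A_orig`,
capped at 1:

```
P(x) = min(1, x^z)          (power law, default z = 0.25)
P(x) = min(1, g(x)),  g(x) = exp(-a e^{-bx}) / exp(-a e^{-b})   (modified Gompertz)
```

A land-cover change in one coarse cell *i* moves each species from `A_now`
to `A_scen = A_now + ΔAOH_s(i)`, evaluated at fine resolution inside the
species' current range (so a cropland-tolerant species can gain habitat in
parts of its range it does not currently occupy). The change in its
extinction probability is `P(A_now/A_orig) − P(A_scen/A_orig)`; migratory
species combine breeding and non-breeding seasons by the geometric mean of
the two seasonal persistence probabilities. Because summed persistence
changes over independent species equal the change in the expected number of
extinctions, the cell's score is

```
L(i) = Σ_s ΔE_s(i) / (area changed in cell i, km²)
```

positive where change increases expected extinctions, negative where it
decreases them, and nodata (NaN) where the scenario changes nothing. Two
archetypal scenarios are built in: conversion of all non-urban land to
arable, and reversion of arable and pasture to their PNV class.

## Worked example

The canonical three-species worked example is built in. Species A retains
one-third of its human-absent AOH, and the focal cell holds 25% of its
current AOH:

```python
>>> import lifescore as ls
>>> world, species, cell = ls.fig1_fixture()
>>> a = ls.species_aoh(species[0], world)[0]
>>> a.fraction_remaining
0.3333333333333333
>>> d = ls.species_cell_delta_aoh(species[0], world, ls.conversion(), cell)
>>> ls.delta_extinction(a.original_km2, a.current_km2,
...                     a.current_km2 + d["resident"], ls.CurveSpec())
0.05272890446504497
>>> ls.life_score_map(world, species, ls.conversion()).values[cell]
0.07155037283290777
```

Converting the focal cell drops species A from 1/3 to 1/4 of its original
AOH, raising its extinction probability by `(1/3)^0.25 − (1/4)^0.25 ≈
0.0527`. Adding the other two species' changes and dividing by the ~3.4 km²
cell gives ≈ 0.0716 expected extinctions per km² converted.

The same pipeline runs from the shell:

```sh
life synth --seed 7 -o run/          # synthetic world + species
life aoh   -i run/ -o run/aoh        # AOH tables, exclusions, summary
life score -i run/ -o run/score --scenario conversion
life sensitivity -i run/ -o run/sens # one map per persistence curve
life scalability -i run/ -o run/scal # action-size deviation tables
```

Each command writes a `manifest.json` with the config hash, seed and
sha256 checksums of every output, so reruns are verifiably byte-identical.

## Layout

| module | contents |
| --- | --- |
| `lifescore.grid` | georeferencing, latitude-dependent pixel areas, fine→coarse aggregation |
| `lifescore.landcover` | class vocabulary, level-1/level-2 crosswalk, roles |
| `lifescore.synth` | seeded synthetic worlds, species generator, worked-example fixture |
| `lifescore.species` | species records, inclusion/exclusion rules, range-component selection |
| `lifescore.aoh` | current/original AOH per species-season, summary statistics |
| `lifescore.curves` | persistence curves, extinction deltas, seasonal combination |
| `lifescore.scenarios` | conversion/reversion transforms, changed-area maps |
| `lifescore.pipeline` | per-cell scoring, taxon disaggregation, curve sensitivity |
| `lifescore.predictors` | richness/endemism/habitat-loss layers, regression tables |
| `lifescore.scalability` | large-action and sub-cell deviation simulations |
| `lifescore.rasters`, `lifescore.config`, `lifescore.cli` | I/O, run config, CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical choices.
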