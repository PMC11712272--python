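"""Raster and table I/O.

Rasters are stored as TIFF arrays (via :mod:`tifffile`) with the grid
georeferencing, CRS and nodata convention embedded as JSON in the TIFF
ImageDescription tag, so a write/read round trip reproduces integer layers
bit-exactly and float layers to full float64 precision. All grids are
geographic (EPSG:4326).

Species sets are stored as a directory of plain-text tables plus one mask
stack: ``species.csv`` (one row per species-season), ``components.csv``
(one row per range component) and ``components.tif`` (one boolean page per
component). Real-mode range polygons are accepted as GeoJSON and rasterized
onto the grid by point-in-polygon tests at pixel centers.

Nodata convention: NaN in float rasters; 0 is a legal score and never used
as nodata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import landcover as lc
from .grid import GridSpec
from .pipeline import LifeMap
from .species import RangeComponent, SpeciesRecord
from .worlds import RegistrationError, WorldLayers

CRS = "EPSG:4326"


def write_raster(
    path, array: np.ndarray, grid: GridSpec, meta: dict | None = None
) -> None:
    """Write one raster band with embedded georeferencing."""
    desc = {"crs": CRS, "grid": grid.to_dict(), "meta": meta or {}}
    tifffile.imwrite(str(path), array, description=json.dumps(desc))


def read_raster(path) -> tuple[np.ndarray, GridSpec, dict]:
    """Read a raster band; returns (array, grid, metadata)."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        desc = json.loads(page.description)
        array = page.asarray()
    if desc.get("crs") != CRS:
        raise RegistrationError(
            f"{path}: CRS {desc.get('crs')!r} is not geographic {CRS}"
        )
    return array, GridSpec.from_dict(desc["grid"]), desc.get("meta", {})


def write_world(world: WorldLayers, directory) -> dict[str, Path]:
    """Write the three world layers as one TIFF each."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in (
        ("current_lc", world.current_lc),
        ("pnv", world.pnv),
        ("dem", world.dem),
    ):
        p = directory / f"{name}.tif"
        write_raster(p, arr, world.grid, meta={"layer": name})
        paths[name] = p
    return paths


def read_world(paths: dict | str | Path) -> WorldLayers:
    """Read the three world layers, verifying co-registration.

    ``paths`` is either a directory holding ``current_lc.tif``, ``pnv.tif``
    and ``dem.tif``, or a mapping from those layer names to files.
    """
    if not isinstance(paths, dict):
        d = Path(paths)
        paths = {n: d / f"{n}.tif" for n in ("current_lc", "pnv", "dem")}
    layers, grids = {}, {}
    for name, p in paths.items():
        arr, grid, _ = read_raster(p)
        layers[name] = arr
        grids[name] = grid
    ref_name, ref = next(iter(grids.items()))
    for name, g in grids.items():
        if g != ref:
            raise RegistrationError(
                f"layer {name!r} grid {g.to_dict()} does not match "
                f"{ref_name!r} grid {ref.to_dict()}"
            )
    return WorldLayers(
        grid=ref,
        current_lc=layers["current_lc"].astype(np.int16),
        pnv=layers["pnv"].astype(np.int16),
        dem=layers["dem"].astype(float),
    )


def write_lifemap(life_map: LifeMap, path) -> None:
    """Write a score map (float64, NaN nodata) with scenario/curve metadata."""
    write_raster(
        path,
        life_map.values.astype(np.float64),
        life_map.grid,
        meta={
            "scenario": life_map.scenario,
            "curve": life_map.curve.label,
            "taxon": life_map.taxon,
            "nodata": "NaN",
        },
    )


def read_lifemap(path) -> tuple[np.ndarray, GridSpec, dict]:
    return read_raster(path)


# ---------------------------------------------------------------------------
# species tables
# ---------------------------------------------------------------------------

def _codes_to_names(codes) -> str:
    return ";".join(lc.CLASS_NAMES[c] for c in sorted(codes))


def _names_to_codes(text: str) -> frozenset[int]:
    if not isinstance(text, str) or not text.strip():
        return frozenset()
    return frozenset(lc.NAME_TO_CODE[n.strip()] for n in text.split(";") if n.strip())


def write_species(records: list[SpeciesRecord], directory) -> None:
    """Write species as CSV tables plus a boolean mask stack."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    srows, crows, masks = [], [], []
    for rec in records:
        for season, prefs in rec.preferences.items():
            srows.append(
                {
                    "species_id": rec.species_id,
                    "taxon_group": rec.taxon_group,
                    "systems": rec.systems,
                    "cave_subterranean": rec.cave_subterranean,
                    "season": season,
                    "habitats": _codes_to_names(prefs),
                    "elevation_min": rec.elevation_min,
                    "elevation_max": rec.elevation_max,
                    "elevation_unbounded": rec.elevation_unbounded,
                }
            )
        for comp in rec.components:
            crows.append(
                {
                    "species_id": rec.species_id,
                    "page": len(masks),
                    "presence": comp.presence,
                    "origin": comp.origin,
                    "seasonality": comp.seasonality,
                }
            )
            masks.append(comp.mask)
    pd.DataFrame(srows).to_csv(directory / "species.csv", index=False)
    pd.DataFrame(crows).to_csv(directory / "components.csv", index=False)
    tifffile.imwrite(str(directory / "components.tif"), np.stack(masks))


def read_species(directory) -> list[SpeciesRecord]:
    """Read species written by :func:`write_species`.

    Rows with missing preference or elevation fields become records with
    those fields unset — they route to the MISSING_DATA filter instead of
    raising here.
    """
    directory = Path(directory)
    sdf = pd.read_csv(directory / "species.csv")
    cdf = pd.read_csv(directory / "components.csv")
    stack = tifffile.imread(str(directory / "components.tif"))
    if stack.ndim == 2:
        stack = stack[None]
    records = []
    for sid, srows in sdf.groupby("species_id", sort=False):
        first = srows.iloc[0]
        prefs = {
            row["season"]: _names_to_codes(row.get("habitats", ""))
            for _, row in srows.iterrows()
        }
        comps = [
            RangeComponent(
                mask=stack[int(row["page"])].astype(bool),
                presence=row["presence"],
                origin=row["origin"],
                seasonality=row["seasonality"],
            )
            for _, row in cdf[cdf["species_id"] == sid].iterrows()
        ]
        def _num(v):
            return None if pd.isna(v) else float(v)
        records.append(
            SpeciesRecord(
                species_id=str(sid),
                taxon_group=first["taxon_group"],
                components=comps,
                preferences=prefs,
                elevation_min=_num(first.get("elevation_min")),
                elevation_max=_num(first.get("elevation_max")),
                elevation_unbounded=bool(first.get("elevation_unbounded", False)),
                systems=first.get("systems", "terrestrial"),
                cave_subterranean=bool(first.get("cave_subterranean", False)),
            )
        )
    return records


def rasterize_polygon(geometry: dict, grid: GridSpec) -> np.ndarray:
    """Rasterize a GeoJSON (Multi)Polygon: pixel centers inside the shape."""
    from shapely import contains_xy
    from shapely.geometry import shape

    geom = shape(geometry)
    rows = np.arange(grid.n_fine_rows)
    cols = np.arange(grid.n_fine_cols)
    lats = np.asarray(grid.fine_lat_center(rows), dtype=float)
    lons = np.asarray(grid.fine_lon_center(cols), dtype=float)
    lon_g, lat_g = np.meshgrid(lons, lats)
    return contains_xy(geom, lon_g, lat_g)


def read_species_geojson(path, grid: GridSpec) -> list[SpeciesRecord]:
    """Thin real-mode adapter: one GeoJSON feature per range component.

    Feature properties: ``species_id, taxon_group, presence, origin,
    seasonality, season, habitats`` (semicolon-separated class names),
    ``elevation_min, elevation_max``, optional ``systems`` and
    ``cave_subterranean``. Polygons are rasterized onto ``grid``.
    """
    with open(path) as fh:
        fc = json.load(fh)
    by_species: dict[str, dict] = {}
    for feat in fc["features"]:
        props = feat["properties"]
        sid = str(props["species_id"])
        entry = by_species.setdefault(
            sid, {"props": props, "components": [], "preferences": {}}
        )
        entry["components"].append(
            RangeComponent(
                mask=rasterize_polygon(feat["geometry"], grid),
                presence=props.get("presence", "extant"),
                origin=props.get("origin", "native"),
                seasonality=props.get("seasonality", "resident"),
            )
        )
        season = props.get("season", props.get("seasonality", "resident"))
        if season in ("breeding", "non-breeding", "resident"):
            entry["preferences"].setdefault(
                season, _names_to_codes(props.get("habitats", ""))
            )
    records = []
    for sid, entry in by_species.items():
        p = entry["props"]
        records.append(
            SpeciesRecord(
                species_id=sid,
                taxon_group=p.get("taxon_group", "bird"),
                components=entry["components"],
                preferences=entry["preferences"]
                or {"resident": frozenset()},
                elevation_min=p.get("elevation_min"),
                elevation_max=p.get("elevation_max"),
                elevation_unbounded=bool(p.get("elevation_unbounded", False)),
                systems=p.get("systems", "terrestrial"),
                cave_subterranean=bool(p.get("cave_subterranean", False)),
            )
        )
    return records
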