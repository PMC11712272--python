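"""Land-cover class vocabulary and the class-role crosswalk.

The vocabulary mirrors the two-level structure of the IUCN habitat
classification at much reduced granularity: natural habitats carry level-2
codes (10..59) that collapse to level-1 parents (1..5), while artificial
classes (arable, pasture, urban) are mapped at level 2 only. The potential
natural vegetation (PNV) layer stores level-1 natural codes; the current
land-cover layer stores level-2 codes, so matching a species' habitat
preferences against the two layers happens at different levels (see
:mod:`lifescore.aoh`).
"""

from __future__ import annotations

from enum import Enum

import numpy as np

# level-1 natural parents
FOREST = 1
SHRUBLAND = 2
GRASSLAND = 3
WETLAND = 4
DESERT = 5

# level-2 natural classes
FOREST_MOIST = 10
FOREST_DRY = 11
SHRUBLAND_L2 = 20
GRASSLAND_NATURAL = 30
WETLAND_L2 = 40
DESERT_L2 = 50

# artificial classes (level 2; they have no natural level-1 parent)
ARABLE = 60
PASTURE = 61
URBAN = 62

CLASS_NAMES: dict[int, str] = {
    FOREST: "forest",
    SHRUBLAND: "shrubland",
    GRASSLAND: "grassland",
    WETLAND: "wetland",
    DESERT: "desert",
    FOREST_MOIST: "forest_moist",
    FOREST_DRY: "forest_dry",
    SHRUBLAND_L2: "shrubland_l2",
    GRASSLAND_NATURAL: "grassland_natural",
    WETLAND_L2: "wetland_l2",
    DESERT_L2: "desert_l2",
    ARABLE: "arable",
    PASTURE: "pasture",
    URBAN: "urban",
}
NAME_TO_CODE = {v: k for k, v in CLASS_NAMES.items()}

#: level-2 (or level-1) code -> level-1 code; artificial classes map to themselves
LEVEL1_PARENT: dict[int, int] = {
    FOREST: FOREST,
    SHRUBLAND: SHRUBLAND,
    GRASSLAND: GRASSLAND,
    WETLAND: WETLAND,
    DESERT: DESERT,
    FOREST_MOIST: FOREST,
    FOREST_DRY: FOREST,
    SHRUBLAND_L2: SHRUBLAND,
    GRASSLAND_NATURAL: GRASSLAND,
    WETLAND_L2: WETLAND,
    DESERT_L2: DESERT,
    ARABLE: ARABLE,
    PASTURE: PASTURE,
    URBAN: URBAN,
}

NATURAL_L1 = (FOREST, SHRUBLAND, GRASSLAND, WETLAND, DESERT)
NATURAL_L2 = (FOREST_MOIST, FOREST_DRY, SHRUBLAND_L2, GRASSLAND_NATURAL,
              WETLAND_L2, DESERT_L2)
ARTIFICIAL = (ARABLE, PASTURE, URBAN)
ALL_CODES = tuple(CLASS_NAMES)


class Role(str, Enum):
    """Role a class plays in the scenario crosswalk."""

    NATURAL = "natural"
    ARABLE = "arable"
    PASTURE = "pasture"
    URBAN = "urban"


#: default crosswalk: class code -> role
DEFAULT_CROSSWALK: dict[int, Role] = {
    **{c: Role.NATURAL for c in NATURAL_L1 + NATURAL_L2},
    ARABLE: Role.ARABLE,
    PASTURE: Role.PASTURE,
    URBAN: Role.URBAN,
}


class UnknownClassError(KeyError):
    """A raster or preference set contains a code outside the vocabulary."""


def to_level1(code: int) -> int:
    try:
        return LEVEL1_PARENT[int(code)]
    except KeyError:
        raise UnknownClassError(f"unknown land-cover code {code!r}") from None


_MAX_CODE = max(ALL_CODES)
_L1_LUT = np.full(_MAX_CODE + 1, -1, dtype=np.int16)
for _c, _p in LEVEL1_PARENT.items():
    _L1_LUT[_c] = _p


def to_level1_array(raster: np.ndarray) -> np.ndarray:
    """Vectorized level-1 collapse of a class-code raster."""
    r = np.asarray(raster)
    if r.min() < 0 or r.max() > _MAX_CODE:
        raise UnknownClassError("raster contains codes outside the vocabulary")
    out = _L1_LUT[r]
    if (out < 0).any():
        bad = sorted(set(np.unique(r)) - set(ALL_CODES))
        raise UnknownClassError(f"raster contains unknown codes {bad}")
    return out


def is_natural(code: int) -> bool:
    return DEFAULT_CROSSWALK[to_level1(code) if code in LEVEL1_PARENT else code] is Role.NATURAL


def validate_codes(codes) -> None:
    unknown = [c for c in codes if c not in LEVEL1_PARENT]
    if unknown:
        raise UnknownClassError(f"unknown land-cover codes {unknown}")
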