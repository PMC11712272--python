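"""The two archetypal land-cover transformations.

* ``conversion_to_arable`` — every non-urban pixel (natural habitat,
  pasture and other artificial land) becomes arable cropland;
* ``reversion_to_natural`` — arable and pasture pixels are restored to the
  potential natural vegetation mapped for them; everything else is left
  alone.

Urban land is never modified by either scenario: neither farmland expansion
nor restoration is assumed to displace existing settlements. Pasture plays a
dual role — convertible under conversion, restorable under reversion —
encoded in the class-role crosswalk rather than hard-coded class names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import landcover as lc

CONVERSION = "conversion_to_arable"
REVERSION = "reversion_to_natural"


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    crosswalk: dict[int, lc.Role] = field(
        default_factory=lambda: dict(lc.DEFAULT_CROSSWALK)
    )

    def __post_init__(self) -> None:
        if self.name not in (CONVERSION, REVERSION):
            raise ValueError(f"unknown scenario {self.name!r}")

    def role(self, code: int) -> lc.Role:
        try:
            return self.crosswalk[int(code)]
        except KeyError:
            raise lc.UnknownClassError(
                f"code {code!r} missing from scenario crosswalk"
            ) from None


def conversion() -> ScenarioSpec:
    return ScenarioSpec(CONVERSION)


def reversion() -> ScenarioSpec:
    return ScenarioSpec(REVERSION)


def transform_pixel(current_class: int, pnv_class: int, scenario: ScenarioSpec) -> int:
    """Class of one pixel after applying the scenario (pure function)."""
    role = scenario.role(current_class)
    scenario.role(pnv_class)  # validate
    if scenario.name == CONVERSION:
        return int(current_class) if role is lc.Role.URBAN else lc.ARABLE
    # reversion
    if role in (lc.Role.ARABLE, lc.Role.PASTURE):
        return int(pnv_class)
    return int(current_class)


_ROLE_CODE = {lc.Role.NATURAL: 0, lc.Role.ARABLE: 1, lc.Role.PASTURE: 2,
              lc.Role.URBAN: 3}


def transform_raster(
    current_lc: np.ndarray, pnv: np.ndarray, scenario: ScenarioSpec
) -> np.ndarray:
    """Vectorized :func:`transform_pixel` over co-registered rasters."""
    lc.validate_codes(np.unique(current_lc))
    lc.validate_codes(np.unique(pnv))
    lut = np.full(int(max(scenario.crosswalk)) + 1, -1, dtype=np.int8)
    for code, role in scenario.crosswalk.items():
        lut[code] = _ROLE_CODE[role]
    role_of = lut[current_lc]
    out = current_lc.copy()
    if scenario.name == CONVERSION:
        out[role_of != _ROLE_CODE[lc.Role.URBAN]] = lc.ARABLE
    else:
        restorable = (role_of == _ROLE_CODE[lc.Role.ARABLE]) | (
            role_of == _ROLE_CODE[lc.Role.PASTURE]
        )
        out[restorable] = pnv[restorable]
    return out


def changed_mask(world, scenario: ScenarioSpec) -> tuple[np.ndarray, np.ndarray]:
    """Pixels the scenario alters and the changed area per coarse cell.

    Returns ``(fine boolean mask, coarse float raster of changed km^2)``.
    Coarse cells with zero changed area are flagged nodata downstream.
    """
    from .grid import aggregate_fine_to_coarse, fine_area_raster

    scen = transform_raster(world.current_lc, world.pnv, scenario)
    mask = scen != world.current_lc
    areas = fine_area_raster(world.grid)
    changed = aggregate_fine_to_coarse(
        np.where(mask, areas, 0.0), world.grid.fine_factor
    )
    return mask, changed
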