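"""The co-registered raster stack every stage operates on."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import landcover as lc
from .grid import GridSpec


class RegistrationError(ValueError):
    """Rasters do not share the grid they are required to share."""


@dataclass
class WorldLayers:
    """Current land cover, potential natural vegetation and elevation on one grid.

    ``current_lc`` holds level-2 class codes (natural and artificial);
    ``pnv`` holds level-1 natural codes only; ``dem`` is elevation in metres.
    All three share ``grid.fine_shape`` exactly.
    """

    grid: GridSpec
    current_lc: np.ndarray
    pnv: np.ndarray
    dem: np.ndarray

    def __post_init__(self) -> None:
        shape = self.grid.fine_shape
        for name in ("current_lc", "pnv", "dem"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise RegistrationError(
                    f"{name} shape {arr.shape} does not match grid {shape}"
                )
        lc.validate_codes(np.unique(self.current_lc))
        pnv_codes = set(np.unique(self.pnv))
        bad = pnv_codes - set(lc.NATURAL_L1)
        if bad:
            raise RegistrationError(
                f"pnv must contain only level-1 natural codes; found {sorted(bad)}"
            )
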