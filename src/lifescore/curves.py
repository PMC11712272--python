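"""Persistence curves and the expected-extinctions bookkeeping.

A persistence curve maps the fraction ``x`` of a species' original (human-
absent) Area of Habitat that remains to its probability ``P(x)`` of avoiding
extinction over the assessment horizon (a century, by the framing the scores
inherit). Two families are supported:

* power law, ``P(x) = min(1, x**z)`` — default ``z = 0.25``, the exponent
  used throughout the persistence-score literature;
* modified Gompertz, a sigmoid rescaled so that ``P(1) = 1``, which makes
  persistence collapse disproportionately fast at low remaining fractions
  (demographic stochasticity at small population sizes).

Both families are capped at 1: a species at or above its original AOH is
assumed to persist regardless — human-driven abundance above the original
state confers no extra credit. The change in a species' extinction
probability under a land-cover change is minus the change in its
persistence, and summing those changes over independent species gives the
expected number of extinctions (linearity of expectation over Bernoulli
indicators).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_Z = 0.25
#: exponents examined in the curve-shape sensitivity analysis
SENSITIVITY_Z_VALUES = (0.1, 0.25, 0.5, 1.0)


@dataclass(frozen=True)
class CurveSpec:
    """Persistence-curve family and parameters.

    ``family="power"`` uses exponent ``z``; ``family="gompertz"`` uses shape
    parameters ``a`` (initial suppression) and ``b`` (rate), with the curve
    ``g(x) = exp(-a*exp(-b*x)) / exp(-a*exp(-b))`` so that ``g(1) = 1``.
    """

    family: str = "power"
    z: float = DEFAULT_Z
    a: float = 5.0
    b: float = 6.0

    def __post_init__(self) -> None:
        if self.family not in ("power", "gompertz"):
            raise ValueError(f"unknown curve family {self.family!r}")
        if self.family == "power" and self.z <= 0:
            raise ValueError("power exponent z must be positive")
        if self.family == "gompertz" and (self.a <= 0 or self.b <= 0):
            raise ValueError("gompertz parameters a, b must be positive")

    @property
    def label(self) -> str:
        if self.family == "power":
            return f"power:z={self.z:g}"
        return f"gompertz:a={self.a:g},b={self.b:g}"

    @classmethod
    def parse(cls, text: str) -> "CurveSpec":
        """Parse ``power:z=0.25`` / ``gompertz:a=5,b=6`` style strings."""
        family, _, params = text.partition(":")
        kwargs: dict[str, float] = {}
        if params:
            for item in params.split(","):
                key, _, val = item.partition("=")
                key = key.strip()
                if key not in ("z", "a", "b"):
                    raise ValueError(f"unknown curve parameter {key!r}")
                kwargs[key] = float(val)
        return cls(family=family.strip(), **kwargs)


def default_sensitivity_curves() -> list[CurveSpec]:
    """The curve set of the sensitivity analysis: power z in
    {0.1, 0.25, 0.5, 1.0} plus the modified Gompertz."""
    curves = [CurveSpec("power", z=z) for z in SENSITIVITY_Z_VALUES]
    curves.append(CurveSpec("gompertz"))
    return curves


def persistence(x, curve: CurveSpec = CurveSpec()):
    """Probability of persistence at remaining fraction ``x`` (scalar or array).

    ``x`` must be >= 0; values above 1 are capped to persistence 1. The cap
    is applied after the power/exponential so the curve is exact below it.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("remaining fraction x must be non-negative")
    if curve.family == "power":
        p = np.minimum(1.0, np.power(arr, curve.z))
    else:
        # normalizer evaluated with the same exp as the numerator so that
        # g(1) is exactly 1.0 in floating point
        norm = float(np.exp(-curve.a * np.exp(-curve.b * 1.0)))
        p = np.minimum(1.0, np.exp(-curve.a * np.exp(-curve.b * arr)) / norm)
    return p if isinstance(x, np.ndarray) else float(p)


def delta_extinction(a_orig, a_now, a_scenario, curve: CurveSpec = CurveSpec()):
    """Change in extinction probability moving from ``a_now`` to ``a_scenario``.

    Equals ``P(a_now/a_orig) - P(a_scenario/a_orig)``: positive when habitat
    is lost, negative when gained, zero when both states sit at or above the
    cap. Accepts scalars or arrays in ``a_scenario``/``a_now``.
    """
    a_orig = float(a_orig)
    if a_orig <= 0:
        raise ValueError("original AOH must be positive")
    now = np.asarray(a_now, dtype=float)
    scen = np.asarray(a_scenario, dtype=float)
    if np.any(now < 0) or np.any(scen < 0):
        raise ValueError("AOH values must be non-negative")
    out = np.asarray(
        persistence(now / a_orig, curve) - persistence(scen / a_orig, curve)
    )
    return float(out) if out.ndim == 0 else out


def combine_seasons(p_breeding, p_nonbreeding):
    """Overall persistence of a migratory species: geometric mean of its
    breeding- and non-breeding-season persistence probabilities."""
    pb = np.asarray(p_breeding, dtype=float)
    pn = np.asarray(p_nonbreeding, dtype=float)
    out = np.sqrt(pb * pn)
    return float(out) if out.ndim == 0 else out


def expected_extinctions(persistence_probs) -> float:
    """Expected number of extinctions among independent species:
    ``sum(1 - P_s)`` over per-species persistence probabilities."""
    p = np.asarray(persistence_probs, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("persistence probabilities must lie in [0, 1]")
    return float(np.sum(1.0 - p))
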