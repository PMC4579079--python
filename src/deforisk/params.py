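"""Model constants.

The defaults are the reference experiment calibration for the Congo
Basin demonstration: multiplicative risk weights ``k`` (dimensionless
ratios — what matters is the ratio of risk inside/outside a driver's
influence), e-folding scales ``l`` (km), and the reforestation
constants.  ``tau_r`` is the regrowth timescale in years; ``tau_rp``
controls how weighted population density suppresses the recoverable
potential cover (people km-2).  ``f_t`` is the potential forest cover
fraction, 0.86 for the Congo core region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Literal

__all__ = ["RiskParams", "PHYSICAL_PARAMS"]

FragNormalization = Literal["as_printed", "k_at_half"]

#: Continuous physical parameters subject to perturbed-physics draws
#: and one-at-a-time sensitivity sweeps.
PHYSICAL_PARAMS: tuple[str, ...] = (
    "k_road",
    "k_pop",
    "k_river",
    "k_frag",
    "k_log",
    "k_park",
    "l_road",
    "l_river",
    "l_p",
    "l_f",
    "d_p",
    "tau_rp",
    "tau_r",
)


@dataclass(frozen=True)
class RiskParams:
    """All risk-model constants with the reference-experiment defaults."""

    k_road: float = 3.5      # weight of roads
    k_pop: float = 3.5       # weight of population
    k_river: float = 3.5     # weight of rivers
    k_frag: float = 3.5      # weight of fragmentation
    k_log: float = 1.3       # weight inside logging concessions
    k_park: float = 1.0      # weight inside protected areas
    p: float = 4.0           # beta shape exponent on local cover
    q: float = 4.0           # beta shape exponent on (1 - weighted cover)
    l_road: float = 100.0    # km, e-folding scale of road influence
    l_river: float = 1.0     # km, e-folding scale of river influence
    l_p: float = 15.0        # km, population kernel scale
    l_f: float = 2.5         # km, forest-density kernel scale
    d_p: float = 100.0       # people km-2, e-folding of population risk
    tau_rp: float = 200.0    # people km-2, permanent-deforestation sensitivity
    tau_r: float = 60.0      # years, reforestation timescale
    f_t: float = 0.86        # fraction, potential forest cover
    frag_normalization: FragNormalization = "as_printed"

    def __post_init__(self) -> None:
        for name in ("k_road", "k_pop", "k_river", "k_frag", "k_log", "k_park"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("l_road", "l_river", "l_p", "l_f", "d_p", "tau_r", "tau_rp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.p < 1 or self.q < 1:
            raise ValueError("beta exponents p, q must be >= 1")
        if not (0.0 < self.f_t <= 1.0):
            raise ValueError("f_t must lie in (0, 1]")
        if self.frag_normalization not in ("as_printed", "k_at_half"):
            raise ValueError(
                f"unknown frag_normalization {self.frag_normalization!r}"
            )

    def with_overrides(self, **kwargs: float) -> "RiskParams":
        """New parameter set with named values replaced.

        Unknown names raise, so sweep/ensemble configs cannot silently
        misspell a parameter.
        """
        known = {f.name for f in fields(self)}
        unknown = set(kwargs) - known
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
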