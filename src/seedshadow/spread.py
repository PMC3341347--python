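"""Asymptotic migration speed under the fat-tailed 2D-t kernel.

When invasion speed is set by the furthest-forward individual and dispersal
follows the 2D-t kernel, the asymptotic wave speed is

    V = sqrt((pi/2) * u * R0) / T      [m/yr],

where T is the generation time (yr), u the dispersal parameter (m^2) and
R0 the expected lifetime number of established offspring.  This is a
"jump"-based minimum rate: early in a migration, when the source population
is large, realized spread is faster.  The ratio of speeds for two
populations sharing demography reduces to sqrt(u1/u2), so between-site
differences in the dispersal parameter translate directly into relative
migration ability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["DemographyParams", "lifetime_R0", "wave_speed", "speed_ratio"]


def lifetime_R0(seeds_per_year: float, reproductive_years: float, survival: float) -> float:
    """Expected lifetime established offspring per individual.

    R0 = seeds/yr x reproductive lifespan (yr) x survival from seed
    dispersal to adulthood.  E.g. 800 seeds/yr over 80 years with 99.9%
    pre-adult mortality gives R0 = 64.
    """
    if not 0.0 <= survival <= 1.0:
        raise ValueError(f"survival must be in [0, 1], got {survival}")
    if seeds_per_year < 0 or reproductive_years < 0:
        raise ValueError("seeds_per_year and reproductive_years must be nonnegative")
    return float(seeds_per_year) * float(reproductive_years) * float(survival)


@dataclass(frozen=True)
class DemographyParams:
    """Demographic inputs for wave-speed calculations.

    generation_time : yr; seeds_per_year : seeds/yr once mature;
    reproductive_years : yr; survival : probability of surviving from seed
    dispersal to adulthood.  ``r0`` is derived on construction.
    """

    generation_time: float
    seeds_per_year: float
    reproductive_years: float
    survival: float

    def __post_init__(self):
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")
        object.__setattr__(
            self, "r0", lifetime_R0(self.seeds_per_year, self.reproductive_years, self.survival)
        )


def wave_speed(generation_time: float, u: float, r0: float) -> float:
    """Asymptotic spread rate V = sqrt((pi/2) * u * R0) / T, in m/yr."""
    if generation_time <= 0 or u <= 0 or r0 < 0:
        raise ValueError("generation_time and u must be positive, R0 nonnegative")
    return math.sqrt((math.pi / 2.0) * u * r0) / generation_time


def speed_ratio(u1: float, u2: float) -> float:
    """Ratio of asymptotic spread rates for two populations.

    With generation time and R0 shared they cancel, leaving sqrt(u1/u2).
    """
    if u1 <= 0 or u2 <= 0:
        raise ValueError("dispersal parameters must be positive")
    return math.sqrt(u1 / u2)
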