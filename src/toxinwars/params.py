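"""Ecological and solver parameters for pairwise strain competitions.

The standard parameter set describes a well-mixed patch seeded with two
strains at equal biomass that compete for a single pool of nutrient over a
fixed competition window (24 h by default), with Monod-limited growth and
toxin-mediated killing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class EcologicalParams:
    """Environment, kinetics and solver settings of a pairwise competition.

    Parameters
    ----------
    K_N : float
        Nutrient saturation constant of the Monod uptake term (gN).
    mu_max : float
        Maximum specific growth rate (1/hr).
    k : float
        Toxin killing efficiency (1/(gT*hr)).
    l_T : float
        First-order toxin loss rate (1/hr).
    N0 : float
        Initial nutrient pool (gN).
    C0_A, C0_B : float
        Initial biomass of each strain (gC).
    t_end : float
        Competition duration (hr).
    extinction_threshold : float
        Biomass below which a strain is treated as stochastically extinct
        and set to zero, irreversibly (gC).
    clamp_threshold : float
        Any state variable below this value is set to zero after each step.
    dt : float
        Implicit-Euler step size (hr). Toxin regulation is re-evaluated at
        the start of every step.
    """

    K_N: float = 5.0
    mu_max: float = 10.0
    k: float = 20.0
    l_T: float = 0.1
    N0: float = 1.0
    C0_A: float = 0.1
    C0_B: float = 0.1
    t_end: float = 24.0
    extinction_threshold: float = 1e-6
    clamp_threshold: float = 1e-8
    dt: float = 0.01

    def __post_init__(self) -> None:
        for name in ("K_N", "mu_max", "k", "l_T", "N0", "C0_A", "C0_B"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.t_end <= 0:
            raise ValueError(f"t_end must be > 0, got {self.t_end}")
        if not (0 < self.dt <= self.t_end):
            raise ValueError(f"dt must be in (0, t_end], got {self.dt}")
        if self.extinction_threshold < 0 or self.clamp_threshold < 0:
            raise ValueError("thresholds must be >= 0")

    def replace(self, **changes: float) -> "EcologicalParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EcologicalParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ecology/solver keys: {sorted(unknown)}")
        return cls(**d)


#: Table of standard values used throughout the analyses.
STANDARD_PARAMS = EcologicalParams()
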