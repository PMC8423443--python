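"""Toxin-production strategies.

A strategy is either *constitutive* (a fixed fraction ``f`` of nutrient
uptake is routed into toxin synthesis) or *regulated*: production switches
between ``f_initial`` and ``f_induced`` when a sensed signal crosses a
threshold. Three sensed signals are modelled, matching the major classes of
bacterial regulatory network:

- ``nutrient_sensing``: nutrient depletion ``N(0) - N(t)`` crossing ``U_N``
  (a stress response to resource limitation),
- ``toxin_sensing``: the opponent's toxin concentration crossing ``U_TB``
  (competition sensing via cell damage, i.e. reciprocation),
- ``quorum_sensing``: the producer's own biomass crossing ``U_QS``.

The switch is a Heaviside step with H(0) = 1, so a signal exactly at the
threshold counts as triggered. ``f_induced`` may be below ``f_initial``
(the signal represses production) or above it (the signal activates it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

MODES = ("constitutive", "nutrient_sensing", "toxin_sensing", "quorum_sensing")
SENSING_MODES = MODES[1:]
MODE_CODES = {mode: i for i, mode in enumerate(MODES)}

#: Threshold constraint ranges used by the whole-strategy-space scans
#: (wide signal ranges, one per sensing mode).
THRESHOLD_RANGES_SCAN = {
    "nutrient_sensing": (0.0, 1.0),
    "toxin_sensing": (0.0, 20.0),
    "quorum_sensing": (0.0, 20.0),
}

#: Threshold ranges for the standing-diversity optimisations (restricted to
#: the signal ranges actually realised in competitions).
THRESHOLD_RANGES_DIVERSITY = {
    "nutrient_sensing": (0.0, 1.0),
    "toxin_sensing": (0.001, 4.0),
    "quorum_sensing": (0.01, 1.2),
}

#: Threshold ranges for the genetic algorithm.
THRESHOLD_RANGES_GA = {
    "nutrient_sensing": (0.0, 1.0),
    "toxin_sensing": (0.0, 4.0),
    "quorum_sensing": (0.0, 1.2),
}


class StrategyError(ValueError):
    """Invalid strategy configuration."""


@dataclass(frozen=True)
class Strategy:
    """A toxin-production rule for one strain.

    Constitutive strategies carry only ``f``; regulated strategies carry
    ``f_initial``, ``f_induced`` and ``threshold``. All investment
    fractions lie in [0, 1]; thresholds are non-negative.
    """

    mode: str
    f: Optional[float] = None
    f_initial: Optional[float] = None
    f_induced: Optional[float] = None
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise StrategyError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.mode == "constitutive":
            if self.f is None:
                raise StrategyError("constitutive strategy requires f")
            if not (0.0 <= self.f <= 1.0):
                raise StrategyError(f"f must be in [0,1], got {self.f}")
            if any(v is not None for v in (self.f_initial, self.f_induced, self.threshold)):
                raise StrategyError("constitutive strategies have no sensing fields")
        else:
            if self.f is not None:
                raise StrategyError("regulated strategies have no fixed f")
            for name in ("f_initial", "f_induced", "threshold"):
                if getattr(self, name) is None:
                    raise StrategyError(f"regulated strategy requires {name}")
            for name in ("f_initial", "f_induced"):
                v = getattr(self, name)
                if not (0.0 <= v <= 1.0):
                    raise StrategyError(f"{name} must be in [0,1], got {v}")
            if self.threshold < 0:
                raise StrategyError(f"threshold must be >= 0, got {self.threshold}")

    @property
    def is_constitutive(self) -> bool:
        return self.mode == "constitutive"

    def encode(self) -> tuple:
        """Internal (mode_code, f_initial, f_induced, threshold) encoding.

        Constitutive strategies encode as the degenerate regulated form
        (f, f, +inf): the trigger never fires, so production stays at f.
        """
        if self.is_constitutive:
            return (0, self.f, self.f, np.inf)
        return (MODE_CODES[self.mode], self.f_initial, self.f_induced, self.threshold)

    def to_dict(self) -> dict:
        d = {"mode": self.mode}
        if self.is_constitutive:
            d["f"] = self.f
        else:
            d.update(f_initial=self.f_initial, f_induced=self.f_induced,
                     threshold=self.threshold)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Strategy":
        allowed = {"mode", "f", "f_initial", "f_induced", "threshold"}
        unknown = set(d) - allowed
        if unknown:
            raise StrategyError(f"unknown strategy keys: {sorted(unknown)}")
        return cls(**d)


def constitutive(f: float) -> Strategy:
    return Strategy(mode="constitutive", f=f)


def nutrient_sensing(f_initial: float, f_induced: float, threshold: float) -> Strategy:
    return Strategy(mode="nutrient_sensing", f_initial=f_initial,
                    f_induced=f_induced, threshold=threshold)


def toxin_sensing(f_initial: float, f_induced: float, threshold: float) -> Strategy:
    return Strategy(mode="toxin_sensing", f_initial=f_initial,
                    f_induced=f_induced, threshold=threshold)


def quorum_sensing(f_initial: float, f_induced: float, threshold: float) -> Strategy:
    return Strategy(mode="quorum_sensing", f_initial=f_initial,
                    f_induced=f_induced, threshold=threshold)


@dataclass(frozen=True)
class StrategyArrays:
    """Column-wise encoding of a batch of strategies for the vector solver."""

    mode: np.ndarray   # int8 codes per MODE_CODES
    f_initial: np.ndarray
    f_induced: np.ndarray
    threshold: np.ndarray

    def __len__(self) -> int:
        return self.mode.shape[0]

    def __getitem__(self, idx) -> "StrategyArrays":
        return StrategyArrays(self.mode[idx], self.f_initial[idx],
                              self.f_induced[idx], self.threshold[idx])


def pack(strategies) -> StrategyArrays:
    """Encode a sequence of :class:`Strategy` into :class:`StrategyArrays`."""
    enc = [s.encode() for s in strategies]
    mode = np.array([e[0] for e in enc], dtype=np.int8)
    fi = np.array([e[1] for e in enc], dtype=float)
    fd = np.array([e[2] for e in enc], dtype=float)
    th = np.array([e[3] for e in enc], dtype=float)
    return StrategyArrays(mode, fi, fd, th)
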