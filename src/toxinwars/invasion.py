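"""Metapopulation-level invasion analysis.

A rare mutant's evolutionary fate is decided by comparing its productivity
against the resident with the resident's productivity against itself: the
invasion index

    I_inv = w(f_inv | f_res) / w(f_res | f_res)

where w(x | y) is the final biomass of a strain playing x in a pairwise
competition against y. I_inv > 1 means the mutant spreads through the
metapopulation. Local success (winning the focal patch) and global success
(I_inv > 1) can disagree, giving four outcome classes: a mutant can win
its patch while producing too few cells to spread, or lose locally while
out-producing the average resident.

A *stable* invasion additionally requires that the displaced resident
cannot re-invade the new mutant population from rare. Scanning the
invasion index over a grid of (invader, resident) constitutive strategies
gives a pairwise invasibility plot, from which the evolutionarily stable
investment f* is read off: the grid strategy that invades every other and
is invaded by none.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dynamics import local_winner, simulate_batch
from .params import EcologicalParams
from .strategies import Strategy, constitutive, pack

#: Invasion indices within this band of 1 are treated as neutral
#: ("cannot invade"): protects PIP diagonals from floating-point noise.
NEUTRAL_BAND = 1e-6

OUTCOME_CLASSES = (
    "win_local_win_global",
    "lose_local_lose_global",
    "win_local_lose_global",
    "lose_local_win_global",
    "mixed",
)


class DegenerateResidentError(ValueError):
    """The resident self-extinguishes, so the invasion index is undefined."""


@dataclass
class InvasionResult:
    """Invasion index of one invader-vs-resident encounter."""

    w_inv: float
    w_res: float
    I_inv: float                 # nan when degenerate
    local_winner: str            # "A" (invader) | "B" (resident) | "tie"
    outcome_class: str
    degenerate: bool = False


def classify_outcome(local: str, I_inv: float,
                     band: float = NEUTRAL_BAND) -> str:
    """Map (local patch winner, invasion index) to the four-way outcome.

    Neutral or tied encounters fall into the residual ``mixed`` class.
    """
    if not np.isfinite(I_inv) or local == "tie" or abs(I_inv - 1.0) <= band:
        return "mixed"
    if local == "A":
        return "win_local_win_global" if I_inv > 1 else "win_local_lose_global"
    return "lose_local_win_global" if I_inv > 1 else "lose_local_lose_global"


def resident_self_fitness(resident: Strategy,
                          params: EcologicalParams) -> float:
    """w(f_res | f_res): one resident strain's final biomass against itself."""
    res = simulate_batch(pack([resident]), pack([resident]), params)
    return float(res.biomass_A[0])


def invasion_index(invader: Strategy, resident: Strategy,
                   params: EcologicalParams,
                   w_res: Optional[float] = None) -> InvasionResult:
    """Invasion index of a rare ``invader`` against a ``resident`` population.

    ``w_res`` may be supplied to reuse a cached resident self-fitness.
    """
    if w_res is None:
        w_res = resident_self_fitness(resident, params)
    res = simulate_batch(pack([invader]), pack([resident]), params)
    w_inv = float(res.biomass_A[0])
    w_res_local = float(res.biomass_B[0])
    local = local_winner(w_inv, w_res_local)
    if w_res <= 0.0:
        return InvasionResult(w_inv=w_inv, w_res=w_res, I_inv=float("nan"),
                              local_winner=local, outcome_class="mixed",
                              degenerate=True)
    I = w_inv / w_res
    return InvasionResult(w_inv=w_inv, w_res=w_res, I_inv=I,
                          local_winner=local,
                          outcome_class=classify_outcome(local, I))


def can_invade(I_inv: float, band: float = NEUTRAL_BAND) -> bool:
    """Invasion requires the index to exceed 1 beyond the neutrality band."""
    return np.isfinite(I_inv) and I_inv > 1.0 + band


def stable_invasion(invader: Strategy, resident: Strategy,
                    params: EcologicalParams) -> str:
    """Classify the two-way invasion test.

    Returns ``"invades_stably"`` when the invader spreads and the
    displaced resident cannot re-invade from rare, ``"mixed"`` when both
    can invade each other, and ``"no_invasion"`` otherwise.
    """
    fwd = invasion_index(invader, resident, params)
    back = invasion_index(resident, invader, params)
    if fwd.degenerate or back.degenerate:
        raise DegenerateResidentError(
            "self-extinguishing strategy: invasion indices undefined")
    invades = can_invade(fwd.I_inv)
    reinvades = can_invade(back.I_inv)
    if invades and not reinvades:
        return "invades_stably"
    if invades and reinvades:
        return "mixed"
    return "no_invasion"


@dataclass
class PIPGrid:
    """Pairwise invasibility plot over a grid of constitutive strategies.

    ``matrix[i, j]`` is the invasion index of invader ``grid[i]`` against
    resident ``grid[j]``; columns of self-extinguishing residents are NaN.
    """

    grid: np.ndarray
    matrix: np.ndarray
    self_fitness: np.ndarray
    params: EcologicalParams = field(default_factory=EcologicalParams)

    @property
    def degenerate(self) -> np.ndarray:
        return self.self_fitness <= 0.0

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.matrix,
                          index=[f"{f:.10g}" for f in self.grid],
                          columns=[f"{f:.10g}" for f in self.grid])
        df.index.name = "invader_f"
        df.to_csv(path, float_format="%.10g")


@dataclass
class ESSResult:
    """Outcome of the grid ESS search, with its certificate.

    ``f_star`` is the strict evolutionarily stable strategy: it invades
    every other grid strategy and is invaded by none. When a globally
    uninvadable-but-non-invading strategy blocks the strict quantifiers
    (the passive f = 0 typically does: a killer beats it locally but
    produces fewer cells than a passive resident pair), ``f_star`` is
    absent while ``f_opt`` still reports the optimal producer: the
    non-degenerate strategy invaded by none that invades the largest
    number of others (ties broken toward lower f). Wherever a strict ESS
    exists the two coincide, and ``f_opt`` matches the convergence-stable
    singular strategy of the near-diagonal invasion pattern.
    """

    f_star: Optional[float]
    index: Optional[int]
    pip: PIPGrid
    invades_all: Optional[np.ndarray] = None   # row check at the winner
    resists_all: Optional[np.ndarray] = None   # column check at the winner
    f_opt: Optional[float] = None
    opt_index: Optional[int] = None
    n_invaded_by_opt: Optional[int] = None

    @property
    def found(self) -> bool:
        return self.f_star is not None

    def certificate_ok(self) -> bool:
        if not self.found:
            return False
        return bool(self.invades_all.all() and self.resists_all.all())

    def to_json(self, path) -> None:
        payload = {
            "f_star": self.f_star,
            "found": self.found,
            "f_opt": self.f_opt,
            "grid": [float(f) for f in self.pip.grid],
            "grid_step": float(np.diff(self.pip.grid).min())
            if len(self.pip.grid) > 1 else None,
            "params": self.pip.params.to_dict(),
            "certificate": None if not self.found else {
                "invades_all": bool(self.invades_all.all()),
                "resists_all": bool(self.resists_all.all()),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def pairwise_invasibility(grid: Sequence[float],
                          params: EcologicalParams) -> PIPGrid:
    """Invasion-index matrix over a sorted grid of constitutive f values.

    Each unordered strategy pair is simulated once (the competition is
    symmetric in roles) and resident self-fitness is cached per grid
    value.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2:
        raise ValueError("grid must contain at least two values")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if grid[0] < 0 or grid[-1] > 1:
        raise ValueError("grid must lie within [0, 1]")
    n = len(grid)
    strats = [constitutive(f) for f in grid]

    selfs = simulate_batch(pack(strats), pack(strats), params)
    w_self = selfs.biomass_A.copy()

    ii, jj = np.triu_indices(n, k=1)
    res = simulate_batch(pack([strats[i] for i in ii]),
                         pack([strats[j] for j in jj]), params)

    matrix = np.full((n, n), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        np.fill_diagonal(matrix, np.where(w_self > 0, 1.0, np.nan))
        matrix[ii, jj] = np.where(w_self[jj] > 0,
                                  res.biomass_A / w_self[jj], np.nan)
        matrix[jj, ii] = np.where(w_self[ii] > 0,
                                  res.biomass_B / w_self[ii], np.nan)
    return PIPGrid(grid=grid, matrix=matrix, self_fitness=w_self,
                   params=params)


def _ess_from_pip(pip: PIPGrid, band: float) -> ESSResult:
    n = len(pip.grid)
    off = ~np.eye(n, dtype=bool)
    valid_col = ~pip.degenerate
    strict = None
    best = (-1, None)  # (number invaded, index) among uninvadable strategies
    for i in range(n):
        if pip.degenerate[i]:
            continue
        cols = off[i] & valid_col
        invades = pip.matrix[i, cols] > 1.0 + band
        resists = pip.matrix[cols, i] <= 1.0 + band
        if resists.all():
            n_inv = int(invades.sum())
            if n_inv > best[0]:
                best = (n_inv, i)
            if invades.all() and strict is None:
                strict = (i, invades, resists)
    if strict is not None:
        i, invades, resists = strict
        return ESSResult(f_star=float(pip.grid[i]), index=i, pip=pip,
                         invades_all=invades, resists_all=resists,
                         f_opt=float(pip.grid[i]), opt_index=i,
                         n_invaded_by_opt=int(invades.sum()))
    if best[1] is not None:
        return ESSResult(f_star=None, index=None, pip=pip,
                         f_opt=float(pip.grid[best[1]]), opt_index=best[1],
                         n_invaded_by_opt=best[0])
    return ESSResult(f_star=None, index=None, pip=pip)


def find_ess(params: EcologicalParams = EcologicalParams(),
             grid_step: float = 0.01, *, refine: bool = False,
             band: float = NEUTRAL_BAND) -> ESSResult:
    """Grid search for the evolutionarily stable constitutive investment.

    Builds the full pairwise invasibility plot on ``f in {0, grid_step,
    ..., 1}`` and returns the strategy that invades every other grid
    strategy and is invaded by none, together with its certificate.
    Reports absence (``found == False``) when no grid strategy qualifies.
    With ``refine=True`` the search is repeated once on a grid of step
    ``grid_step / 5`` spanning one coarse step around the winner.
    """
    if not (0 < grid_step <= 0.1):
        raise ValueError(f"grid_step must be in (0, 0.1], got {grid_step}")
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 12)
    result = _ess_from_pip(pairwise_invasibility(grid, params), band)
    anchor = result.f_star if result.found else result.f_opt
    if refine and anchor is not None:
        lo = max(0.0, anchor - grid_step)
        hi = min(1.0, anchor + grid_step)
        fine = np.round(np.arange(lo, hi + grid_step / 10, grid_step / 5), 12)
        fine_result = _ess_from_pip(pairwise_invasibility(fine, params), band)
        if fine_result.f_opt is not None:
            return fine_result
    return result


def outcome_class_counts(pairs: Sequence[tuple],
                         params: EcologicalParams) -> dict:
    """Outcome-class frequencies over a panel of (invader, resident) pairs."""
    counts = dict.fromkeys(OUTCOME_CLASSES, 0)
    selfs = {}
    for inv, res in pairs:
        if res not in selfs:
            selfs[res] = resident_self_fitness(res, params)
        r = invasion_index(inv, res, params, w_res=selfs[res])
        counts[r.outcome_class] += 1
    return counts
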