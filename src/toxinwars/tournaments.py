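"""Deterministic grid tournaments over the sensing-strategy space.

Two experiments:

1. :func:`invasion_map` — which (f_initial, f_induced) combinations admit,
   for at least one threshold value, a sensing strategy that *stably*
   invades the entire range of constitutive producers (invades every one,
   is re-invaded by none).

2. :func:`diversity_tournament` — optimise each sensing mode against a
   standing diversity of constitutive opponents, fitness being the mean
   final biomass across the competitions with the opponent set, and
   summarise the outcome with a linear fitness regression
   ``F_i ~ N(alpha_S[i] + beta * D_i, sigma)`` where S is a two-level
   toxin-vs-other sensing-type indicator and D the number of opponents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import simulate_batch
from .invasion import NEUTRAL_BAND
from .params import EcologicalParams
from .strategies import SENSING_MODES, Strategy, constitutive, pack

#: Full-resolution grid definitions: (f step, threshold range, threshold step)
#: for the whole-space invasion scan and the standing-diversity optimisation.
_SCAN_FULL = {
    "f_step": 0.02,
    "thresholds": {
        "nutrient_sensing": (0.0, 1.0, 0.002),
        "toxin_sensing": (0.0, 20.0, 0.002),
        "quorum_sensing": (0.0, 20.0, 0.002),
    },
}
_DIVERSITY_FULL = {
    "f_step": 0.05,
    "thresholds": {
        "nutrient_sensing": (0.0, 1.0, 0.02),
        "toxin_sensing": (0.001, 4.0, 0.0005),
        "quorum_sensing": (0.01, 1.2, 0.01),
    },
}


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    vals = np.arange(lo, hi + step / 2, step)
    return np.round(vals, 12)


@dataclass(frozen=True)
class SensingGridSpec:
    """Grid of sensing strategies for one regulation mode."""

    mode: str
    f_initial_values: np.ndarray
    f_induced_values: np.ndarray
    threshold_values: np.ndarray

    def __post_init__(self) -> None:
        if self.mode not in SENSING_MODES:
            raise ValueError(f"mode must be a sensing mode, got {self.mode!r}")
        for name in ("f_initial_values", "f_induced_values", "threshold_values"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 1 or len(v) == 0:
                raise ValueError(f"{name} must be a non-empty 1-d grid")
            object.__setattr__(self, name, v)
        if (self.f_initial_values.min() < 0 or self.f_initial_values.max() > 1
                or self.f_induced_values.min() < 0
                or self.f_induced_values.max() > 1):
            raise ValueError("investment grids must lie within [0, 1]")
        if self.threshold_values.min() < 0:
            raise ValueError("thresholds must be >= 0")

    @property
    def size(self) -> int:
        return (len(self.f_initial_values) * len(self.f_induced_values)
                * len(self.threshold_values))

    def strategies(self) -> list:
        return [Strategy(mode=self.mode, f_initial=fi, f_induced=fd,
                         threshold=th)
                for fi in self.f_initial_values
                for fd in self.f_induced_values
                for th in self.threshold_values]

    @classmethod
    def _scaled(cls, mode: str, table: dict, scale: float) -> "SensingGridSpec":
        if scale < 1:
            raise ValueError("scale must be >= 1 (1 = full-resolution grids)")
        f_step = table["f_step"] * scale
        lo, hi, th_step = table["thresholds"][mode]
        f_vals = _grid(0.0, 1.0, min(f_step, 1.0))
        th_vals = _grid(lo, hi, min(th_step * scale, hi - lo if hi > lo else 1.0))
        return cls(mode=mode, f_initial_values=f_vals, f_induced_values=f_vals,
                   threshold_values=th_vals)

    @classmethod
    def scan_default(cls, mode: str, scale: float = 1.0) -> "SensingGridSpec":
        """Whole-space scan grid, optionally coarsened by ``scale``."""
        return cls._scaled(mode, _SCAN_FULL, scale)

    @classmethod
    def diversity_default(cls, mode: str, scale: float = 1.0) -> "SensingGridSpec":
        """Standing-diversity optimisation grid, coarsened by ``scale``."""
        return cls._scaled(mode, _DIVERSITY_FULL, scale)

    @classmethod
    def desk_scan(cls, mode: str) -> "SensingGridSpec":
        """Desk-scale scan grid: coarse f steps, log-spread thresholds.

        Proportional coarsening of the full scan grid keeps millions of
        threshold values for the wide toxin/quorum signal ranges, so the
        desk grids instead spread a handful of thresholds roughly
        geometrically over the same ranges.
        """
        f_vals = _grid(0.0, 1.0, 0.2)
        th = {
            "nutrient_sensing": [0, .05, .1, .2, .3, .5, .7, .9, 1.0],
            "toxin_sensing": [0, .01, .02, .05, .1, .2, .5, 1, 2, 5, 10, 20],
            "quorum_sensing": [0, .01, .02, .05, .1, .2, .5, 1, 2, 5, 10, 20],
        }[mode]
        return cls(mode=mode, f_initial_values=f_vals, f_induced_values=f_vals,
                   threshold_values=np.asarray(th, dtype=float))

    @classmethod
    def desk_diversity(cls, mode: str) -> "SensingGridSpec":
        """Desk-scale standing-diversity grid over the restricted ranges."""
        f_vals = _grid(0.0, 1.0, 0.2)
        th = {
            "nutrient_sensing": [0, .05, .1, .2, .3, .5, .75, 1.0],
            "toxin_sensing": [.001, .005, .01, .05, .1, .5, 1, 2, 4],
            "quorum_sensing": [.01, .05, .1, .2, .4, .6, .9, 1.2],
        }[mode]
        return cls(mode=mode, f_initial_values=f_vals, f_induced_values=f_vals,
                   threshold_values=np.asarray(th, dtype=float))


def default_constitutive_grid(step: float = 0.01) -> np.ndarray:
    """The reference range of non-regulated producers, f = 0..1."""
    return _grid(0.0, 1.0, step)


# ---------------------------------------------------------------------------
# whole-space invasion map


@dataclass
class InvasionMapResult:
    """Outcome of the sensing-vs-constitutive stable-invasion scan."""

    mode: str
    records: pd.DataFrame          # per sensing strategy: stable_all, any_mixed
    stable_pairs: set              # {(f_initial, f_induced)} with a stable threshold
    stable_producer_pairs: set     # as above but ignoring the passive f = 0
    mixed_pairs: set               # pairs where some threshold gives mixed outcomes
    n_pairs: int                   # sensing-vs-constitutive encounters scanned
    n_invading: int                # encounters where the sensing strategy invades
    n_stable: int
    n_mixed: int
    n_no_invasion: int
    n_degenerate: int

    @property
    def mixed_fraction(self) -> float:
        """Share of successful invaders that can be re-invaded."""
        if self.n_invading == 0:
            return float("nan")
        return self.n_mixed / self.n_invading


def invasion_map(sensing_spec: SensingGridSpec,
                 constitutive_grid: Optional[Sequence[float]] = None,
                 params: EcologicalParams = EcologicalParams(), *,
                 band: float = NEUTRAL_BAND) -> InvasionMapResult:
    """Scan a sensing grid for strategies stably invading all constitutive f.

    For every sensing strategy the forward index I(s|c) (sensing invades a
    constitutive resident) and the back index I(c|s) are computed for each
    constitutive opponent; a strategy counts for its (f_initial,
    f_induced) cell when it invades every constitutive strategy and none
    can re-invade. Encounters where both directions invade are recorded as
    mixed.

    The passive strategy f = 0 is a special resident: a pair of passive
    residents wastes nothing on toxins, so no producer can out-produce it
    globally and no strategy stably invades the *entire* grid when f = 0
    is included. ``stable_producer_pairs`` therefore also reports the
    cells whose best threshold stably invades every *producing*
    constitutive strategy (f > 0), which is the informative notion of a
    universally invading regulator.
    """
    if constitutive_grid is None:
        constitutive_grid = default_constitutive_grid()
    cgrid = np.asarray(constitutive_grid, dtype=float)
    if len(cgrid) == 0 or sensing_spec.size == 0:
        raise ValueError("empty strategy grids")
    sensing = sensing_spec.strategies()
    consts = [constitutive(f) for f in cgrid]
    ns, nc = len(sensing), len(consts)

    w_ss = simulate_batch(pack(sensing), pack(sensing), params).biomass_A
    w_cc = simulate_batch(pack(consts), pack(consts), params).biomass_A

    si, ci = np.meshgrid(np.arange(ns), np.arange(nc), indexing="ij")
    si, ci = si.ravel(), ci.ravel()
    mixed_res = simulate_batch(pack([sensing[i] for i in si]),
                               pack([consts[j] for j in ci]), params)
    with np.errstate(divide="ignore", invalid="ignore"):
        I_fwd = np.where(w_cc[ci] > 0, mixed_res.biomass_A / w_cc[ci], np.nan)
        I_back = np.where(w_ss[si] > 0, mixed_res.biomass_B / w_ss[si], np.nan)

    degenerate = ~np.isfinite(I_fwd) | ~np.isfinite(I_back)
    invades = np.where(degenerate, False, I_fwd > 1.0 + band)
    reinvades = np.where(degenerate, False, I_back > 1.0 + band)
    stable = invades & ~reinvades
    mixed = invades & reinvades

    stable_m = stable.reshape(ns, nc)
    mixed_m = mixed.reshape(ns, nc)
    degen_m = degenerate.reshape(ns, nc)
    stable_all = stable_m.all(axis=1) & ~degen_m.any(axis=1)
    producers = cgrid > 0
    stable_prod = (stable_m[:, producers].all(axis=1)
                   & ~degen_m[:, producers].any(axis=1))
    any_mixed = mixed_m.any(axis=1)

    rows = []
    for idx, s in enumerate(sensing):
        rows.append({"mode": s.mode, "f_initial": s.f_initial,
                     "f_induced": s.f_induced, "threshold": s.threshold,
                     "stable_all": bool(stable_all[idx]),
                     "stable_all_producers": bool(stable_prod[idx]),
                     "any_mixed": bool(any_mixed[idx]),
                     "n_stable": int(stable_m[idx].sum()),
                     "n_mixed": int(mixed_m[idx].sum())})
    records = pd.DataFrame(rows)
    stable_pairs = {(r.f_initial, r.f_induced)
                    for r in records.itertuples() if r.stable_all}
    stable_producer_pairs = {(r.f_initial, r.f_induced)
                             for r in records.itertuples()
                             if r.stable_all_producers}
    mixed_pairs = {(r.f_initial, r.f_induced)
                   for r in records.itertuples() if r.any_mixed}

    n_degen = int(degenerate.sum())
    return InvasionMapResult(
        mode=sensing_spec.mode, records=records, stable_pairs=stable_pairs,
        stable_producer_pairs=stable_producer_pairs,
        mixed_pairs=mixed_pairs, n_pairs=ns * nc,
        n_invading=int(invades.sum()), n_stable=int(stable.sum()),
        n_mixed=int(mixed.sum()),
        n_no_invasion=int((~invades & ~degenerate).sum()),
        n_degenerate=n_degen)


# ---------------------------------------------------------------------------
# standing-diversity tournaments


@dataclass(frozen=True)
class OpponentSet:
    """A standing diversity of constitutive opponents."""

    diversity: int
    f_values: tuple

    def __post_init__(self) -> None:
        if len(self.f_values) != self.diversity:
            raise ValueError("diversity must equal the number of opponents")
        if self.diversity == 0:
            raise ValueError("opponent set must be non-empty")


@dataclass
class TournamentResult:
    """Best sensing strategy against one opponent set."""

    mode: str
    opponents: OpponentSet
    winner: Strategy
    winner_fitness: float              # mean final biomass across the set
    winner_biomasses: np.ndarray       # per-opponent final biomass
    table: pd.DataFrame                # long format, one row per competition


def diversity_tournament(sensing_spec: SensingGridSpec,
                         opponents: OpponentSet,
                         params: EcologicalParams = EcologicalParams(),
                         ) -> TournamentResult:
    """Optimise one sensing mode against a fixed set of constitutive opponents.

    Every grid strategy is competed pairwise against each opponent;
    fitness is the mean final biomass across the set (sums rank
    identically since the set size is fixed). Argmax ties break toward
    lower (f_initial, f_induced, threshold) lexicographically.
    """
    sensing = sensing_spec.strategies()
    opps = [constitutive(f) for f in opponents.f_values]
    ns, no = len(sensing), len(opps)
    si, oi = np.meshgrid(np.arange(ns), np.arange(no), indexing="ij")
    si, oi = si.ravel(), oi.ravel()
    res = simulate_batch(pack([sensing[i] for i in si]),
                         pack([opps[j] for j in oi]), params)
    biomass = res.biomass_A.reshape(ns, no)
    fitness = biomass.mean(axis=1)

    keys = np.array([(s.f_initial, s.f_induced, s.threshold) for s in sensing])
    order = np.lexsort((keys[:, 2], keys[:, 1], keys[:, 0], -fitness))
    best = order[0]

    table = pd.DataFrame({
        "mode": sensing_spec.mode,
        "f_initial": keys[si, 0], "f_induced": keys[si, 1],
        "threshold": keys[si, 2],
        "opponent_f": [opps[j].f for j in oi],
        "final_biomass": res.biomass_A,
    })
    return TournamentResult(
        mode=sensing_spec.mode, opponents=opponents, winner=sensing[best],
        winner_fitness=float(fitness[best]),
        winner_biomasses=biomass[best].copy(), table=table)


def run_diversity_experiment(opponent_sets: Sequence[OpponentSet],
                             params: EcologicalParams = EcologicalParams(),
                             scale: float = 1.0,
                             modes: Sequence[str] = SENSING_MODES,
                             desk: bool = False) -> dict:
    """Optimise every sensing mode against every opponent set.

    Returns ``{"results": {(mode, D): TournamentResult}, "records":
    DataFrame}`` where the records hold the winners' per-competition
    fitness, ready for :func:`fit_fitness_regression`. With ``desk=True``
    the documented desk-scale grids are used instead of proportional
    coarsening.
    """
    results = {}
    rows = []
    for mode in modes:
        spec = (SensingGridSpec.desk_diversity(mode) if desk
                else SensingGridSpec.diversity_default(mode, scale=scale))
        for oset in opponent_sets:
            r = diversity_tournament(spec, oset, params)
            results[(mode, oset.diversity)] = r
            for f_opp, w in zip(oset.f_values, r.winner_biomasses):
                rows.append({"mode": mode, "D": oset.diversity,
                             "opponent_f": f_opp, "fitness": w})
    return {"results": results, "records": pd.DataFrame(rows)}


# ---------------------------------------------------------------------------
# fitness regression


@dataclass
class RegressionModel:
    """Fitted two-group fitness regression F ~ alpha_S + beta D."""

    alpha_toxin: float
    alpha_other: float
    beta: float
    sigma: float
    p_value_type: float            # H0: alpha_toxin == alpha_other
    intercept_ratio: float         # alpha_toxin / alpha_other
    mean_fitness_ratio: float      # group means evaluated at mean D
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("alpha_toxin", "alpha_other", "beta", "sigma",
                 "p_value_type", "intercept_ratio", "mean_fitness_ratio", "n")}


def fit_fitness_regression(records: pd.DataFrame) -> RegressionModel:
    """OLS fit of per-competition fitness on sensing type and diversity.

    ``records`` needs columns ``fitness``, ``mode`` (sensing mode name)
    and ``D`` (number of opponents). The type enters as a two-level
    indicator: toxin sensing vs the other modes.
    """
    import statsmodels.api as sm

    required = {"fitness", "mode", "D"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    df = records.copy()
    df["is_toxin"] = (df["mode"] == "toxin_sensing").astype(float)
    if df["is_toxin"].nunique() < 2:
        raise ValueError("records must span both type groups")
    if df["D"].nunique() < 2:
        raise ValueError("records must span at least two diversity levels")
    X = sm.add_constant(df[["is_toxin", "D"]].astype(float))
    fit = sm.OLS(df["fitness"].astype(float), X).fit()
    if fit.df_resid <= 0:
        raise ValueError("rank-deficient design: no residual degrees of freedom")
    alpha_other = float(fit.params["const"])
    alpha_toxin = alpha_other + float(fit.params["is_toxin"])
    beta = float(fit.params["D"])
    d_mean = float(df["D"].mean())
    mean_other = alpha_other + beta * d_mean
    mean_toxin = alpha_toxin + beta * d_mean
    return RegressionModel(
        alpha_toxin=alpha_toxin, alpha_other=alpha_other, beta=beta,
        sigma=float(np.sqrt(fit.scale)),
        p_value_type=float(fit.pvalues["is_toxin"]),
        intercept_ratio=alpha_toxin / alpha_other if alpha_other != 0
        else float("inf"),
        mean_fitness_ratio=mean_toxin / mean_other if mean_other != 0
        else float("inf"),
        n=int(fit.nobs))
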