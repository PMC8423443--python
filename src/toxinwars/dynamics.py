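"""Pairwise-competition dynamics.

Two strains A and B grow on a shared nutrient pool N and each produces a
toxin that kills only the other strain:

    dC_A/dt = (1 - f_A) mu_max M C_A - k T_B C_A
    dC_B/dt = (1 - f_B) mu_max M C_B - k T_A C_B
    dT_A/dt = f_A M C_A - l_T T_A
    dT_B/dt = f_B M C_B - l_T T_B
    dN/dt   = -M (C_A + C_B),        M = N / (N + K_N)

where f_X in [0, 1] is strain X's instantaneous investment into toxin
production — the allocative cost of warfare: a strain investing f grows at
only (1 - f) of its maximal rate. With k = l_T = 0 the quantity
C_A + C_B + mu_max (T_A + T_B + N) is conserved, which the solver tests
exploit as an analytic oracle.

The system is integrated by backward Euler with Newton iteration on each
step. Regulated investments are evaluated from the state at the *start* of
each step and held constant through it, keeping the Heaviside switch
outside the implicit solve. After each step any state variable below the
clamp threshold is zeroed, then any strain below the extinction threshold
is removed for the remainder of the run (its released toxin keeps
decaying).

The solver is vectorised over an arbitrary batch of competitions sharing
one parameter set; the scalar API wraps a batch of one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import EcologicalParams
from .strategies import Strategy, StrategyArrays, pack

_IDX = {"C_A": 0, "C_B": 1, "T_A": 2, "T_B": 3, "N": 4}
_EYE5 = np.eye(5)

#: Relative tolerance used to call a pairwise competition a tie.
TIE_RTOL = 1e-9


class ConvergenceError(RuntimeError):
    """The implicit step solver failed to converge."""


@dataclass(frozen=True)
class SystemState:
    """Instantaneous state of one competition."""

    t: float
    C_A: float
    C_B: float
    T_A: float
    T_B: float
    N: float

    def __post_init__(self) -> None:
        for name in ("C_A", "C_B", "T_A", "T_B", "N"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.C_A, self.C_B, self.T_A, self.T_B, self.N])


@dataclass
class Trajectory:
    """Stored solver steps of one competition plus realised investments."""

    t: np.ndarray
    C_A: np.ndarray
    C_B: np.ndarray
    T_A: np.ndarray
    T_B: np.ndarray
    N: np.ndarray
    f_A: np.ndarray
    f_B: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.t, "C_A": self.C_A, "C_B": self.C_B,
            "T_A": self.T_A, "T_B": self.T_B, "N": self.N,
            "f_A": self.f_A, "f_B": self.f_B,
        })

    def conserved_quantity(self, mu_max: float) -> np.ndarray:
        """C_A + C_B + mu_max (T_A + T_B + N) at every stored step."""
        return self.C_A + self.C_B + mu_max * (self.T_A + self.T_B + self.N)


@dataclass
class CompetitionOutcome:
    """Final result of one pairwise competition."""

    final_biomass_A: float
    final_biomass_B: float
    extinct_A: bool
    extinct_B: bool
    local_winner: str  # "A" | "B" | "tie"
    trajectory: Optional[Trajectory] = None


def toxin_investment(strategy: Strategy, state: SystemState, N0: float) -> float:
    """Instantaneous toxin investment of a strain following ``strategy``.

    ``state`` is read from the strain's own perspective: ``C_A``/``T_B``
    are the strain's own biomass and the opponent's toxin. The Heaviside
    trigger uses H(0) = 1, so a signal exactly at threshold is activated.
    """
    if strategy.mode == "constitutive":
        return strategy.f
    if strategy.mode == "nutrient_sensing":
        signal = N0 - state.N
    elif strategy.mode == "toxin_sensing":
        signal = state.T_B
    elif strategy.mode == "quorum_sensing":
        signal = state.C_A
    else:  # pragma: no cover - Strategy validates mode
        raise ValueError(f"unknown strategy mode {strategy.mode!r}")
    triggered = signal >= strategy.threshold
    return strategy.f_initial + (strategy.f_induced - strategy.f_initial) * triggered


def derivatives(state: SystemState, f_A: float, f_B: float,
                params: EcologicalParams) -> np.ndarray:
    """Right-hand side of the competition ODEs at one state.

    Returns d/dt of (C_A, C_B, T_A, T_B, N).
    """
    x = state.as_array()[None, :]
    return _rhs(x, np.array([f_A]), np.array([f_B]), params)[0]


# ---------------------------------------------------------------------------
# vectorised core


def _rhs(x: np.ndarray, f_A: np.ndarray, f_B: np.ndarray,
         p: EcologicalParams) -> np.ndarray:
    CA, CB, TA, TB, N = x[:, 0], x[:, 1], x[:, 2], x[:, 3], x[:, 4]
    M = N / (N + p.K_N)
    out = np.empty_like(x)
    out[:, 0] = (1.0 - f_A) * p.mu_max * M * CA - p.k * TB * CA
    out[:, 1] = (1.0 - f_B) * p.mu_max * M * CB - p.k * TA * CB
    out[:, 2] = f_A * M * CA - p.l_T * TA
    out[:, 3] = f_B * M * CB - p.l_T * TB
    out[:, 4] = -M * (CA + CB)
    return out


def _jacobian(x: np.ndarray, f_A: np.ndarray, f_B: np.ndarray,
              p: EcologicalParams) -> np.ndarray:
    CA, CB, TA, TB, N = x[:, 0], x[:, 1], x[:, 2], x[:, 3], x[:, 4]
    denom = N + p.K_N
    M = N / denom
    dM = p.K_N / (denom * denom)
    n = x.shape[0]
    J = np.zeros((n, 5, 5))
    J[:, 0, 0] = (1.0 - f_A) * p.mu_max * M - p.k * TB
    J[:, 0, 3] = -p.k * CA
    J[:, 0, 4] = (1.0 - f_A) * p.mu_max * dM * CA
    J[:, 1, 1] = (1.0 - f_B) * p.mu_max * M - p.k * TA
    J[:, 1, 2] = -p.k * CB
    J[:, 1, 4] = (1.0 - f_B) * p.mu_max * dM * CB
    J[:, 2, 0] = f_A * M
    J[:, 2, 2] = -p.l_T
    J[:, 2, 4] = f_A * dM * CA
    J[:, 3, 1] = f_B * M
    J[:, 3, 3] = -p.l_T
    J[:, 3, 4] = f_B * dM * CB
    J[:, 4, 0] = -M
    J[:, 4, 1] = -M
    J[:, 4, 4] = -dM * (CA + CB)
    return J


def _backward_euler_step(x_old: np.ndarray, f_A: np.ndarray, f_B: np.ndarray,
                         dt: float, p: EcologicalParams, *,
                         tol: float = 1e-11, max_iter: int = 50,
                         depth: int = 0) -> np.ndarray:
    """Solve x = x_old + dt f(x) by damped-projection Newton, batched.

    Rows that fail to converge are re-integrated with two half steps
    (recursively, bounded depth).
    """
    # explicit-Euler predictor, projected onto the non-negative orthant.
    # Rows are frozen at their first converged iterate so that a
    # competition's result is bit-identical regardless of which batch it
    # is solved in (the Newton blocks are row-independent).
    x = np.maximum(x_old + dt * _rhs(x_old, f_A, f_B, p), 0.0)
    active = np.ones(x.shape[0], dtype=bool)
    for _ in range(max_iter):
        xa = x[active]
        ga = xa - x_old[active] - dt * _rhs(xa, f_A[active], f_B[active], p)
        done = np.abs(ga).max(axis=1) < tol
        if done.any():
            idx = np.flatnonzero(active)
            active[idx[done]] = False
            if not active.any():
                return x
            xa, ga = xa[~done], ga[~done]
        J = _EYE5 - dt * _jacobian(xa, f_A[active], f_B[active], p)
        x[active] = np.maximum(xa - np.linalg.solve(J, ga[..., None])[..., 0],
                               0.0)
    xa = x[active]
    ga = xa - x_old[active] - dt * _rhs(xa, f_A[active], f_B[active], p)
    done = np.abs(ga).max(axis=1) < tol
    idx = np.flatnonzero(active)
    active[idx[done]] = False
    if not active.any():
        return x
    converged = ~active
    if depth >= 12:
        raise ConvergenceError(
            f"implicit step failed to converge at dt={dt} after substepping")
    bad = ~converged
    half = 0.5 * dt
    xb = _backward_euler_step(x_old[bad], f_A[bad], f_B[bad], half, p,
                              tol=tol, max_iter=max_iter, depth=depth + 1)
    xb = _backward_euler_step(xb, f_A[bad], f_B[bad], half, p,
                              tol=tol, max_iter=max_iter, depth=depth + 1)
    x[bad] = xb
    return x


def _investments(pack_: StrategyArrays, x: np.ndarray, own_col: int,
                 opp_toxin_col: int, N0: float) -> np.ndarray:
    signal = np.zeros(len(pack_))
    m = pack_.mode
    nut = m == 1
    tox = m == 2
    quo = m == 3
    if nut.any():
        signal[nut] = N0 - x[nut, 4]
    if tox.any():
        signal[tox] = x[tox, opp_toxin_col]
    if quo.any():
        signal[quo] = x[quo, own_col]
    active = signal >= pack_.threshold  # H(0) = 1; inf threshold never fires
    return pack_.f_initial + (pack_.f_induced - pack_.f_initial) * active


@dataclass
class BatchResult:
    """Final states of a batch of competitions."""

    final: np.ndarray        # (M, 5) state at t_end
    extinct_A: np.ndarray    # (M,) bool
    extinct_B: np.ndarray

    @property
    def biomass_A(self) -> np.ndarray:
        return self.final[:, 0]

    @property
    def biomass_B(self) -> np.ndarray:
        return self.final[:, 1]


def _step_schedule(t_end: float, dt: float) -> list:
    n_full = int(np.floor(t_end / dt + 1e-9))
    steps = [dt] * n_full
    rem = t_end - n_full * dt
    if rem > 1e-9 * max(t_end, 1.0):
        steps.append(rem)
    return steps


def simulate_batch(strats_A: StrategyArrays, strats_B: StrategyArrays,
                   params: EcologicalParams, *, record: bool = False,
                   chunk_size: int = 20000):
    """Integrate a batch of pairwise competitions sharing one parameter set.

    Returns a :class:`BatchResult`, or ``(BatchResult, list[Trajectory])``
    when ``record=True``. Large batches are processed in chunks.
    """
    m = len(strats_A)
    if len(strats_B) != m:
        raise ValueError("strategy batches must have equal length")
    if m > chunk_size and not record:
        parts = [simulate_batch(strats_A[i:i + chunk_size],
                                strats_B[i:i + chunk_size], params)
                 for i in range(0, m, chunk_size)]
        return BatchResult(
            final=np.concatenate([r.final for r in parts]),
            extinct_A=np.concatenate([r.extinct_A for r in parts]),
            extinct_B=np.concatenate([r.extinct_B for r in parts]),
        )

    p = params
    x = np.zeros((m, 5))
    x[:, 0] = p.C0_A
    x[:, 1] = p.C0_B
    x[:, 4] = p.N0
    ext_A = np.zeros(m, dtype=bool)
    ext_B = np.zeros(m, dtype=bool)

    steps = _step_schedule(p.t_end, p.dt)
    if record:
        times = [0.0]
        states = [x.copy()]
        fa_hist, fb_hist = [], []

    t = 0.0
    for h in steps:
        f_A = _investments(strats_A, x, own_col=0, opp_toxin_col=3, N0=p.N0)
        f_B = _investments(strats_B, x, own_col=1, opp_toxin_col=2, N0=p.N0)
        x = _backward_euler_step(x, f_A, f_B, h, p)
        x[x < p.clamp_threshold] = 0.0
        dead_A = x[:, 0] < p.extinction_threshold
        dead_B = x[:, 1] < p.extinction_threshold
        x[dead_A, 0] = 0.0
        x[dead_B, 1] = 0.0
        ext_A |= dead_A
        ext_B |= dead_B
        t += h
        if record:
            times.append(t)
            states.append(x.copy())
            fa_hist.append(f_A.copy())
            fb_hist.append(f_B.copy())

    result = BatchResult(final=x, extinct_A=ext_A, extinct_B=ext_B)
    if not record:
        return result

    # investments at the final state close the per-step trace
    f_A = _investments(strats_A, x, 0, 3, p.N0)
    f_B = _investments(strats_B, x, 1, 2, p.N0)
    fa_hist.append(f_A.copy())
    fb_hist.append(f_B.copy())
    tarr = np.array(times)
    S = np.stack(states)          # (n_steps+1, M, 5)
    FA = np.stack(fa_hist)
    FB = np.stack(fb_hist)
    trajectories = [
        Trajectory(t=tarr, C_A=S[:, i, 0], C_B=S[:, i, 1], T_A=S[:, i, 2],
                   T_B=S[:, i, 3], N=S[:, i, 4], f_A=FA[:, i], f_B=FB[:, i])
        for i in range(m)
    ]
    return result, trajectories


def local_winner(biomass_A: float, biomass_B: float,
                 rtol: float = TIE_RTOL) -> str:
    """Compare final biomasses within one patch; near-equal is a tie."""
    scale = max(abs(biomass_A), abs(biomass_B))
    if scale == 0.0 or abs(biomass_A - biomass_B) <= rtol * scale:
        return "tie"
    return "A" if biomass_A > biomass_B else "B"


def simulate_competition(strategy_A: Strategy, strategy_B: Strategy,
                         params: EcologicalParams = EcologicalParams(), *,
                         record_trajectory: bool = False) -> CompetitionOutcome:
    """Run one pairwise competition from t=0 to t_end.

    Deterministic: identical inputs give identical outputs.
    """
    pa = pack([strategy_A])
    pb = pack([strategy_B])
    if record_trajectory:
        res, trajs = simulate_batch(pa, pb, params, record=True)
        traj = trajs[0]
    else:
        res = simulate_batch(pa, pb, params)
        traj = None
    a = float(res.biomass_A[0])
    b = float(res.biomass_B[0])
    return CompetitionOutcome(
        final_biomass_A=a,
        final_biomass_B=b,
        extinct_A=bool(res.extinct_A[0]),
        extinct_B=bool(res.extinct_B[0]),
        local_winner=local_winner(a, b),
        trajectory=traj,
    )
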