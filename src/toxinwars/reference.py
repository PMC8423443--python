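"""Independent reference integration for solver verification.

The production solver is first-order implicit Euler at a fixed step. To
verify it, competitions are re-run with scipy's adaptive high-order
integrators and the final biomasses compared. Regulation is held
piecewise-constant per output interval (the same interval as the implicit
solver's step), so the comparison isolates time-discretisation error
rather than penalising switch-timing semantics. When both strategies are
constitutive the investments never change and the run is integrated in one
adaptive sweep per extinction epoch, with extinction located by event
detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .dynamics import _investments, _rhs, _step_schedule, local_winner
from .params import EcologicalParams
from .strategies import Strategy, pack


def _rhs_scalar(p: EcologicalParams, f_A: float, f_B: float):
    def fun(t, y):
        return _rhs(y[None, :], np.array([f_A]), np.array([f_B]), p)[0]
    return fun


def _apply_rules(x: np.ndarray, p: EcologicalParams,
                 ext: np.ndarray) -> np.ndarray:
    x = np.where(x < p.clamp_threshold, 0.0, x)
    for side in (0, 1):
        if x[side] < p.extinction_threshold:
            x[side] = 0.0
            ext[side] = True
    return x


def _reference_constitutive(f_A: float, f_B: float, p: EcologicalParams,
                            rtol: float, atol: float):
    """One adaptive sweep per extinction epoch, with crossing events."""
    x = np.array([p.C0_A, p.C0_B, 0.0, 0.0, p.N0])
    ext = np.zeros(2, dtype=bool)
    fun = _rhs_scalar(p, f_A, f_B)
    t = 0.0
    x = _apply_rules(x, p, ext)

    def make_event(idx):
        def ev(t, y):
            return y[idx] - p.extinction_threshold
        ev.terminal = True
        ev.direction = -1.0
        return ev

    for _ in range(4):  # at most one extinction epoch per strain
        alive = [i for i in (0, 1) if not ext[i]]
        events = [make_event(i) for i in alive]
        sol = solve_ivp(fun, (t, p.t_end), x, method="LSODA",
                        rtol=rtol, atol=atol, events=events or None)
        if not sol.success:
            raise RuntimeError(f"reference integration failed: {sol.message}")
        x = sol.y[:, -1].copy()
        t = sol.t[-1]
        if sol.status == 1:  # a strain hit the extinction threshold
            for ev_idx, times in enumerate(sol.t_events):
                if len(times):
                    x[alive[ev_idx]] = 0.0
                    ext[alive[ev_idx]] = True
        x = _apply_rules(x, p, ext)
        if t >= p.t_end * (1 - 1e-12):
            break
    return x, ext


def _reference_regulated(sa, sb, p: EcologicalParams, rtol: float, atol: float):
    """Interval-by-interval adaptive integration with frozen investments."""
    x = np.array([[p.C0_A, p.C0_B, 0.0, 0.0, p.N0]])
    ext = np.zeros(2, dtype=bool)
    t = 0.0
    for h in _step_schedule(p.t_end, p.dt):
        f_A = float(_investments(sa, x, 0, 3, p.N0)[0])
        f_B = float(_investments(sb, x, 1, 2, p.N0)[0])
        sol = solve_ivp(_rhs_scalar(p, f_A, f_B), (t, t + h), x[0],
                        method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"reference integration failed: {sol.message}")
        x = _apply_rules(sol.y[:, -1].copy(), p, ext)[None, :]
        t += h
    return x[0], ext


def _signal_value(strategy: Strategy, y: np.ndarray, side: int,
                  N0: float) -> float:
    if strategy.mode == "nutrient_sensing":
        return N0 - y[4]
    if strategy.mode == "toxin_sensing":
        return y[3 - side]  # opponent's toxin
    return y[side]  # quorum: own biomass


def _reference_events(strategy_A: Strategy, strategy_B: Strategy,
                      p: EcologicalParams, rtol: float, atol: float,
                      max_epochs: int = 400):
    """Hybrid-system integration: switch and extinction events, exact in time.

    Toxin investments change at the instant a sensed signal crosses its
    threshold, rather than on the solver grid; used for refined-step
    validation of the production solver.
    """
    y = np.array([p.C0_A, p.C0_B, 0.0, 0.0, p.N0])
    ext = np.zeros(2, dtype=bool)
    strategies = (strategy_A, strategy_B)
    t = 0.0

    def investment(s: Strategy, side: int, yy: np.ndarray) -> float:
        if s.is_constitutive:
            return s.f
        trig = _signal_value(s, yy, side, p.N0) >= s.threshold
        return s.f_initial + (s.f_induced - s.f_initial) * trig

    for _ in range(max_epochs):
        f_A = investment(strategy_A, 0, y)
        f_B = investment(strategy_B, 1, y)
        fun = _rhs_scalar(p, f_A, f_B)
        events = []
        for side in (0, 1):
            if not ext[side]:
                def ev_ext(tt, yy, side=side):
                    return yy[side] - p.extinction_threshold
                ev_ext.terminal = True
                ev_ext.direction = -1.0
                events.append(("ext", side, ev_ext))
        for side, s in enumerate(strategies):
            if not s.is_constitutive:
                def ev_sw(tt, yy, s=s, side=side):
                    return _signal_value(s, yy, side, p.N0) - s.threshold
                ev_sw.terminal = True
                ev_sw.direction = 0.0
                events.append(("switch", side, ev_sw))
        sol = solve_ivp(fun, (t, p.t_end), y, method="LSODA",
                        rtol=rtol, atol=atol, events=[e[2] for e in events])
        if not sol.success:
            raise RuntimeError(f"reference integration failed: {sol.message}")
        y = sol.y[:, -1].copy()
        t_new = sol.t[-1]
        if sol.status == 1:
            for (kind, side, _), times in zip(events, sol.t_events):
                if len(times) and kind == "ext":
                    y[side] = 0.0
                    ext[side] = True
            # always step a hair past the event before re-arming event
            # detection: restarting exactly on a zero of an event function
            # breaks the root bracketing inside solve_ivp
            eps = max(1e-9, 1e-12 * p.t_end)
            if t_new + eps < p.t_end:
                f_A = investment(strategy_A, 0, y)
                f_B = investment(strategy_B, 1, y)
                sol2 = solve_ivp(_rhs_scalar(p, f_A, f_B), (t_new, t_new + eps),
                                 y, method="LSODA", rtol=rtol, atol=atol)
                y = sol2.y[:, -1].copy()
                t_new = t_new + eps
        y = _apply_rules(y, p, ext)
        t = t_new
        if t >= p.t_end * (1 - 1e-12):
            return y, ext
    raise RuntimeError("reference hybrid integration exceeded the epoch "
                       "budget (possible threshold chattering)")


def reference_competition(strategy_A: Strategy, strategy_B: Strategy,
                          params: EcologicalParams, *, rtol: float = 1e-10,
                          atol: float = 1e-13, regulation: str = "interval"):
    """Final state of a competition under the adaptive reference integrator.

    Returns ``(final_state, extinct_flags)`` with the same clamping and
    extinction rules as the production solver. ``regulation`` selects how
    regulated investments are handled: ``"interval"`` freezes them per
    production step (matching the implicit solver's switching grid) while
    ``"event"`` resolves threshold crossings exactly in time.
    """
    if strategy_A.is_constitutive and strategy_B.is_constitutive:
        return _reference_constitutive(strategy_A.f, strategy_B.f,
                                       params, rtol, atol)
    if regulation == "event":
        return _reference_events(strategy_A, strategy_B, params, rtol, atol)
    if regulation != "interval":
        raise ValueError(f"unknown regulation handling {regulation!r}")
    return _reference_regulated(pack([strategy_A]), pack([strategy_B]),
                                params, rtol, atol)


@dataclass
class DeviationReport:
    """Solver-vs-reference comparison of one competition."""

    biomass_A: float
    biomass_B: float
    ref_biomass_A: float
    ref_biomass_B: float
    max_relative_deviation: float
    winner_agrees: bool


def _rel(a: float, b: float) -> float:
    scale = max(abs(a), abs(b))
    if scale == 0.0:
        return 0.0
    return abs(a - b) / scale


def validate_against_reference(strategy_A: Strategy, strategy_B: Strategy,
                               params: EcologicalParams = EcologicalParams(),
                               *, regulation: str = "interval",
                               ) -> DeviationReport:
    """Max relative final-biomass deviation between solver and reference."""
    from .dynamics import simulate_competition

    out = simulate_competition(strategy_A, strategy_B, params)
    ref, _ = reference_competition(strategy_A, strategy_B, params,
                                   regulation=regulation)
    dev = max(_rel(out.final_biomass_A, ref[0]),
              _rel(out.final_biomass_B, ref[1]))
    return DeviationReport(
        biomass_A=out.final_biomass_A,
        biomass_B=out.final_biomass_B,
        ref_biomass_A=float(ref[0]),
        ref_biomass_B=float(ref[1]),
        max_relative_deviation=dev,
        winner_agrees=(out.local_winner == local_winner(float(ref[0]),
                                                        float(ref[1]))),
    )
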