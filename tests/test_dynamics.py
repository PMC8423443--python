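"""Pairwise-competition dynamics: investments, derivatives, solver rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from toxinwars import (EcologicalParams, Strategy, SystemState, constitutive,
                       derivatives, nutrient_sensing, quorum_sensing,
                       simulate_competition, toxin_investment, toxin_sensing)
from toxinwars.dynamics import _step_schedule, local_winner
from toxinwars.strategies import StrategyError


def state(C_A=0.1, C_B=0.1, T_A=0.0, T_B=0.0, N=1.0, t=0.0):
    return SystemState(t=t, C_A=C_A, C_B=C_B, T_A=T_A, T_B=T_B, N=N)


class TestToxinInvestment:
    def test_constitutive_is_fixed(self):
        assert toxin_investment(constitutive(0.37), state(), 1.0) == 0.37

    def test_quorum_triggers_exactly_at_threshold(self):
        # the Heaviside switch uses H(0) = 1
        s = quorum_sensing(0.1, 0.8, 0.25)
        assert toxin_investment(s, state(C_A=0.25), 1.0) == 0.8
        assert toxin_investment(s, state(C_A=0.2499), 1.0) == 0.1

    def test_equal_initial_and_induced_removes_the_trigger(self):
        for s in (nutrient_sensing(0.2, 0.2, 0.1),
                  toxin_sensing(0.2, 0.2, 5.0),
                  quorum_sensing(0.2, 0.2, 0.0)):
            assert toxin_investment(s, state(T_B=9.0, C_A=9.0, N=0.0),
                                    1.0) == pytest.approx(0.2)

    @pytest.mark.parametrize("N_now,expected", [(0.8, 0.0), (0.6, 0.5)])
    def test_nutrient_sensing_keys_on_depletion(self, N_now, expected):
        s = nutrient_sensing(0.0, 0.5, 0.3)
        assert toxin_investment(s, state(N=N_now), 1.0) == expected

    def test_toxin_sensing_reads_opponent_toxin(self):
        s = toxin_sensing(0.0, 0.9, 0.05)
        assert toxin_investment(s, state(T_B=0.06), 1.0) == 0.9
        assert toxin_investment(s, state(T_A=0.06), 1.0) == 0.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(StrategyError):
            Strategy(mode="telepathy", f=0.1)


class TestDerivatives:
    def test_no_nutrient_shuts_down_uptake(self, params):
        d = derivatives(state(T_B=0.2, T_A=0.3, N=0.0), 0.4, 0.1, params)
        # only killing and toxin decay remain
        assert d[0] == pytest.approx(-params.k * 0.2 * 0.1)
        assert d[2] == pytest.approx(-params.l_T * 0.3)
        assert d[4] == 0.0

    def test_hand_evaluated_standard_state(self, params):
        f_A = 0.0
        d = derivatives(state(), f_A, 0.0, params)
        monod = 1.0 / 6.0
        assert d[0] == pytest.approx((1 - f_A) * 10 * monod * 0.1)
        assert d[4] == pytest.approx(-monod * 0.2)

    def test_conservation_identity_of_the_rhs(self, params):
        p = params.replace(k=0.0, l_T=0.0)
        d = derivatives(state(C_A=0.3, C_B=0.2, T_A=0.05, T_B=0.01, N=0.7),
                        0.25, 0.6, p)
        total = d[0] + d[1] + p.mu_max * (d[2] + d[3] + d[4])
        assert total == pytest.approx(0.0, abs=1e-12)


class TestSimulateCompetition:
    def test_higher_investment_wins_the_standard_duel(self, params):
        out = simulate_competition(constitutive(0.3), constitutive(0.1),
                                   params)
        assert out.local_winner == "A"
        assert out.final_biomass_A > out.final_biomass_B

    def test_identical_strategies_stay_symmetric(self, fast_params):
        out = simulate_competition(constitutive(0.2), constitutive(0.2),
                                   fast_params, record_trajectory=True)
        np.testing.assert_array_equal(out.trajectory.C_A, out.trajectory.C_B)
        assert out.local_winner == "tie"

    def test_zero_toxin_conserved_total(self, params):
        out = simulate_competition(constitutive(0.0), constitutive(0.0),
                                   params)
        total = (out.final_biomass_A + out.final_biomass_B)
        # nutrient from the trajectory-free run via conservation:
        out2 = simulate_competition(constitutive(0.0), constitutive(0.0),
                                    params, record_trajectory=True)
        q = out2.trajectory.conserved_quantity(params.mu_max)
        assert np.all(np.abs(q - 10.2) < 1e-6)
        assert total == pytest.approx(out2.final_biomass_A
                                      + out2.final_biomass_B)

    def test_deterministic_bit_identical(self, params):
        a = simulate_competition(toxin_sensing(0.02, 0.7, 0.01),
                                 constitutive(0.31), params)
        b = simulate_competition(toxin_sensing(0.02, 0.7, 0.01),
                                 constitutive(0.31), params)
        assert a.final_biomass_A == b.final_biomass_A
        assert a.final_biomass_B == b.final_biomass_B

    def test_extinction_is_flagged_and_zeroed(self, params):
        out = simulate_competition(constitutive(0.6), constitutive(0.0),
                                   params)
        assert out.extinct_B and out.final_biomass_B == 0.0
        assert not out.extinct_A

    def test_partial_final_step_schedule(self):
        steps = _step_schedule(1.05, 0.1)
        assert len(steps) == 11
        assert sum(steps) == pytest.approx(1.05)

    def test_tie_detection(self):
        assert local_winner(1.0, 1.0 + 1e-12) == "tie"
        assert local_winner(0.0, 0.0) == "tie"
        assert local_winner(2.0, 1.0) == "A"


def _random_strategy(draw_mode, f1, f2, th):
    if draw_mode == 0:
        return constitutive(f1)
    mode = ("nutrient_sensing", "toxin_sensing", "quorum_sensing")[draw_mode - 1]
    return Strategy(mode=mode, f_initial=f1, f_induced=f2, threshold=th)


frac = st.floats(0.0, 1.0, allow_nan=False, width=32)
thr = st.floats(0.0, 2.0, allow_nan=False, width=32)
strategy_st = st.builds(_random_strategy, st.integers(0, 3), frac, frac, thr)


class TestTrajectoryProperties:
    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(sa=strategy_st, sb=strategy_st)
    def test_nonnegative_and_nutrient_monotone(self, sa, sb, fast_params):
        out = simulate_competition(sa, sb, fast_params,
                                   record_trajectory=True)
        tr = out.trajectory
        for arr in (tr.C_A, tr.C_B, tr.T_A, tr.T_B, tr.N):
            assert np.all(arr >= 0.0)
        assert np.all(np.diff(tr.N) <= 1e-15)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(sa=strategy_st, sb=strategy_st)
    def test_conservation_without_loss_or_killing(self, sa, sb):
        p = EcologicalParams(t_end=6.0, dt=0.02, k=0.0, l_T=0.0)
        out = simulate_competition(sa, sb, p, record_trajectory=True)
        q = out.trajectory.conserved_quantity(p.mu_max)
        assert np.max(np.abs(q - q[0])) < 1e-6

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(sa=strategy_st, sb=strategy_st)
    def test_role_swap_swaps_the_outcome_exactly(self, sa, sb, fast_params):
        ab = simulate_competition(sa, sb, fast_params)
        ba = simulate_competition(sb, sa, fast_params)
        assert ab.final_biomass_A == ba.final_biomass_B
        assert ab.final_biomass_B == ba.final_biomass_A
        assert ab.extinct_A == ba.extinct_B


class TestValidation:
    def test_parameter_invariants(self):
        with pytest.raises(ValueError):
            EcologicalParams(dt=30.0)
        with pytest.raises(ValueError):
            EcologicalParams(k=-1.0)
        with pytest.raises(ValueError):
            EcologicalParams(t_end=0.0)

    def test_strategy_field_exclusivity(self):
        with pytest.raises(StrategyError):
            Strategy(mode="constitutive", f=0.2, f_initial=0.1,
                     f_induced=0.2, threshold=0.1)
        with pytest.raises(StrategyError):
            Strategy(mode="toxin_sensing", f=0.2)
        with pytest.raises(StrategyError):
            toxin_sensing(0.1, 1.2, 0.5)
        with pytest.raises(StrategyError):
            quorum_sensing(0.1, 0.2, -0.5)

    def test_state_nonnegativity_enforced(self):
        with pytest.raises(ValueError):
            SystemState(t=0, C_A=-0.1, C_B=0, T_A=0, T_B=0, N=1)
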