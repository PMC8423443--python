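"""Grid tournaments: invasion maps, diversity optimisation, regression."""

import numpy as np
import pandas as pd
import pytest

from toxinwars import (EcologicalParams, OpponentSet, SensingGridSpec,
                       constitutive, diversity_tournament,
                       fit_fitness_regression, invasion_map,
                       stable_invasion)
from toxinwars.strategies import Strategy


@pytest.fixture(scope="module")
def coarse_params():
    return EcologicalParams(dt=0.02)


@pytest.fixture(scope="module")
def tiny_spec():
    return SensingGridSpec(
        mode="toxin_sensing",
        f_initial_values=np.array([0.0, 0.4]),
        f_induced_values=np.array([0.2, 0.7]),
        threshold_values=np.array([0.01, 0.5]))


class TestGridSpecs:
    def test_validation(self):
        with pytest.raises(ValueError):
            SensingGridSpec(mode="constitutive",
                            f_initial_values=np.array([0.0]),
                            f_induced_values=np.array([0.0]),
                            threshold_values=np.array([0.1]))
        with pytest.raises(ValueError):
            SensingGridSpec(mode="toxin_sensing",
                            f_initial_values=np.array([1.4]),
                            f_induced_values=np.array([0.0]),
                            threshold_values=np.array([0.1]))

    def test_full_scan_grid_stepping(self):
        spec = SensingGridSpec.scan_default("nutrient_sensing")
        assert spec.f_initial_values[1] - spec.f_initial_values[0] \
            == pytest.approx(0.02)
        assert spec.threshold_values[1] - spec.threshold_values[0] \
            == pytest.approx(0.002)
        assert spec.threshold_values[-1] == pytest.approx(1.0)

    def test_full_diversity_grid_ranges(self):
        tox = SensingGridSpec.diversity_default("toxin_sensing")
        assert tox.threshold_values[0] == pytest.approx(0.001)
        assert tox.threshold_values[-1] <= 4.0
        quo = SensingGridSpec.diversity_default("quorum_sensing")
        assert quo.threshold_values[0] == pytest.approx(0.01)
        assert quo.threshold_values[-1] <= 1.2

    def test_scaling_coarsens_proportionally(self):
        full = SensingGridSpec.scan_default("nutrient_sensing")
        half = SensingGridSpec.scan_default("nutrient_sensing", scale=2.0)
        assert len(half.f_initial_values) == (len(full.f_initial_values) + 1) // 2
        with pytest.raises(ValueError):
            SensingGridSpec.scan_default("nutrient_sensing", scale=0.5)

    def test_desk_grids_cover_the_signal_ranges(self):
        for mode in ("nutrient_sensing", "toxin_sensing", "quorum_sensing"):
            scan = SensingGridSpec.desk_scan(mode)
            div = SensingGridSpec.desk_diversity(mode)
            assert scan.f_initial_values[0] == 0.0
            assert scan.f_initial_values[-1] == 1.0
            assert div.size < 600  # desk-sized


class TestInvasionMap:
    def test_matches_bruteforce_stable_invasion(self, tiny_spec,
                                                coarse_params):
        cgrid = np.array([0.1, 0.4])
        r = invasion_map(tiny_spec, cgrid, coarse_params)
        for row in r.records.itertuples():
            s = Strategy(mode="toxin_sensing", f_initial=row.f_initial,
                         f_induced=row.f_induced, threshold=row.threshold)
            verdicts = [stable_invasion(s, constitutive(f), coarse_params)
                        for f in cgrid]
            assert row.stable_all == all(v == "invades_stably"
                                         for v in verdicts)
            assert row.n_mixed == sum(v == "mixed" for v in verdicts)

    def test_degenerate_regulation_cannot_invade_its_own_fixed_point(
            self, coarse_params):
        # f_initial = f_induced = f behaves exactly like constitutive f,
        # so it is neutral against that resident and excluded
        spec = SensingGridSpec(
            mode="quorum_sensing",
            f_initial_values=np.array([0.3]),
            f_induced_values=np.array([0.3]),
            threshold_values=np.array([0.2]))
        r = invasion_map(spec, np.array([0.3]), coarse_params)
        assert not r.records.stable_all.any()
        assert r.n_no_invasion == 1

    def test_threshold_superset_monotonicity(self, coarse_params):
        f_vals = np.array([0.0, 0.5])
        small = SensingGridSpec(mode="nutrient_sensing",
                                f_initial_values=f_vals,
                                f_induced_values=f_vals,
                                threshold_values=np.array([0.3]))
        big = SensingGridSpec(mode="nutrient_sensing",
                              f_initial_values=f_vals,
                              f_induced_values=f_vals,
                              threshold_values=np.array([0.1, 0.3, 0.6]))
        cgrid = np.array([0.1, 0.31, 0.5])
        r_small = invasion_map(small, cgrid, coarse_params)
        r_big = invasion_map(big, cgrid, coarse_params)
        assert r_small.stable_pairs <= r_big.stable_pairs
        assert r_small.stable_producer_pairs <= r_big.stable_producer_pairs

    def test_partition_bookkeeping(self, tiny_spec, coarse_params):
        r = invasion_map(tiny_spec, np.array([0.0, 0.2, 0.6]), coarse_params)
        assert (r.n_stable + r.n_mixed + r.n_no_invasion + r.n_degenerate
                == r.n_pairs)
        assert r.n_invading == r.n_stable + r.n_mixed

    def test_empty_grid_rejected(self, coarse_params, tiny_spec):
        with pytest.raises(ValueError):
            invasion_map(tiny_spec, np.array([]), coarse_params)


class TestDiversityTournament:
    def test_winner_is_the_exhaustive_argmax(self, tiny_spec, coarse_params):
        oset = OpponentSet(diversity=3, f_values=(0.4, 0.5, 0.6))
        r = diversity_tournament(tiny_spec, oset, coarse_params)
        per_strategy = r.table.groupby(
            ["f_initial", "f_induced", "threshold"])["final_biomass"].mean()
        assert r.winner_fitness == pytest.approx(per_strategy.max())
        key = (r.winner.f_initial, r.winner.f_induced, r.winner.threshold)
        assert per_strategy[key] == pytest.approx(r.winner_fitness)

    def test_deterministic_fitness_for_identical_inputs(self, tiny_spec,
                                                        coarse_params):
        oset = OpponentSet(diversity=1, f_values=(0.5,))
        a = diversity_tournament(tiny_spec, oset, coarse_params)
        b = diversity_tournament(tiny_spec, oset, coarse_params)
        assert np.array_equal(a.winner_biomasses, b.winner_biomasses)
        assert a.winner == b.winner

    def test_tie_break_is_lexicographic(self, coarse_params):
        # two grid entries with identical strategies tie exactly; the
        # lower lexicographic key must win
        spec = SensingGridSpec(
            mode="nutrient_sensing",
            f_initial_values=np.array([0.2]),
            f_induced_values=np.array([0.2]),
            threshold_values=np.array([0.1, 0.9]))  # same behaviour
        oset = OpponentSet(diversity=1, f_values=(0.5,))
        r = diversity_tournament(spec, oset, coarse_params)
        assert r.winner.threshold == 0.1

    def test_opponent_set_validation(self):
        with pytest.raises(ValueError):
            OpponentSet(diversity=2, f_values=(0.5,))


class TestFitnessRegression:
    def test_parameter_recovery_on_model_generated_data(self, rng):
        alpha_t, alpha_o, beta, sigma = 2.0, 1.0, -0.05, 0.01
        rows = []
        for _ in range(200):
            is_toxin = rng.random() < 0.5
            D = rng.choice([1, 3, 5, 7, 9])
            mu = (alpha_t if is_toxin else alpha_o) + beta * D
            rows.append({"mode": "toxin_sensing" if is_toxin
                         else "quorum_sensing", "D": D,
                         "fitness": rng.normal(mu, sigma)})
        m = fit_fitness_regression(pd.DataFrame(rows))
        se = sigma / np.sqrt(len(rows) / 4)
        assert abs(m.alpha_toxin - alpha_t) < 3 * se * 4
        assert abs(m.alpha_other - alpha_o) < 3 * se * 4
        assert abs(m.beta - beta) < 0.01
        assert m.p_value_type < 1e-6

    @pytest.mark.parametrize("n", [50, 200, 800])
    def test_estimates_tighten_with_sample_size(self, n, rng):
        alpha_t, alpha_o, beta = 1.5, 1.0, -0.02
        rows = [{"mode": "toxin_sensing" if i % 2 else "nutrient_sensing",
                 "D": [1, 3, 5, 7, 9][i % 5],
                 "fitness": (alpha_t if i % 2 else alpha_o)
                 + beta * [1, 3, 5, 7, 9][i % 5] + rng.normal(0, 0.2)}
                for i in range(n)]
        m = fit_fitness_regression(pd.DataFrame(rows))
        assert abs(m.beta - beta) < 1.0 / np.sqrt(n)

    def test_constant_fitness_gives_flat_fit(self):
        rows = [{"mode": m, "D": d, "fitness": 1.7}
                for m in ("toxin_sensing", "quorum_sensing")
                for d in (1, 3, 5)]
        m = fit_fitness_regression(pd.DataFrame(rows))
        assert m.beta == pytest.approx(0.0, abs=1e-12)
        assert m.alpha_toxin == pytest.approx(1.7)
        assert m.alpha_other == pytest.approx(1.7)

    def test_degenerate_designs_rejected(self):
        one_group = pd.DataFrame([{"mode": "toxin_sensing", "D": d,
                                   "fitness": 1.0} for d in (1, 3)])
        with pytest.raises(ValueError):
            fit_fitness_regression(one_group)
        one_level = pd.DataFrame([{"mode": m, "D": 3, "fitness": 1.0}
                                  for m in ("toxin_sensing",
                                            "nutrient_sensing")])
        with pytest.raises(ValueError):
            fit_fitness_regression(one_level)
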