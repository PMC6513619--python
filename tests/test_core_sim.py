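"""Unit and property tests for the generalized Eden simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heterospread import (
    ColonyState,
    SimConfig,
    generate_disorder,
    growth_rate,
    replay_final_state,
    run_colony,
    run_linear,
)
from heterospread.workbench import make_fixture


class TestSimConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rho": 1.2},
            {"rho": -0.1},
            {"k": 1.5},
            {"mu": 2.0},
            {"s": -1.0},
            {"N_target": 0},
            {"N_target": 10**6},  # exceeds L^2
            {"geometry": "hexagonal"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        base = dict(L=50, N_target=100, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            SimConfig(**base)

    @given(
        rho=st.floats(0, 1),
        k=st.floats(0, 1),
        mu=st.floats(0, 1),
        s=st.floats(-0.9, 2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_valid_parameter_space_accepted(self, rho, k, mu, s):
        cfg = SimConfig(L=20, rho=rho, k=k, mu=mu, s=s, N_target=50, seed=1)
        assert cfg.rho == rho


class TestDisorder:
    def test_zero_density_all_normal(self):
        field = generate_disorder(50, 0.0, seed=3)
        assert not field.mask.any()

    def test_full_density_respects_protected(self):
        field = generate_disorder(50, 1.0, seed=3, protected=[(25, 25)])
        assert not field.mask[25, 25]
        assert field.mask.sum() == 50 * 50 - 1

    def test_realized_density_within_binomial_bound(self):
        # 3 sigma of Binomial(10^4, 0.4)
        field = generate_disorder(100, 0.4, seed=1)
        sigma = np.sqrt(0.4 * 0.6 / 10**4)
        assert abs(field.rho_realized - 0.4) < 3 * sigma

    def test_reproducible_from_seed(self):
        a = generate_disorder(40, 0.3, seed=9)
        b = generate_disorder(40, 0.3, seed=9)
        assert np.array_equal(a.mask, b.mask)

    def test_protected_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            generate_disorder(10, 0.5, seed=0, protected=[(10, 0)])


class TestGrowthRate:
    def _state(self):
        occ = np.zeros((3, 3), dtype=np.uint8)
        gen = np.zeros((3, 3), dtype=np.uint8)
        occ[1, 1] = occ[1, 2] = 1
        gen[1, 2] = 1  # mutant
        return ColonyState(occ, gen, np.zeros((3, 3), np.int32), 0.0, 2, False)

    def test_wild_type_on_normal_site_is_unit(self):
        state = self._state()
        field = generate_disorder(3, 0.0, seed=0)
        assert growth_rate(state, field, (1, 1), k=0.5, s=0.3) == 1.0

    def test_mutant_on_disorder_site_multiplies(self):
        state = self._state()
        field = generate_disorder(3, 0.0, seed=0)
        field.mask[1, 2] = True
        rate = growth_rate(state, field, (2, 1), k=0.1, s=0.2)
        assert rate == pytest.approx(0.1 * 1.2)

    def test_impassable_obstacle_rate_zero(self):
        state = self._state()
        field = generate_disorder(3, 0.0, seed=0)
        field.mask[1, 1] = True
        assert growth_rate(state, field, (1, 1), k=0.0, s=0.0) == 0.0

    def test_unoccupied_site_rejected(self):
        state = self._state()
        field = generate_disorder(3, 0.0, seed=0)
        with pytest.raises(ValueError):
            growth_rate(state, field, (0, 0), k=0.5, s=0.0)


class TestStepProbabilities:
    """Empirical event frequencies vs enumerated probabilities."""

    def test_founder_daughter_uniform_over_neighbors(self):
        # first event from a lone founder: each 4-neighbor w.p. 1/4
        fix = make_fixture("founder4")
        counts = {}
        n = 4000
        for seed in range(n):
            cfg = SimConfig(L=7, rho=0.0, N_target=2, seed=seed)
            r = run_colony(cfg)
            d = (int(r.log.daughter[0]) % 7, int(r.log.daughter[0]) // 7)
            counts[d] = counts.get(d, 0) + 1
        assert len(counts) == 4
        p = fix.expected["placement_prob"]
        sigma = np.sqrt(p * (1 - p) / n)
        for c in counts.values():
            assert abs(c / n - p) < 4 * sigma

    def test_selection_odds_between_two_rates(self):
        # WT and MT(s=0.2) mothers: second-division odds 1 : 1.2.
        # mu=1 makes the first daughter always mutant, regardless of seed.
        n = 6000
        mt_divides = 0
        for seed in range(n):
            cfg = SimConfig(L=9, rho=0.0, s=0.2, mu=1.0, N_target=3, seed=seed)
            r = run_colony(cfg)
            assert r.log.genotype[0] == 1
            if r.log.genotype[1] == 1 and r.log.mutated[1] == 0:
                # second daughter inherited MT: the mutant divided
                mother2 = r.log.mother[1]
                assert mother2 == r.log.daughter[0]
                mt_divides += 1
        p_expected = 1.2 / 2.2
        sigma = np.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(mt_divides / n - p_expected) < 4 * sigma

    def test_mu_one_always_mutates_wild_type(self):
        cfg = SimConfig(L=9, rho=0.0, mu=1.0, N_target=5, seed=11)
        r = run_colony(cfg)
        assert (r.log.genotype == 1).all()
        # first daughter founds a clone; mutants never re-mutate
        assert r.log.mutated[0] == 1


class TestRunColony:
    def test_homogeneous_growth_reaches_target(self):
        r = run_colony(SimConfig(L=101, rho=0.0, N_target=1000, seed=1))
        assert r.terminated_by == "reached_N"
        assert r.final_state.n_occupied == 1000

    def test_founder_ringed_by_obstacles_pins_immediately(self):
        r = run_colony(SimConfig(L=7, rho=1.0, k=0.0, N_target=10, seed=0))
        assert r.terminated_by == "pinned"
        assert r.final_state.n_occupied == 1

    def test_supercritical_density_pins_before_target(self):
        pinned = 0
        for seed in range(10):
            r = run_colony(
                SimConfig(L=151, rho=0.5, k=0.0, N_target=10000, seed=seed)
            )
            pinned += r.terminated_by == "pinned"
        assert pinned >= 9  # far above the percolation threshold

    def test_log_replay_reconstructs_final_state(self, disordered_colony):
        replayed = replay_final_state(disordered_colony)
        final = disordered_colony.final_state
        assert np.array_equal(replayed.occupied, final.occupied)
        assert np.array_equal(
            replayed.genotype[final.occupied > 0], final.genotype[final.occupied > 0]
        )
        assert np.array_equal(
            replayed.clone_id[final.occupied > 0], final.clone_id[final.occupied > 0]
        )

    def test_one_event_per_new_site(self, small_colony):
        assert len(small_colony.log) == small_colony.final_state.n_occupied - 1

    def test_k0_never_occupies_obstacles(self, disordered_colony):
        occ = disordered_colony.final_state.occupied > 0
        assert not (occ & disordered_colony.disorder.mask).any()

    def test_time_strictly_increasing(self, small_colony):
        assert (np.diff(small_colony.log.time) > 0).all()

    def test_mean_completion_time_nondecreasing_in_rho(self):
        # statistical monotonicity of time-to-N in rho at k=0
        means = []
        for rho in (0.0, 0.2, 0.35):
            ts = []
            for seed in range(15):
                r = run_colony(
                    SimConfig(L=151, rho=rho, k=0.0, N_target=2000, seed=3000 + seed)
                )
                if r.terminated_by == "reached_N":
                    ts.append(r.final_state.t_now)
            means.append(np.mean(ts))
        assert means[0] < means[1] < means[2]


class TestKOneNeutrality:
    def test_k1_trajectory_bit_identical_to_rho0(self):
        a = run_colony(SimConfig(L=101, rho=0.0, k=0.0, mu=0.01, N_target=1500, seed=5))
        b = run_colony(SimConfig(L=101, rho=0.7, k=1.0, mu=0.01, N_target=1500, seed=5))
        assert np.array_equal(a.log.daughter, b.log.daughter)
        assert np.array_equal(a.log.mother, b.log.mother)
        assert np.array_equal(a.log.clone_id, b.log.clone_id)
        assert np.allclose(a.log.time, b.log.time)


class TestRunLinear:
    def test_reaches_height_target(self, small_linear):
        assert small_linear.terminated_by == "reached_N"

    def test_supercritical_disorder_pins_at_finite_height(self):
        r = run_linear(
            SimConfig(L=64, geometry="linear", rho=0.6, k=0.0, h_target=200, seed=3)
        )
        assert r.terminated_by == "pinned"

    def test_k1_linear_identical_to_rho0(self):
        a = run_linear(SimConfig(L=32, geometry="linear", rho=0.0, k=0.0, h_target=20, seed=9))
        b = run_linear(SimConfig(L=32, geometry="linear", rho=0.5, k=1.0, h_target=20, seed=9))
        assert np.array_equal(a.log.daughter, b.log.daughter)


class TestDeterminism:
    def test_same_seed_same_run(self):
        a = run_colony(SimConfig(L=101, rho=0.2, k=0.1, mu=0.005, N_target=1000, seed=77))
        b = run_colony(SimConfig(L=101, rho=0.2, k=0.1, mu=0.005, N_target=1000, seed=77))
        assert np.array_equal(a.log.daughter, b.log.daughter)
        assert a.final_state.t_now == b.final_state.t_now
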