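"""Tests for front extraction, widths, speeds and exponent fits."""

import numpy as np
import pytest

from heterospread import (
    ColonyState,
    DisorderField,
    SimConfig,
    expansion_speed,
    extract_front,
    fit_power_law,
    height_profile,
    interface_widths,
    local_width,
    run_colony,
    run_linear,
    spanning_probability,
)
from heterospread.interface_analysis import estimate_critical_density


def _state_from_mask(occ):
    occ = np.asarray(occ, dtype=np.uint8)
    return ColonyState(
        occupied=occ,
        genotype=np.zeros_like(occ),
        clone_id=np.zeros(occ.shape, np.int32),
        t_now=0.0,
        n_occupied=int(occ.sum()),
        pinned=False,
    )


def _no_disorder(shape):
    return DisorderField(mask=np.zeros(shape, bool), rho_realized=0.0)


class TestExtractFront:
    def test_full_block_perimeter(self):
        occ = np.zeros((7, 7))
        occ[2:5, 2:5] = 1  # 3x3 block
        front = extract_front(_state_from_mask(occ), _no_disorder((7, 7)))
        assert len(front.sites) == 8  # all perimeter sites of a 3x3 block

    def test_enclosed_hole_excluded(self):
        # hand-built 7x7 ring: the interior hole boundary is not front
        occ = np.zeros((7, 7))
        occ[1:6, 1:6] = 1
        occ[3, 3] = 0  # enclosed hole
        front = extract_front(_state_from_mask(occ), _no_disorder((7, 7)))
        hole_neighbors = {(3, 2), (3, 4), (2, 3), (4, 3)}
        front_set = {tuple(s) for s in front.sites}
        # ring outer boundary: 16 sites; hole neighbors are interior
        assert front_set.isdisjoint(hole_neighbors) or all(
            fs not in hole_neighbors or occ[fs[1], fs[0] - 1] == 0 for fs in front_set
        )
        # outer boundary sites present
        assert (1, 1) in front_set and (5, 5) in front_set
        # hole-adjacent interior sites absent
        for site in hole_neighbors:
            assert site not in front_set

    def test_obstacle_blocked_corridor_not_exterior(self):
        # a pocket sealed by k=0 obstacles is not exterior-connected
        occ = np.zeros((7, 7))
        occ[2:5, 2:5] = 1
        occ[3, 4] = 0  # open pocket on the right edge of the block
        dis = np.zeros((7, 7), bool)
        dis[3, 5] = True  # obstacle seals the pocket
        field = DisorderField(mask=dis, rho_realized=dis.mean())
        front = extract_front(_state_from_mask(occ), field, k=0.0)
        front_set = {tuple(s) for s in front.sites}
        assert (4, 2) in front_set  # still on the outer front (above pocket)
        # (3,3) borders only the sealed pocket and interior sites: not front
        assert (3, 3) not in front_set


class TestHeightProfile:
    def test_initial_row_only(self):
        r = run_linear(SimConfig(L=16, geometry="linear", rho=0.0, h_target=0.01, seed=1))
        # no events required: profile of the base row is flat zero
        h = height_profile(r)
        assert (h >= 0).all()

    def test_single_added_cell(self):
        occ = np.zeros((5, 8), dtype=np.uint8)
        occ[0, :] = 1
        occ[1, 3] = 1
        state = _state_from_mask(occ)
        cfg = SimConfig(L=8, geometry="linear", rho=0.0, h_target=1, seed=0)
        from heterospread import SimResult, DivisionLog

        r = SimResult(
            config=cfg,
            final_state=state,
            log=DivisionLog(*[np.empty(0)] * 6, W=8),
            disorder=_no_disorder((5, 8)),
            terminated_by="reached_N",
        )
        h = height_profile(r)
        assert h[3] == 1 and h.sum() == 1

    def test_radial_rejected(self, small_colony):
        with pytest.raises(ValueError):
            height_profile(small_colony)


class TestWidths:
    def test_flat_profile_zero_width(self):
        assert local_width(np.full(32, 5.0), [4, 8])[0] == 0.0

    def test_alternating_profile_closed_form(self):
        # h alternating 0/1: rms deviation is exactly 0.5
        prof = np.tile([0.0, 1.0], 16)
        w = local_width(prof, [32])[0]
        assert w == pytest.approx(0.5)

    def test_global_width_saturates(self, small_linear):
        thr = np.geomspace(1, 100, 20)
        curves = interface_widths(small_linear, thr)
        # late widths stop growing: last three within 50% of each other
        late = curves.W_G[-3:]
        assert late.max() < 1.5 * late.min()
        assert (curves.W_G >= 0).all()

    def test_wloc_nondecreasing_in_window(self, small_linear):
        curves = interface_widths(small_linear, [50, 100])
        assert (np.diff(curves.W_loc) >= -1e-9).all()

    def test_wloc_at_L_equals_global(self, small_linear):
        prof = height_profile(small_linear)
        wloc = local_width(prof, [len(prof)])[0]
        assert wloc == pytest.approx(prof.std())

    def test_empty_snapshots_rejected(self, small_linear):
        with pytest.raises(ValueError):
            interface_widths(small_linear, [])


class TestFitPowerLaw:
    def test_exact_power_law_recovered(self):
        x = np.linspace(1, 50, 30)
        y = 2.0 * x**0.5
        slope, err, intercept = fit_power_law(x, y)
        assert slope == pytest.approx(0.5, abs=1e-12)
        assert err == pytest.approx(0.0, abs=1e-10)
        assert np.exp(intercept) == pytest.approx(2.0)

    def test_noisy_power_law_within_tolerance(self):
        rng = np.random.default_rng(0)
        x = np.geomspace(1, 100, 50)
        y = x**0.33 * np.exp(rng.normal(0, 0.01, 50))
        slope, _, _ = fit_power_law(x, y)
        assert slope == pytest.approx(0.33, abs=0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law(np.array([1, 2, -3.0]), np.array([1.0, 2, 3]))


class TestExpansionSpeed:
    def test_homogeneous_speed_positive_and_reproducible(self):
        runs = [
            run_colony(SimConfig(L=101, rho=0.0, N_target=3000, seed=s))
            for s in (1, 2, 3)
        ]
        est = expansion_speed(runs)
        assert est.v > 0
        est2 = expansion_speed(
            [run_colony(SimConfig(L=101, rho=0.0, N_target=3000, seed=1))]
        )
        single = expansion_speed([runs[0]])
        assert single.v == pytest.approx(est2.v)

    def test_pinned_run_reports_zero(self):
        r = run_colony(SimConfig(L=7, rho=1.0, k=0.0, N_target=10, seed=0))
        assert expansion_speed([r]).v == 0.0

    def test_speed_decreases_with_obstacle_density(self):
        def mean_speed(rho, seeds):
            runs = []
            for s in seeds:
                r = run_colony(SimConfig(L=151, rho=rho, k=0.0, N_target=2500, seed=s))
                if r.terminated_by == "reached_N":
                    runs.append(r)
            return expansion_speed(runs).v

        v20 = mean_speed(0.2, range(10))
        v35 = mean_speed(0.35, range(10))
        assert v20 > v35 > 0


class TestSpanning:
    def test_zero_density_always_spans(self):
        assert spanning_probability(0.0, 64, 0.0, reps=5, seed=1) == 1.0

    def test_far_supercritical_never_spans(self):
        assert spanning_probability(0.0, 64, 0.6, reps=10, seed=1) == 0.0

    def test_unbracketed_grid_rejected(self):
        with pytest.raises(ValueError):
            estimate_critical_density(0.0, 32, [0.05, 0.1], reps=5, seed=1)

    def test_spanning_probability_nonincreasing(self):
        probs = [
            spanning_probability(0.0, 64, rho, reps=40, seed=5)
            for rho in (0.1, 0.38, 0.55)
        ]
        assert probs[0] >= probs[1] >= probs[2]
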