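import dataclasses

import numpy as np
import pytest

from instpgg import (
    C1,
    C2,
    D1,
    D2,
    GammaUndefinedError,
    ModelParams,
    Protocol,
    Trajectory,
    bistability_probe,
    classify_phase,
    classify_point,
    detect_threshold,
    gamma_statistic,
    named_initial_condition,
    phase_scan,
    solve_replicator,
    time_average,
    time_averaged_gamma,
)


def synthetic_trajectory(freqs, params=None):
    freqs = np.asarray(freqs, dtype=float)
    params = params or ModelParams()
    totals = np.zeros_like(freqs) + params.pi0
    return Trajectory(
        times=np.arange(len(freqs)),
        freqs=freqs,
        payoffs_total=totals,
        payoffs_game=totals - params.pi0,
        params=params,
        initial_label="synthetic",
    )


class TestTimeAverage:
    def test_constant_series(self):
        traj = synthetic_trajectory(np.tile([0.1, 0.2, 0.3, 0.4], (50, 1)))
        ta = time_average(traj, 20)
        np.testing.assert_allclose(ta.mean_freqs, [0.1, 0.2, 0.3, 0.4])
        np.testing.assert_array_equal(ta.amplitudes, 0.0)

    def test_alternating_series(self):
        a = [0.1, 0.2, 0.3, 0.4]
        b = [0.3, 0.2, 0.1, 0.4]
        traj = synthetic_trajectory(np.array([a, b] * 25))
        ta = time_average(traj, 50)
        np.testing.assert_allclose(ta.mean_freqs, [0.2, 0.2, 0.2, 0.4])
        np.testing.assert_allclose(ta.amplitudes, [0.1, 0.0, 0.1, 0.0])

    def test_window_validation(self):
        traj = synthetic_trajectory(np.tile([0.25] * 4, (10, 1)))
        with pytest.raises(ValueError):
            time_average(traj, 0)
        with pytest.raises(ValueError):
            time_average(traj, 11)

    def test_red_queen_game_payoffs_fluctuate_around_zero(self, params):
        """In the red-queen orbit costly cooperators' and defectors' mean game
        payoffs are close to zero despite large frequency oscillations."""
        traj = solve_replicator(named_initial_condition("uniform"), params, 9000)
        ta = time_average(traj, 2000)
        assert abs(ta.mean_game_payoffs[C1]) < 0.05
        assert abs(ta.mean_game_payoffs[D1]) < 0.05


class TestGammaStatistic:
    def test_symmetric_state_gives_zero(self):
        assert gamma_statistic([0.25, 0.25, 0.25, 0.25]) == pytest.approx(0.0)

    def test_direct_evaluation(self):
        assert gamma_statistic([0.4, 0.1, 0.1, 0.4]) == pytest.approx(0.6)

    def test_empty_institution_is_an_error(self):
        with pytest.raises(GammaUndefinedError):
            gamma_statistic([0.0, 0.0, 0.5, 0.5])

    def test_bounded(self, rng):
        for rho in rng.dirichlet(np.ones(4), size=20):
            assert -1.0 <= gamma_statistic(rho) <= 1.0

    def test_time_averaged_gamma_on_symmetric_dynamics(self):
        """Institution-swap symmetry (equal r, equal costs, symmetric start)
        pins gamma at zero along the whole trajectory."""
        p = ModelParams(cg1=0.0, cg2=0.0, r1=2.0, r2=2.0)
        traj = solve_replicator(named_initial_condition("uniform"), p, 500)
        assert time_averaged_gamma(traj, 200) == pytest.approx(0.0, abs=1e-12)


class TestClassifyPhase:
    def test_defective_fixed_point(self):
        traj = synthetic_trajectory(np.tile([0.001, 0.004, 0.001, 0.994], (100, 1)))
        assert classify_phase(traj, 50).label == "DEFECT_FP"

    def test_red_queen_orbit(self):
        a = [0.30, 0.20, 0.01, 0.49]
        b = [0.10, 0.40, 0.01, 0.49]
        traj = synthetic_trajectory(np.array([a, b] * 50))
        assert classify_phase(traj, 50).label == "RED_QUEEN_ORBIT"

    def test_black_queen_orbit(self):
        a = [0.30, 0.20, 0.30, 0.20]
        b = [0.10, 0.40, 0.10, 0.40]
        traj = synthetic_trajectory(np.array([a, b] * 50))
        assert classify_phase(traj, 50).label == "BLACK_QUEEN_ORBIT"

    @pytest.mark.parametrize(
        "state,label",
        [
            ([0.55, 0.0, 0.45, 0.0], "COOP_FP"),
            ([0.99, 0.005, 0.0, 0.005], "COSTLY_COOP_FP"),
            ([0.0, 0.005, 0.99, 0.005], "NONCOSTLY_COOP_FP"),
            ([0.5, 0.5, 0.0, 0.0], "PARTIAL_COOP_FP"),
        ],
    )
    def test_fixed_point_sublabels(self, state, label):
        traj = synthetic_trajectory(np.tile(state, (100, 1)))
        assert classify_phase(traj, 50).label == label

    @pytest.mark.parametrize(
        "r,label",
        [(1.2, "DEFECT_FP"), (1.7, "RED_QUEEN_ORBIT"), (2.2, "BLACK_QUEEN_ORBIT")],
    )
    def test_replicator_regimes(self, r, label):
        p = ModelParams(r1=r, r2=r)
        assert classify_point(p).label == label

    def test_window_shift_invariance_on_converged_trajectory(self, params):
        traj = solve_replicator(named_initial_condition("uniform"), params, 9000)
        labels = {classify_phase(traj, 2000 + d).label for d in (-100, 0, 100)}
        assert labels == {"RED_QUEEN_ORBIT"}


class TestDetectThreshold:
    def test_not_found_below_first_threshold(self, params):
        grid = np.array([1.05, 1.1, 1.15, 1.2])
        res = detect_threshold(params, grid, "costly_coop_onset", Protocol(T=2000, window=500))
        assert not res.found and res.r is None

    def test_unknown_criterion(self, params):
        with pytest.raises(ValueError):
            detect_threshold(params, np.array([1.5]), "altruism_onset")

    def test_unsorted_grid_rejected(self, params):
        with pytest.raises(ValueError):
            detect_threshold(params, np.array([1.5, 1.2]), "costly_coop_onset")

    def test_costly_onset_tracks_entrance_cost(self):
        """The detected costly-cooperation onset is nondecreasing in cg,
        consistent with the analytic relation r* = 1 + cg."""
        grid = np.round(np.arange(1.05, 2.01, 0.05), 10)
        proto = Protocol(T=4000, window=1000)
        onsets = []
        for cg in (0.2, 0.4, 0.6):
            p = ModelParams(cg1=cg)
            res = detect_threshold(p, grid, "costly_coop_onset", proto)
            assert res.found
            onsets.append(res.r)
        assert onsets == sorted(onsets)
        for cg, r_star in zip((0.2, 0.4, 0.6), onsets):
            assert abs(r_star - (1 + cg)) < 0.15


class TestPhaseScan:
    def test_coarse_grid_layout_and_bookkeeping(self, params):
        grid = phase_scan(
            np.linspace(1.2, 2.6, 5),
            np.linspace(0.0, 0.8, 5),
            params,
            Protocol(T=8000, window=2000),
        )
        # bookkeeping identity: stored rho_C equals the sum of component means
        np.testing.assert_allclose(
            grid.rho_C, grid.mean_freqs[:, :, C1] + grid.mean_freqs[:, :, C2], atol=1e-14
        )
        labels = grid.labels
        assert all(label == "DEFECT_FP" for label in labels[0])  # low r
        assert "RED_QUEEN_ORBIT" in set(labels.ravel())
        assert "BLACK_QUEEN_ORBIT" in set(labels.ravel())

    def test_pure_selection_symmetric_costless_column(self):
        """With nu = 0 and no entrance cost the two institutions are exactly
        interchangeable: surviving profiles come in equal-density pairs."""
        p = ModelParams(cg1=0.0, nu=0.0, r1=2.0, r2=2.0)
        traj = solve_replicator(named_initial_condition("uniform"), p, 5000)
        ta = time_average(traj, 1000)
        assert abs(ta.mean_freqs[C1] - ta.mean_freqs[C2]) < 1e-3
        assert abs(ta.mean_freqs[D1] - ta.mean_freqs[D2]) < 1e-3


class TestBistabilityProbe:
    def test_high_cost_point_is_monostable(self, params):
        res = bistability_probe(1.7, 0.398, params)
        assert not res.bistable
        assert res.lower_branch.label == res.upper_branch.label

    def test_tiny_r_is_defective_from_both_starts(self, params):
        res = bistability_probe(0.8, 0.398, params, Protocol(T=2000, window=500))
        assert res.lower_branch.label == "DEFECT_FP"
        assert res.upper_branch.label == "DEFECT_FP"

    def test_low_cost_band_contains_a_bistable_cell(self, params):
        found = False
        for r in (1.6, 1.8, 2.0, 2.2):
            if bistability_probe(r, 0.1, params).bistable:
                found = True
                break
        assert found
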