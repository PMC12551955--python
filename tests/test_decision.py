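import numpy as np
import pytest

from tests.conftest import TOY_K, TOY_TREF
from vectorplan import (
    DecisionProblemSpec,
    ReleaseEvent,
    ReleaseSchedule,
    build_deterministic,
    build_stochastic,
    count_deployments,
    evaluate_objective,
    rollout_discrete,
    solve,
    total_released,
    verify_consistency,
)
from vectorplan.decision import biweekly_mask, weekly_mask
from vectorplan.dynamics import StateLayout, Trajectory, wild_female_series
from vectorplan.errors import ConfigurationError
from vectorplan.scenarios import ScenarioParams, ScenarioSet, generate_scenario

T_SMALL = 90
SOLVE_OPTS = {"maxiter": 120, "ftol": 1e-9}


def small_spec(**kw) -> DecisionProblemSpec:
    defaults = dict(
        t_end=T_SMALL,
        t_0=45,
        psi=0.30,
        release_mask=biweekly_mask(T_SMALL),
        c_max=5e4,
        n_sub=2,
    )
    defaults.update(kw)
    return DecisionProblemSpec(**defaults)


@pytest.fixture(scope="module")
def small_model(ridl_cube, toy_network, toy_equilibrium):
    temps = np.full(T_SMALL, TOY_TREF)
    return build_deterministic(
        small_spec(), ridl_cube, toy_network, temps, init_state=toy_equilibrium
    )


class TestSpecValidation:
    def test_defaults_match_policy_goal(self):
        spec = DecisionProblemSpec()
        assert spec.t_end == 365 and spec.t_0 == 200 and spec.psi == 0.20

    def test_masks(self):
        assert weekly_mask(28) == (1, 8, 15, 22)
        assert biweekly_mask(28) == (1, 15)
        assert set(biweekly_mask(365)) <= set(weekly_mask(365))

    @pytest.mark.parametrize(
        "kw",
        [
            dict(psi=0.0),
            dict(psi=1.5),
            dict(t_0=400),
            dict(release_mask=(0, 7)),
            dict(release_mask=(400,)),
            dict(n_sub=0),
            dict(c_max=-1.0),
            dict(tracking_window="sometimes"),
        ],
    )
    def test_invalid_spec(self, kw):
        with pytest.raises(ConfigurationError):
            DecisionProblemSpec(**kw)

    def test_window_days(self):
        spec = DecisionProblemSpec(t_end=10, t_0=7)
        assert spec.window_days.tolist() == [7, 8, 9, 10]
        spec = DecisionProblemSpec(t_end=10, t_0=7, tracking_window="full_horizon")
        assert spec.window_days.tolist() == list(range(1, 11))


def _micro_trajectory(f_values):
    """Single-node trajectory with the given wild-female (WW x WW) counts."""
    lay = StateLayout(3)
    states = np.zeros((len(f_values), 1, lay.n))
    states[:, 0, lay.F.start] = f_values
    return Trajectory(
        days=np.arange(1, len(f_values) + 1),
        states=states,
        node_names=("n",),
        genotype_labels=("WW", "RW", "RR"),
    )


class TestEvaluateObjective:
    def test_worked_micro_example(self, ridl_cube):
        # window {1,2}, psi=0.5, F_1=10, F_2=6, c_2=4 -> (10-5)^2 + 4 + (6-5)^2 = 30
        spec = DecisionProblemSpec(t_end=2, t_0=1, psi=0.5, release_mask=(2,))
        traj = _micro_trajectory([10.0, 6.0])
        sched = ReleaseSchedule(entries=(ReleaseEvent(2, "n", "RR", 4.0),), horizon=2)
        val = evaluate_objective(traj, [1.0], sched, spec, ridl_cube.genotypes)
        assert val == 30.0

    def test_perfect_tracking_is_zero(self, ridl_cube):
        spec = DecisionProblemSpec(t_end=3, t_0=2, psi=0.5, release_mask=())
        traj = _micro_trajectory([10.0, 5.0, 5.0])
        val = evaluate_objective(
            traj, [1.0], ReleaseSchedule.empty(3), spec, ridl_cube.genotypes
        )
        assert val == 0.0

    def test_duplicated_scenarios_equal_single(self, ridl_cube):
        spec = DecisionProblemSpec(t_end=2, t_0=1, psi=0.5, release_mask=(2,))
        traj = _micro_trajectory([10.0, 6.0])
        sched = ReleaseSchedule(entries=(ReleaseEvent(2, "n", "RR", 4.0),), horizon=2)
        one = evaluate_objective(traj, [1.0], sched, spec, ridl_cube.genotypes)
        two = evaluate_objective(
            (traj, traj), [0.5, 0.5], sched, spec, ridl_cube.genotypes
        )
        assert one == two

    def test_weight_mismatch(self, ridl_cube):
        spec = DecisionProblemSpec(t_end=2, t_0=1, psi=0.5)
        traj = _micro_trajectory([10.0, 6.0])
        with pytest.raises(ConfigurationError):
            evaluate_objective(
                (traj,), [0.5, 0.5], ReleaseSchedule.empty(2), spec, ridl_cube.genotypes
            )


class TestScheduleAccounting:
    def test_totals(self):
        sched = ReleaseSchedule(
            entries=(
                ReleaseEvent(200, "n", "RR", 3.0),
                ReleaseEvent(214, "n", "RR", 4.5),
            ),
            horizon=365,
        )
        assert total_released(sched) == 7.5
        assert total_released(ReleaseSchedule.empty(365)) == 0.0

    def test_reorder_invariance(self):
        e = [
            ReleaseEvent(200, "n", "RR", 3.0),
            ReleaseEvent(214, "n", "RR", 4.5),
            ReleaseEvent(228, "n", "RR", 2.0),
        ]
        assert total_released(
            ReleaseSchedule(entries=tuple(e), horizon=365)
        ) == total_released(ReleaseSchedule(entries=tuple(reversed(e)), horizon=365))

    def test_count_deployments(self):
        sched = ReleaseSchedule(
            entries=(
                ReleaseEvent(200, "n", "RR", 10.0),
                ReleaseEvent(214, "n", "RR", 10.0),
                ReleaseEvent(228, "n", "RR", 10.0),
            ),
            horizon=365,
        )
        assert count_deployments(sched) == 3
        assert count_deployments(ReleaseSchedule.empty(365)) == 0

    def test_subthreshold_release_not_a_trip(self):
        sched = ReleaseSchedule(
            entries=(ReleaseEvent(200, "n", "RR", 0.5),), horizon=365
        )
        assert count_deployments(sched, theta_trip=1.0) == 0

    def test_same_day_entries_pool_into_one_trip(self):
        sched = ReleaseSchedule(
            entries=(
                ReleaseEvent(200, "n", "RR", 0.6),
                ReleaseEvent(200, "n", "RR", 0.6),
            ),
            horizon=365,
        )
        assert count_deployments(sched) == 1


class TestGradients:
    def test_adjoint_matches_finite_differences(self, small_model):
        rng = np.random.default_rng(5)
        c = rng.uniform(0.0, 800.0, small_model.n_var)
        ga = small_model.gradient_adjoint(c)
        gf = small_model.gradient(c, 1e-2)
        np.testing.assert_allclose(ga, gf, rtol=1e-4, atol=1e-4)


class TestBuildAndSolve:
    def test_empty_mask_forces_zero_release(
        self, ridl_cube, toy_network, toy_equilibrium
    ):
        temps = np.full(T_SMALL, TOY_TREF)
        model = build_deterministic(
            small_spec(release_mask=()), ridl_cube, toy_network, temps,
            init_state=toy_equilibrium,
        )
        report = solve(model)
        assert report.n_deployments == 0
        assert total_released(report.schedule) == 0.0
        baseline = rollout_discrete(
            toy_equilibrium, temps, toy_network, ridl_cube, n_sub=2
        )
        np.testing.assert_array_equal(report.trajectories[0].states, baseline.states)

    def test_feasible_point_consistency_is_machine_precision(self, small_model):
        # hand-built feasible point: states generated from the schedule itself
        c = np.linspace(0.0, 900.0, small_model.n_var)
        quick = solve(small_model, {"maxiter": 2})
        hand = _fake_report(
            quick, small_model.trajectories(c), small_model.schedule_from(c)
        )
        assert verify_consistency(hand, small_model) <= 1e-12

    def test_corrupted_state_detected(self, small_model):
        report = solve(small_model, {"maxiter": 5})
        bad_states = report.trajectories[0].states.copy()
        bad_states[10] += 1.0
        bad = _fake_report(
            report,
            (
                Trajectory(
                    days=report.trajectories[0].days,
                    states=bad_states,
                    node_names=report.trajectories[0].node_names,
                    genotype_labels=report.trajectories[0].genotype_labels,
                ),
            ),
            report.schedule,
        )
        assert verify_consistency(bad, small_model) > 1e-6

    def test_psi_one_at_equilibrium_zero_release(
        self, ridl_cube, toy_network, toy_equilibrium
    ):
        temps = np.full(T_SMALL, TOY_TREF)
        model = build_deterministic(
            small_spec(psi=1.0), ridl_cube, toy_network, temps,
            init_state=toy_equilibrium,
        )
        report = solve(model, SOLVE_OPTS)
        assert report.total_organisms <= 1e-3
        assert report.objective_value <= 1e-3

    def test_objective_decomposition(self, small_model, ridl_cube):
        report = solve(small_model, SOLVE_OPTS)
        recomputed = evaluate_objective(
            report.trajectories,
            report.scenario_weights,
            report.schedule,
            small_model.spec,
            ridl_cube.genotypes,
        )
        assert report.objective_value == pytest.approx(recomputed, rel=1e-8)

    def test_solver_consistency_residual(self, small_model):
        report = solve(small_model, SOLVE_OPTS)
        assert verify_consistency(report, small_model) <= 1e-6

    def test_mask_compliance_exact(self, small_model):
        report = solve(small_model, SOLVE_OPTS)
        mask = set(small_model.spec.release_mask)
        assert all(e.day in mask for e in report.schedule.entries)

    def test_suppression_beats_baseline(self, small_model, ridl_cube):
        report = solve(small_model, SOLVE_OPTS)
        zero = small_model.trajectories(np.zeros(small_model.n_var))[0]
        wf_opt = wild_female_series(report.trajectories[0], ridl_cube.genotypes)
        wf_base = wild_female_series(zero, ridl_cube.genotypes)
        assert wf_opt[-1] < wf_base[-1]

    def test_budget_constraint_respected(
        self, ridl_cube, toy_network, toy_equilibrium
    ):
        temps = np.full(T_SMALL, TOY_TREF)
        budget = 500.0
        model = build_deterministic(
            small_spec(budget=budget), ridl_cube, toy_network, temps,
            init_state=toy_equilibrium,
        )
        report = solve(model, {"maxiter": 60})
        # SLSQP enforces feasibility to its own tolerance, not exactly
        assert report.total_organisms <= budget * (1 + 1e-5)
        assert report.max_constraint_violation <= budget * 1e-5

    def test_unknown_solver_option(self, small_model):
        with pytest.raises(ConfigurationError, match="unknown solver options"):
            solve(small_model, {"no_such_option": 1})

    def test_bad_x0_shape(self, small_model):
        with pytest.raises(ConfigurationError, match="x0"):
            solve(small_model, {"x0": np.zeros(3)})


def _fake_report(report, trajectories, schedule):
    from dataclasses import replace

    return replace(report, trajectories=tuple(trajectories), schedule=schedule)


class TestStochastic:
    def _series(self, seed, T=T_SMALL):
        return generate_scenario(
            ScenarioParams(T_mean=TOY_TREF, amplitude=1.5, ar1_rho=0.5, daily_sd=0.8, seed=seed),
            T,
        )

    def test_degenerate_single_scenario(self, ridl_cube, toy_network, toy_equilibrium):
        s1 = self._series(11)
        spec = small_spec()
        det = solve(
            build_deterministic(spec, ridl_cube, toy_network, s1, init_state=toy_equilibrium),
            SOLVE_OPTS,
        )
        sto = solve(
            build_stochastic(
                spec, ridl_cube, toy_network,
                ScenarioSet(series=(s1,), weights=np.array([1.0])),
                init_state=toy_equilibrium,
            ),
            SOLVE_OPTS,
        )
        assert (
            np.abs(sto.release_vector - det.release_vector).max()
            <= 1e-4 * spec.c_max
        )

    def test_zero_weight_scenario_inert(self, ridl_cube, toy_network, toy_equilibrium):
        s1, s2 = self._series(11), self._series(12)
        spec = small_spec()
        det = solve(
            build_deterministic(spec, ridl_cube, toy_network, s1, init_state=toy_equilibrium),
            SOLVE_OPTS,
        )
        sto = solve(
            build_stochastic(
                spec, ridl_cube, toy_network,
                ScenarioSet(series=(s1, s2), weights=np.array([1.0, 0.0])),
                init_state=toy_equilibrium,
            ),
            SOLVE_OPTS,
        )
        assert (
            np.abs(sto.release_vector - det.release_vector).max()
            <= 1e-4 * spec.c_max
        )

    def test_duplicated_scenarios_match_single(
        self, ridl_cube, toy_network, toy_equilibrium
    ):
        s1 = self._series(13)
        spec = small_spec()
        single = solve(
            build_stochastic(
                spec, ridl_cube, toy_network,
                ScenarioSet(series=(s1,), weights=np.array([1.0])),
                init_state=toy_equilibrium,
            ),
            SOLVE_OPTS,
        )
        double = solve(
            build_stochastic(
                spec, ridl_cube, toy_network,
                ScenarioSet(series=(s1, s1), weights=np.array([0.5, 0.5])),
                init_state=toy_equilibrium,
            ),
            SOLVE_OPTS,
        )
        np.testing.assert_allclose(
            double.release_vector, single.release_vector, atol=1e-6 * spec.c_max
        )

    def test_bad_weight_sum_rejected(self, ridl_cube, toy_network, toy_equilibrium):
        s1 = self._series(11)
        with pytest.raises(ConfigurationError):
            ScenarioSet(series=(s1,), weights=np.array([0.7]))


class TestMaskRelaxation:
    def test_weekly_warm_started_never_worse_than_biweekly(
        self, ridl_cube, toy_network, toy_equilibrium
    ):
        temps = np.full(T_SMALL, TOY_TREF)
        spec_bi = small_spec()
        m_bi = build_deterministic(
            spec_bi, ridl_cube, toy_network, temps, init_state=toy_equilibrium
        )
        r_bi = solve(m_bi, SOLVE_OPTS)
        spec_wk = small_spec(release_mask=weekly_mask(T_SMALL))
        m_wk = build_deterministic(
            spec_wk, ridl_cube, toy_network, temps, init_state=toy_equilibrium
        )
        # embed the bi-weekly optimum into the weekly variable space
        by_day = {d: c for (d, n), c in zip(m_bi.var_index, r_bi.release_vector)}
        x0 = np.array([by_day.get(d, 0.0) for d, n in m_wk.var_index])
        assert m_wk.objective(x0) == pytest.approx(r_bi.objective_value, rel=1e-10)
        r_wk = solve(m_wk, {**SOLVE_OPTS, "x0": x0})
        assert r_wk.objective_value <= r_bi.objective_value * (1 + 1e-4)
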