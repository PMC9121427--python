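"""Trajectory cost, coefficient of determination and parameter recovery."""

import numpy as np
import pytest

from slipgait.fitting import (
    KinematicTrajectory,
    fit_parameters,
    r_squared,
    trajectory_cost,
)
from slipgait.io_fixtures import FixtureSpec, generate_fixture
from slipgait.model_core import ModelParams


@pytest.fixture(scope="module")
def clean_fixture(trial_fixture_solution):
    spec = FixtureSpec(
        params=trial_fixture_solution.params, speed=2.86,
        noise_sigma=0.0, seed=1,
    )
    return generate_fixture(spec, solution=trial_fixture_solution)


class TestTrajectoryCost:
    def test_zero_for_self_trajectory(self, trial_fixture_solution, clean_fixture):
        assert trajectory_cost(trial_fixture_solution, clean_fixture) < 1e-12

    def test_constant_offset_in_y(self, trial_fixture_solution, clean_fixture):
        delta = 0.01
        shifted = KinematicTrajectory(
            t=clean_fixture.t,
            q=clean_fixture.q + np.array([0, delta, 0, 0]),
            qdot=clean_fixture.qdot,
        )
        T = clean_fixture.t[-1]
        cost = trajectory_cost(trial_fixture_solution, shifted)
        assert cost == pytest.approx(delta**2 * T, rel=1e-6)

    def test_invariant_to_x_origin(self, trial_fixture_solution, clean_fixture):
        shifted = KinematicTrajectory(
            t=clean_fixture.t,
            q=clean_fixture.q + np.array([5.0, 0, 0, 0]),
            qdot=clean_fixture.qdot,
        )
        c0 = trajectory_cost(trial_fixture_solution, clean_fixture)
        c1 = trajectory_cost(trial_fixture_solution, shifted)
        assert c1 == pytest.approx(c0, abs=1e-12)


class TestRSquared:
    def test_perfect_match_is_one(self, trial_fixture_solution, clean_fixture):
        for ch in ("x", "y", "alpha_l", "alpha_r"):
            assert r_squared(trial_fixture_solution, clean_fixture, ch) == (
                pytest.approx(1.0, abs=1e-9)
            )

    def test_zero_variance_channel_flagged(self, trial_fixture_solution, clean_fixture):
        flat = KinematicTrajectory(
            t=clean_fixture.t,
            q=np.column_stack(
                [clean_fixture.q[:, 0], np.ones(len(clean_fixture.t)),
                 clean_fixture.q[:, 2:]],
            ),
            qdot=clean_fixture.qdot,
        )
        with pytest.raises(ZeroDivisionError):
            r_squared(trial_fixture_solution, flat, "y")

    def test_unknown_channel_rejected(self, trial_fixture_solution, clean_fixture):
        with pytest.raises(ValueError):
            r_squared(trial_fixture_solution, clean_fixture, "z")


class TestParameterRecovery:
    def test_noiseless_recovery_from_perturbed_init(
        self, trial_fixture_solution, clean_fixture
    ):
        true = trial_fixture_solution.params
        init = ModelParams(
            omega=true.omega * 1.1,
            phi_l=true.phi_l + 0.05,
            phi_r=true.phi_r * 0.9,
        )
        res = fit_parameters(clean_fixture, init=init)
        assert res.params.omega == pytest.approx(true.omega, rel=1e-2)
        assert res.params.phi_l == pytest.approx(true.phi_l, abs=1e-3)
        assert res.params.phi_r == pytest.approx(true.phi_r, abs=1e-3)
        assert all(v > 0.999 for v in res.r2.values())

    def test_noisy_recovery_median_errors(self, trial_fixture_solution):
        # repeated-seed study at noise sigma = 0.005 lo
        true = trial_fixture_solution.params
        errs_om, errs_phl, errs_phr = [], [], []
        for seed in range(8):
            spec = FixtureSpec(
                params=true, speed=2.86, noise_sigma=0.005, seed=seed,
            )
            traj = generate_fixture(spec, solution=trial_fixture_solution)
            init = ModelParams(
                omega=true.omega * 1.05, phi_l=true.phi_l + 0.03,
                phi_r=true.phi_r - 0.03,
            )
            try:
                res = fit_parameters(traj, init=init)
            except Exception:
                continue
            errs_om.append(abs(res.params.omega - true.omega) / true.omega)
            errs_phl.append(abs(res.params.phi_l - true.phi_l))
            errs_phr.append(abs(res.params.phi_r - true.phi_r))
        assert len(errs_om) >= 6
        assert np.median(errs_om) < 0.02
        assert np.median(errs_phl) < 0.02
        assert np.median(errs_phr) < 0.02

    def test_trial_like_r_squared_range(self, trial_fixture_solution):
        # fits of trial-like noisy strides reach the empirical-quality range
        spec = FixtureSpec(
            params=trial_fixture_solution.params, speed=2.86,
            noise_sigma=0.003, seed=3,
        )
        traj = generate_fixture(spec, solution=trial_fixture_solution)
        res = fit_parameters(traj, init=trial_fixture_solution.params,
                             seed=trial_fixture_solution)
        assert all(v >= 0.83 for v in res.r2.values())
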