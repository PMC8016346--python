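"""Redundancy solver: static optimization seeding, small solves, reports."""

import numpy as np
import pytest

from myotendon import limb_geometry as lg
from myotendon import redundancy_solver as rs
from myotendon import synthetic_data as sd
from myotendon.mtu_model import MuscleParams


@pytest.fixture(scope="module")
def tiny_bundle():
    """Cheap 1-DOF, 2-MTU walk/run bundle for solver unit tests."""
    return sd.make_study_bundle(seed=1, n_dof=1, n_mtu=2, n_samples=41)


def _single_muscle_trial(arm=0.010, fmax=10.0, m_ext=0.05, n=11):
    p = MuscleParams(
        name="solo", m=1e-3, ell_o=0.02, L_S=1e-9, alpha_o=0.0, F_max=fmax,
        k_T=1e6, tau_act=0.007, tau_deact=0.027,
    )
    c0 = p.L_S + p.ell_o
    geom = lg.MTUGeometry("solo", ["q1"], [((0,), c0), ((1,), -arm)])
    limb = lg.LimbModel(dofs=[lg.DOFSpec("q1", -0.5, 0.5)], mtus=[(p, geom)])
    time = np.linspace(0, 0.5, n)
    q = np.zeros((n, 1))
    m = np.full((n, 1), m_ext)
    trial = lg.derive_trial_geometry(limb, time, q, m, "iso")
    return limb, trial


def test_weights_defaults_and_validation():
    w = rs.ObjectiveWeights()
    assert (w.w1, w.w2, w.w3, w.w4, w.w5, w.w6) == (2.0, 500.0, 1.0, 100.0, 2.0, 1.0)
    with pytest.raises(ValueError):
        rs.ObjectiveWeights(w2=-1.0)


def test_static_seed_zero_moments_zero_activation():
    limb, trial = _single_muscle_trial(m_ext=0.0)
    seed = rs.static_optimization_seed([trial], limb)[0]
    np.testing.assert_allclose(seed["a"], 0.0, atol=1e-10)


def test_static_seed_hand_moment_balance():
    # a * F_max * arm = M  ->  a = 0.05 / (10 * 0.01) = 0.5 at the optimum pose
    limb, trial = _single_muscle_trial(arm=0.010, fmax=10.0, m_ext=0.05)
    seed = rs.static_optimization_seed([trial], limb, reserves_enabled=False)[0]
    np.testing.assert_allclose(seed["a"], 0.5, atol=1e-6)


def test_static_seed_no_cocontraction(tiny_bundle):
    limb, trials, _ = tiny_bundle
    trial = trials[0]
    zero = lg.GaitTrial(
        label="zero", time=trial.time, q=trial.q, M_ext=np.zeros_like(trial.M_ext),
        lmt=trial.lmt, arms=trial.arms, dof_names=trial.dof_names,
        muscle_names=trial.muscle_names, duty_factor=trial.duty_factor,
    )
    seed = rs.static_optimization_seed([zero], limb, reserves_enabled=False)[0]
    # antagonists may only fight each other's passive force; with fibres near
    # or below optimum the minimum-cost solution is essentially full rest
    assert np.max(seed["a"]) < 0.05


def test_solve_zero_moment_trial_rest_solution(tiny_bundle):
    """A trial demanding no moments is solved by (near-)zero activations and
    a near-zero objective with tuning factors staying at one."""
    limb, trials, _ = tiny_bundle
    trial = trials[0]
    zero = lg.GaitTrial(
        label="zero", time=trial.time, q=trial.q, M_ext=np.zeros_like(trial.M_ext),
        lmt=trial.lmt, arms=trial.arms, dof_names=trial.dof_names,
        muscle_names=trial.muscle_names, duty_factor=trial.duty_factor,
    )
    sol = rs.solve_redundancy([zero], limb, mesh=10, freeze_tuning=False, maxiter=300)
    assert sol.feasible
    assert np.max(np.abs(sol.trials[0].activation)) < 0.02
    np.testing.assert_allclose(sol.tuning.p_ell, 1.0, atol=0.02)
    np.testing.assert_allclose(sol.tuning.p_L, 1.0, atol=0.02)
    assert sol.objective < 0.01
    # activation bounds respected
    assert sol.trials[0].activation.min() >= -1e-8
    assert sol.trials[0].activation.max() <= 1 + 1e-8


def test_small_recovery_and_feasibility(tiny_bundle):
    """Mesh-10 solve of a noise-free 1-DOF bundle recovers the ground truth
    closely and satisfies all transcribed constraints."""
    limb, trials, truths = tiny_bundle
    sol = rs.solve_redundancy([trials[0]], limb, mesh=12, freeze_tuning=True, maxiter=300)
    assert sol.feasible and sol.constr_violation < 1e-6
    ts = sol.trials[0]
    truth_a = np.column_stack(
        [np.interp(ts.time, trials[0].time, truths[0].activations[:, m]) for m in range(2)]
    )
    rmse = np.sqrt(np.mean((ts.activation - truth_a) ** 2, axis=0))
    assert np.all(rmse < 0.03)
    assert np.abs(ts.reserve).max() < 0.1


def test_duplicate_trial_idempotent_tuning(tiny_bundle):
    """Solving the same trial listed twice yields the same tuning factors as
    solving it once (the shared coupling adds no spurious pull)."""
    limb, trials, _ = tiny_bundle
    one = rs.solve_redundancy([trials[0]], limb, mesh=10, maxiter=250)
    two = rs.solve_redundancy([trials[0], trials[0]], limb, mesh=10, maxiter=250)
    np.testing.assert_allclose(two.tuning.p_ell, one.tuning.p_ell, atol=0.02)
    np.testing.assert_allclose(two.tuning.p_L, one.tuning.p_L, atol=0.02)


def test_reserve_report_arithmetic():
    sol = rs.RedundancySolution(
        trials=[
            rs.TrialSolution(
                label="t", time=np.linspace(0, 1, 5),
                excitation=np.zeros((5, 1)), activation=np.zeros((5, 1)),
                f_til=np.zeros((5, 1)), tendon_force=np.zeros((5, 1)),
                ell_norm=np.ones((5, 1)), v_norm=np.zeros((5, 1)),
                f_passive=np.zeros((5, 1)),
                reserve=np.full((5, 1), 0.1), duty_factor=0.6,
            )
        ],
        tuning=rs.TuningFactors(np.ones(1), np.ones(1)),
        objective=0.0, objective_breakdown={}, status="", converged=True,
        feasible=True, constr_violation=0.0, n_iter=0, solve_time=0.0,
        muscle_names=["m"], dof_names=["q"], reserve_caps={"q": 0.02},
    )
    trial = lg.GaitTrial(
        label="t", time=np.linspace(0, 1, 5), q=np.zeros((5, 1)),
        M_ext=np.full((5, 1), 0.04), lmt=np.full((5, 1), 0.03),
        arms=np.zeros((5, 1, 1)), dof_names=["q"], muscle_names=["m"],
        duty_factor=0.6,
    )
    rep = rs.reserve_contribution_report(sol, [trial])
    # |0.1 * 0.02| / 0.04 = 0.05
    assert rep["t"]["q"]["max"] == pytest.approx(0.05)
    assert rep["t"]["q"]["stance_mean"] == pytest.approx(0.05)


def test_reserves_disabled_zero_fraction(tiny_bundle):
    limb, trials, _ = tiny_bundle
    sol = rs.solve_redundancy(
        [trials[0]], limb, mesh=10, freeze_tuning=True, reserves_enabled=False,
        maxiter=200,
    )
    rep = rs.reserve_contribution_report(sol, [trials[0]])
    assert all(v["max"] == 0.0 for v in rep[trials[0].label].values())


def test_solution_roundtrip(tmp_path, tiny_bundle):
    limb, trials, _ = tiny_bundle
    sol = rs.solve_redundancy([trials[0]], limb, mesh=10, freeze_tuning=True, maxiter=150)
    rs.save_solution(sol, tmp_path / "sol")
    back = rs.load_solution(tmp_path / "sol")
    np.testing.assert_allclose(back.trials[0].activation, sol.trials[0].activation, atol=1e-12)
    np.testing.assert_allclose(back.trials[0].f_til, sol.trials[0].f_til, atol=1e-9)
    np.testing.assert_allclose(back.tuning.p_ell, sol.tuning.p_ell)
    assert back.reserve_caps == sol.reserve_caps


def test_reserve_weight_monotonicity():
    """Raising the reserve penalty never increases converged reserve usage.

    Noisy moments force genuine reserve use; the integrated squared reserve
    activation must be non-increasing across three w2 settings."""
    limb, trials, _ = sd.make_study_bundle(seed=2, n_dof=1, n_mtu=2, n_samples=41,
                                           noise_sd=2e-3)
    usages = []
    for w2 in (5.0, 50.0, 500.0):
        sol = rs.solve_redundancy(
            [trials[0]], limb, weights=rs.ObjectiveWeights(w2=w2), mesh=10,
            freeze_tuning=True, maxiter=250,
        )
        assert sol.feasible
        ts = sol.trials[0]
        dt = np.gradient(ts.time)
        usages.append(float(np.sum(dt[:, None] * ts.reserve**2)))
    assert usages[0] >= usages[1] - 1e-9 >= usages[2] - 2e-9


def test_large_passive_penalty_limits_fibre_stretch(tiny_bundle):
    """With the passive-force weight made very large, converged fibres stay
    at or below optimal length (to a small margin) because the tuning pushes
    them off the descending limb."""
    limb, trials, _ = tiny_bundle
    sol = rs.solve_redundancy(
        trials[:1], limb, weights=rs.ObjectiveWeights(w4=1e5), mesh=10,
        freeze_tuning=False, maxiter=300,
    )
    assert sol.feasible
    assert float(np.max(sol.trials[0].ell_norm)) <= 1.05


def test_mesh_validation(tiny_bundle):
    limb, trials, _ = tiny_bundle
    with pytest.raises(ValueError, match="mesh"):
        rs.solve_redundancy([trials[0]], limb, mesh=5)
    with pytest.raises(ValueError, match="trial"):
        rs.solve_redundancy([], limb)
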