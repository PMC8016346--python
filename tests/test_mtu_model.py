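"""Hill-type MTU model: parameterization, curves, equilibrium, dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

from myotendon import mtu_model as mm
from myotendon.synthetic_data import tinamou_table


# ---------------------------------------------------------------------------
# architecture parameterization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "mass_g, ell_mm, expected_N, tol",
    [
        (1.35, 15.5, 24.65, 5e-4),    # iliotrochantericus caudalis (ant.)
        (2.55, 24.2, 29.816, 5e-3),   # gastrocnemius lateralis (rounded inputs)
        (2.49, 62.2, 11.324, 5e-3),   # iliotibialis cranialis
        (0.0, 10.0, 0.0, 0.0),
    ],
)
def test_fmax_matches_printed_architecture(mass_g, ell_mm, expected_N, tol):
    got = mm.compute_fmax(mass_g * 1e-3, ell_mm * 1e-3)
    assert got == pytest.approx(expected_N, rel=tol, abs=1e-12)


def test_fmax_scaling_linearity():
    base = mm.compute_fmax(2e-3, 0.03)
    assert mm.compute_fmax(4e-3, 0.03) == pytest.approx(2 * base, rel=1e-12)
    assert mm.compute_fmax(2e-3, 0.06) == pytest.approx(base / 2, rel=1e-12)


def test_fmax_rejects_bad_inputs():
    with pytest.raises(ValueError):
        mm.compute_fmax(1e-3, 0.0)
    with pytest.raises(ValueError):
        mm.compute_fmax(-1e-3, 0.01)


def test_fixture_fmax_reproduced_for_most_rows():
    """Eq-1 force from printed mass and fibre length matches the printed
    F_max within 1% for at least 30 of the 36 rows (known anomalous rows
    excluded: their printed forces presumably used unrounded inputs)."""
    anomalies = {"FMTL", "ILFB", "ILPOa", "ILPOp", "OL"}
    df = tinamou_table()
    n_ok = 0
    for row in df.itertuples():
        got = mm.compute_fmax(row.mass_g * 1e-3, row.fibre_length_mm * 1e-3)
        rel = abs(got - row.fmax_N) / row.fmax_N
        if rel < 0.01:
            n_ok += 1
        else:
            assert row.abbreviation in anomalies, (
                f"{row.abbreviation}: {got:.3f} vs printed {row.fmax_N}"
            )
    assert n_ok >= 30


def test_tendon_stiffness_hand_value():
    # E*A_T chosen so the numerator equals the pennation-adjusted F_max -> 1
    const = mm.TissueConstants()
    m, ell, alpha = 2e-3, 0.02, math.radians(20)
    EA = m * const.sigma * math.cos(alpha) / (const.rho_muscle * ell)
    k = mm.compute_tendon_stiffness(EA, 1.0, m, ell, alpha, const)
    assert k == pytest.approx(1.0, rel=1e-12)
    # hand evaluation
    k2 = mm.compute_tendon_stiffness(1.2e9, 0.5e-6, 2.55e-3, 24.2e-3, math.radians(30))
    assert k2 == pytest.approx(23.2, rel=2e-3)
    # linear in tendon cross-section
    assert mm.compute_tendon_stiffness(
        1.2e9, 1.0e-6, 2.55e-3, 24.2e-3, math.radians(30)
    ) == pytest.approx(2 * k2, rel=1e-12)


def test_time_constant_body_mass_scaling():
    tact = mm.scale_time_constant(0.015, 64.8, 0.545)
    tdeact = mm.scale_time_constant(0.060, 64.8, 0.545)
    assert round(tact, 3) == 0.007
    assert round(tdeact, 3) == 0.027
    assert mm.scale_time_constant(0.02, 5.0, 5.0) == pytest.approx(0.02)
    with pytest.raises(ValueError):
        mm.scale_time_constant(0.02, 0.0, 1.0)


@pytest.mark.parametrize(
    "lmin_mm, lmax_mm, ell_mm, alpha_deg, expected_mm",
    [
        (20.0, 30.0, 10.0, 0.0, 15.0),
        (20.0, 32.0, 10.0, 0.0, 16.0),
        (20.0, 30.0, 10.0, 30.0, 17.92893),
    ],
)
def test_slack_length_first_approximation(lmin_mm, lmax_mm, ell_mm, alpha_deg, expected_mm):
    got = mm.estimate_slack_length(
        lmin_mm * 1e-3, lmax_mm * 1e-3, ell_mm * 1e-3, math.radians(alpha_deg)
    )
    assert got == pytest.approx(expected_mm * 1e-3, rel=1e-5)


def test_slack_length_clamped_non_negative():
    assert mm.estimate_slack_length(0.004, 0.016, 0.010, 0.0) >= 0.0


# ---------------------------------------------------------------------------
# characteristic curves
# ---------------------------------------------------------------------------


def test_curve_anchors_exact():
    assert mm.active_force_length(1.0) == pytest.approx(1.0, abs=1e-12)
    assert mm.passive_force_length(1.0) == pytest.approx(0.0, abs=1e-12)
    assert mm.force_velocity(0.0) == pytest.approx(1.0, abs=1e-12)
    assert mm.tendon_force_strain(1.0, 100.0) == pytest.approx(0.0, abs=1e-12)


def test_active_curve_shape():
    assert mm.active_force_length(0.5) < mm.active_force_length(0.8) < 1.0
    assert mm.active_force_length(1.4) < 1.0
    # peak is at the optimum within grid resolution
    grid = np.linspace(0.3, 1.7, 1401)
    assert abs(grid[np.argmax(mm.active_force_length(grid))] - 1.0) < 0.02


def test_passive_curve_zero_below_optimum_then_monotone():
    x = np.linspace(0.3, 1.0, 50)
    assert np.all(mm.passive_force_length(x) == 0.0)
    y = mm.passive_force_length(np.linspace(1.0, 1.8, 100))
    assert np.all(np.diff(y) > 0)
    assert mm.passive_force_length(1.6) == pytest.approx(1.0, rel=1e-12)


def test_force_velocity_monotone_and_limits():
    v = np.linspace(-1.0, 0.5, 200)
    f = mm.force_velocity(v)
    assert np.all(np.diff(f) > 0)
    assert abs(mm.force_velocity(-1.0)) < 0.02  # ~zero at maximal shortening
    assert mm.force_velocity(0.5) > 1.0


@pytest.mark.parametrize("k_T", [35.0, 100.0, 1000.0])
def test_tendon_curve_recalibrated_per_stiffness(k_T):
    """Zero at unit strain ratio and slope k_T (to 10%) where f_T = 1,
    whatever the stiffness; inverse and compliance are consistent."""
    assert mm.tendon_force_strain(1.0, k_T) == pytest.approx(0.0, abs=1e-14)
    x1 = float(mm.tendon_strain_from_force(1.0, k_T))
    fd = (mm.tendon_force_strain(x1 + 1e-7, k_T) - mm.tendon_force_strain(x1 - 1e-7, k_T)) / 2e-7
    assert fd == pytest.approx(k_T, rel=0.1)
    f = np.linspace(0.0, 2.0, 30)
    x = mm.tendon_strain_from_force(f, k_T)
    np.testing.assert_allclose(mm.tendon_force_strain(x, k_T), f, atol=1e-12)
    fd2 = (mm.tendon_strain_from_force(0.5 + 1e-7, k_T) - mm.tendon_strain_from_force(0.5 - 1e-7, k_T)) / 2e-7
    assert fd2 == pytest.approx(float(mm.tendon_strain_derivative(0.5, k_T)), rel=1e-5)


def test_evaluate_hill_curves_bundle():
    f_act, f_pass, f_v, f_T = mm.evaluate_hill_curves(1.0, 0.0, 1.0, 100.0)
    assert (f_act, f_pass, f_v, f_T) == pytest.approx((1.0, 0.0, 1.0, 0.0), abs=1e-12)
    with pytest.raises(ValueError):
        mm.evaluate_hill_curves(-0.1, 0.0, 1.0)


@given(st.floats(0.3, 1.7), st.floats(0.3, 1.7))
@settings(max_examples=50, deadline=None)
def test_passive_curve_monotone_property(x1, x2):
    lo, hi = sorted((x1, x2))
    assert mm.passive_force_length(lo) <= mm.passive_force_length(hi) + 1e-15


# ---------------------------------------------------------------------------
# pennation and fibre state
# ---------------------------------------------------------------------------


def test_pennation_angle(pennate_muscle, plain_muscle):
    assert mm.pennation_angle(pennate_muscle.ell_o, pennate_muscle) == pytest.approx(
        pennate_muscle.alpha_o
    )
    assert mm.pennation_angle(0.05, plain_muscle) == 0.0
    got = mm.pennation_angle(2 * pennate_muscle.ell_o, pennate_muscle)
    assert got == pytest.approx(math.asin(0.25), rel=1e-12)
    with pytest.raises(mm.InfeasibleGeometryError):
        mm.pennation_angle(0.5 * pennate_muscle.thickness, pennate_muscle)


def test_fibre_state_slack_tendon(plain_muscle):
    st_ = mm.fibre_state_from_tendon_force(
        0.0, plain_muscle.L_S + plain_muscle.ell_o, plain_muscle
    )
    assert st_.ell_norm == pytest.approx(1.0, rel=1e-12)
    assert st_.alpha == 0.0


def test_fibre_state_shortens_with_force(pennate_muscle):
    l_mt = pennate_muscle.L_S + pennate_muscle.ell_o
    ells = [
        mm.fibre_state_from_tendon_force(f, l_mt, pennate_muscle).ell
        for f in np.linspace(0, 1, 10)
    ]
    assert np.all(np.diff(ells) < 0)


def test_fibre_state_infeasible_geometry(plain_muscle):
    with pytest.raises(mm.InfeasibleGeometryError):
        mm.fibre_state_from_tendon_force(1.0, plain_muscle.L_S * 0.9, plain_muscle)


# ---------------------------------------------------------------------------
# static equilibrium
# ---------------------------------------------------------------------------


def _bisect_oracle(a, l_mt, params, tol=1e-14):
    """Independent bracketing root of the static residual in F~."""
    f_hi = a * 1.1 + 50.0
    lo, hi = 0.0, f_hi
    while mm._static_residual(hi, a, l_mt, params) > 0:
        hi *= 2
    return bisect(mm._static_residual, lo, hi, args=(a, l_mt, params), xtol=tol)


def test_rigid_tendon_limit():
    p = mm.MuscleParams(
        name="rigid", m=1e-3, ell_o=0.02, L_S=0.03, alpha_o=0.0, F_max=10.0,
        k_T=1e6, tau_act=0.007, tau_deact=0.027,
    )
    for a in (0.0, 0.5, 1.0):
        st_ = mm.solve_static_equilibrium(a, p.L_S + p.ell_o, p)
        assert st_.ell_norm == pytest.approx(1.0, abs=1e-4)


def test_activation_shortens_fibre(pennate_muscle):
    l_mt = pennate_muscle.L_S + 0.95 * pennate_muscle.ell_o
    s0 = mm.solve_static_equilibrium(0.0, l_mt, pennate_muscle)
    s1 = mm.solve_static_equilibrium(1.0, l_mt, pennate_muscle)
    assert s1.ell <= s0.ell
    for s, a in ((s0, 0.0), (s1, 1.0)):
        assert abs(mm.equilibrium_residual(s, a, pennate_muscle)) < 1e-6


def test_slack_system_zero_residual(plain_muscle):
    st_ = mm.solve_static_equilibrium(0.0, plain_muscle.L_S + 0.9 * plain_muscle.ell_o, plain_muscle)
    assert st_.F_T == pytest.approx(0.0, abs=1e-9 * plain_muscle.F_max)
    assert mm.equilibrium_residual(st_, 0.0, plain_muscle) == pytest.approx(0.0, abs=1e-12)


def test_equilibrium_residual_sign_change(pennate_muscle):
    l_mt = pennate_muscle.L_S + 0.95 * pennate_muscle.ell_o
    eq = mm.solve_static_equilibrium(0.7, l_mt, pennate_muscle).F_T / pennate_muscle.F_max
    below = mm._static_residual(0.8 * eq, 0.7, l_mt, pennate_muscle)
    above = mm._static_residual(1.2 * eq, 0.7, l_mt, pennate_muscle)
    assert below > 0 > above


def test_equilibrium_infeasible_below_slack(plain_muscle):
    with pytest.raises(mm.InfeasibleGeometryError):
        mm.solve_static_equilibrium(0.5, plain_muscle.L_S * 0.99, plain_muscle)


def test_equilibrium_matches_bisection_oracle():
    """Safeguarded solver vs an independent bisection oracle on random draws."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        ell_o = rng.uniform(0.01, 0.06)
        p = mm.MuscleParams(
            name="r", m=1e-3, ell_o=ell_o,
            L_S=rng.uniform(0.1, 4.0) * ell_o,
            alpha_o=math.radians(rng.uniform(0, 35)),
            F_max=rng.uniform(1, 30), tau_act=0.007, tau_deact=0.027,
        )
        a = rng.uniform(0, 1)
        l_mt = p.L_S + rng.uniform(0.6, 1.4) * p.ell_o
        got = mm.solve_static_equilibrium(a, l_mt, p).F_T / p.F_max
        want = _bisect_oracle(a, l_mt, p)
        assert got == pytest.approx(want, rel=1e-8, abs=1e-10)


def test_batch_equilibrium_agrees_with_scalar(pennate_muscle):
    a = np.array([0.0, 0.3, 0.8, 1.0])
    l_mt = pennate_muscle.L_S + np.array([0.7, 0.9, 1.1, 1.3]) * pennate_muscle.ell_o
    ft, ln, ok = mm.solve_static_equilibrium_batch(a, l_mt, pennate_muscle)
    assert ok.all()
    for i in range(4):
        st_ = mm.solve_static_equilibrium(a[i], l_mt[i], pennate_muscle)
        assert ft[i] == pytest.approx(st_.F_T / pennate_muscle.F_max, abs=1e-9)
        assert ln[i] == pytest.approx(st_.ell_norm, abs=1e-9)


def test_batch_flags_infeasible(plain_muscle):
    ft, ln, ok = mm.solve_static_equilibrium_batch(
        0.5, np.array([plain_muscle.L_S * 0.5, plain_muscle.L_S + plain_muscle.ell_o]),
        plain_muscle,
    )
    assert not ok[0] and ok[1]
    assert np.isnan(ft[0]) and np.isfinite(ft[1])


# ---------------------------------------------------------------------------
# activation dynamics
# ---------------------------------------------------------------------------


def test_activation_steady_state(plain_muscle):
    assert mm.activation_dynamics_residual(0.4, 0.4, 0.0, plain_muscle) == pytest.approx(0.0)


def test_activation_step_response_time_scales(plain_muscle):
    p = plain_muscle

    def integrate(e, a0, t_end):
        sol = solve_ivp(
            lambda t, a: mm.activation_rate(e, a, p), (0, t_end), [a0],
            rtol=1e-9, atol=1e-12, dense_output=True,
        )
        return sol

    up = integrate(1.0, 0.0, 5 * p.tau_act)
    t63 = next(t for t in np.linspace(0, 5 * p.tau_act, 2000) if up.sol(t)[0] >= 0.632)
    assert t63 == pytest.approx(p.tau_act, rel=0.2)

    down = integrate(0.0, 1.0, 5 * p.tau_deact)
    t37 = next(t for t in np.linspace(0, 5 * p.tau_deact, 2000) if down.sol(t)[0] <= 0.368)
    assert t37 == pytest.approx(p.tau_deact, rel=0.2)


def test_excitation_inversion_roundtrip(plain_muscle):
    rng = np.random.default_rng(3)
    a = rng.uniform(0.05, 0.9, 20)
    e_true = np.clip(a + rng.uniform(-0.05, 0.1, 20), 0, 1)
    dadt = mm.activation_rate(e_true, a, plain_muscle)
    e = mm.excitation_from_rate(a, dadt, plain_muscle)
    np.testing.assert_allclose(e, e_true, atol=1e-8)
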