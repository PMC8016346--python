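"""Hill-type muscle-tendon unit (MTU) model.

An MTU is a muscle belly (contractile + parallel passive element) in series
with an elastic tendon, reduced to a force along a line of action.  The belly
is characterised by its optimal fibre length ``ell_o`` (length of peak active
isometric force), pennation angle ``alpha_o`` at that length, and maximal
isometric force ``F_max``; the tendon by its slack length ``L_S`` and a
dimensionless stiffness ``k_T`` (normalised slope of its force-strain curve).

Conventions used throughout:

* normalised fibre length  ``ell* = ell / ell_o``
* normalised fibre velocity ``v*  = (d ell/dt) / (v_max * ell_o)`` (shortening
  negative), i.e. the argument of the force-velocity curve
* normalised tendon force  ``F~ = F_T / F_max``
* pennation follows the constant-muscle-thickness rule
  ``ell * sin(alpha) = ell_o * sin(alpha_o)``.

All quantities are SI (m, N, s, kg, rad) unless a name says otherwise.

The characteristic curves are smooth (C1), algorithmically differentiable
forms: a Gaussian-sum active force-length curve, an exponential passive curve
that is exactly zero at and below ``ell* = 1``, a logarithmic (arcsinh)
force-velocity curve, and an exponential tendon curve whose constants are
re-solved for each ``k_T`` so that the curve is exactly zero at unit strain
ratio and has slope exactly ``k_T`` where the tendon carries ``F_max``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

__all__ = [
    "TissueConstants",
    "MuscleParams",
    "MuscleState",
    "InfeasibleGeometryError",
    "EquilibriumConvergenceError",
    "compute_fmax",
    "compute_tendon_stiffness",
    "scale_time_constant",
    "estimate_slack_length",
    "active_force_length",
    "passive_force_length",
    "force_velocity",
    "force_velocity_inverse",
    "tendon_force_strain",
    "tendon_strain_from_force",
    "tendon_strain_derivative",
    "evaluate_hill_curves",
    "pennation_angle",
    "fibre_state_from_tendon_force",
    "equilibrium_residual",
    "solve_static_equilibrium",
    "solve_static_equilibrium_batch",
    "activation_rate",
    "activation_dynamics_residual",
    "excitation_from_rate",
]

# Numerical damping on the fibre force (fraction of F_max per unit v*),
# regularising the equilibrium inversion; standard in implicit formulations.
DAMPING_BETA = 0.01

# Fibre length floor above the constant-thickness height (m).
FIBRE_LENGTH_EPS = 1e-6

# Normalised fibre length band outside which curve evaluation is logged.
EXTRAPOLATION_BAND = (0.2, 1.8)


class InfeasibleGeometryError(ValueError):
    """MTU geometry admits no equilibrium (e.g. path shorter than the tendon)."""


class EquilibriumConvergenceError(RuntimeError):
    """Root finding for muscle-tendon equilibrium failed to converge."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueConstants:
    """Bulk tissue properties of vertebrate skeletal muscle and tendon."""

    sigma: float = 300_000.0        # max isometric muscle stress, N/m^2
    rho_muscle: float = 1060.0      # muscle density, kg/m^3
    E_tendon: float = 1.2e9         # tendon Young's modulus, Pa
    rho_tendon: float = 1120.0      # tendon density, kg/m^3

    def __post_init__(self) -> None:
        for name in ("sigma", "rho_muscle", "E_tendon", "rho_tendon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class MuscleParams:
    """Architecture and physiology of one muscle-tendon unit."""

    name: str
    m: float                        # belly mass, kg
    ell_o: float                    # optimal fibre length, m
    L_S: float                      # tendon slack length, m
    alpha_o: float                  # pennation at ell_o, rad
    F_max: float                    # maximal isometric force, N
    k_T: float = 100.0              # dimensionless tendon stiffness
    v_max: float = 10.0             # max shortening velocity, ell_o/s
    tau_act: float = 0.015          # activation time constant, s
    tau_deact: float = 0.060        # deactivation time constant, s

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("belly mass must be non-negative")
        if self.ell_o <= 0:
            raise ValueError("optimal fibre length must be positive")
        if self.L_S < 0:
            raise ValueError("tendon slack length must be non-negative")
        if not 0 <= self.alpha_o < math.pi / 2:
            raise ValueError("pennation angle must lie in [0, pi/2)")
        if self.F_max < 0:
            raise ValueError("F_max must be non-negative")
        if self.k_T <= 0 or self.v_max <= 0:
            raise ValueError("k_T and v_max must be positive")
        if not 0 < self.tau_act <= self.tau_deact:
            raise ValueError("require 0 < tau_act <= tau_deact")

    @property
    def thickness(self) -> float:
        """Constant muscle thickness ``ell_o * sin(alpha_o)`` (m)."""
        return self.ell_o * math.sin(self.alpha_o)

    def tuned(self, p_ell: float = 1.0, p_L: float = 1.0) -> "MuscleParams":
        """Return a copy with fibre/slack lengths scaled by tuning factors."""
        return replace(self, ell_o=self.ell_o * p_ell, L_S=self.L_S * p_L)


@dataclass
class MuscleState:
    """Instantaneous mechanical state of one MTU."""

    a: float                        # activation, 0-1
    F_T: float                      # tendon force, N
    ell: float                      # fibre length, m
    ell_norm: float                 # ell / ell_o
    v_norm: float = 0.0             # normalised fibre velocity
    alpha: float = 0.0              # instantaneous pennation, rad
    F_passive: float = 0.0          # passive fibre force (along fibre), N


# ---------------------------------------------------------------------------
# architecture parameterization
# ---------------------------------------------------------------------------


def compute_fmax(m: float, ell_o: float, constants: TissueConstants | None = None) -> float:
    """Maximal isometric force from belly mass and optimal fibre length.

    ``F_max = m * sigma / (rho_muscle * ell_o)``: the physiological
    cross-sectional area ``m / (rho * ell_o)`` times the maximum muscle
    stress.  Pennation is deliberately not applied here; it enters the
    contraction geometry instead.
    """
    constants = constants or TissueConstants()
    if ell_o <= 0:
        raise ValueError("optimal fibre length must be positive")
    if m < 0:
        raise ValueError("belly mass must be non-negative")
    return m * constants.sigma / (constants.rho_muscle * ell_o)


def compute_tendon_stiffness(
    E: float,
    A_T: float,
    m: float,
    ell_o: float,
    alpha_o: float,
    constants: TissueConstants | None = None,
) -> float:
    """Dimensionless tendon stiffness ``k_T = E*A_T / (F_max * cos(alpha_o))``.

    Expanded with the mass-based F_max this is
    ``E * A_T * rho_muscle * ell_o / (m * sigma * cos(alpha_o))``.  The
    pennation factor appears because the whole MTU is reduced to a force along
    its line of action, so the reference force for the in-series tendon is the
    projected maximal fibre force.
    """
    constants = constants or TissueConstants()
    if min(E, A_T, m, ell_o) <= 0:
        raise ValueError("E, A_T, m and ell_o must be positive")
    if not 0 <= alpha_o < math.pi / 2:
        raise ValueError("pennation angle must lie in [0, pi/2)")
    return E * A_T * constants.rho_muscle * ell_o / (m * constants.sigma * math.cos(alpha_o))


def scale_time_constant(tau_ref: float, m_ref: float, m_target: float) -> float:
    """Scale an activation/deactivation time constant by body mass^(1/6)."""
    if m_ref <= 0 or m_target <= 0:
        raise ValueError("body masses must be positive")
    if tau_ref <= 0:
        raise ValueError("time constant must be positive")
    return tau_ref * (m_target / m_ref) ** (1.0 / 6.0)


def _projected_fibre(ell: float, thickness: float) -> float:
    """Length of the fibre projected on the line of action (0 if degenerate)."""
    rad = ell * ell - thickness * thickness
    return math.sqrt(rad) if rad > 0 else 0.0


def estimate_slack_length(
    l_MT_min: float, l_MT_max: float, ell_o: float, alpha_o: float = 0.0
) -> float:
    """First-approximation tendon slack length.

    Assumes the fibre should be able to span 0.5-1.5x ``ell_o`` as the MTU
    sweeps its full length range: the two one-equation estimates
    ``L_S = l_MT_min - w(0.5 ell_o)`` and ``L_S = l_MT_max - w(1.5 ell_o)``
    (``w`` the pennation-projected fibre length) are combined by least squares,
    i.e. averaged, and clamped at zero.
    """
    if not l_MT_min < l_MT_max:
        raise ValueError("require l_MT_min < l_MT_max")
    if ell_o <= 0:
        raise ValueError("optimal fibre length must be positive")
    h = ell_o * math.sin(alpha_o)
    lo = l_MT_min - _projected_fibre(0.5 * ell_o, h)
    hi = l_MT_max - _projected_fibre(1.5 * ell_o, h)
    return max(0.0, 0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# characteristic curves
# ---------------------------------------------------------------------------

# Gaussian-sum active force-length constants (rows: b1, b2, b3, b4), normalised
# below so the curve is exactly 1 at ell* = 1.
_FL_ACT = np.array(
    [
        [0.814483478343008, 1.055033428970575, 0.162384573599574, 0.063303448465465],
        [0.433004984392647, 0.716775413397760, -0.029947116970696, 0.200356847296188],
        [0.100, 1.000, 0.353553390593274, 0.000],
    ]
)


def _fl_act_raw(ell_norm):
    x = np.asarray(ell_norm, dtype=float)
    total = np.zeros_like(x)
    for b1, b2, b3, b4 in _FL_ACT:
        den = b3 + b4 * x
        total = total + b1 * np.exp(-0.5 * ((x - b2) / den) ** 2)
    return total


_FL_ACT_NORM = float(_fl_act_raw(1.0))


def active_force_length(ell_norm):
    """Active force-length multiplier; exactly 1 at ``ell* = 1``."""
    return _fl_act_raw(ell_norm) / _FL_ACT_NORM


def _fl_act_raw_deriv(ell_norm):
    x = np.asarray(ell_norm, dtype=float)
    total = np.zeros_like(x)
    for b1, b2, b3, b4 in _FL_ACT:
        den = b3 + b4 * x
        z = (x - b2) / den
        dz = (den - (x - b2) * b4) / den**2
        total = total + b1 * np.exp(-0.5 * z * z) * (-z * dz)
    return total


def active_force_length_deriv(ell_norm):
    return _fl_act_raw_deriv(ell_norm) / _FL_ACT_NORM


# Passive curve: zero at and below ell* = 1, C1 at the junction, reaching 1 at
# ell* = 1 + _PASSIVE_E0 with exponential shape constant _PASSIVE_KPE.
_PASSIVE_KPE = 4.0
_PASSIVE_E0 = 0.6
_PASSIVE_NORM = math.expm1(_PASSIVE_KPE) - _PASSIVE_KPE


def passive_force_length(ell_norm):
    """Passive force-length multiplier; 0 for ``ell* <= 1``, 1 at ``ell* = 1.6``."""
    x = np.asarray(ell_norm, dtype=float)
    z = np.maximum(x - 1.0, 0.0) * (_PASSIVE_KPE / _PASSIVE_E0)
    return (np.expm1(z) - z) / _PASSIVE_NORM


def passive_force_length_deriv(ell_norm):
    x = np.asarray(ell_norm, dtype=float)
    z = np.maximum(x - 1.0, 0.0) * (_PASSIVE_KPE / _PASSIVE_E0)
    return np.expm1(z) * (_PASSIVE_KPE / _PASSIVE_E0) / _PASSIVE_NORM


# Force-velocity curve (arcsinh form); anchored so f_v(0) = 1 exactly.
_FV_D1 = -0.318323436899127
_FV_D2 = -8.149156043475250
_FV_D3 = -0.374121508647863
_FV_D4 = 1.0 - _FV_D1 * math.asinh(_FV_D3)


def force_velocity(v_norm):
    """Force-velocity multiplier of ``v* = v / (v_max ell_o)``; 1 at v* = 0."""
    v = np.asarray(v_norm, dtype=float)
    return _FV_D1 * np.arcsinh(_FV_D2 * v + _FV_D3) + _FV_D4


def force_velocity_deriv(v_norm):
    v = np.asarray(v_norm, dtype=float)
    z = _FV_D2 * v + _FV_D3
    return _FV_D1 * _FV_D2 / np.sqrt(z * z + 1.0)


def force_velocity_inverse(f_v):
    """Normalised velocity at which the force-velocity multiplier equals f_v."""
    f = np.asarray(f_v, dtype=float)
    return (np.sinh((f - _FV_D4) / _FV_D1) - _FV_D3) / _FV_D2


# Tendon force-strain curve: f_T(x) = c * (exp(khat (x - 1)) - 1) with
# x = l_T / L_S.  Constants are re-solved per k_T: zero force at x = 1 is exact
# and the slope where f_T = 1 equals k_T exactly (khat = k_T / (1 + c)).
_TENDON_C = 0.2


def _tendon_khat(k_T: float) -> float:
    return k_T / (1.0 + _TENDON_C)


def tendon_force_strain(strain_ratio, k_T: float = 100.0):
    """Normalised tendon force from the length ratio ``x = l_T / L_S``."""
    x = np.asarray(strain_ratio, dtype=float)
    return _TENDON_C * np.expm1(_tendon_khat(k_T) * (x - 1.0))


def tendon_strain_from_force(f_T, k_T: float = 100.0):
    """Inverse tendon curve: length ratio ``l_T / L_S`` carrying force f_T."""
    f = np.asarray(f_T, dtype=float)
    return 1.0 + np.log1p(f / _TENDON_C) / _tendon_khat(k_T)


def tendon_strain_derivative(f_T, k_T: float = 100.0):
    """d(l_T / L_S)/d f_T along the tendon curve (compliance)."""
    f = np.asarray(f_T, dtype=float)
    return 1.0 / (_tendon_khat(k_T) * (f + _TENDON_C))


def evaluate_hill_curves(ell_norm, v_norm, tendon_strain_ratio, k_T: float = 100.0):
    """Evaluate all four characteristic multipliers at once.

    Returns ``(f_act, f_pass, f_v, f_T)``.  Inputs may be scalars or arrays.
    Fibre lengths outside the calibrated band are permitted (the static pose
    battery reaches extreme postures) but logged.
    """
    x = np.asarray(ell_norm, dtype=float)
    if np.any(x <= 0) or np.any(np.asarray(tendon_strain_ratio, dtype=float) <= 0):
        raise ValueError("normalised lengths must be positive")
    n_out = int(np.sum((x < EXTRAPOLATION_BAND[0]) | (x > EXTRAPOLATION_BAND[1])))
    if n_out:
        logger.info(
            "evaluating Hill curves outside ell* in [%.1f, %.1f] at %d point(s)",
            *EXTRAPOLATION_BAND,
            n_out,
        )
    return (
        active_force_length(ell_norm),
        passive_force_length(ell_norm),
        force_velocity(v_norm),
        tendon_force_strain(tendon_strain_ratio, k_T),
    )


# ---------------------------------------------------------------------------
# pennation geometry and equilibrium
# ---------------------------------------------------------------------------


def pennation_angle(ell: float, params: MuscleParams) -> float:
    """Instantaneous pennation from the constant-thickness rule."""
    h = params.thickness
    if ell < h:
        raise InfeasibleGeometryError(
            f"{params.name}: fibre length {ell:.6g} m below muscle thickness {h:.6g} m"
        )
    if h == 0.0:
        return 0.0
    return math.asin(h / ell)


def fibre_state_from_tendon_force(
    F_T_norm: float, l_MT: float, params: MuscleParams
) -> MuscleState:
    """Fibre lengths implied by a normalised tendon force at a given MTU length.

    The tendon length follows from the inverse tendon curve; the fibre spans
    the remainder of the path, closing the constant-thickness triangle.
    """
    if F_T_norm < -0.5 * _TENDON_C:
        # The smooth tendon curve tolerates slightly negative forces (its toe
        # region), which implicit damped formulations can transiently produce;
        # anything further is a usage error.
        raise ValueError("tendon force below the smooth-curve toe region")
    l_T = params.L_S * float(tendon_strain_from_force(F_T_norm, params.k_T))
    span = l_MT - l_T
    if span <= 0:
        raise InfeasibleGeometryError(
            f"{params.name}: MTU length {l_MT:.6g} m does not exceed tendon length {l_T:.6g} m"
        )
    h = params.thickness
    ell = math.hypot(span, h)
    ell_norm = ell / params.ell_o
    alpha = math.atan2(h, span)
    return MuscleState(
        a=math.nan,
        F_T=F_T_norm * params.F_max,
        ell=ell,
        ell_norm=ell_norm,
        alpha=alpha,
        F_passive=float(passive_force_length(ell_norm)) * params.F_max,
    )


def equilibrium_residual(state: MuscleState, a: float, params: MuscleParams) -> float:
    """Dimensionless muscle-tendon force balance residual.

    ``(a f_act(ell*) f_v(v*) + f_pass(ell*) + beta v*) cos(alpha) - F_T/F_max``;
    zero at physical equilibrium.
    """
    f_act = float(active_force_length(state.ell_norm))
    f_pass = float(passive_force_length(state.ell_norm))
    f_v = float(force_velocity(state.v_norm))
    fibre = a * f_act * f_v + f_pass + DAMPING_BETA * state.v_norm
    return fibre * math.cos(state.alpha) - state.F_T / params.F_max


def _static_residual(F_til: float, a: float, l_MT: float, params: MuscleParams) -> float:
    """Residual as a function of normalised tendon force at v* = 0."""
    l_T = params.L_S * float(tendon_strain_from_force(F_til, params.k_T))
    span = l_MT - l_T
    if span <= 0:
        return -(F_til + 1.0)
    h = params.thickness
    ell = math.hypot(span, h)
    ell_norm = ell / params.ell_o
    cos_alpha = span / ell
    fibre = a * float(active_force_length(ell_norm)) + float(passive_force_length(ell_norm))
    return fibre * cos_alpha - F_til


def solve_static_equilibrium(a: float, l_MT: float, params: MuscleParams) -> MuscleState:
    """Solve muscle-tendon equilibrium at zero fibre velocity.

    Raises :class:`InfeasibleGeometryError` when the pose admits no
    equilibrium (``l_MT <= L_S``, or the fibre would be compressed below the
    constant-thickness floor), and :class:`EquilibriumConvergenceError` when
    bracketing fails for numerical reasons.
    """
    if not 0 <= a <= 1:
        raise ValueError("activation must lie in [0, 1]")
    if l_MT <= params.L_S:
        raise InfeasibleGeometryError(
            f"{params.name}: MTU length {l_MT:.6g} m at or below slack length {params.L_S:.6g} m"
        )
    if params.L_S == 0.0:
        # Rigid (zero-length) tendon: the fibre spans the whole path.
        state = _rigid_state(a, l_MT, params)
        return state

    h = params.thickness
    ell0 = math.hypot(l_MT - params.L_S, h)
    # Upper bracket: projected fibre force can never exceed this.
    f_hi = a * 1.1 + float(passive_force_length(ell0 / params.ell_o)) + 1.0
    # Geometric cap: tendon cannot be longer than the path less the floor.
    span_min = FIBRE_LENGTH_EPS
    ratio_cap = (l_MT - span_min) / params.L_S
    if ratio_cap > 1.0:
        z = min(_tendon_khat(params.k_T) * (ratio_cap - 1.0), 40.0)
        f_hi = min(f_hi, _TENDON_C * math.expm1(z))
    else:
        raise InfeasibleGeometryError(f"{params.name}: no room for the fibre at this pose")

    r0 = _static_residual(0.0, a, l_MT, params)
    if r0 <= 0.0:
        # Slack system: zero force is the equilibrium (r0 == 0 up to rounding).
        return _state_at(0.0, a, l_MT, params)
    r_hi = _static_residual(f_hi, a, l_MT, params)
    if r_hi > 0.0:
        raise InfeasibleGeometryError(
            f"{params.name}: fibre compressed to the thickness floor (no equilibrium)"
        )
    try:
        f_eq = brentq(_static_residual, 0.0, f_hi, args=(a, l_MT, params), xtol=1e-14, rtol=1e-15)
    except RuntimeError as exc:  # pragma: no cover - safeguard
        raise EquilibriumConvergenceError(str(exc)) from exc
    return _state_at(float(f_eq), a, l_MT, params)


def _rigid_state(a: float, l_MT: float, params: MuscleParams) -> MuscleState:
    h = params.thickness
    span = l_MT
    ell = math.hypot(span, h)
    ell_norm = ell / params.ell_o
    cos_alpha = span / ell
    f_til = (a * float(active_force_length(ell_norm)) + float(passive_force_length(ell_norm))) * cos_alpha
    return MuscleState(
        a=a,
        F_T=f_til * params.F_max,
        ell=ell,
        ell_norm=ell_norm,
        alpha=math.atan2(h, span),
        F_passive=float(passive_force_length(ell_norm)) * params.F_max,
    )


def _state_at(F_til: float, a: float, l_MT: float, params: MuscleParams) -> MuscleState:
    state = fibre_state_from_tendon_force(F_til, l_MT, params)
    state.a = a
    state.v_norm = 0.0
    return state


def solve_static_equilibrium_batch(
    a, l_MT, params: MuscleParams, n_iter: int = 90
):
    """Vectorised bisection solve of static equilibrium over arrays.

    Parameters are one MTU's; ``a`` and ``l_MT`` broadcast against each other.
    Returns ``(F_til, ell_norm, feasible)`` where infeasible entries (path at
    or below slack length, or fibre crushed) carry NaN and ``feasible`` False.
    """
    a = np.asarray(a, dtype=float)
    l_MT = np.asarray(l_MT, dtype=float)
    a, l_MT = np.broadcast_arrays(a, l_MT)
    shape = a.shape
    a = a.ravel()
    l_MT = l_MT.ravel()
    h = params.thickness
    khat = _tendon_khat(params.k_T)

    feasible = l_MT > params.L_S + FIBRE_LENGTH_EPS

    def residual(f_til):
        l_T = params.L_S * (1.0 + np.log1p(f_til / _TENDON_C) / khat)
        span = l_MT - l_T
        bad = span <= 0
        span_safe = np.where(bad, 1.0, span)
        ell = np.hypot(span_safe, h)
        ell_norm = ell / params.ell_o
        cos_alpha = span_safe / ell
        fibre = a * active_force_length(ell_norm) + passive_force_length(ell_norm)
        out = fibre * cos_alpha - f_til
        return np.where(bad, -(f_til + 1.0), out)

    ell0 = np.hypot(np.maximum(l_MT - params.L_S, FIBRE_LENGTH_EPS), h)
    hi = a * 1.1 + passive_force_length(ell0 / params.ell_o) + 1.0
    if params.L_S > 0:
        ratio_cap = np.maximum((l_MT - FIBRE_LENGTH_EPS) / params.L_S, 1.0 + 1e-12)
        hi = np.minimum(hi, _TENDON_C * np.expm1(np.minimum(khat * (ratio_cap - 1.0), 40.0)))
    lo = np.zeros_like(hi)
    r_lo = residual(lo)
    r_hi = residual(hi)
    crushed = feasible & (r_hi > 0)
    feasible = feasible & ~crushed
    slack = feasible & (r_lo <= 0)

    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        r_mid = residual(mid)
        take_hi = r_mid > 0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    f_til = np.where(slack, 0.0, 0.5 * (lo + hi))
    f_til = np.where(feasible, f_til, np.nan)

    l_T = params.L_S * (1.0 + np.log1p(np.where(feasible, f_til, 0.0) / _TENDON_C) / khat)
    span = np.maximum(l_MT - l_T, FIBRE_LENGTH_EPS)
    ell_norm = np.hypot(span, h) / params.ell_o
    ell_norm = np.where(feasible, ell_norm, np.nan)
    return f_til.reshape(shape), ell_norm.reshape(shape), feasible.reshape(shape)


# ---------------------------------------------------------------------------
# excitation-activation dynamics
# ---------------------------------------------------------------------------

_BLEND_WIDTH = 0.1


def activation_rate(e, a, params: MuscleParams):
    """First-order activation rate with a smooth act/deact blend.

    ``da/dt = (e - a) * (s / tau_act + (1 - s) / tau_deact)`` with a tanh
    switch ``s`` in the sign of ``e - a``, giving a C-infinity blend between
    the activation and deactivation time constants.
    """
    e = np.asarray(e, dtype=float)
    a = np.asarray(a, dtype=float)
    d = e - a
    s = 0.5 * (1.0 + np.tanh(d / _BLEND_WIDTH))
    return d * (s / params.tau_act + (1.0 - s) / params.tau_deact)


def activation_rate_partials(e, a, params: MuscleParams):
    """Partial derivatives (d rate/d e, d rate/d a) of :func:`activation_rate`."""
    e = np.asarray(e, dtype=float)
    a = np.asarray(a, dtype=float)
    d = e - a
    t = np.tanh(d / _BLEND_WIDTH)
    s = 0.5 * (1.0 + t)
    gain = s / params.tau_act + (1.0 - s) / params.tau_deact
    dgain = (0.5 * (1.0 - t * t) / _BLEND_WIDTH) * (1.0 / params.tau_act - 1.0 / params.tau_deact)
    dd = gain + d * dgain
    return dd, -dd


def activation_dynamics_residual(e: float, a: float, dadt: float, params: MuscleParams) -> float:
    """Residual of the excitation-activation ODE: ``dadt - rate(e, a)``."""
    if not (0 <= np.min(e) and np.max(e) <= 1 and 0 <= np.min(a) and np.max(a) <= 1):
        raise ValueError("excitation and activation must lie in [0, 1]")
    return dadt - activation_rate(e, a, params)


def excitation_from_rate(a, dadt, params: MuscleParams, clip: bool = True):
    """Invert the activation dynamics: excitation producing ``dadt`` at ``a``.

    Solved per element by bisection on the monotone rate function; optionally
    clipped to [0, 1] (rates outside the achievable envelope saturate).
    """
    a = np.asarray(a, dtype=float)
    dadt = np.asarray(dadt, dtype=float)
    a, dadt = np.broadcast_arrays(a, dadt)
    lo = np.full(a.shape, -0.5)
    hi = np.full(a.shape, 1.5)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        r = activation_rate(mid, a, params) - dadt
        lo = np.where(r < 0, mid, lo)
        hi = np.where(r < 0, hi, mid)
    e = 0.5 * (lo + hi)
    return np.clip(e, 0.0, 1.0) if clip else e
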