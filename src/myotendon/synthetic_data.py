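"""Synthetic limb models and gait trials with known ground truth.

The inverse (muscle-redundancy) problem and the static posture battery are
exercised here on toy limbs whose architecture spreads mimic a small ground
bird's hindlimb (masses of a gram to a few grams, fibre lengths of one to a
few centimetres, pennation up to 35 degrees, tendon slack lengths from a
twentieth to several multiples of fibre length).  Gait trials are built the
way the physics runs forward: smooth periodic joint kinematics are prescribed,
ground-truth activations drive each MTU's contraction dynamics along its
path-length trajectory, and the external joint moments are *defined* as the
moments those tendon forces produce about each joint.  A trial generated this
way is, by construction, an exactly feasible point of the redundancy problem
with zero reserve usage, so recovery of activations and tuning factors is
testable against known truth.

Ground-truth activation profiles are smoothed boxcar bursts: for each
antagonist pair, the muscle with the positive moment arm fires during stance
and its antagonist during swing, with transition widths slow enough that the
implied excitations stay within [0, 1] given the deactivation time constant.
Disjoint bursts keep the load sharing of the toy problem essentially unique,
which is what makes activation recovery a meaningful test.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from . import mtu_model as mm
from .limb_geometry import (
    DOFSpec,
    GaitTrial,
    LimbModel,
    MTUGeometry,
    moment_arms,
    mtu_length,
)
from .mtu_model import MuscleParams, TissueConstants

__all__ = [
    "GaitSpec",
    "GaitKinematics",
    "GroundTruth",
    "WALK_SPEC",
    "RUN_SPEC",
    "make_toy_limb",
    "make_gait_kinematics",
    "make_activation_profiles",
    "forward_generate_trial",
    "make_study_bundle",
    "tinamou_fixture",
    "tinamou_table",
]


@dataclass(frozen=True)
class GaitSpec:
    """Stride-level description of one locomotor trial."""

    speed: float          # m/s
    duty_factor: float    # stance fraction of the stride
    stride_time: float    # s
    n_samples: int = 101
    label: str = "walk"

    def __post_init__(self) -> None:
        if not 0 < self.duty_factor < 1:
            raise ValueError("duty factor must lie in (0, 1)")
        if self.n_samples < 20:
            raise ValueError("need at least 20 samples per stride")


# Default two-trial study conditions: a slow walk and a grounded run.
WALK_SPEC = GaitSpec(speed=0.39, duty_factor=0.71, stride_time=0.70, label="walk")
RUN_SPEC = GaitSpec(speed=1.39, duty_factor=0.57, stride_time=0.55, label="run")


@dataclass
class GaitKinematics:
    """Joint-angle time series for one stride."""

    time: np.ndarray
    q: np.ndarray           # (n, n_dof) rad
    duty_factor: float
    label: str


@dataclass
class GroundTruth:
    """The known quantities a recovery experiment is scored against."""

    activations: np.ndarray      # (n, n_mtu), 0-1
    excitations: np.ndarray      # (n, n_mtu), 0-1
    tendon_forces: np.ndarray    # (n, n_mtu), N
    p_ell: np.ndarray            # (n_mtu,) fibre-length tuning factors
    p_L: np.ndarray              # (n_mtu,) slack-length tuning factors
    M_clean: np.ndarray          # (n, n_dof) noise-free external moments, N*m


# ---------------------------------------------------------------------------
# toy limb generation
# ---------------------------------------------------------------------------


def make_toy_limb(
    n_dof: int = 2,
    n_mtu: int = 4,
    seed: int = 0,
    constants: TissueConstants | None = None,
    ln_mid: dict[str, float] | None = None,
) -> LimbModel:
    """Random toy limb with guaranteed antagonist coverage of every DOF.

    The first ``2 * n_dof`` MTUs form monoarticular antagonist pairs (one per
    moment sense per DOF); any further MTUs are biarticular with random
    couplings.  Architecture is sampled over spreads typical of a small bird
    hindlimb: pennation 0-35 deg, slack-to-fibre-length ratio 0.05-8, maximal
    isometric force 0.6-30 N.  Bit-reproducible for a given seed.

    ``ln_mid`` optionally fixes the normalised fibre length of named MTUs
    (``mtu1``, ``mtu2``, ...) at the neutral (range-centre) pose; the default
    samples it near 1.  Values above ~1.1 pose a muscle slightly stretched,
    so its passive force participates in the joint moments — the regime in
    which fibre-length tuning is identifiable from gait data.
    """
    if n_dof < 1:
        raise ValueError("need at least one DOF")
    if n_mtu < max(2, 2 * n_dof):
        raise ValueError(
            f"need at least {max(2, 2 * n_dof)} MTUs to give every DOF an antagonist pair"
        )
    constants = constants or TissueConstants()
    rng = np.random.default_rng(seed)

    dofs = []
    for j in range(n_dof):
        centre = rng.uniform(-0.2, 0.2)
        half = rng.uniform(0.5, 0.8)
        dofs.append(DOFSpec(name=f"q{j + 1}", range_min=centre - half, range_max=centre + half))
    mids = np.array([(d.range_min + d.range_max) / 2 for d in dofs])
    halves = np.array([(d.range_max - d.range_min) / 2 for d in dofs])

    mtus: list[tuple[MuscleParams, MTUGeometry]] = []
    pair_capacity: dict[int, float] = {}  # DOF -> agonist moment capacity
    for i in range(n_mtu):
        ell_o = math.exp(rng.uniform(math.log(0.012), math.log(0.055)))
        alpha_o = math.radians(rng.uniform(0.0, 35.0))
        # Monoarticular (pair) muscles carry proximal-like slack ratios; the
        # very long relative tendons of real limbs belong to multi-joint
        # distal muscles, which is where the wider band is sampled.
        hi_ratio = 3.0 if i < 2 * n_dof else 8.0
        ratio = math.exp(rng.uniform(math.log(0.05), math.log(hi_ratio)))
        L_S = ratio * ell_o
        F_max = math.exp(rng.uniform(math.log(0.6), math.log(30.0)))

        if i < 2 * n_dof:
            coupled = [i // 2]
            signs = [1.0 if i % 2 == 0 else -1.0]
        else:
            if n_dof == 1:
                coupled = [0]
            else:
                coupled = sorted(rng.choice(n_dof, size=2, replace=False).tolist())
            signs = [1.0 if rng.random() < 0.5 else -1.0 for _ in coupled]

        # Primary moment arm sized so the MTU's excursion over the full range
        # box is at least one fibre length (the classical assumption for limb
        # muscles) and grows with the relative tendon length; in real limbs
        # long-tendoned (distal) muscles cross large-excursion joints, which
        # is what keeps fibre-length ranges at or below MTU-length ranges
        # despite tendon stretch across activation states.
        excursion = max(0.9, 0.14 * ratio) * rng.uniform(1.0, 1.2) * ell_o
        arm_mags = [excursion / (2.0 * halves[coupled[0]])]
        arm_mags += [rng.uniform(0.10, 0.20) * ell_o for _ in coupled[1:]]

        # Antagonist moment capacities are matched within a pair (to within a
        # few-fold jitter), as they are in real limbs: flexors and extensors
        # of one joint have the same order of moment-generating capacity.
        if i < 2 * n_dof:
            if i % 2 == 0:
                pair_capacity[coupled[0]] = F_max * arm_mags[0]
            else:
                target = pair_capacity[coupled[0]] * math.exp(rng.uniform(-0.7, 0.7))
                F_max = min(30.0, max(0.6, target / arm_mags[0]))
        mass = F_max * constants.rho_muscle * ell_o / constants.sigma

        # l_MT(q) = c0 - sum_d s_d r_d (q_d - mid_d) - sum_d g_d (q_d - mid_d)^2,
        # expanded below into absolute-angle polynomial terms; the quadratic
        # term gives each arm a mild (<= ~15%) angle dependence.
        terms: dict[tuple[int, ...], float] = {}

        def add(powers: tuple[int, ...], coeff: float) -> None:
            terms[powers] = terms.get(powers, 0.0) + coeff

        h = ell_o * math.sin(alpha_o)
        ell_mid = rng.uniform(0.95, 1.05)
        if ln_mid and f"mtu{i + 1}" in ln_mid:
            ell_mid = ln_mid[f"mtu{i + 1}"]
        ell_mid *= ell_o
        c0 = L_S + math.sqrt(max(ell_mid**2 - h**2, 1e-10))
        nd = len(coupled)
        add((0,) * nd, c0)
        for d_local, (s, r) in enumerate(zip(signs, arm_mags)):
            mid = mids[coupled[d_local]]
            half = halves[coupled[d_local]]
            kappa = rng.uniform(-0.15, 0.15)
            g = kappa * r / (2.0 * half)
            lin = tuple(1 if j == d_local else 0 for j in range(nd))
            quad = tuple(2 if j == d_local else 0 for j in range(nd))
            # -s*r*(q-mid) term
            add(lin, -s * r)
            add((0,) * nd, s * r * mid)
            # -g*(q-mid)^2 term
            add(quad, -g)
            add(lin, 2.0 * g * mid)
            add((0,) * nd, -g * mid * mid)

        geom = MTUGeometry(
            muscle=f"mtu{i + 1}",
            dof_coupling=[dofs[c].name for c in coupled],
            terms=sorted(terms.items()),
        )
        params = MuscleParams(
            name=f"mtu{i + 1}",
            m=mass,
            ell_o=ell_o,
            L_S=L_S,
            alpha_o=alpha_o,
            F_max=F_max,
            k_T=100.0,
            v_max=10.0,
            tau_act=0.007,
            tau_deact=0.027,
        )
        mtus.append((params, geom))

    model = LimbModel(dofs=dofs, mtus=mtus, reserve_caps={})
    _assert_actuatable(model)
    # Crude reserve caps (10% of summed moment capacity); study bundles
    # overwrite these with 10% of each trial's peak external moment.
    q_mid = mids[np.newaxis, :]
    arms = moment_arms(model, q_mid)[0]
    fmax = np.array([p.F_max for p, _ in mtus])
    caps = 0.1 * np.sum(np.abs(arms) * fmax[:, None], axis=0)
    model.reserve_caps = {d.name: float(c) for d, c in zip(dofs, caps)}
    return model


def _assert_actuatable(model: LimbModel) -> None:
    mids = np.array([(d.range_min + d.range_max) / 2 for d in model.dofs])
    arms = moment_arms(model, mids[np.newaxis, :])[0]
    for j, dof in enumerate(model.dofs):
        if dof.kind != "actuated":
            continue
        col = arms[:, j]
        if not (np.any(col > 1e-6) and np.any(col < -1e-6)):
            raise RuntimeError(f"DOF {dof.name} lacks an antagonist pair")


# ---------------------------------------------------------------------------
# kinematics and activation profiles
# ---------------------------------------------------------------------------


def make_gait_kinematics(spec: GaitSpec, limb: LimbModel, seed: int = 0) -> GaitKinematics:
    """Smooth periodic joint-angle trajectories inside the DOF ranges.

    Each actuated DOF follows a two-harmonic sinusoid about the range centre
    with total amplitude at most 55% of the half-range, so trajectories can
    never leave the range box; fixed DOFs hold the centre angle.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, spec.stride_time, spec.n_samples)
    tau = t / spec.stride_time
    q = np.zeros((spec.n_samples, limb.n_dof))
    for j, dof in enumerate(limb.dofs):
        mid = 0.5 * (dof.range_min + dof.range_max)
        half = 0.5 * (dof.range_max - dof.range_min)
        if dof.kind != "actuated":
            q[:, j] = mid
            continue
        a1 = rng.uniform(0.25, 0.40) * half
        a2 = rng.uniform(0.05, 0.15) * half
        p1, p2 = rng.uniform(0.0, 1.0, size=2)
        q[:, j] = mid + a1 * np.sin(2 * np.pi * (tau - p1)) + a2 * np.sin(4 * np.pi * (tau - p2))
    return GaitKinematics(time=t, q=q, duty_factor=spec.duty_factor, label=spec.label)


def _smooth_burst(tau: np.ndarray, on: float, off: float, width: float) -> np.ndarray:
    return 0.5 * (np.tanh((tau - on) / width) - np.tanh((tau - off) / width))


def make_activation_profiles(
    limb: LimbModel,
    spec: GaitSpec,
    seed: int = 0,
    amp_range: tuple[float, float] = (0.25, 0.45),
) -> np.ndarray:
    """Ground-truth activations: stance bursts for positive-arm muscles,
    swing bursts for their antagonists, zero for any extra MTUs.

    Transition widths are tied to the deactivation time constant
    (``w * T >= ~2 tau_deact``) so the decaying tails remain reachable by the
    excitation-activation dynamics with excitations in [0, 1], and bursts sit
    at least two transition widths inside the stride so activations and their
    rates are essentially zero at both stride boundaries (the inverse problem
    imposes no initial or final conditions, so edge transients in the truth
    would not be recoverable).
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, spec.stride_time, spec.n_samples)
    tau = t / spec.stride_time
    act = np.zeros((spec.n_samples, limb.n_mtu))
    duty = spec.duty_factor
    n_pairs = min(limb.n_mtu // 2, limb.n_dof)
    for i in range(2 * n_pairs):
        params = limb.params[i]
        # Transitions are kept gentle: fast enough for the excitation bound
        # (>= ~2 tau_deact) but no sharper than ~0.14 stride, so that the
        # solver's rate-smoothing regularisation perturbs the optimum by much
        # less than the recovery tolerance.
        w = max(0.14, 2.2 * params.tau_deact / spec.stride_time)
        amp = rng.uniform(*amp_range)
        if i % 2 == 0:  # stance burst
            wb = min(w, duty / 4.5)
            on = 1.9 * wb + rng.uniform(0.0, 0.03)
            off = duty - 1.9 * wb - rng.uniform(0.0, 0.03)
        else:  # swing burst, slightly weaker
            amp *= 0.6
            wb = min(w, (1.0 - duty) / 4.5)
            on = duty + 1.6 * wb + rng.uniform(0.0, 0.02)
            off = 1.0 - 1.8 * wb - rng.uniform(0.0, 0.02)
        if off <= on:
            on, off = 0.5 * (on + off) - 0.01, 0.5 * (on + off) + 0.01
        act[:, i] = amp * _smooth_burst(tau, on, off, wb)
    return act


# ---------------------------------------------------------------------------
# forward trial generation
# ---------------------------------------------------------------------------


def _integrate_contraction(
    params: MuscleParams,
    t_grid: np.ndarray,
    lmt_spline: CubicSpline,
    act_spline: CubicSpline,
    rtol: float = 1e-8,
) -> np.ndarray:
    """Integrate the implicit contraction dynamics with tendon force as state.

    At each instant the normalised fibre velocity is solved from the Hill
    force balance (monotone in velocity thanks to the force-velocity curve
    and damping), which then yields the tendon force rate through the tendon
    compliance.  Returns the normalised tendon force at ``t_grid``.
    """
    h = params.thickness
    khat = params.k_T / (1.0 + mm._TENDON_C)

    def velocity_residual(v_norm, a, ell_norm, cos_alpha, f_til):
        fibre = (
            a * mm.active_force_length(ell_norm) * mm.force_velocity(v_norm)
            + mm.passive_force_length(ell_norm)
            + mm.DAMPING_BETA * v_norm
        )
        return fibre * cos_alpha - f_til

    def rhs(t, y):
        f_til = y[0]
        lmt = float(lmt_spline(t))
        vmt = float(lmt_spline(t, 1))
        a = float(np.clip(act_spline(t), 0.0, 1.0))
        l_T = params.L_S * (1.0 + math.log1p(f_til / mm._TENDON_C) / khat)
        span = lmt - l_T
        if span <= mm.FIBRE_LENGTH_EPS:
            raise mm.InfeasibleGeometryError(
                f"{params.name}: infeasible geometry at t={t:.4f}s during forward generation"
            )
        ell = math.hypot(span, h)
        ell_norm = ell / params.ell_o
        cos_alpha = span / ell
        lo, hi = -2.0, 2.0
        while velocity_residual(lo, a, ell_norm, cos_alpha, f_til) > 0:
            lo *= 2.0
        while velocity_residual(hi, a, ell_norm, cos_alpha, f_til) < 0:
            hi *= 2.0
        v_norm = brentq(
            velocity_residual, lo, hi, args=(a, ell_norm, cos_alpha, f_til), xtol=1e-12
        )
        v_fibre = v_norm * params.v_max * params.ell_o
        v_T = vmt - v_fibre / cos_alpha
        df_til = v_T * khat * (f_til + mm._TENDON_C) / params.L_S
        return [df_til]

    # Initial condition: static equilibrium, then one warm-up stride so the
    # recorded stride starts from a dynamically consistent state.
    state0 = mm.solve_static_equilibrium(
        float(np.clip(act_spline(t_grid[0]), 0, 1)), float(lmt_spline(t_grid[0])), params
    )
    f0 = state0.F_T / params.F_max
    span = t_grid[-1] - t_grid[0]
    warm = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), [f0], method="Radau", rtol=rtol, atol=1e-10
    )
    if not warm.success:
        raise mm.EquilibriumConvergenceError(
            f"{params.name}: contraction integration failed ({warm.message})"
        )
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [warm.y[0, -1]],
        method="Radau",
        rtol=rtol,
        atol=1e-10,
        t_eval=t_grid,
        dense_output=False,
    )
    if not sol.success:
        raise mm.EquilibriumConvergenceError(
            f"{params.name}: contraction integration failed ({sol.message})"
        )
    return sol.y[0]


def forward_generate_trial(
    limb: LimbModel,
    kinematics: GaitKinematics,
    activation_profiles: np.ndarray,
    tuning_truth: tuple[np.ndarray, np.ndarray] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[GaitTrial, GroundTruth]:
    """Manufacture a dynamically consistent trial from known activations.

    Each MTU's contraction dynamics are integrated forward along its
    prescribed path-length trajectory (with tuning factors applied to the
    architecture), and the external joint moments are defined as the summed
    tendon-force moments plus optional Gaussian noise.  With zero noise the
    returned pair is an exactly feasible point of the redundancy problem with
    zero reserve usage.
    """
    act = np.asarray(activation_profiles, dtype=float)
    if act.shape != (len(kinematics.time), limb.n_mtu):
        raise ValueError("activation profile shape mismatch")
    if np.any(act < 0) or np.any(act > 1):
        raise ValueError("activations must lie in [0, 1]")
    if tuning_truth is None:
        p_ell = np.ones(limb.n_mtu)
        p_L = np.ones(limb.n_mtu)
    else:
        p_ell = np.asarray(tuning_truth[0], dtype=float)
        p_L = np.asarray(tuning_truth[1], dtype=float)

    t = kinematics.time
    lmt = mtu_length(limb, kinematics.q)
    arms = moment_arms(limb, kinematics.q)

    f_til = np.zeros_like(act)
    excit = np.zeros_like(act)
    for i, params in enumerate(limb.params):
        tuned = params.tuned(float(p_ell[i]), float(p_L[i]))
        lmt_spline = CubicSpline(t, lmt[:, i])
        act_spline = CubicSpline(t, act[:, i])
        f_til[:, i] = _integrate_contraction(tuned, t, lmt_spline, act_spline)
        dadt = act_spline(t, 1)
        excit[:, i] = mm.excitation_from_rate(act[:, i], dadt, tuned)

    fmax = np.array([p.F_max for p in limb.params])
    forces = f_til * fmax
    m_clean = np.einsum("nm,nmk->nk", forces, arms)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=m_clean.shape) if noise_sd > 0 else 0.0
    trial = GaitTrial(
        label=kinematics.label,
        time=t,
        q=kinematics.q,
        M_ext=m_clean + noise,
        lmt=lmt,
        arms=arms,
        dof_names=limb.dof_names,
        muscle_names=limb.muscle_names,
        duty_factor=kinematics.duty_factor,
    )
    truth = GroundTruth(
        activations=act,
        excitations=excit,
        tendon_forces=forces,
        p_ell=p_ell,
        p_L=p_L,
        M_clean=m_clean,
    )
    return trial, truth


def make_study_bundle(
    seed: int = 0,
    n_dof: int = 2,
    n_mtu: int = 4,
    tuning: dict[str, tuple[float, float]] | None = None,
    noise_sd: float = 0.0,
    n_samples: int = 101,
    specs: tuple[GaitSpec, GaitSpec] = (WALK_SPEC, RUN_SPEC),
    ln_mid: dict[str, float] | None = None,
) -> tuple[LimbModel, list[GaitTrial], list[GroundTruth]]:
    """The default two-trial study: a slow walk and a grounded run.

    ``tuning`` maps muscle names to ground-truth ``(p_ell, p_L)`` factors.
    Reserve caps are set to 10% of each DOF's peak external moment across the
    two trials.  Walking uses lower activation amplitudes than running.
    """
    limb = make_toy_limb(n_dof=n_dof, n_mtu=n_mtu, seed=seed, ln_mid=ln_mid)
    p_ell = np.ones(limb.n_mtu)
    p_L = np.ones(limb.n_mtu)
    for name, (pe, pl) in (tuning or {}).items():
        idx = limb.muscle_names.index(name)
        p_ell[idx] = pe
        p_L[idx] = pl

    trials, truths = [], []
    amp = {"walk": (0.25, 0.45), "run": (0.35, 0.55)}
    for k, spec in enumerate(specs):
        spec = GaitSpec(
            speed=spec.speed,
            duty_factor=spec.duty_factor,
            stride_time=spec.stride_time,
            n_samples=n_samples,
            label=spec.label,
        )
        kin = make_gait_kinematics(spec, limb, seed=seed + 11 * k + 1)
        act = make_activation_profiles(
            limb, spec, seed=seed + 11 * k + 2, amp_range=amp.get(spec.label, (0.3, 0.6))
        )
        trial, truth = forward_generate_trial(
            limb, kin, act, tuning_truth=(p_ell, p_L), noise_sd=noise_sd, seed=seed + 11 * k + 3
        )
        trials.append(trial)
        truths.append(truth)

    peak = np.maximum.reduce([np.max(np.abs(tr.M_ext), axis=0) for tr in trials])
    limb.reserve_caps = {
        d.name: float(max(0.1 * p, 1e-3)) for d, p in zip(limb.dofs, peak)
    }
    return limb, trials, truths


# ---------------------------------------------------------------------------
# packaged hindlimb architecture fixture
# ---------------------------------------------------------------------------


def tinamou_table() -> pd.DataFrame:
    """The packaged 36-MTU hindlimb architecture table (printed units)."""
    ref = importlib.resources.files("myotendon.data") / "tinamou_mtu_architecture.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


def tinamou_fixture(tuned: bool = False) -> list[MuscleParams]:
    """The 36 hindlimb MTU parameter sets (original or inverse-tuned lengths).

    Activation/deactivation time constants are the body-mass-scaled values
    (0.007 s and 0.027 s); ``k_T = 100`` and ``v_max = 10`` throughout.
    """
    df = tinamou_table()
    out = []
    for _, row in df.iterrows():
        ell = row["tuned_fibre_length_mm"] if tuned else row["fibre_length_mm"]
        slack = row["tuned_slack_length_mm"] if tuned else row["slack_length_mm"]
        out.append(
            MuscleParams(
                name=row["abbreviation"],
                m=row["mass_g"] * 1e-3,
                ell_o=ell * 1e-3,
                L_S=slack * 1e-3,
                alpha_o=math.radians(row["pennation_deg"]),
                F_max=row["fmax_N"],
                k_T=100.0,
                v_max=10.0,
                tau_act=0.007,
                tau_deact=0.027,
            )
        )
    return out
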