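"""Static equilibrium simulations over randomly sampled limb postures.

Four simulations delimit each muscle's attainable fibre operating range
purely from the geometric/skeletal system (gravity and inertia ignored):

1. whole-limb minimum of the summed squared activations subject to zero net
   joint moment at every DOF and muscle-tendon equilibrium in every MTU;
2. the corresponding maximum;
3. each MTU in isolation at zero activation;
4. each MTU in isolation at full activation.

Simulations 1-2 are small per-pose NLPs over the activation vector.  Inside
each pose the monotone map from activation to equilibrium tendon force is
tabulated by vectorised bisection on an activation grid and replaced by a
cubic polynomial surrogate (the map is near-linear for stiff tendons), which
keeps the 2 x n_poses optimizations cheap; the final states of every viable
pose are then re-solved by exact root finding, so reported equilibria are
accurate to the root-finder tolerance, not the surrogate's.

Viability filters are applied in a fixed order and the first failure is
recorded per pose: (i) whole-limb equilibrium + moment balance impossible
(simulations 1-2); (ii) MTU path shorter than the tendon slack length
(simulations 3-4, per MTU); (iii) a configurable per-MTU cap on MTU length,
screening out non-physiological extremes of the geometry model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import mtu_model as mm
from .limb_geometry import LimbModel, moment_arms, mtu_length

logger = logging.getLogger(__name__)

__all__ = [
    "PoseSet",
    "SimulationResult",
    "PoseBatteryResult",
    "REASON_NONE",
    "REASON_EQUILIBRIUM",
    "REASON_BELOW_SLACK",
    "REASON_LMT_CAP",
    "sample_poses",
    "run_min_max_activation",
    "run_isolated_muscle",
    "filter_viable",
]

REASON_NONE = ""
REASON_EQUILIBRIUM = "equilibrium-infeasible"
REASON_BELOW_SLACK = "lmt-below-slack"
REASON_LMT_CAP = "lmt-cap-exceeded"

_A_GRID = np.linspace(0.0, 1.0, 13)


@dataclass
class PoseSet:
    """Randomly sampled joint postures (rad) plus the sampling provenance."""

    q_matrix: np.ndarray                  # (n_poses, n_dof)
    seed: int
    ranges: dict[str, tuple[float, float]]
    overrides: dict[str, float] = field(default_factory=dict)
    dof_names: list[str] = field(default_factory=list)

    @property
    def n_poses(self) -> int:
        return self.q_matrix.shape[0]


@dataclass
class SimulationResult:
    """Per-pose, per-MTU equilibrium states for one simulation.

    ``viable`` and ``reason`` are per (pose, MTU); for the whole-limb
    simulations (1-2) viability is a pose property broadcast to all MTUs.
    ``objective`` holds the summed squared activations (simulations 1-2).
    """

    sim: int
    ell_norm: np.ndarray     # (n_poses, n_mtu)
    f_til: np.ndarray        # (n_poses, n_mtu)
    activation: np.ndarray   # (n_poses, n_mtu)
    viable: np.ndarray       # (n_poses, n_mtu) bool
    reason: np.ndarray       # (n_poses, n_mtu) object (str)
    objective: np.ndarray | None = None  # (n_poses,)

    def pose_viable(self) -> np.ndarray:
        return self.viable.all(axis=1)


@dataclass
class PoseBatteryResult:
    poses: PoseSet
    lmt: np.ndarray                     # (n_poses, n_mtu)
    sims: dict[int, SimulationResult]
    muscle_names: list[str]

    def viable_counts(self) -> dict[str, int]:
        out = {}
        if 1 in self.sims and 2 in self.sims:
            out["sims_1_2"] = int(
                (self.sims[1].pose_viable() & self.sims[2].pose_viable()).sum()
            )
        if 3 in self.sims and 4 in self.sims:
            out["sims_3_4"] = int(
                (self.sims[3].pose_viable() & self.sims[4].pose_viable()).sum()
            )
        return out


def sample_poses(
    limb: LimbModel,
    n: int = 5000,
    seed: int = 0,
    overrides: dict[str, float] | None = None,
) -> PoseSet:
    """Uniform independent pose sampling per actuated DOF.

    ``overrides`` maps DOF names to fixed angles (rad), e.g. holding
    out-of-plane joint rotations at their mean stride angles; fixed-kind DOFs
    without an override are held at their range centre.
    """
    if n < 1:
        raise ValueError("need at least one pose")
    overrides = overrides or {}
    rng = np.random.default_rng(seed)
    q = np.empty((n, limb.n_dof))
    ranges = {}
    for j, dof in enumerate(limb.dofs):
        if dof.name in overrides:
            q[:, j] = overrides[dof.name]
            ranges[dof.name] = (overrides[dof.name], overrides[dof.name])
        elif dof.kind != "actuated":
            mid = 0.5 * (dof.range_min + dof.range_max)
            q[:, j] = mid
            ranges[dof.name] = (mid, mid)
        else:
            q[:, j] = rng.uniform(dof.range_min, dof.range_max, size=n)
            ranges[dof.name] = (dof.range_min, dof.range_max)
    return PoseSet(
        q_matrix=q, seed=seed, ranges=ranges, overrides=dict(overrides),
        dof_names=limb.dof_names,
    )


# ---------------------------------------------------------------------------
# simulations 3-4: isolated muscles
# ---------------------------------------------------------------------------


def run_isolated_muscle(
    poses: PoseSet, limb: LimbModel, activation_level: float
) -> SimulationResult:
    """Static equilibrium of every MTU in isolation at a fixed activation."""
    if activation_level not in (0, 1, 0.0, 1.0):
        raise ValueError("activation level must be 0 or 1")
    n, M = poses.n_poses, limb.n_mtu
    lmt = mtu_length(limb, poses.q_matrix)
    ell = np.full((n, M), np.nan)
    f_til = np.full((n, M), np.nan)
    viable = np.zeros((n, M), dtype=bool)
    reason = np.full((n, M), REASON_NONE, dtype=object)
    for i, p in enumerate(limb.params):
        below = lmt[:, i] <= p.L_S + mm.FIBRE_LENGTH_EPS
        ft, ln, ok = mm.solve_static_equilibrium_batch(
            float(activation_level), lmt[:, i], p
        )
        viable[:, i] = ok
        ell[ok, i] = ln[ok]
        f_til[ok, i] = ft[ok]
        reason[below, i] = REASON_BELOW_SLACK
        crushed = ~ok & ~below
        reason[crushed, i] = REASON_EQUILIBRIUM
    sim = 3 if activation_level == 0 else 4
    act = np.full((n, M), float(activation_level))
    act[~viable] = np.nan
    return SimulationResult(
        sim=sim, ell_norm=ell, f_til=f_til, activation=act, viable=viable, reason=reason
    )


# ---------------------------------------------------------------------------
# simulations 1-2: whole-limb min/max activation
# ---------------------------------------------------------------------------


def _force_polynomials(limb: LimbModel, lmt: np.ndarray):
    """Cubic surrogates of the per-(pose, MTU) activation -> force maps.

    Returns (coeffs, a_hi, pose_ok): polynomial coefficients (n, M, 4) of the
    normalised tendon force in the activation, the largest activation with
    feasible equilibrium per (pose, MTU), and the poses where every MTU has an
    equilibrium at zero activation.
    """
    n, M = lmt.shape
    G = len(_A_GRID)
    forces = np.full((n, M, G), np.nan)
    a_hi = np.ones((n, M))
    ok0 = np.ones((n, M), dtype=bool)
    for i, p in enumerate(limb.params):
        ft, _, ok = mm.solve_static_equilibrium_batch(
            _A_GRID[None, :], lmt[:, i][:, None], p
        )
        forces[:, i, :] = ft
        ok0[:, i] = ok[:, 0]
        # highest grid activation still feasible (fibres can crush at high a)
        feas = np.where(ok, _A_GRID[None, :], np.nan)
        a_hi[:, i] = np.where(ok[:, 0], np.nanmax(feas, axis=1), 0.0)
    # Vandermonde least squares, shared grid for all (pose, MTU)
    V = np.vander(_A_GRID, 4, increasing=True)
    pinv = np.linalg.pinv(V)
    filled = np.nan_to_num(forces, nan=0.0)
    coeffs = np.einsum("ga,nmg->nma", pinv.T, filled)
    return coeffs, a_hi, ok0


def _pose_nlp(coeffs, a_hi, arms, fmax, mode, rng, mscale):
    """Min/max sum(a^2) under zero net moment, on the polynomial surrogate."""
    M = coeffs.shape[0]
    K = arms.shape[1]
    powers = np.arange(4)

    def force(a):
        return (coeffs * a[:, None] ** powers).sum(axis=1)

    def dforce(a):
        return (coeffs[:, 1:] * powers[1:] * a[:, None] ** (powers[1:] - 1)).sum(axis=1)

    def cons(a):
        return (force(a) * fmax) @ arms / mscale

    def cons_jac(a):
        return (arms.T * (dforce(a) * fmax)) / mscale[:, None]

    sign = 1.0 if mode == "min" else -1.0
    bounds = [(0.0, float(h)) for h in a_hi]

    def obj(a):
        return sign * float(a @ a), sign * 2.0 * a

    # feasibility phase: minimise the squared moment residual
    def feas_obj(a):
        r = cons(a)
        return float(r @ r), 2.0 * cons_jac(a).T @ r

    best = None
    for trial in range(3):
        a0 = np.zeros(M) if trial == 0 else rng.uniform(0, np.minimum(a_hi, 1.0))
        res = minimize(feas_obj, a0, jac=True, bounds=bounds, method="SLSQP",
                       options={"maxiter": 60, "ftol": 1e-14})
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < 1e-12:
            break
    if best.fun > 1e-10:
        return None, None  # rule i: no admissible activation balances the limb
    a_feas = best.x

    best = None
    n_starts = 1 if mode == "min" else 3
    for trial in range(n_starts):
        a0 = a_feas if trial == 0 else np.clip(
            a_feas + rng.uniform(-0.5, 0.5, M), 0.0, np.minimum(a_hi, 1.0)
        )
        res = minimize(
            obj, a0, jac=True, bounds=bounds, method="SLSQP",
            constraints=[{"type": "eq", "fun": cons, "jac": cons_jac}],
            options={"maxiter": 80, "ftol": 1e-12},
        )
        feas_err = np.max(np.abs(cons(res.x)))
        if feas_err < 1e-6 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        return None, None
    return best.x, float(best.x @ best.x)


def run_min_max_activation(
    poses: PoseSet, limb: LimbModel, mode: str, seed: int = 0
) -> SimulationResult:
    """Whole-limb minimum (simulation 1) or maximum (simulation 2) activation.

    Gravity and inertia are absent: the constraint is zero net muscle moment
    at every DOF with all MTUs in static equilibrium.  Maximisation is solved
    as minimisation of the negated objective from 3 seeded starts.
    """
    if mode not in ("min", "max"):
        raise ValueError("mode must be 'min' or 'max'")
    rng = np.random.default_rng(seed + (0 if mode == "min" else 1))
    n, M = poses.n_poses, limb.n_mtu
    lmt = mtu_length(limb, poses.q_matrix)
    arms = moment_arms(limb, poses.q_matrix)
    fmax = np.array([p.F_max for p in limb.params])
    coeffs, a_hi, ok0 = _force_polynomials(limb, lmt)
    cap = np.abs(arms).transpose(0, 2, 1) @ fmax  # (n, K) moment capacity scale
    mscale = np.maximum(cap, 1e-9)

    ell = np.full((n, M), np.nan)
    f_til = np.full((n, M), np.nan)
    act = np.full((n, M), np.nan)
    viable_pose = np.zeros(n, dtype=bool)
    objective = np.full(n, np.nan)
    reason = np.full((n, M), REASON_NONE, dtype=object)

    for ipose in range(n):
        if not ok0[ipose].all():
            reason[ipose, :] = REASON_EQUILIBRIUM
            continue
        a_opt, obj = _pose_nlp(
            coeffs[ipose], a_hi[ipose], arms[ipose], fmax, mode, rng, mscale[ipose]
        )
        if a_opt is None:
            reason[ipose, :] = REASON_EQUILIBRIUM
            continue
        viable_pose[ipose] = True
        act[ipose] = a_opt
        objective[ipose] = obj
    # exact re-solve of the equilibria at the optimal activations
    for i, p in enumerate(limb.params):
        sel = viable_pose
        if sel.any():
            ft, ln, ok = mm.solve_static_equilibrium_batch(
                act[sel, i], lmt[sel, i], p
            )
            f_til[sel, i] = ft
            ell[sel, i] = ln
    viable = np.repeat(viable_pose[:, None], M, axis=1)
    n_bad = int((~viable_pose).sum())
    if n_bad:
        logger.info("simulation %s: %d/%d poses infeasible (rule i)", mode, n_bad, n)
    return SimulationResult(
        sim=1 if mode == "min" else 2,
        ell_norm=ell, f_til=f_til, activation=act,
        viable=viable, reason=reason, objective=objective,
    )


# ---------------------------------------------------------------------------
# battery assembly and filtering
# ---------------------------------------------------------------------------


def run_battery(
    limb: LimbModel,
    n_poses: int = 5000,
    seed: int = 0,
    overrides: dict[str, float] | None = None,
    sims: tuple[int, ...] = (1, 2, 3, 4),
    lmt_caps: dict[str, float] | None = None,
) -> PoseBatteryResult:
    """Sample poses, run the requested simulations, apply the filters."""
    poses = sample_poses(limb, n_poses, seed, overrides)
    lmt = mtu_length(limb, poses.q_matrix)
    results: dict[int, SimulationResult] = {}
    if 1 in sims:
        results[1] = run_min_max_activation(poses, limb, "min", seed)
    if 2 in sims:
        results[2] = run_min_max_activation(poses, limb, "max", seed)
    if 3 in sims:
        results[3] = run_isolated_muscle(poses, limb, 0)
    if 4 in sims:
        results[4] = run_isolated_muscle(poses, limb, 1)
    battery = PoseBatteryResult(
        poses=poses, lmt=lmt, sims=results, muscle_names=limb.muscle_names
    )
    return filter_viable(battery, lmt_caps)


def filter_viable(
    battery: PoseBatteryResult, lmt_caps: dict[str, float] | None = None
) -> PoseBatteryResult:
    """Apply the MTU-length cap (rule iii) on top of rules i and ii.

    A pose whose capped MTU exceeds its length cap is inviable in every
    simulation; poses already inviable keep their earlier (rule i/ii) reason.
    """
    if not lmt_caps:
        return battery
    n = battery.poses.n_poses
    over = np.zeros(n, dtype=bool)
    for name, cap in lmt_caps.items():
        i = battery.muscle_names.index(name)
        over |= battery.lmt[:, i] > cap
    for sim in battery.sims.values():
        newly = over[:, None] & sim.viable
        sim.reason[newly] = REASON_LMT_CAP
        sim.viable &= ~over[:, None]
        sim.ell_norm[~sim.viable] = np.nan
        sim.f_til[~sim.viable] = np.nan
        if sim.objective is not None:
            sim.objective[over] = np.nan
    return battery


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------


def battery_to_frames(battery: PoseBatteryResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format frames: (poses with sampling metadata, per-state results)."""
    poses = battery.poses
    pose_df = pd.DataFrame(
        np.degrees(poses.q_matrix),
        columns=[f"q_{d}_deg" for d in poses.dof_names],
    )
    pose_df.insert(0, "pose", np.arange(poses.n_poses))
    pose_df.attrs["seed"] = poses.seed
    rows = []
    for s, sim in sorted(battery.sims.items()):
        for i, name in enumerate(battery.muscle_names):
            rows.append(
                pd.DataFrame(
                    {
                        "pose": np.arange(poses.n_poses),
                        "sim": s,
                        "muscle": name,
                        "lmt_mm": battery.lmt[:, i] * 1e3,
                        "ell_norm": sim.ell_norm[:, i],
                        "f_til": sim.f_til[:, i],
                        "activation": sim.activation[:, i],
                        "viable": sim.viable[:, i],
                        "reason": sim.reason[:, i],
                        "objective": (
                            sim.objective if sim.objective is not None else np.nan
                        ),
                    }
                )
            )
    return pose_df, pd.concat(rows, ignore_index=True)


def battery_from_frames(
    pose_df: pd.DataFrame, result_df: pd.DataFrame, seed: int = -1
) -> PoseBatteryResult:
    """Rebuild a :class:`PoseBatteryResult` from its long-format frames."""
    dof_names = [c[2:-4] for c in pose_df.columns if c.startswith("q_")]
    q = np.radians(pose_df[[f"q_{d}_deg" for d in dof_names]].to_numpy())
    muscle_names = list(dict.fromkeys(result_df["muscle"]))
    n = len(pose_df)
    M = len(muscle_names)
    lmt = np.full((n, M), np.nan)
    sims: dict[int, SimulationResult] = {}
    for s, grp in result_df.groupby("sim"):
        ell = np.full((n, M), np.nan)
        f_til = np.full((n, M), np.nan)
        act = np.full((n, M), np.nan)
        viable = np.zeros((n, M), dtype=bool)
        reason = np.full((n, M), REASON_NONE, dtype=object)
        objective = np.full(n, np.nan)
        for i, name in enumerate(muscle_names):
            sub = grp[grp["muscle"] == name].sort_values("pose")
            idx = sub["pose"].to_numpy()
            lmt[idx, i] = sub["lmt_mm"].to_numpy() * 1e-3
            ell[idx, i] = sub["ell_norm"].to_numpy()
            f_til[idx, i] = sub["f_til"].to_numpy()
            act[idx, i] = sub["activation"].to_numpy()
            viable[idx, i] = sub["viable"].to_numpy(dtype=bool)
            reason[idx, i] = sub["reason"].fillna(REASON_NONE).to_numpy()
            objective[idx] = sub["objective"].to_numpy()
        sims[int(s)] = SimulationResult(
            sim=int(s), ell_norm=ell, f_til=f_til, activation=act,
            viable=viable, reason=reason,
            objective=objective if int(s) in (1, 2) else None,
        )
    poses = PoseSet(
        q_matrix=q, seed=seed,
        ranges={d: (float(q[:, j].min()), float(q[:, j].max())) for j, d in enumerate(dof_names)},
        dof_names=dof_names,
    )
    return PoseBatteryResult(poses=poses, lmt=lmt, sims=sims, muscle_names=muscle_names)
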