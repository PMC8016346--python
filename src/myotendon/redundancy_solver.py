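"""Multi-trial inverse (muscle-redundancy) optimal control with MTU tuning.

Given one or more gait trials (joint kinematics, external joint moments, MTU
lengths and moment arms), solve for the muscle excitations that reproduce the
external moments while obeying excitation-activation dynamics, implicit
contraction dynamics (normalised tendon force as a state, its scaled rate as
a control), muscle-tendon equilibrium, and per-DOF moment balance with
heavily penalised reserve actuators.  Optimal fibre length and tendon slack
length may simultaneously be tuned through per-muscle multipliers ``p_ell``
and ``p_L`` shared across all trials.

The optimal control problem is transcribed by direct collocation on evenly
spaced mesh intervals with two-stage (third-order) Radau IIA points and
solved as a sparse nonlinear program with :func:`scipy.optimize.minimize`
(``trust-constr``), using an analytic objective gradient and grouped
finite-difference constraint Jacobians on the exact sparsity pattern.

The six-term objective (integrated squared muscle activations; heavily
weighted integrated squared reserve activations; squared activation and
tendon-force rates for conditioning; squared passive fibre forces, which
stops the tuning from parking fibres on the descending limb where passive
force is free; and quadratic penalties on tuning-factor deviations from one)
uses default weights ``w1..w6 = 2, 500, 1, 100, 2, 1``.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.interpolate import CubicSpline
from scipy.optimize import Bounds, NonlinearConstraint, minimize

from . import mtu_model as mm
from .limb_geometry import GaitTrial, LimbModel

logger = logging.getLogger(__name__)

__all__ = [
    "ObjectiveWeights",
    "TuningFactors",
    "TrialSolution",
    "RedundancySolution",
    "SolverError",
    "static_optimization_seed",
    "solve_redundancy",
    "reserve_contribution_report",
]

# Radau IIA, two stages (order 3): abscissae, Butcher matrix, quadrature weights.
_RADAU_C = np.array([1.0 / 3.0, 1.0])
_RADAU_A = np.array([[5.0 / 12.0, -1.0 / 12.0], [3.0 / 4.0, 1.0 / 4.0]])
_RADAU_B = np.array([3.0 / 4.0, 1.0 / 4.0])

# Tendon-force rate control scaling (dF~/dt = u_F * _F_RATE_SCALE) and the
# time scale used to non-dimensionalise the rate penalties in the objective.
_F_RATE_SCALE = 10.0  # 1/s
_RATE_TIME_SCALE = 0.01  # s

_SPAN_SMOOTH = 1e-5  # m; smooth positive-part width for the fibre span
_FORCE_SMOOTH = 0.01  # smooth floor width for F~ + c in tendon-curve inverses


def _safe_force_offset(f_til):
    """Smooth positive part of ``F~ + c`` so tendon-curve inverses stay
    defined (and differentiable) at arbitrary NLP iterates."""
    y = f_til + mm._TENDON_C
    return 0.5 * (y + np.sqrt(y * y + _FORCE_SMOOTH**2))


class SolverError(RuntimeError):
    """The NLP terminated without an acceptable solution."""


@dataclass(frozen=True)
class ObjectiveWeights:
    """Weights of the six objective terms (all dimensionless, >= 0)."""

    w1: float = 2.0     # muscle activations
    w2: float = 500.0   # reserve activations
    w3: float = 1.0     # activation and tendon-force rates
    w4: float = 100.0   # passive fibre forces
    w5: float = 2.0     # fibre-length tuning deviations
    w6: float = 1.0     # slack-length tuning deviations

    def __post_init__(self) -> None:
        if any(getattr(self, f"w{i}") < 0 for i in range(1, 7)):
            raise ValueError("objective weights must be non-negative")


@dataclass
class TuningFactors:
    """Per-muscle multipliers on optimal fibre length and tendon slack length."""

    p_ell: np.ndarray
    p_L: np.ndarray


@dataclass
class TrialSolution:
    """State/control trajectories of one trial at the collocation nodes."""

    label: str
    time: np.ndarray           # node times, s
    excitation: np.ndarray     # (n_nodes, M)
    activation: np.ndarray     # (n_nodes, M)
    f_til: np.ndarray          # normalised tendon force (n_nodes, M)
    tendon_force: np.ndarray   # N
    ell_norm: np.ndarray
    v_norm: np.ndarray
    f_passive: np.ndarray      # normalised passive fibre force
    reserve: np.ndarray        # (n_nodes, K) reserve activations per DOF
    duty_factor: float | None = None

    def activation_at(self, times: np.ndarray) -> np.ndarray:
        out = np.empty((len(times), self.activation.shape[1]))
        for m in range(self.activation.shape[1]):
            out[:, m] = np.interp(times, self.time, self.activation[:, m])
        return out


@dataclass
class RedundancySolution:
    trials: list[TrialSolution]
    tuning: TuningFactors
    objective: float
    objective_breakdown: dict[str, float]
    status: str
    converged: bool          # NLP optimality reached
    feasible: bool           # all constraints within the feasibility tolerance
    constr_violation: float
    n_iter: int
    solve_time: float
    muscle_names: list[str] = field(default_factory=list)
    dof_names: list[str] = field(default_factory=list)
    reserve_caps: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# static optimization seeding
# ---------------------------------------------------------------------------


def _bounded_min_norm(B: np.ndarray, b: np.ndarray, weights: np.ndarray,
                      lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Minimise z'Wz subject to Bz = b and box bounds, by KKT with clipping.

    Small active-set iteration adequate for the per-instant load sharing
    problems (a handful of variables); falls back to a least-squares moment
    fit when the equality system cannot be met within the bounds.
    """
    n = B.shape[1]
    z = np.zeros(n)
    free = np.ones(n, dtype=bool)
    for _ in range(n + 1):
        Bf = B[:, free]
        Winv = 1.0 / weights[free]
        resid = b - B[:, ~free] @ z[~free]
        M = (Bf * Winv) @ Bf.T
        try:
            lam = np.linalg.solve(M, resid)
        except np.linalg.LinAlgError:
            lam = np.linalg.pinv(M) @ resid
        zf = Winv * (Bf.T @ lam)
        z[free] = zf
        viol_lo = free & (z < lo - 1e-12)
        viol_hi = free & (z > hi + 1e-12)
        if not (viol_lo.any() or viol_hi.any()):
            return np.clip(z, lo, hi)
        z[viol_lo] = lo[viol_lo]
        z[viol_hi] = hi[viol_hi]
        free = free & ~(viol_lo | viol_hi)
        if not free.any():
            break
    return np.clip(z, lo, hi)


def static_optimization_seed(
    trials: list[GaitTrial], limb: LimbModel, reserves_enabled: bool = True
) -> list[dict[str, np.ndarray]]:
    """Per-instant minimum-activation load sharing under rigid tendons.

    For every sample of every trial, solves ``min sum a^2 (+ W sum s^2)``
    subject to moment balance with rigid-tendon muscle forces evaluated at the
    instantaneous normalised fibre length and velocity.  Used as the initial
    guess of the collocation NLP.  Instants where the muscles (plus bounded
    reserves) cannot balance the moments keep the least-squares reserve-
    saturated point and are logged.
    """
    out = []
    reserve_w = 100.0
    for trial in trials:
        n = len(trial.time)
        M = limb.n_mtu
        vmt = trial.vmt()
        a_seed = np.zeros((n, M))
        f_seed = np.zeros((n, M))
        caps = np.array([limb.reserve_caps.get(d, 0.0) for d in trial.dof_names])
        if not reserves_enabled:
            caps = np.zeros_like(caps)
        use_res = caps > 0
        n_bad = 0
        for k in range(n):
            gain = np.zeros(M)
            f0 = np.zeros(M)
            for i, p in enumerate(limb.params):
                h = p.thickness
                span = max(trial.lmt[k, i] - p.L_S, mm.FIBRE_LENGTH_EPS)
                ell = math.hypot(span, h)
                ln = ell / p.ell_o
                cos_a = span / ell
                vn = (vmt[k, i] * cos_a) / (p.v_max * p.ell_o)
                gain[i] = (
                    float(mm.active_force_length(ln)) * float(mm.force_velocity(vn)) * cos_a * p.F_max
                )
                f0[i] = float(mm.passive_force_length(ln)) * cos_a * p.F_max
            b = trial.M_ext[k] - trial.arms[k].T @ f0
            B = np.concatenate([(trial.arms[k] * gain[:, None]).T, np.diag(caps)[:, use_res]], axis=1)
            w = np.concatenate([np.ones(M), np.full(int(use_res.sum()), reserve_w)])
            lo = np.concatenate([np.zeros(M), -np.ones(int(use_res.sum()))])
            hi = np.ones(M + int(use_res.sum()))
            z = _bounded_min_norm(B, b, w, lo, hi)
            a_seed[k] = z[:M]
            if np.max(np.abs(B @ z - b)) > 1e-6 + 1e-3 * np.max(np.abs(trial.M_ext[k])):
                n_bad += 1
            f_seed[k] = (z[:M] * gain + f0) / np.array([p.F_max for p in limb.params])
        if n_bad:
            logger.warning(
                "static optimization: %d/%d instants of trial '%s' left unbalanced "
                "(reserve-saturated least-squares point kept)", n_bad, n, trial.label,
            )
        out.append({"time": trial.time, "a": a_seed, "f_til": f_seed})
    return out


# ---------------------------------------------------------------------------
# collocation transcription
# ---------------------------------------------------------------------------


class _Transcription:
    """Index bookkeeping plus vectorised constraint/objective evaluation."""

    def __init__(
        self,
        trials: list[GaitTrial],
        limb: LimbModel,
        weights: ObjectiveWeights,
        mesh: int,
        tuning_bounds: tuple[float, float],
        reserves_enabled: bool,
        tuning_free: bool,
    ):
        self.limb = limb
        self.weights = weights
        self.tuning_free = tuning_free
        self.tuning_bounds = tuning_bounds
        M = limb.n_mtu
        K = limb.n_dof
        self.M, self.K = M, K
        self.params = limb.params
        self.fmax = np.array([p.F_max for p in self.params])
        self.ell_o = np.array([p.ell_o for p in self.params])
        self.L_S = np.array([p.L_S for p in self.params])
        self.sin_a = np.array([math.sin(p.alpha_o) for p in self.params])
        self.khat = np.array([p.k_T / (1.0 + mm._TENDON_C) for p in self.params])
        self.v_max = np.array([p.v_max for p in self.params])

        caps = np.array([limb.reserve_caps.get(d, 0.0) for d in limb.dof_names])
        if not reserves_enabled:
            caps = np.zeros_like(caps)
        self.res_dofs = np.flatnonzero(caps > 0)
        self.caps = caps[self.res_dofs]
        self.Kr = len(self.res_dofs)

        self.trial_meta = []
        offset = 0
        rows = 0
        for trial in trials:
            N = mesh
            Nc = 2 * N
            Ng = Nc + 1
            h = trial.duration / N
            t0 = trial.time[0]
            t_grid = np.empty(Ng)
            t_grid[0::2] = t0 + h * np.arange(N + 1)
            t_grid[1::2] = t0 + h * (np.arange(N) + _RADAU_C[0])
            t_nodes = t_grid[1:]

            lmt_s = [CubicSpline(trial.time, trial.lmt[:, i]) for i in range(M)]
            lmt_n = np.column_stack([s(t_nodes) for s in lmt_s])
            vmt_n = np.column_stack([s(t_nodes, 1) for s in lmt_s])
            arms_n = np.empty((Nc, M, K))
            for i in range(M):
                for k in range(K):
                    col = trial.arms[:, i, k]
                    if np.any(col != 0.0):
                        arms_n[:, i, k] = CubicSpline(trial.time, col)(t_nodes)
                    else:
                        arms_n[:, i, k] = 0.0
            mext_n = np.column_stack(
                [CubicSpline(trial.time, trial.M_ext[:, k])(t_nodes) for k in range(K)]
            )
            mscale = np.maximum(np.max(np.abs(mext_n), axis=0), 1e-4)
            full_caps = np.zeros(K)
            full_caps[self.res_dofs] = self.caps
            mscale = np.maximum(mscale, full_caps)

            wq = np.empty(Nc)
            wq[0::2] = h * _RADAU_B[0]
            wq[1::2] = h * _RADAU_B[1]

            sizes = {
                "A": Ng * M, "F": Ng * M, "LN": Nc * M,
                "E": Nc * M, "UF": Nc * M, "RES": Nc * self.Kr,
            }
            offs = {}
            o = offset
            for key in ("A", "F", "LN", "E", "UF", "RES"):
                offs[key] = o
                o += sizes[key]
            meta = {
                "label": trial.label, "N": N, "Nc": Nc, "Ng": Ng, "h": h,
                "t_grid": t_grid, "t_nodes": t_nodes, "lmt": lmt_n, "vmt": vmt_n,
                "arms": arms_n, "mext": mext_n, "mscale": mscale, "wq": wq,
                "offs": offs, "duty": trial.duty_factor,
                "row0": rows,
            }
            rows += 2 * (2 * N * M) + 2 * (Nc * M) + Nc * K
            offset = o
            self.trial_meta.append(meta)

        if tuning_free:
            self.off_pe = offset
            self.off_pl = offset + M
            offset += 2 * M
        self.n_vars = offset
        self.n_rows = rows

    # -- decoding ----------------------------------------------------------

    def _blocks(self, x: np.ndarray, meta: dict):
        M, Kr = self.M, self.Kr
        Ng, Nc = meta["Ng"], meta["Nc"]
        o = meta["offs"]
        A = x[o["A"]: o["A"] + Ng * M].reshape(Ng, M)
        F = x[o["F"]: o["F"] + Ng * M].reshape(Ng, M)
        LN = x[o["LN"]: o["LN"] + Nc * M].reshape(Nc, M)
        E = x[o["E"]: o["E"] + Nc * M].reshape(Nc, M)
        UF = x[o["UF"]: o["UF"] + Nc * M].reshape(Nc, M)
        RES = x[o["RES"]: o["RES"] + Nc * Kr].reshape(Nc, Kr)
        return A, F, LN, E, UF, RES

    def tuning_of(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.tuning_free:
            return x[self.off_pe: self.off_pe + self.M], x[self.off_pl: self.off_pl + self.M]
        return np.ones(self.M), np.ones(self.M)

    # -- constraints -------------------------------------------------------

    def constraints(self, x: np.ndarray) -> np.ndarray:
        p_ell, p_L = self.tuning_of(x)
        ell_t = self.ell_o * p_ell
        LS_t = self.L_S * p_L
        h_t = ell_t * self.sin_a
        out = np.empty(self.n_rows)
        for meta in self.trial_meta:
            A, F, LN, E, UF, RES = self._blocks(x, meta)
            N, Nc, h = meta["N"], meta["Nc"], meta["h"]
            M, K = self.M, self.K
            A_nodes = A[1:]
            F_nodes = F[1:]

            # state derivatives at the nodes
            rate = _activation_rate_multi(E, A_nodes, self.params)
            dF = UF * _F_RATE_SCALE

            r0 = meta["row0"]
            # Radau defects for activation and tendon-force states
            for X, f, base in ((A, rate, r0), (F, dF, r0 + 2 * N * M)):
                X0 = X[0:-1:2]
                X1 = X[1::2]
                X2 = X[2::2]
                f1 = f[0::2]
                f2 = f[1::2]
                d1 = X1 - X0 - h * (_RADAU_A[0, 0] * f1 + _RADAU_A[0, 1] * f2)
                d2 = X2 - X0 - h * (_RADAU_A[1, 0] * f1 + _RADAU_A[1, 1] * f2)
                block = np.empty((Nc, M))
                block[0::2] = d1
                block[1::2] = d2
                out[base: base + Nc * M] = block.ravel()

            # geometry: LN consistent with tendon force and path length
            sp = _safe_force_offset(F_nodes)
            lT = LS_t * (1.0 + np.log(sp / mm._TENDON_C) / self.khat)
            span = meta["lmt"] - lT
            span_s = 0.5 * (span + np.sqrt(span * span + _SPAN_SMOOTH**2))
            ell = np.hypot(span_s, h_t)
            base = r0 + 2 * Nc * M
            out[base: base + Nc * M] = (LN - ell / ell_t).ravel()

            # Hill equilibrium with velocity from the tendon-force rate
            cos_a = span_s / ell
            vT = LS_t / (self.khat * sp) * dF
            v_norm = cos_a * (meta["vmt"] - vT) / (self.v_max * ell_t)
            fibre = (
                A_nodes * mm.active_force_length(LN) * mm.force_velocity(v_norm)
                + mm.passive_force_length(LN)
                + mm.DAMPING_BETA * v_norm
            )
            base = r0 + 3 * Nc * M
            out[base: base + Nc * M] = (fibre * cos_a - F_nodes).ravel()

            # moment balance per DOF
            forces = F_nodes * self.fmax
            mom = np.einsum("nm,nmk->nk", forces, meta["arms"])
            if self.Kr:
                mom[:, self.res_dofs] += RES * self.caps
            base = r0 + 4 * Nc * M
            out[base: base + Nc * K] = ((mom - meta["mext"]) / meta["mscale"]).ravel()
        return out

    def jac_sparsity(self) -> sparse.csr_matrix:
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        M, K, Kr = self.M, self.K, self.Kr

        def add(r, c):
            r = np.asarray(r).ravel()
            c = np.asarray(c).ravel()
            rows.append(r)
            cols.append(c)

        for meta in self.trial_meta:
            N, Nc = meta["N"], meta["Nc"]
            o = meta["offs"]
            r0 = meta["row0"]
            m_idx = np.arange(M)
            i_idx = np.arange(N)

            def grid_col(key, p, m):  # p (..,) m (..,)
                return o[key] + p * M + m

            def node_col(key, n, m):
                return o[key] + n * M + m

            # defects: rows (n, m) with n = 2i+j
            for s, (state_key, ctrl_key) in enumerate((("A", "E"), ("F", "UF"))):
                base = r0 + s * 2 * N * M
                for j in (0, 1):
                    n = 2 * i_idx[:, None] + j          # (N,1)
                    row = base + n * M + m_idx[None, :]  # (N,M)
                    for p_off in (0, 1, 2):
                        add(row, grid_col(state_key, 2 * i_idx[:, None] + p_off, m_idx[None, :]))
                    for n_off in (0, 1):
                        add(row, node_col(ctrl_key, 2 * i_idx[:, None] + n_off, m_idx[None, :]))
                    if state_key == "A":
                        # rate at node n' depends on A at grid n'+1 (already
                        # covered by the three state columns above)
                        pass

            n_idx = np.arange(Nc)
            # geometry rows
            base = r0 + 2 * Nc * M
            row = base + n_idx[:, None] * M + m_idx[None, :]
            add(row, node_col("LN", n_idx[:, None], m_idx[None, :]))
            add(row, grid_col("F", n_idx[:, None] + 1, m_idx[None, :]))
            # Hill rows
            base = r0 + 3 * Nc * M
            row = base + n_idx[:, None] * M + m_idx[None, :]
            add(row, grid_col("A", n_idx[:, None] + 1, m_idx[None, :]))
            add(row, grid_col("F", n_idx[:, None] + 1, m_idx[None, :]))
            add(row, node_col("LN", n_idx[:, None], m_idx[None, :]))
            add(row, node_col("UF", n_idx[:, None], m_idx[None, :]))
            if self.tuning_free:
                for b in (r0 + 2 * Nc * M, r0 + 3 * Nc * M):
                    row = b + n_idx[:, None] * M + m_idx[None, :]
                    add(row, np.broadcast_to(self.off_pe + m_idx[None, :], row.shape))
                    add(row, np.broadcast_to(self.off_pl + m_idx[None, :], row.shape))
            # moment rows
            base = r0 + 4 * Nc * M
            coupled = np.any(meta["arms"] != 0.0, axis=0)  # (M, K)
            for k in range(K):
                row = base + n_idx * K + k
                for m in np.flatnonzero(coupled[:, k]):
                    add(row, grid_col("F", n_idx + 1, np.full(Nc, m)))
            for kr, k in enumerate(self.res_dofs):
                row = base + n_idx * K + k
                add(row, o["RES"] + n_idx * Kr + kr)

        data = np.ones(sum(len(r) for r in rows))
        pattern = sparse.coo_matrix(
            (data, (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_rows, self.n_vars),
        )
        pattern.sum_duplicates()
        return pattern.tocsr()

    # -- objective ---------------------------------------------------------

    def objective_terms(self, x: np.ndarray) -> dict[str, float]:
        w = self.weights
        p_ell, p_L = self.tuning_of(x)
        terms = {k: 0.0 for k in ("activation", "reserve", "rates", "passive")}
        for meta in self.trial_meta:
            A, F, LN, E, UF, RES = self._blocks(x, meta)
            wq = meta["wq"][:, None]
            A_nodes = A[1:]
            rate = _activation_rate_multi(E, A_nodes, self.params)
            fp = mm.passive_force_length(LN)
            terms["activation"] += float(np.sum(wq * A_nodes**2))
            terms["reserve"] += float(np.sum(meta["wq"][:, None] * RES**2))
            terms["rates"] += float(
                np.sum(wq * ((rate * _RATE_TIME_SCALE) ** 2 + UF**2))
            )
            terms["passive"] += float(np.sum(wq * fp**2))
        breakdown = {
            "activation": w.w1 * terms["activation"],
            "reserve": w.w2 * terms["reserve"],
            "rates": w.w3 * terms["rates"],
            "passive": w.w4 * terms["passive"],
            "tuning_fibre": w.w5 * float(np.sum((p_ell - 1.0) ** 2)),
            "tuning_slack": w.w6 * float(np.sum((p_L - 1.0) ** 2)),
        }
        breakdown["total"] = sum(breakdown.values())
        return breakdown

    def objective(self, x: np.ndarray) -> float:
        return self.objective_terms(x)["total"]

    def gradient(self, x: np.ndarray) -> np.ndarray:
        w = self.weights
        g = np.zeros_like(x)
        for meta in self.trial_meta:
            A, F, LN, E, UF, RES = self._blocks(x, meta)
            o = meta["offs"]
            Nc, Ng = meta["Nc"], meta["Ng"]
            M, Kr = self.M, self.Kr
            wq = meta["wq"][:, None]
            A_nodes = A[1:]
            rate = _activation_rate_multi(E, A_nodes, self.params)
            d_e, d_a = _activation_rate_partials_multi(E, A_nodes, self.params)
            fp = mm.passive_force_length(LN)
            dfp = mm.passive_force_length_deriv(LN)
            ts2 = _RATE_TIME_SCALE**2

            gA_nodes = wq * (2.0 * w.w1 * A_nodes + 2.0 * w.w3 * ts2 * rate * d_a)
            gA = np.zeros((Ng, M))
            gA[1:] = gA_nodes
            g[o["A"]: o["A"] + Ng * M] += gA.ravel()
            g[o["E"]: o["E"] + Nc * M] += (wq * 2.0 * w.w3 * ts2 * rate * d_e).ravel()
            g[o["UF"]: o["UF"] + Nc * M] += (wq * 2.0 * w.w3 * UF).ravel()
            g[o["LN"]: o["LN"] + Nc * M] += (wq * 2.0 * w.w4 * fp * dfp).ravel()
            if Kr:
                g[o["RES"]: o["RES"] + Nc * Kr] += (
                    meta["wq"][:, None] * 2.0 * w.w2 * RES
                ).ravel()
        if self.tuning_free:
            p_ell, p_L = self.tuning_of(x)
            g[self.off_pe: self.off_pe + self.M] += 2.0 * w.w5 * (p_ell - 1.0)
            g[self.off_pl: self.off_pl + self.M] += 2.0 * w.w6 * (p_L - 1.0)
        return g

    # -- bounds and initial guess ------------------------------------------

    def bounds(self) -> Bounds:
        lb = np.empty(self.n_vars)
        ub = np.empty(self.n_vars)
        for meta in self.trial_meta:
            o = meta["offs"]
            Ng, Nc = meta["Ng"], meta["Nc"]
            M, Kr = self.M, self.Kr

            def set_box(key, size, lo, hi):
                lb[o[key]: o[key] + size] = lo
                ub[o[key]: o[key] + size] = hi

            set_box("A", Ng * M, 0.0, 1.0)
            set_box("F", Ng * M, -0.1, 5.0)
            set_box("LN", Nc * M, 0.05, 2.5)
            set_box("E", Nc * M, 0.0, 1.0)
            set_box("UF", Nc * M, -60.0, 60.0)
            set_box("RES", Nc * Kr, -1.0, 1.0)
        if self.tuning_free:
            lb[self.off_pe:] = self.tuning_bounds[0]
            ub[self.off_pe:] = self.tuning_bounds[1]
        return Bounds(lb, ub)

    def initial_guess(self, seeds: list[dict[str, np.ndarray]]) -> np.ndarray:
        x0 = np.zeros(self.n_vars)
        for meta, seed in zip(self.trial_meta, seeds):
            o = meta["offs"]
            Ng, Nc = meta["Ng"], meta["Nc"]
            M = self.M
            t_grid, t_nodes = meta["t_grid"], meta["t_nodes"]
            A = np.empty((Ng, M))
            F = np.empty((Ng, M))
            for m in range(M):
                A[:, m] = np.interp(t_grid, seed["time"], seed["a"][:, m])
                F[:, m] = np.interp(t_grid, seed["time"], seed["f_til"][:, m])
            A = np.clip(A, 0.0, 1.0)
            F = np.clip(F, 0.0, 5.0)
            x0[o["A"]: o["A"] + Ng * M] = A.ravel()
            x0[o["F"]: o["F"] + Ng * M] = F.ravel()
            F_nodes = F[1:]
            lT = self.L_S * (1.0 + np.log1p(F_nodes / mm._TENDON_C) / self.khat)
            span = meta["lmt"] - lT
            span_s = 0.5 * (span + np.sqrt(span * span + _SPAN_SMOOTH**2))
            LN = np.hypot(span_s, self.ell_o * self.sin_a) / self.ell_o
            x0[o["LN"]: o["LN"] + Nc * M] = np.clip(LN, 0.05, 2.5).ravel()
            x0[o["E"]: o["E"] + Nc * M] = A[1:].ravel()
            dF = np.gradient(F, t_grid, axis=0)[1:] / _F_RATE_SCALE
            x0[o["UF"]: o["UF"] + Nc * M] = np.clip(dF, -60, 60).ravel()
        if self.tuning_free:
            x0[self.off_pe: self.off_pe + 2 * self.M] = 1.0
        return x0

    # -- extraction --------------------------------------------------------

    def extract(self, x: np.ndarray) -> list[TrialSolution]:
        p_ell, p_L = self.tuning_of(x)
        ell_t = self.ell_o * p_ell
        LS_t = self.L_S * p_L
        h_t = ell_t * self.sin_a
        sols = []
        for meta in self.trial_meta:
            A, F, LN, E, UF, RES = self._blocks(x, meta)
            F_nodes = F[1:]
            sp = _safe_force_offset(F_nodes)
            lT = LS_t * (1.0 + np.log(sp / mm._TENDON_C) / self.khat)
            span = meta["lmt"] - lT
            span_s = 0.5 * (span + np.sqrt(span * span + _SPAN_SMOOTH**2))
            ell = np.hypot(span_s, h_t)
            cos_a = span_s / ell
            vT = LS_t / (self.khat * sp) * UF * _F_RATE_SCALE
            v_norm = cos_a * (meta["vmt"] - vT) / (self.v_max * ell_t)
            reserve = np.zeros((meta["Nc"], self.K))
            if self.Kr:
                reserve[:, self.res_dofs] = RES
            sols.append(
                TrialSolution(
                    label=meta["label"],
                    time=meta["t_nodes"],
                    excitation=E.copy(),
                    activation=A[1:].copy(),
                    f_til=F_nodes.copy(),
                    tendon_force=F_nodes * self.fmax,
                    ell_norm=LN.copy(),
                    v_norm=v_norm,
                    f_passive=np.asarray(mm.passive_force_length(LN)),
                    reserve=reserve,
                    duty_factor=meta["duty"],
                )
            )
        return sols


def _activation_rate_multi(E, A, params_list):
    out = np.empty_like(E)
    for m, p in enumerate(params_list):
        out[:, m] = mm.activation_rate(E[:, m], A[:, m], p)
    return out


def _activation_rate_partials_multi(E, A, params_list):
    de = np.empty_like(E)
    da = np.empty_like(E)
    for m, p in enumerate(params_list):
        de[:, m], da[:, m] = mm.activation_rate_partials(E[:, m], A[:, m], p)
    return de, da


# ---------------------------------------------------------------------------
# public solve
# ---------------------------------------------------------------------------


def solve_redundancy(
    trials: list[GaitTrial],
    limb: LimbModel,
    weights: ObjectiveWeights | None = None,
    mesh: int = 100,
    tuning_bounds: tuple[float, float] = (0.5, 2.0),
    reserves_enabled: bool = True,
    freeze_tuning: bool = False,
    seed_guess: list[dict[str, np.ndarray]] | None = None,
    maxiter: int = 500,
    feas_tol: float = 1e-6,
    gtol: float = 1e-7,
    verbose: int = 0,
) -> RedundancySolution:
    """Solve the multi-trial redundancy problem by direct collocation.

    ``mesh`` is the number of collocation intervals per trial (default 100,
    two Radau points each).  With ``freeze_tuning`` the tuning factors are
    held at one, which decouples the trials; they are then solved as
    independent NLPs and the solutions merged, which is mathematically
    identical to the joint problem and substantially faster.
    """
    if not trials:
        raise ValueError("need at least one trial")
    if mesh < 10:
        raise ValueError("mesh must be at least 10 intervals")
    for tr in trials:
        if tr.muscle_names != limb.muscle_names or tr.dof_names != limb.dof_names:
            raise ValueError("all trials must share the limb model's MTUs and DOFs")
    weights = weights or ObjectiveWeights()

    if freeze_tuning and len(trials) > 1:
        parts = [
            solve_redundancy(
                [tr], limb, weights=weights, mesh=mesh, tuning_bounds=tuning_bounds,
                reserves_enabled=reserves_enabled, freeze_tuning=True,
                seed_guess=None if seed_guess is None else [seed_guess[i]],
                maxiter=maxiter, feas_tol=feas_tol, gtol=gtol, verbose=verbose,
            )
            for i, tr in enumerate(trials)
        ]
        breakdown = {
            k: sum(p.objective_breakdown[k] for p in parts)
            for k in parts[0].objective_breakdown
        }
        return RedundancySolution(
            trials=[p.trials[0] for p in parts],
            tuning=parts[0].tuning,
            objective=breakdown["total"],
            objective_breakdown=breakdown,
            status="; ".join(p.status for p in parts),
            converged=all(p.converged for p in parts),
            feasible=all(p.feasible for p in parts),
            constr_violation=max(p.constr_violation for p in parts),
            n_iter=sum(p.n_iter for p in parts),
            solve_time=sum(p.solve_time for p in parts),
            muscle_names=limb.muscle_names,
            dof_names=limb.dof_names,
            reserve_caps=parts[0].reserve_caps,
        )

    tr_obj = _Transcription(
        trials, limb, weights, mesh, tuning_bounds, reserves_enabled,
        tuning_free=not freeze_tuning,
    )
    if seed_guess is None:
        seed_guess = static_optimization_seed(trials, limb, reserves_enabled)
    x0 = tr_obj.initial_guess(seed_guess)

    pattern = tr_obj.jac_sparsity()
    constraint = NonlinearConstraint(
        tr_obj.constraints, 0.0, 0.0, jac="2-point", finite_diff_jac_sparsity=pattern
    )
    t_start = time.perf_counter()
    res = minimize(
        tr_obj.objective,
        x0,
        jac=tr_obj.gradient,
        bounds=tr_obj.bounds(),
        constraints=[constraint],
        method="trust-constr",
        options={
            "maxiter": maxiter,
            "gtol": gtol,
            "xtol": 1e-14,
            # activations/excitations sit at or near their lower bounds over
            # most of the stride; a small initial barrier keeps the interior
            # point from first pushing the iterate deep into co-contraction
            "initial_barrier_parameter": 1e-4,
            "verbose": verbose,
        },
    )
    elapsed = time.perf_counter() - t_start
    viol = float(np.max(np.abs(tr_obj.constraints(res.x))))
    feasible = viol < feas_tol
    converged = feasible and res.status in (1, 2)
    if not feasible and viol > 100 * feas_tol:
        raise SolverError(
            f"redundancy NLP failed: status={res.status} ({res.message}), "
            f"worst constraint violation {viol:.3e}"
        )
    breakdown = tr_obj.objective_terms(res.x)
    p_ell, p_L = tr_obj.tuning_of(res.x)
    solution = RedundancySolution(
        trials=tr_obj.extract(res.x),
        tuning=TuningFactors(p_ell=np.array(p_ell), p_L=np.array(p_L)),
        objective=breakdown["total"],
        objective_breakdown=breakdown,
        status=f"status={res.status}: {res.message}",
        converged=converged,
        feasible=feasible,
        constr_violation=viol,
        n_iter=int(res.niter),
        solve_time=elapsed,
        muscle_names=limb.muscle_names,
        dof_names=limb.dof_names,
        reserve_caps={
            d: (limb.reserve_caps.get(d, 0.0) if reserves_enabled else 0.0)
            for d in limb.dof_names
        },
    )
    logger.info(
        "redundancy solve: %d vars, %d constraints, %d iters, %.1fs, violation %.2e",
        tr_obj.n_vars, tr_obj.n_rows, solution.n_iter, elapsed, viol,
    )
    return solution


def reserve_contribution_report(
    solution: RedundancySolution,
    trials: list[GaitTrial],
    floor_frac: float = 0.05,
) -> dict[str, dict]:
    """Reserve moment as a fraction of the external joint moment.

    The denominator is floored at ``floor_frac`` of the DOF's peak external
    moment so the ratio stays finite near moment zero-crossings.  Returns per
    trial and per DOF the fraction time series plus max and stance/swing
    means.
    """
    report: dict[str, dict] = {}
    for sol, trial in zip(solution.trials, trials):
        mext = np.column_stack(
            [
                np.interp(sol.time, trial.time, trial.M_ext[:, k])
                for k in range(len(solution.dof_names))
            ]
        )
        per_dof = {}
        for k, dof in enumerate(solution.dof_names):
            cap = solution.reserve_caps.get(dof, 0.0)
            peak = max(np.max(np.abs(mext[:, k])), 1e-12)
            floor = floor_frac * peak
            frac = np.abs(sol.reserve[:, k] * cap) / np.maximum(np.abs(mext[:, k]), floor)
            entry = {"fraction": frac, "max": float(np.max(frac)), "mean": float(np.mean(frac))}
            if sol.duty_factor is not None:
                tau = (sol.time - sol.time[0]) / (sol.time[-1] - sol.time[0])
                stance = tau <= sol.duty_factor
                entry["stance_mean"] = float(np.mean(frac[stance])) if stance.any() else 0.0
                entry["swing_mean"] = float(np.mean(frac[~stance])) if (~stance).any() else 0.0
            per_dof[dof] = entry
        report[sol.label] = per_dof
    return report


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------


def save_solution(solution: RedundancySolution, out_dir) -> None:
    """Write the solution as one CSV per trial plus JSON metadata."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    for ts in solution.trials:
        cols = {"time_s": ts.time}
        for i, m in enumerate(solution.muscle_names):
            cols[f"e_{m}"] = ts.excitation[:, i]
            cols[f"a_{m}"] = ts.activation[:, i]
            cols[f"ft_{m}_N"] = ts.tendon_force[:, i]
            cols[f"ln_{m}"] = ts.ell_norm[:, i]
            cols[f"vn_{m}"] = ts.v_norm[:, i]
        for k, d in enumerate(solution.dof_names):
            cols[f"res_{d}"] = ts.reserve[:, k]
        pd.DataFrame(cols).to_csv(out / f"solution_{ts.label}.csv", index=False)
    meta = {
        "tuning": {
            "p_ell": dict(zip(solution.muscle_names, solution.tuning.p_ell.tolist())),
            "p_L": dict(zip(solution.muscle_names, solution.tuning.p_L.tolist())),
        },
        "objective": solution.objective,
        "objective_breakdown": solution.objective_breakdown,
        "status": solution.status,
        "converged": solution.converged,
        "feasible": solution.feasible,
        "constr_violation": solution.constr_violation,
        "n_iter": solution.n_iter,
        "solve_time_s": solution.solve_time,
        "reserve_caps": solution.reserve_caps,
        "f_max": {
            m: _fmax_of(solution, i) for i, m in enumerate(solution.muscle_names)
        },
        "trials": [ts.label for ts in solution.trials],
        "duty_factors": {
            ts.label: ts.duty_factor for ts in solution.trials
        },
    }
    (out / "solution_meta.json").write_text(json.dumps(meta, indent=2))


def _fmax_of(solution: RedundancySolution, i: int) -> float:
    for ts in solution.trials:
        k = int(np.argmax(np.abs(ts.f_til[:, i])))
        if abs(ts.f_til[k, i]) > 1e-9:
            return float(ts.tendon_force[k, i] / ts.f_til[k, i])
    return 1.0


def load_solution(out_dir) -> RedundancySolution:
    """Rebuild a :class:`RedundancySolution` from :func:`save_solution` output."""
    import json
    from pathlib import Path

    import pandas as pd

    out = Path(out_dir)
    meta = json.loads((out / "solution_meta.json").read_text())
    muscle_names = list(meta["tuning"]["p_ell"].keys())
    dof_names = list(meta["reserve_caps"].keys())
    trials = []
    fmax = np.array([meta.get("f_max", {}).get(m, 1.0) for m in muscle_names])
    for label in meta["trials"]:
        df = pd.read_csv(out / f"solution_{label}.csv")
        forces = np.column_stack([df[f"ft_{m}_N"] for m in muscle_names])
        trials.append(
            TrialSolution(
                label=label,
                time=df["time_s"].to_numpy(),
                excitation=np.column_stack([df[f"e_{m}"] for m in muscle_names]),
                activation=np.column_stack([df[f"a_{m}"] for m in muscle_names]),
                f_til=forces / fmax,
                tendon_force=forces,
                ell_norm=np.column_stack([df[f"ln_{m}"] for m in muscle_names]),
                v_norm=np.column_stack([df[f"vn_{m}"] for m in muscle_names]),
                f_passive=np.asarray(
                    mm.passive_force_length(
                        np.column_stack([df[f"ln_{m}"] for m in muscle_names])
                    )
                ),
                reserve=np.column_stack([df[f"res_{d}"] for d in dof_names]),
                duty_factor=meta.get("duty_factors", {}).get(label),
            )
        )
    return RedundancySolution(
        trials=trials,
        tuning=TuningFactors(
            p_ell=np.array(list(meta["tuning"]["p_ell"].values())),
            p_L=np.array(list(meta["tuning"]["p_L"].values())),
        ),
        objective=meta["objective"],
        objective_breakdown=meta["objective_breakdown"],
        status=meta["status"],
        converged=meta["converged"],
        feasible=meta["feasible"],
        constr_violation=meta["constr_violation"],
        n_iter=meta["n_iter"],
        solve_time=meta["solve_time_s"],
        muscle_names=muscle_names,
        dof_names=dof_names,
        reserve_caps=meta["reserve_caps"],
    )
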