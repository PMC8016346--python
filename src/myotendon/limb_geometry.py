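"""Limb kinematic geometry: MTU lengths and moment arms from joint angles.

Musculoskeletal path geometry (wrapping surfaces, via points) is represented
functionally: each MTU's length is a smooth multivariate polynomial of the
joint angles it crosses.  Moment arms then follow exactly from the tendon
excursion identity ``r_{m,k} = -d l_MT / d q_k`` (an MTU that shortens as a
joint flexes has a positive moment arm about that motion), so arms and
lengths are consistent by construction and every gradient downstream is
exact.

File formats
------------
* Limb model: YAML with a ``units`` header; joint ranges in degrees,
  architecture in g / mm / deg, polynomial coefficients in metres per
  radian^power (see :func:`save_limb_model`).
* Gait trial: CSV with header columns ``time_s``, ``q_<dof>_deg``,
  ``M_<dof>_Nm`` and optional ``lmt_<mtu>_mm`` / ``r_<mtu>_<dof>_mm``
  columns.  Explicit length/arm columns win over model evaluation, so
  externally computed muscle analyses can be imported directly.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mtu_model import MuscleParams

__all__ = [
    "DOFSpec",
    "MTUGeometry",
    "LimbModel",
    "GaitTrial",
    "mtu_length",
    "moment_arms",
    "check_tendon_excursion",
    "save_limb_model",
    "load_limb_model",
    "save_trial",
    "load_trial",
]


@dataclass(frozen=True)
class DOFSpec:
    """One rotational degree of freedom with its admissible angle range."""

    name: str
    range_min: float  # rad
    range_max: float  # rad
    kind: str = "actuated"  # actuated | fixed

    def __post_init__(self) -> None:
        if not self.range_min < self.range_max:
            raise ValueError(f"DOF {self.name}: require range_min < range_max")
        if self.kind not in ("actuated", "fixed"):
            raise ValueError(f"DOF {self.name}: kind must be 'actuated' or 'fixed'")


@dataclass
class MTUGeometry:
    """Polynomial MTU-length geometry over the DOFs the MTU crosses.

    ``terms`` maps exponent tuples (one exponent per coupled DOF, in
    ``dof_coupling`` order) to coefficients in metres per radian^total degree.
    """

    muscle: str
    dof_coupling: list[str]
    terms: list[tuple[tuple[int, ...], float]]

    def __post_init__(self) -> None:
        for powers, _ in self.terms:
            if len(powers) != len(self.dof_coupling):
                raise ValueError(
                    f"{self.muscle}: exponent tuple {powers} does not match coupled DOFs"
                )

    def length(self, q_sub: np.ndarray) -> np.ndarray:
        """Evaluate l_MT at angles of the coupled DOFs, shape (..., n_coupled)."""
        q_sub = np.asarray(q_sub, dtype=float)
        out = np.zeros(q_sub.shape[:-1])
        for powers, coeff in self.terms:
            term = np.full(q_sub.shape[:-1], coeff)
            for j, p in enumerate(powers):
                if p:
                    term = term * q_sub[..., j] ** p
            out = out + term
        return out

    def arm(self, q_sub: np.ndarray, local_dof: int) -> np.ndarray:
        """Moment arm about coupled DOF ``local_dof``: ``-d l_MT / d q``."""
        q_sub = np.asarray(q_sub, dtype=float)
        out = np.zeros(q_sub.shape[:-1])
        for powers, coeff in self.terms:
            p_k = powers[local_dof]
            if p_k == 0:
                continue
            term = np.full(q_sub.shape[:-1], coeff * p_k)
            for j, p in enumerate(powers):
                pj = p - 1 if j == local_dof else p
                if pj:
                    term = term * q_sub[..., j] ** pj
            out = out + term
        return -out


@dataclass
class LimbModel:
    """DOF set plus per-MTU architecture and geometry."""

    dofs: list[DOFSpec]
    mtus: list[tuple[MuscleParams, MTUGeometry]]
    reserve_caps: dict[str, float] = field(default_factory=dict)  # N*m per DOF

    def __post_init__(self) -> None:
        names = self.dof_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate DOF names")
        for _, geom in self.mtus:
            if not geom.dof_coupling:
                raise ValueError(f"MTU {geom.muscle} couples no DOF")
            for d in geom.dof_coupling:
                if d not in names:
                    raise ValueError(f"MTU {geom.muscle} couples unknown DOF {d}")
        for dof, cap in self.reserve_caps.items():
            if cap < 0:
                raise ValueError(f"reserve cap for {dof} must be non-negative")

    @property
    def dof_names(self) -> list[str]:
        return [d.name for d in self.dofs]

    @property
    def actuated_dofs(self) -> list[DOFSpec]:
        return [d for d in self.dofs if d.kind == "actuated"]

    @property
    def muscle_names(self) -> list[str]:
        return [g.muscle for _, g in self.mtus]

    @property
    def params(self) -> list[MuscleParams]:
        return [p for p, _ in self.mtus]

    @property
    def n_dof(self) -> int:
        return len(self.dofs)

    @property
    def n_mtu(self) -> int:
        return len(self.mtus)

    def dof_index(self, name: str) -> int:
        return self.dof_names.index(name)

    def with_params(self, params: list[MuscleParams]) -> "LimbModel":
        """Copy of the model with substituted muscle parameters (same order)."""
        if len(params) != self.n_mtu:
            raise ValueError("parameter list length mismatch")
        return LimbModel(
            dofs=list(self.dofs),
            mtus=[(p, g) for p, (_, g) in zip(params, self.mtus)],
            reserve_caps=dict(self.reserve_caps),
        )


def _check_box(model: LimbModel, q: np.ndarray) -> None:
    q = np.atleast_2d(q)
    if q.shape[-1] != model.n_dof:
        raise ValueError(f"expected {model.n_dof} joint angles, got {q.shape[-1]}")
    for j, dof in enumerate(model.dofs):
        pad = 0.1 * (dof.range_max - dof.range_min)
        lo, hi = dof.range_min - pad, dof.range_max + pad
        if np.any(q[..., j] < lo) or np.any(q[..., j] > hi):
            raise ValueError(
                f"angle(s) for DOF {dof.name} outside the expanded range [{lo:.4g}, {hi:.4g}] rad"
            )


def mtu_length(model: LimbModel, q: np.ndarray) -> np.ndarray:
    """MTU lengths (m) at joint angles ``q`` (rad), shape (..., n_dof) -> (..., n_mtu)."""
    q = np.asarray(q, dtype=float)
    _check_box(model, q)
    cols = []
    for _, geom in model.mtus:
        idx = [model.dof_index(d) for d in geom.dof_coupling]
        cols.append(geom.length(q[..., idx]))
    return np.stack(cols, axis=-1)


def moment_arms(model: LimbModel, q: np.ndarray) -> np.ndarray:
    """Moment arms (m), shape (..., n_dof) -> (..., n_mtu, n_dof).

    Zero exactly for DOFs an MTU does not couple.
    """
    q = np.asarray(q, dtype=float)
    _check_box(model, q)
    out = np.zeros(q.shape[:-1] + (model.n_mtu, model.n_dof))
    for i, (_, geom) in enumerate(model.mtus):
        idx = [model.dof_index(d) for d in geom.dof_coupling]
        q_sub = q[..., idx]
        for local, gidx in enumerate(idx):
            out[..., i, gidx] = geom.arm(q_sub, local)
    return out


def check_tendon_excursion(
    model: LimbModel, n_samples: int = 50, seed: int = 0, step: float = 1e-6
) -> dict[str, float]:
    """Verify analytic arms against central differences of the length map.

    Samples ``n_samples`` poses uniformly inside the DOF box and returns the
    maximum absolute discrepancy (m) per MTU.
    """
    rng = np.random.default_rng(seed)
    lo = np.array([d.range_min for d in model.dofs])
    hi = np.array([d.range_max for d in model.dofs])
    q = rng.uniform(lo, hi, size=(n_samples, model.n_dof))
    arms = moment_arms(model, q)
    worst = np.zeros(model.n_mtu)
    for k in range(model.n_dof):
        dq = np.zeros(model.n_dof)
        dq[k] = step
        fd = -(mtu_length(model, q + dq) - mtu_length(model, q - dq)) / (2 * step)
        worst = np.maximum(worst, np.max(np.abs(fd - arms[:, :, k]), axis=0))
    return dict(zip(model.muscle_names, worst))


# ---------------------------------------------------------------------------
# limb-model serialization
# ---------------------------------------------------------------------------


def _model_to_dict(model: LimbModel) -> dict:
    return {
        "units": {
            "dof_range": "deg",
            "architecture": "g / mm / deg",
            "geometry_coefficients": "m per rad^power",
            "reserve_caps": "N*m",
        },
        "dofs": [
            {
                "name": d.name,
                "range_min_deg": float(math.degrees(d.range_min)),
                "range_max_deg": float(math.degrees(d.range_max)),
                "kind": d.kind,
            }
            for d in model.dofs
        ],
        "mtus": [
            {
                "name": g.muscle,
                "architecture": {
                    "mass_g": float(p.m * 1e3),
                    "fibre_length_mm": float(p.ell_o * 1e3),
                    "slack_length_mm": float(p.L_S * 1e3),
                    "pennation_deg": float(math.degrees(p.alpha_o)),
                    "fmax_N": float(p.F_max),
                    "k_T": float(p.k_T),
                    "v_max": float(p.v_max),
                    "tau_act_s": float(p.tau_act),
                    "tau_deact_s": float(p.tau_deact),
                },
                "geometry": {
                    "dofs": list(g.dof_coupling),
                    "terms": [
                        {"powers": [int(p_) for p_ in powers], "coeff": float(coeff)}
                        for powers, coeff in g.terms
                    ],
                },
            }
            for p, g in model.mtus
        ],
        "reserve_caps": {k: float(v) for k, v in model.reserve_caps.items()},
    }


def _model_from_dict(data: dict) -> LimbModel:
    dofs = [
        DOFSpec(
            name=d["name"],
            range_min=math.radians(d["range_min_deg"]),
            range_max=math.radians(d["range_max_deg"]),
            kind=d.get("kind", "actuated"),
        )
        for d in data["dofs"]
    ]
    mtus = []
    for entry in data["mtus"]:
        arch = entry["architecture"]
        params = MuscleParams(
            name=entry["name"],
            m=arch["mass_g"] * 1e-3,
            ell_o=arch["fibre_length_mm"] * 1e-3,
            L_S=arch["slack_length_mm"] * 1e-3,
            alpha_o=math.radians(arch["pennation_deg"]),
            F_max=arch["fmax_N"],
            k_T=arch.get("k_T", 100.0),
            v_max=arch.get("v_max", 10.0),
            tau_act=arch.get("tau_act_s", 0.015),
            tau_deact=arch.get("tau_deact_s", 0.060),
        )
        geom = MTUGeometry(
            muscle=entry["name"],
            dof_coupling=list(entry["geometry"]["dofs"]),
            terms=[
                (tuple(t["powers"]), float(t["coeff"])) for t in entry["geometry"]["terms"]
            ],
        )
        mtus.append((params, geom))
    return LimbModel(dofs=dofs, mtus=mtus, reserve_caps=dict(data.get("reserve_caps", {})))


def save_limb_model(model: LimbModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_model_to_dict(model), sort_keys=False))


def load_limb_model(path: str | Path) -> LimbModel:
    return _model_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# gait trials
# ---------------------------------------------------------------------------


@dataclass
class GaitTrial:
    """One locomotor trial: kinematics, external moments and MTU geometry.

    ``q`` and ``M_ext`` have shape (n, n_dof); ``lmt`` (n, n_mtu); ``arms``
    (n, n_mtu, n_dof).  ``duty_factor`` (fraction of the stride in stance)
    is optional metadata used for phase-resolved summaries.
    """

    label: str
    time: np.ndarray               # s
    q: np.ndarray                  # rad
    M_ext: np.ndarray              # N*m
    lmt: np.ndarray                # m
    arms: np.ndarray               # m
    dof_names: list[str]
    muscle_names: list[str]
    duty_factor: float | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        if self.q.shape != (n, len(self.dof_names)):
            raise ValueError("q shape mismatch")
        if self.M_ext.shape != self.q.shape:
            raise ValueError("M_ext shape mismatch")
        if self.lmt.shape != (n, len(self.muscle_names)):
            raise ValueError("lmt shape mismatch")
        if self.arms.shape != (n, len(self.muscle_names), len(self.dof_names)):
            raise ValueError("arms shape mismatch")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def vmt(self) -> np.ndarray:
        """MTU lengthening velocities (m/s) by centred differences in time."""
        return np.gradient(self.lmt, self.time, axis=0)

    def stance_mask(self) -> np.ndarray | None:
        if self.duty_factor is None:
            return None
        tau = (self.time - self.time[0]) / self.duration
        return tau <= self.duty_factor


def derive_trial_geometry(model: LimbModel, time, q, M_ext, label: str,
                          duty_factor: float | None = None) -> GaitTrial:
    """Build a :class:`GaitTrial` evaluating lengths/arms from the model."""
    time = np.asarray(time, dtype=float)
    q = np.asarray(q, dtype=float)
    M_ext = np.asarray(M_ext, dtype=float)
    return GaitTrial(
        label=label,
        time=time,
        q=q,
        M_ext=M_ext,
        lmt=mtu_length(model, q),
        arms=moment_arms(model, q),
        dof_names=model.dof_names,
        muscle_names=model.muscle_names,
        duty_factor=duty_factor,
    )


def save_trial(trial: GaitTrial, path: str | Path) -> None:
    cols: dict[str, np.ndarray] = {"time_s": trial.time}
    for j, d in enumerate(trial.dof_names):
        cols[f"q_{d}_deg"] = np.degrees(trial.q[:, j])
    for j, d in enumerate(trial.dof_names):
        cols[f"M_{d}_Nm"] = trial.M_ext[:, j]
    for i, m in enumerate(trial.muscle_names):
        cols[f"lmt_{m}_mm"] = trial.lmt[:, i] * 1e3
    for i, m in enumerate(trial.muscle_names):
        for j, d in enumerate(trial.dof_names):
            if np.any(trial.arms[:, i, j] != 0.0):
                cols[f"r_{m}_{d}_mm"] = trial.arms[:, i, j] * 1e3
    df = pd.DataFrame(cols)
    header = f"# gait trial '{trial.label}'"
    if trial.duty_factor is not None:
        header += f", duty_factor={trial.duty_factor}"
    Path(path).write_text(header + "\n" + df.to_csv(index=False))


def load_trial(path: str | Path, model: LimbModel, label: str | None = None) -> GaitTrial:
    """Load a trial CSV; explicit lmt/arm columns win over model evaluation."""
    text = Path(path).read_text()
    duty = None
    if text.startswith("#"):
        first, _, rest = text.partition("\n")
        if "duty_factor=" in first:
            duty = float(first.rsplit("duty_factor=", 1)[1])
        if label is None and "'" in first:
            label = first.split("'")[1]
        text = rest
    df = pd.read_csv(io.StringIO(text))
    time = df["time_s"].to_numpy()
    q = np.column_stack([np.radians(df[f"q_{d}_deg"]) for d in model.dof_names])
    M_ext = np.column_stack([df[f"M_{d}_Nm"] for d in model.dof_names])
    lmt_cols = [f"lmt_{m}_mm" for m in model.muscle_names]
    if all(c in df.columns for c in lmt_cols):
        lmt = np.column_stack([df[c] for c in lmt_cols]) * 1e-3
        arms = np.zeros((len(time), model.n_mtu, model.n_dof))
        for i, m in enumerate(model.muscle_names):
            for j, d in enumerate(model.dof_names):
                col = f"r_{m}_{d}_mm"
                if col in df.columns:
                    arms[:, i, j] = df[col] * 1e-3
    else:
        lmt = mtu_length(model, q)
        arms = moment_arms(model, q)
    return GaitTrial(
        label=label or Path(path).stem,
        time=time,
        q=q,
        M_ext=M_ext,
        lmt=lmt,
        arms=arms,
        dof_names=model.dof_names,
        muscle_names=model.muscle_names,
        duty_factor=duty,
    )
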