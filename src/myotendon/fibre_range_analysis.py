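"""Post-processing of operating ranges, linearity fits and decoupling.

Summarises normalised fibre-length (``ell* = ell / ell_o``) operating ranges
from static pose batteries and inverse-simulation solutions, classifies where
fibres sit on the active force-length curve, fits hyperplanes quantifying how
linearly ``ell*`` follows the joint angles, and regresses the degree of
MTU-to-fibre range decoupling against pennation and relative tendon length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .limb_geometry import LimbModel
from .mtu_model import MuscleParams
from .static_posture_battery import PoseBatteryResult

logger = logging.getLogger(__name__)

__all__ = [
    "HyperplaneFit",
    "RegionBoundaries",
    "RangeSummary",
    "hyperplane_fit",
    "classify_fl_region",
    "operating_range_summary",
    "decoupling_regression",
]

REGION_LABELS = ("steep_ascending", "shallow_ascending", "plateau", "descending")


@dataclass(frozen=True)
class RegionBoundaries:
    """Edges between force-length regions, in units of ``ell*``.

    The defaults place the steep ascending limb below 0.80, the shallow
    ascending limb in [0.80, 0.95), the plateau in [0.95, 1.05], and the
    descending limb above; these divisions are conventional approximations
    and fully configurable.
    """

    steep_to_shallow: float = 0.80
    shallow_to_plateau: float = 0.95
    plateau_to_descending: float = 1.05

    def __post_init__(self) -> None:
        if not (
            0.0 < self.steep_to_shallow < self.shallow_to_plateau < self.plateau_to_descending
        ):
            raise ValueError("region boundaries must be strictly increasing and positive")


@dataclass
class HyperplaneFit:
    """Least-squares hyperplane of ``ell*`` against joint angles.

    ``coeffs`` holds one slope per angle followed by the intercept (the
    minimum-norm solution via the Moore-Penrose pseudoinverse of the
    ones-augmented angle matrix).  ``r2`` is NaN with ``r2_defined`` False
    when the observations have zero variance.
    """

    coeffs: np.ndarray
    r2: float
    rmse: float
    eps_max: float
    n_obs: int
    r2_defined: bool = True

    @property
    def slopes(self) -> np.ndarray:
        return self.coeffs[:-1]

    @property
    def intercept(self) -> float:
        return float(self.coeffs[-1])


def hyperplane_fit(ell_norm_obs: np.ndarray, angles: np.ndarray) -> HyperplaneFit:
    """Fit ``ell* ~ c1 q1 + ... + c_{eta-1} q_{eta-1} + c_eta``.

    Uses the pseudoinverse of the ones-augmented angle matrix, giving the
    minimum-norm least-squares coefficients even for rank-deficient designs
    (e.g. constant angles).
    """
    y = np.asarray(ell_norm_obs, dtype=float).ravel()
    X = np.asarray(angles, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, n_angles = X.shape
    eta = n_angles + 1
    if len(y) != n:
        raise ValueError("observation count mismatch")
    if n < eta:
        raise ValueError(f"need at least {eta} observations for {n_angles} angle(s)")
    aug = np.column_stack([X, np.ones(n)])
    coeffs = np.linalg.pinv(aug) @ y
    pred = aug @ coeffs
    resid = y - pred
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2, defined = float("nan"), False
    else:
        r2, defined = 1.0 - ss_res / ss_tot, True
    return HyperplaneFit(
        coeffs=coeffs,
        r2=r2,
        rmse=float(np.sqrt(ss_res / n)),
        eps_max=float(np.max(np.abs(resid))) if n else 0.0,
        n_obs=n,
        r2_defined=defined,
    )


def classify_fl_region(ell_norm, boundaries: RegionBoundaries | None = None):
    """Map ``ell*`` to its force-length region label.

    The four labels partition (0, inf): steep ascending, shallow ascending,
    plateau, descending.  Accepts scalars or arrays.
    """
    b = boundaries or RegionBoundaries()
    x = np.asarray(ell_norm, dtype=float)
    if np.any(x <= 0):
        raise ValueError("normalised fibre length must be positive")
    labels = np.select(
        [x < b.steep_to_shallow, x < b.shallow_to_plateau, x <= b.plateau_to_descending],
        REGION_LABELS[:3],
        default=REGION_LABELS[3],
    )
    if labels.ndim == 0:
        return str(labels)
    return labels.astype(object)


@dataclass
class RangeSummary:
    """Per-MTU operating-range bookkeeping.

    ``table`` columns: viable ``ell*`` and ``l_MT`` extrema (per simulation
    pair and overall), the MTU-to-fibre range ratio, in-vivo ranges per trial
    and the fraction of the viable range used in vivo.  ``histograms`` maps
    MTU name to (bin_edges, counts) of viable ``ell*`` samples;
    ``region_counts`` maps MTU name to per-region sample counts.
    """

    table: pd.DataFrame
    histograms: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    region_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    bin_width: float = 0.02


def _pooled(battery: PoseBatteryResult, sims: tuple[int, ...], muscle: int):
    ln, lm = [], []
    for s in sims:
        if s not in battery.sims:
            continue
        r = battery.sims[s]
        sel = r.viable[:, muscle] & np.isfinite(r.ell_norm[:, muscle])
        ln.append(r.ell_norm[sel, muscle])
        lm.append(battery.lmt[sel, muscle])
    if not ln:
        return np.array([]), np.array([])
    return np.concatenate(ln), np.concatenate(lm)


def operating_range_summary(
    battery: PoseBatteryResult,
    solutions=None,
    limb: LimbModel | None = None,
    boundaries: RegionBoundaries | None = None,
    bin_width: float = 0.02,
) -> RangeSummary:
    """Viable operating ranges per MTU, optionally with in-vivo usage.

    ``solutions`` is an optional list of :class:`RedundancySolution`; their
    fibre-length trajectories give the in-vivo range per trial and the
    fraction of the viable range used.  Histogram bins have width
    ``bin_width`` (in units of ``ell_o``).
    """
    if limb is None:
        raise ValueError("limb model required (for ell_o and parameter context)")
    boundaries = boundaries or RegionBoundaries()
    rows = []
    histograms = {}
    region_counts = {}
    for i, p in enumerate(limb.params):
        row: dict[str, object] = {"muscle": p.name}
        ln_all, lm_all = _pooled(battery, (1, 2, 3, 4), i)
        for label, sims in (("sims12", (1, 2)), ("sims34", (3, 4)), ("all", (1, 2, 3, 4))):
            ln, lm = _pooled(battery, sims, i)
            if len(ln) == 0:
                row[f"ln_min_{label}"] = np.nan
                row[f"ln_max_{label}"] = np.nan
                row[f"lmt_min_{label}"] = np.nan
                row[f"lmt_max_{label}"] = np.nan
                continue
            row[f"ln_min_{label}"] = float(np.min(ln))
            row[f"ln_max_{label}"] = float(np.max(ln))
            row[f"lmt_min_{label}"] = float(np.min(lm))
            row[f"lmt_max_{label}"] = float(np.max(lm))
        if len(ln_all):
            fibre_range = float(np.max(ln_all) - np.min(ln_all))
            mtu_range = float((np.max(lm_all) - np.min(lm_all)) / p.ell_o)
            row["fibre_range"] = fibre_range
            row["mtu_range_norm"] = mtu_range
            row["range_ratio"] = mtu_range / fibre_range if fibre_range > 0 else np.nan
            if fibre_range > mtu_range * (1 + 1e-6) + 1e-8:
                logger.warning(
                    "%s: fibre range %.4f exceeds MTU range %.4f (parity violation)",
                    p.name, fibre_range, mtu_range,
                )
            lo = np.floor(np.min(ln_all) / bin_width) * bin_width
            hi = np.ceil(np.max(ln_all) / bin_width) * bin_width
            edges = np.arange(lo, hi + bin_width / 2, bin_width)
            if len(edges) < 2:
                edges = np.array([lo, lo + bin_width])
            counts, edges = np.histogram(ln_all, bins=edges)
            histograms[p.name] = (edges, counts)
            labels = classify_fl_region(ln_all, boundaries)
            region_counts[p.name] = {
                lab: int(np.sum(labels == lab)) for lab in REGION_LABELS
            }
            row["flagged_empty"] = False
        else:
            row["fibre_range"] = np.nan
            row["mtu_range_norm"] = np.nan
            row["range_ratio"] = np.nan
            row["flagged_empty"] = True

        if solutions:
            lo_iv, hi_iv = np.inf, -np.inf
            for sol in solutions:
                for ts in sol.trials:
                    ln_t = ts.ell_norm[:, i]
                    row[f"ln_min_{ts.label}"] = float(np.min(ln_t))
                    row[f"ln_max_{ts.label}"] = float(np.max(ln_t))
                    lo_iv = min(lo_iv, float(np.min(ln_t)))
                    hi_iv = max(hi_iv, float(np.max(ln_t)))
            if len(ln_all) and np.isfinite(lo_iv):
                viable_range = float(np.max(ln_all) - np.min(ln_all))
                row["fraction_used"] = (
                    (hi_iv - lo_iv) / viable_range if viable_range > 0 else np.nan
                )
        rows.append(row)
    return RangeSummary(
        table=pd.DataFrame(rows).set_index("muscle"),
        histograms=histograms,
        region_counts=region_counts,
        bin_width=bin_width,
    )


def decoupling_regression(
    summary: RangeSummary, params: list[MuscleParams]
) -> dict[str, dict[str, float]]:
    """OLS of the fibre-to-MTU range ratio on pennation and tendon length.

    The response is ``fibre range / (MTU range / ell_o)`` (1 means the fibre
    tracks the whole MTU excursion; lower values mean tendon compliance and
    pennation decouple the fibre).  Regressed separately against the
    pennation angle at optimal fibre length and against ``L_S / ell_o``.
    """
    names = [p.name for p in params]
    tbl = summary.table.loc[[n for n in names if n in summary.table.index]]
    ratio = (tbl["fibre_range"] / tbl["mtu_range_norm"]).to_numpy(dtype=float)
    keep = np.isfinite(ratio)
    if keep.sum() < 3:
        raise ValueError("need at least 3 MTUs with defined ranges")
    by_name = {p.name: p for p in params}
    alpha = np.array([by_name[n].alpha_o for n in tbl.index])[keep]
    rel_tendon = np.array([by_name[n].L_S / by_name[n].ell_o for n in tbl.index])[keep]
    ratio = ratio[keep]

    out = {}
    degenerate = []
    for key, x in (("pennation", alpha), ("relative_tendon_length", rel_tendon)):
        if np.ptp(x) == 0.0:
            degenerate.append(key)
            continue
        model = sm.OLS(ratio, sm.add_constant(x)).fit()
        out[key] = {
            "slope": float(model.params[1]),
            "intercept": float(model.params[0]),
            "r2": float(model.rsquared),
            "p_value": float(model.pvalues[1]),
            "n": int(model.nobs),
        }
    if not out:
        raise ValueError(
            f"degenerate design: predictor(s) {degenerate} have zero variance"
        )
    for key in degenerate:
        out[key] = {"error": "zero-variance predictor"}
    return out
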