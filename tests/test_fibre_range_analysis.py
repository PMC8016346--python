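"""Range summaries, region classification, hyperplane fits, decoupling."""

import numpy as np
import pytest

from myotendon import fibre_range_analysis as fra
from myotendon import synthetic_data as sd
from myotendon import static_posture_battery as spb
from myotendon.mtu_model import MuscleParams


# ---------------------------------------------------------------------------
# hyperplane fits
# ---------------------------------------------------------------------------


def test_hyperplane_exact_affine_data():
    q = np.linspace(-1, 1, 40)
    y = 0.5 + 0.01 * q
    fit = fra.hyperplane_fit(y, q)
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)
    assert fit.rmse == pytest.approx(0.0, abs=1e-12)
    assert fit.eps_max == pytest.approx(0.0, abs=1e-10)
    assert fit.slopes[0] == pytest.approx(0.01, rel=1e-10)
    assert fit.intercept == pytest.approx(0.5, rel=1e-10)


def test_hyperplane_matches_normal_equations_oracle():
    rng = np.random.default_rng(17)
    X = rng.normal(size=(200, 2))
    y = 0.9 + 0.05 * X[:, 0] - 0.12 * X[:, 1] + rng.normal(0, 0.02, 200)
    fit = fra.hyperplane_fit(y, X)
    aug = np.column_stack([X, np.ones(200)])
    want = np.linalg.solve(aug.T @ aug, aug.T @ y)
    np.testing.assert_allclose(fit.coeffs, want, atol=1e-8)
    resid = y - aug @ fit.coeffs
    assert fit.rmse == pytest.approx(np.sqrt(np.mean(resid**2)), rel=1e-10)
    assert fit.eps_max >= fit.rmse


def test_hyperplane_rank_deficient_minimum_norm():
    """Constant angles: pseudoinverse gives the minimum-norm solution, and
    duplicating observations leaves a full-rank fit unchanged."""
    y = np.array([0.8, 0.9, 1.0, 1.1])
    q = np.full(4, 0.3)
    fit = fra.hyperplane_fit(y, q)
    aug = np.column_stack([q, np.ones(4)])
    want = np.linalg.pinv(aug) @ y
    np.testing.assert_allclose(fit.coeffs, want, atol=1e-12)

    rng = np.random.default_rng(0)
    q2 = rng.normal(size=30)
    y2 = 1.0 + 0.2 * q2 + rng.normal(0, 0.01, 30)
    f1 = fra.hyperplane_fit(y2, q2)
    f2 = fra.hyperplane_fit(np.tile(y2, 2), np.tile(q2, 2))
    np.testing.assert_allclose(f1.coeffs, f2.coeffs, atol=1e-10)


def test_hyperplane_degenerate_inputs():
    with pytest.raises(ValueError):
        fra.hyperplane_fit(np.array([1.0]), np.zeros((1, 2)))
    fit = fra.hyperplane_fit(np.full(10, 0.7), np.linspace(0, 1, 10))
    assert not fit.r2_defined and np.isnan(fit.r2)


# ---------------------------------------------------------------------------
# region classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ln, label",
    [
        (1.0, "plateau"),
        (0.55, "steep_ascending"),
        (0.85, "shallow_ascending"),
        (1.30, "descending"),
        (0.95, "plateau"),
        (1.05, "plateau"),
    ],
)
def test_region_classification_defaults(ln, label):
    assert fra.classify_fl_region(ln) == label


def test_region_partition_exhaustive():
    x = np.linspace(0.01, 3.0, 1000)
    labels = fra.classify_fl_region(x)
    assert set(labels) <= set(fra.REGION_LABELS)
    # monotone label sequence: each region is a contiguous interval
    order = {lab: i for i, lab in enumerate(fra.REGION_LABELS)}
    idx = np.array([order[lab] for lab in labels])
    assert np.all(np.diff(idx) >= 0)


def test_region_boundary_validation():
    with pytest.raises(ValueError):
        fra.RegionBoundaries(0.9, 0.8, 1.05)


# ---------------------------------------------------------------------------
# operating-range summaries
# ---------------------------------------------------------------------------


def test_range_summary_bookkeeping(small_battery, toy_limb):
    summary = fra.operating_range_summary(small_battery, limb=toy_limb)
    tbl = summary.table
    assert set(tbl.index) == set(toy_limb.muscle_names)
    for name in toy_limb.muscle_names:
        row = tbl.loc[name]
        assert row["ln_min_all"] <= row["ln_max_all"]
        # parity: fibre range never exceeds the normalised MTU range
        assert row["fibre_range"] <= row["mtu_range_norm"] + 1e-9
        edges, counts = summary.histograms[name]
        assert counts.sum() > 0
        assert np.allclose(np.diff(edges), summary.bin_width)
        assert sum(summary.region_counts[name].values()) == counts.sum()


def test_rigid_parallel_muscle_range_equals_mtu_range():
    """Zero pennation + effectively rigid tendon: the viable fibre range is
    the MTU length range divided by the optimal fibre length."""
    import dataclasses

    limb = sd.make_toy_limb(1, 2, seed=2)
    params = []
    for p in limb.params:
        params.append(
            dataclasses.replace(p, alpha_o=0.0, k_T=1e7, L_S=0.2 * p.ell_o)
        )
    rigid = limb.with_params(params)
    battery = spb.run_battery(rigid, n_poses=150, seed=3, sims=(3, 4))
    summary = fra.operating_range_summary(battery, limb=rigid)
    for name in rigid.muscle_names:
        row = summary.table.loc[name]
        assert row["fibre_range"] == pytest.approx(row["mtu_range_norm"], abs=1e-5)


def test_fraction_used_equals_one_for_identical_ranges(small_battery, toy_limb):
    class _FakeTrial:
        pass

    # craft a fake solution whose in-vivo range equals the viable range
    summary0 = fra.operating_range_summary(small_battery, limb=toy_limb)

    class _TS:
        def __init__(self, ln, label):
            self.ell_norm = ln
            self.label = label

    class _Sol:
        def __init__(self, trials):
            self.trials = trials

    lns = []
    for i, name in enumerate(toy_limb.muscle_names):
        row = summary0.table.loc[name]
        lns.append(np.linspace(row["ln_min_all"], row["ln_max_all"], 7))
    sol = _Sol([_TS(np.column_stack(lns), "walk")])
    summary = fra.operating_range_summary(small_battery, solutions=[sol], limb=toy_limb)
    for name in toy_limb.muscle_names:
        assert summary.table.loc[name, "fraction_used"] == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# decoupling regression
# ---------------------------------------------------------------------------


def _params(name, alpha_deg, ratio, ell=0.02):
    return MuscleParams(
        name=name, m=1e-3, ell_o=ell, L_S=ratio * ell,
        alpha_o=np.radians(alpha_deg), F_max=10.0, tau_act=0.007, tau_deact=0.027,
    )


def _summary_from(ratios_table):
    import pandas as pd

    return fra.RangeSummary(
        table=pd.DataFrame(ratios_table).set_index("muscle")
    )


def test_decoupling_matches_closed_form_ols():
    params = [_params(f"m{i}", a, r) for i, (a, r) in enumerate(
        [(0, 0.2), (10, 0.5), (20, 1.0), (30, 2.0), (35, 4.0)]
    )]
    ratio = np.array([0.95, 0.90, 0.82, 0.71, 0.60])
    tbl = [
        {"muscle": p.name, "fibre_range": float(r), "mtu_range_norm": 1.0}
        for p, r in zip(params, ratio)
    ]
    rep = fra.decoupling_regression(_summary_from(tbl), params)
    x = np.array([p.alpha_o for p in params])
    sx, sy = x - x.mean(), ratio - ratio.mean()
    slope = float(sx @ sy / (sx @ sx))
    intercept = float(ratio.mean() - slope * x.mean())
    assert rep["pennation"]["slope"] == pytest.approx(slope, abs=1e-10)
    assert rep["pennation"]["intercept"] == pytest.approx(intercept, abs=1e-10)
    assert rep["pennation"]["slope"] < 0  # more pennation -> more decoupling


def test_decoupling_pennation_family_negative_slope():
    """A family varying only pennation at near-rigid tendon stiffness shows
    the constant-thickness prediction: the fibre-to-MTU range ratio falls as
    pennation rises."""
    from myotendon import limb_geometry as lg

    rows, params = [], []
    ell, slack, arm = 0.020, 0.010, 0.008
    for i, alpha in enumerate([0.0, 10.0, 20.0, 30.0, 35.0]):
        a = np.radians(alpha)
        p = MuscleParams(
            name=f"fam{i}", m=1e-3, ell_o=ell, L_S=slack, alpha_o=a,
            F_max=10.0, k_T=1e6, tau_act=0.007, tau_deact=0.027,
        )
        c0 = slack + ell * np.cos(a)  # fibre at optimum in the neutral pose
        mk = lambda name, sign: lg.MTUGeometry(
            muscle=name, dof_coupling=["q1"], terms=[((0,), c0), ((1,), sign * arm)]
        )
        antagonist = MuscleParams(
            name="ant", m=1e-3, ell_o=ell, L_S=slack, alpha_o=0.0,
            F_max=10.0, k_T=1e6, tau_act=0.007, tau_deact=0.027,
        )
        limb_i = lg.LimbModel(
            dofs=[lg.DOFSpec("q1", -0.8, 0.8)],
            mtus=[(p, mk(p.name, 1.0)), (antagonist, mk("ant", -1.0))],
        )
        battery = spb.run_battery(limb_i, n_poses=80, seed=4, sims=(3, 4))
        row = fra.operating_range_summary(battery, limb=limb_i).table.loc[p.name]
        assert np.isfinite(row["fibre_range"])
        rows.append({
            "muscle": p.name,
            "fibre_range": row["fibre_range"],
            "mtu_range_norm": row["mtu_range_norm"],
        })
        params.append(p)
    rep = fra.decoupling_regression(_summary_from(rows), params)
    assert rep["pennation"]["slope"] < 0


def test_decoupling_degenerate_design():
    params = [_params(f"m{i}", 10, 1.0) for i in range(4)]
    tbl = [
        {"muscle": p.name, "fibre_range": 0.5, "mtu_range_norm": 1.0} for p in params
    ]
    with pytest.raises(ValueError, match="zero variance"):
        fra.decoupling_regression(_summary_from(tbl), params)
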