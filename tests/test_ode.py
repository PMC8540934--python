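"""Structural and dynamical properties of the 17-equation ODE system."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tme import (
    ModelState,
    ParameterSet,
    SimulationConfig,
    dimensionalize,
    nondimensionalize,
    rhs,
    simulate,
    total_cells,
)
from tme.ode import parameter_jacobian, state_jacobian, steady_state_residual
from tme.state import PARAM_INDEX, PARAM_NAMES, STATE_INDEX, STATE_NAMES


def random_params(rng) -> ParameterSet:
    vals = rng.uniform(0.01, 1.0, size=75)
    vals[PARAM_INDEX["alpha_NC"]] = rng.uniform(0.1, 1.0)
    for cap in ("C0", "A0", "E0"):
        vals[PARAM_INDEX[cap]] = rng.uniform(10.0, 100.0)
    return ParameterSet(vals)


def test_zero_state_only_sources_flow(cluster1):
    """At the origin every mass-action and logistic term vanishes; only the
    constant naive-pool sources remain."""
    p = cluster1.params
    dx = rhs(np.zeros(17), p)
    expected = np.zeros(17)
    expected[STATE_INDEX["TN"]] = p["A_TN"]
    expected[STATE_INDEX["DN"]] = p["A_DN"]
    expected[STATE_INDEX["MN"]] = p["A_M"]
    np.testing.assert_allclose(dx, expected, rtol=0, atol=0)


def test_cancer_at_capacity_decays_only(cluster1):
    """With C = C0 the logistic factor vanishes and dC/dt = -delta_C C0."""
    p = cluster1.params
    x = np.zeros(17)
    x[STATE_INDEX["C"]] = p["C0"]
    dx = rhs(x, p)
    assert dx[STATE_INDEX["C"]] == pytest.approx(-p["delta_C"] * p["C0"], rel=1e-12)


def test_total_cells_weights():
    x = np.zeros(17)
    assert total_cells(x) == 0.0
    x[STATE_INDEX["MN"]] = 100.0
    assert total_cells(x) == pytest.approx(20.0)  # naive macrophages at 20%


def test_total_cells_cluster1_steady(cluster1):
    # direct arithmetic over the cluster-1 steady-state row
    assert total_cells(cluster1.profile.steady.values) == pytest.approx(218084.0)


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_naive_pool_flux_conservation(seed):
    """Activation losses of the naive pools reappear, with identical
    magnitude, as gains of the activated pools."""
    rng = np.random.default_rng(seed)
    p = random_params(rng)
    x = rng.uniform(0.0, 5.0, size=17)
    dx = rhs(x, p)
    g = {n: x[STATE_INDEX[n]] for n in STATE_NAMES}
    th_loss = (p["delta_ThTr"] * g["Tr"] + p["delta_ThIL10"] * g["IL10"]
               + p["delta_Th"]) * g["Th"]
    tc_loss = (p["delta_TcTr"] * g["Tr"] + p["delta_TcIL10"] * g["IL10"]
               + p["delta_Tc"]) * g["Tc"]
    tr_loss = p["delta_Tr"] * g["Tr"]
    gain = (dx[STATE_INDEX["Th"]] + th_loss
            + dx[STATE_INDEX["Tc"]] + tc_loss
            + dx[STATE_INDEX["Tr"]] + tr_loss)
    tn_balance = p["A_TN"] - gain - p["delta_TN"] * g["TN"]
    assert dx[STATE_INDEX["TN"]] == pytest.approx(tn_balance, rel=1e-10, abs=1e-12)


def test_negative_state_rejected(cluster1):
    x = np.zeros(17)
    x[0] = -1.0
    with pytest.raises(ValueError, match="negative"):
        rhs(x, cluster1.params)


def test_nan_params_rejected(cluster1):
    bad = cluster1.params.values.copy()
    with pytest.raises(ValueError, match="non-finite"):
        ParameterSet(bad * np.nan)


def test_logistic_bound_monotone_approach():
    """With no inhibitors and delta_C = 0, cancer follows a pure logistic
    approach to C0, monotone from any interior start."""
    vals = np.zeros(75)
    vals[PARAM_INDEX["lambda_C"]] = 0.1
    vals[PARAM_INDEX["alpha_NC"]] = 0.5
    vals[PARAM_INDEX["C0"]] = 1000.0
    vals[PARAM_INDEX["A0"]] = 1.0
    vals[PARAM_INDEX["E0"]] = 1.0
    p = ParameterSet(vals)
    x0 = np.zeros(17)
    x0[STATE_INDEX["C"]] = 250.0
    traj = simulate(p, x0, SimulationConfig(horizon=400.0, n_points=200))
    c = traj.states[:, STATE_INDEX["C"]]
    assert np.all(np.diff(c) >= -1e-6 * 1000.0)
    assert c[-1] == pytest.approx(1000.0, rel=1e-4)
    assert np.all(c <= 1000.0 + 1e-6)


def test_fixed_point_is_constant(cluster1):
    """Starting exactly on the fitted steady state, every component stays
    within 0.1% over the full horizon."""
    ss = cluster1.profile.steady.values
    traj = simulate(cluster1.params, ss, SimulationConfig(n_points=100))
    rel = np.abs(traj.states - ss) / ss
    assert rel.max() < 1e-3


def test_trajectory_nonnegative(cluster1):
    traj = cluster1.simulate()
    assert np.all(traj.states >= 0.0)


def test_trajectory_csv_schema(cluster1, tmp_path):
    traj = cluster1.simulate(cfg=SimulationConfig(horizon=50, n_points=10))
    out = tmp_path / "traj.csv"
    traj.to_csv(out)
    header = out.read_text().splitlines()[0].split(",")
    assert header == ["time_days", *STATE_NAMES, "total_cells"]


def test_jacobians_match_finite_differences(cluster1):
    """The analytic state/parameter Jacobians agree with central finite
    differences of the right-hand side."""
    rng = np.random.default_rng(1)
    p = cluster1.params
    x = cluster1.profile.steady.values * rng.uniform(0.5, 1.5, size=17)
    J = state_jacobian(x, p)
    for j in rng.choice(17, 6, replace=False):
        h = 1e-6 * max(x[j], 1.0)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        fd = (rhs(xp, p) - rhs(xm, p)) / (2 * h)
        np.testing.assert_allclose(J[:, j], fd, rtol=1e-5, atol=1e-8 * np.abs(fd).max())
    Jp = parameter_jacobian(x, p)
    for j in rng.choice(75, 10, replace=False):
        name = PARAM_NAMES[j]
        v = p[name]
        h = 1e-6 * max(v, 1e-8)
        fd = (rhs(x, p.replace(**{name: v + h}))
              - rhs(x, p.replace(**{name: v - h}))) / (2 * h)
        np.testing.assert_allclose(
            Jp[:, j], fd, rtol=1e-5,
            atol=1e-8 * max(np.abs(fd).max(), 1e-12),
        )


class TestNondimensionalization:
    def test_unit_scales_identity(self, cluster1):
        nd = nondimensionalize(cluster1.params, np.ones(17))
        np.testing.assert_array_equal(nd.values, cluster1.params.values)

    def test_round_trip(self, cluster1):
        scales = cluster1.profile.scale_max.values
        back = dimensionalize(nondimensionalize(cluster1.params, scales))
        np.testing.assert_allclose(back.values, cluster1.params.values, rtol=1e-12)

    def test_invalid_scales_rejected(self, cluster1):
        with pytest.raises(ValueError):
            nondimensionalize(cluster1.params, np.zeros(17))

    def test_trajectory_equivalence(self, cluster1):
        """Rescaled simulation of the nondimensional system reproduces the
        dimensional trajectory to 1e-6 relative."""
        scales = cluster1.profile.scale_max.values
        nd = nondimensionalize(cluster1.params, scales)
        cfg = SimulationConfig(horizon=600.0, n_points=150)
        t_dim = simulate(cluster1.params, cluster1.profile.initial.values, cfg)
        t_nd = simulate(nd, cluster1.profile.initial.values / scales, cfg)
        ref = np.maximum(np.abs(t_dim.states), 1e-6 * t_dim.states.max())
        rel = np.abs(t_nd.states * scales - t_dim.states) / ref
        assert rel.max() < 1e-6


def test_steady_state_residual_of_fit(fitted):
    for res in fitted.values():
        assert steady_state_residual(res.profile.steady.values, res.params) < 1e-8
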