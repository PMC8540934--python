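"""Steady-state parameter estimation: exactness, positivity, structure."""

import numpy as np
import pytest

from tme import ModelState, apply_scale, default_assumptions, default_known_rates, estimate
from tme.estimation import (
    UNKNOWN_NAMES,
    AssumptionSet,
    EstimationOptions,
    KnownDeathRates,
    build_linear_system,
)
from tme.ode import rhs
from tme.profiles import ClusterProfile, study_profiles
from tme.state import HALF_LIFE_RATE_NAMES, PARAM_NAMES


def test_unknown_partition():
    """17 steady-state equations + 40 assumption relations determine the
    57 non-configured rates; 13 half-life rates and 5 configured constants
    complete the 75."""
    assert len(UNKNOWN_NAMES) == 57
    assert len(default_assumptions()) == 40
    assert len(UNKNOWN_NAMES) + len(HALF_LIFE_RATE_NAMES) + 5 == 75


def test_exact_solve_and_residual(fitted):
    """The default system is square and consistent: exact mode, machine-level
    linear residual, and the fitted set zeroes the right-hand side at the
    steady state."""
    for res in fitted.values():
        assert res.report.mode == "exact"
        assert res.report.rank == 57
        assert res.residual < 1e-10
        f = rhs(res.profile.steady.values, res.params)
        assert np.linalg.norm(f) / np.linalg.norm(res.profile.steady.values) < 1e-10


def test_positivity(fitted):
    for res in fitted.values():
        assert np.all(res.params.values >= 0.0)


def test_adipocyte_rate_closed_form(fitted):
    """The adipocyte equation involves a single unknown, so
    lambda_A = delta_A / (1 - A_inf/A0) in closed form."""
    for res in fitted.values():
        p = res.params
        a_inf = res.profile.steady["A"]
        expected = p["delta_A"] / (1.0 - a_inf / p["A0"])
        assert p["lambda_A"] == pytest.approx(expected, rel=1e-10)


def test_kill_split_tc_vs_ifng_row_coefficients(cluster1):
    """The kill-split relation enters as
    delta_CTc [Tc_max] - 6 delta_CIg [Ig_max] = 0."""
    profile = cluster1.profile
    system = build_linear_system(profile)
    i = system.row_labels.index("kill_split_tc_vs_ifng")
    row = system.matrix[i]
    nz = {UNKNOWN_NAMES[j]: row[j] for j in np.nonzero(row)[0]}
    assert set(nz) == {"delta_CTc", "delta_CIg"}
    assert nz["delta_CTc"] == pytest.approx(profile.scale_max["Tc"])
    assert nz["delta_CIg"] == pytest.approx(-6.0 * profile.scale_max["Ig"])
    assert system.rhs[i] == 0.0


def test_scale_one_is_identity(cluster1):
    """Scaling any relation by 1.0 reproduces the estimate bit-exactly."""
    profile = cluster1.profile
    scaled = apply_scale(default_assumptions(), "kill_split_tc_vs_ifng", 1.0)
    rep = estimate(profile, scaled)
    np.testing.assert_array_equal(rep.params.values, cluster1.params.values)


def test_unknown_relation_label():
    with pytest.raises(KeyError):
        default_assumptions().scaled("no_such_relation", 2.0)
    with pytest.raises(ValueError):
        default_assumptions().scaled("kill_split_tc_vs_ifng", -1.0)


@pytest.mark.parametrize("label,direction", [("kill_split_tc_vs_ifng", "down"), ("death_split_natural_vs_ifng", "down")])
def test_monotone_response_patterns(cluster1, label, direction):
    """Down-scaling the Tc-vs-IFN kill split (kill_split_tc_vs_ifng) raises delta_CTc and
    lowers delta_C; down-scaling the natural-death split (death_split_natural_vs_ifng) does the
    opposite — the response pattern of the scaled-assumption tables."""
    base = cluster1.params
    rep = estimate(cluster1.profile, apply_scale(default_assumptions(), label, 0.2))
    if label == "kill_split_tc_vs_ifng":
        assert rep.params["delta_CTc"] > base["delta_CTc"]
        assert rep.params["delta_C"] < base["delta_C"]
    else:
        assert rep.params["delta_CTc"] < base["delta_CTc"]
        assert rep.params["delta_C"] > base["delta_C"]
    assert rep.params["delta_CIg"] < base["delta_CIg"]


def test_end_to_end_consistency(cluster1):
    """Simulating the fitted system from the cluster's initial conditions
    converges to the steady state used for estimation, within 1% in every
    variable."""
    traj = cluster1.simulate(require_convergence=True)
    ss = cluster1.profile.steady.values
    assert traj.converged
    np.testing.assert_allclose(traj.final_state, ss, rtol=1e-2)


def test_zero_steady_state_rejected(cluster1):
    bad = cluster1.profile.steady.to_dict()
    bad["D"] = 0.0
    with pytest.raises(ValueError):
        ClusterProfile(
            cluster="x",
            initial=cluster1.profile.initial,
            steady=ModelState.from_dict(bad),
            scale_max=cluster1.profile.scale_max,
        )


def test_known_rates_validation():
    with pytest.raises(ValueError, match="13"):
        KnownDeathRates({"delta_TN": 0.1})
    rates = default_known_rates()
    assert len(rates.rates) == 13
    assert all(v > 0 for v in rates.rates.values())


def test_provenance_flags(cluster1):
    prov = cluster1.params.provenance
    assert sum(v == "estimated" for v in prov.values()) == 57
    assert sum(v == "half_life" for v in prov.values()) == 13
    assert sum(v == "configured" for v in prov.values()) == 5
    assert prov["delta_Tc"] == "half_life"
    assert prov["C0"] == "configured"


def test_params_json_round_trip(cluster1, tmp_path):
    path = tmp_path / "p.json"
    cluster1.params.to_json(path)
    from tme.state import ParameterSet
    back = ParameterSet.from_json(path)
    np.testing.assert_array_equal(back.values, cluster1.params.values)
    assert back.cluster == cluster1.params.cluster


def test_synthetic_profiles_estimable(synthetic_cohort):
    """Estimation succeeds, in exact mode with positive rates, on profiles
    extracted from a synthetic cohort."""
    for profile in synthetic_cohort["profiles"]:
        rep = estimate(profile)
        assert rep.mode == "exact"
        assert np.all(rep.params.values >= 0.0)
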