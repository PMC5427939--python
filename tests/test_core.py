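"""Robust constraint algebra: means, deviations, assembly, solves, audits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rampfba as rf
from rampfba import fixtures
from rampfba.core import RampProblem, _linear_constraint_rows
from rampfba.exceptions import ParameterError, SolverStatusError, UnsupportedStructureError
from rampfba.scenarios import ScenarioSet, build_model3


def _random_triple(rng, q=4, n=3):
    p = rng.dirichlet(np.ones(q) * 2.0) + 1e-3
    p = p / p.sum()
    S_hat = rng.normal(size=(q, n)) * rng.choice([0.01, 1.0, 10.0])
    v = rng.normal(size=n)
    return p, S_hat, v


def test_mean_row_toy(toy):
    np.testing.assert_allclose(toy.mean, [1.0, -1.0], atol=1e-15)


def test_mean_row_single_scenario():
    row = np.array([[2.0, -3.0, 0.5]])
    np.testing.assert_array_equal(rf.mean_row(np.array([1.0]), row), row[0])


def test_mean_row_matches_weighted_sum(rng):
    for _ in range(50):
        p, S_hat, _ = _random_triple(rng)
        expected = sum(pk * Sk for pk, Sk in zip(p, S_hat))
        np.testing.assert_allclose(rf.mean_row(p, S_hat), expected, atol=1e-12)


def test_mean_row_shape_error():
    with pytest.raises(ValueError):
        rf.mean_row(np.array([0.5, 0.5]), np.ones((3, 2)))


def test_deviation_matrix_identical_rows_is_zero():
    S_hat = np.tile(np.array([1.0, -2.0]), (4, 1))
    R = rf.deviation_matrix(np.full(4, 0.25), S_hat, delta=3.0)
    assert np.abs(R).max() == 0.0


def test_variance_identity_random(rng):
    """||R v||^2 equals delta^2 times the scenario variance of S_k v."""
    for _ in range(100):
        p, S_hat, v = _random_triple(rng)
        delta = float(rng.uniform(0.5, 4.0))
        R = rf.deviation_matrix(p, S_hat, delta)
        vals = S_hat @ v
        mu = p @ vals
        sd = np.sqrt(np.dot(p, (vals - mu) ** 2))
        assert np.linalg.norm(R @ v) == pytest.approx(delta * sd, abs=1e-10)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**9))
def test_variance_identity_property(seed):
    rng = np.random.default_rng(seed)
    p, S_hat, v = _random_triple(rng)
    R = rf.deviation_matrix(p, S_hat, 3.0)
    vals = S_hat @ v
    sd = np.sqrt(np.dot(p, (vals - p @ vals) ** 2))
    assert np.linalg.norm(R @ v) == pytest.approx(3.0 * sd, abs=1e-10)


def test_growth_norm_zero_spread():
    assert rf.growth_norm_coefficient(np.array([0.25, 0.5, 0.25]), [1.0, 1.0, 1.0], 3.0) == 0.0


def test_growth_norm_toy_column(toy):
    r = rf.growth_norm_coefficient(toy.p, [0.9, 1.0, 1.1], 3.0)
    assert r == pytest.approx(3.0 * np.sqrt(0.25 * 0.01 + 0.25 * 0.01), abs=1e-12)
    assert round(r, 4) == 0.2121


def test_growth_norm_agrees_with_full_matrix(rng):
    """Single uncertain column: scalar r times |v_col| equals ||R v||."""
    for _ in range(30):
        q, n = 5, 4
        p = rng.dirichlet(np.ones(q)) + 1e-3
        p /= p.sum()
        base = rng.normal(size=n)
        col = int(rng.integers(0, n))
        S_hat = np.tile(base, (q, 1))
        S_hat[:, col] = base[col] + rng.normal(size=q)
        v = rng.normal(size=n)
        R = rf.deviation_matrix(p, S_hat, 3.0)
        r = rf.growth_norm_coefficient(p, S_hat[:, col], 3.0)
        assert np.linalg.norm(R @ v) == pytest.approx(r * abs(v[col]), abs=1e-10)


# -- assembly and solves -----------------------------------------------------

def test_linear_path_rejects_non_growth_uncertainty(toy):
    net = toy.network
    scen = ScenarioSet(
        q=3,
        probabilities=toy.p,
        growth_scenarios=np.array([[-1.2, -1.0, -0.8]]),
        delta=3.0,
        base_column=1,  # second flux, not the objective column
    )
    with pytest.raises(UnsupportedStructureError, match="socp"):
        rf.assemble_linear_ramp(net, scen, M=0.2)


def test_linear_path_rejects_negative_growth_lower_bound(chain):
    net = chain.copy()
    net.L[net.growth_index] = -1.0
    with pytest.raises(UnsupportedStructureError, match="nonnegative growth"):
        rf.assemble_linear_ramp(net, build_model3(net, 0.1), M=0.0)


def test_zero_spread_m_zero_equals_fba(chain, random_nets):
    for net in [chain] + random_nets[:5]:
        scen = build_model3(net, 0.0)
        prob = rf.assemble_linear_ramp(net, scen, M=np.zeros(net.m))
        ramp = rf.solve_ramp(prob)
        fba = rf.solve_fba(net)
        assert ramp.status == "optimal"
        assert ramp.objective == pytest.approx(fba.objective, abs=1e-8)
        # and the linear rows are algebraically S v = 0 in disguise
        A, b, _ = _linear_constraint_rows(prob)
        np.testing.assert_allclose(A[: net.m], net.S, atol=1e-12)
        np.testing.assert_allclose(b, 0.0, atol=1e-15)


def test_linear_and_socp_paths_agree(chain):
    scen = build_model3(chain, 0.2)
    gamma = rf.solve_fba(chain).objective
    M = rf.fit_M(chain, scen, gamma)
    lin = rf.solve_ramp(rf.assemble_linear_ramp(chain, scen, M))
    socp = rf.solve_ramp(rf.assemble_socp_ramp(chain, scen, M))
    assert lin.status == socp.status == "optimal"
    assert lin.objective == pytest.approx(socp.objective, abs=1e-6)


def test_socp_huge_m_reduces_to_bounds_only(toy):
    prob = RampProblem.from_rows(toy.network, [toy.p], [toy.S_hat], toy.delta, np.array([1e6]))
    state = rf.solve_ramp(prob)
    assert state.objective == pytest.approx(1.0, abs=1e-9)  # v1's upper bound


def test_toy_optimum_lies_in_robust_region(toy):
    state = rf.solve_ramp(toy.problem())
    assert state.status == "optimal"
    assert 0 < state.objective < 1  # strictly inside, unlike FBA's vertex
    audit = rf.audit_feasibility(state.v, toy.problem(), tolerance=1e-7)
    assert audit.feasible


def test_linear_problem_json_round_trip(chain):
    scen = build_model3(chain, 0.2)
    M = rf.fit_M(chain, scen, rf.solve_fba(chain).objective)
    prob = rf.assemble_linear_ramp(chain, scen, M)
    again = RampProblem.from_json_dict(prob.to_json_dict())
    np.testing.assert_allclose(again.mean_rows, prob.mean_rows)
    np.testing.assert_allclose(again.growth_norm, prob.growth_norm)
    np.testing.assert_allclose(again.M, prob.M)
    assert rf.solve_ramp(again).objective == pytest.approx(rf.solve_ramp(prob).objective, abs=1e-9)


def test_growth_monotone_in_m(chain):
    scen = build_model3(chain, 0.2)
    gamma = rf.solve_fba(chain).objective
    M = rf.fit_M(chain, scen, gamma)
    base = rf.solve_ramp(rf.assemble_linear_ramp(chain, scen, M)).objective
    for i in range(chain.m):
        bumped = M.copy()
        bumped[i] += 1.0
        grown = rf.solve_ramp(rf.assemble_linear_ramp(chain, scen, bumped)).objective
        assert grown >= base - 1e-9


# -- M fitting ---------------------------------------------------------------

def test_fit_m_zero_spread_gives_zero(chain):
    gamma = rf.solve_fba(chain).objective
    M = rf.fit_M(chain, build_model3(chain, 0.0), gamma)
    assert np.abs(M).max() <= 1e-9


def test_fit_m_reaches_target(chain, random_nets):
    for net in [chain] + random_nets[:5]:
        gamma = rf.solve_fba(net).objective
        scen = build_model3(net, 0.2)
        M = rf.fit_M(net, scen, gamma)
        state = rf.solve_ramp(rf.assemble_linear_ramp(net, scen, M))
        assert state.objective == pytest.approx(gamma, rel=1e-6)


def test_fit_m_infeasible_target(chain):
    gamma = rf.solve_fba(chain).objective
    with pytest.raises(SolverStatusError):
        rf.fit_M(chain, build_model3(chain, 0.2), gamma * 1.5)


# -- audits and the uncertainty set -----------------------------------------

def test_audit_printed_point_infeasible(toy):
    prob = toy.problem()
    audit = rf.audit_feasibility(np.array([0.75, 0.75]), prob)
    assert not audit.feasible
    assert audit.deviation[0] == pytest.approx(np.sqrt(2) * 0.45 * 0.75, abs=1e-12)
    assert rf.audit_feasibility(np.zeros(2), prob).feasible


def test_audit_allows_small_nonzero_mean(toy):
    """Robust relaxation admits points violating strict steady state."""
    v = np.array([0.05, 0.0])  # mean residual 0.05 <= M - ||Rv||
    audit = rf.audit_feasibility(v, toy.problem())
    assert audit.feasible
    assert abs(audit.mu[0]) > 1e-3  # FBA would reject this point


def test_audit_frame_round_trip(toy):
    df = rf.audit_feasibility(np.zeros(2), toy.problem()).to_frame()
    assert list(df["verdict"]) == ["feasible"]


def test_sampled_rows_stay_within_m(toy, rng):
    state = rf.solve_ramp(toy.problem())
    for _ in range(200):
        u = rng.normal(size=3)
        u /= max(np.linalg.norm(u), 1.0)
        row = rf.sample_uncertainty_constraint(toy.p, toy.S_hat, toy.delta, u)
        assert row @ state.v <= toy.M + 1e-9
    with pytest.raises(ParameterError):
        rf.sample_uncertainty_constraint(toy.p, toy.S_hat, toy.delta, np.array([1.0, 1.0, 1.0]))


def test_u_zero_gives_mean_and_aligned_u_is_tight(toy):
    v = np.array([0.1, -0.05])
    np.testing.assert_allclose(
        rf.sample_uncertainty_constraint(toy.p, toy.S_hat, toy.delta, np.zeros(3)), toy.mean
    )
    Rv = toy.R @ v
    u = Rv / np.linalg.norm(Rv)
    row = rf.sample_uncertainty_constraint(toy.p, toy.S_hat, toy.delta, u)
    assert row @ v == pytest.approx(toy.mean @ v + np.linalg.norm(Rv), abs=1e-12)


# -- scenario possibility (identical-components test) ------------------------

def test_possible_scenarios_constructed():
    # rows scale a common value: S_hat v has identical components
    v = np.array([1.0, 2.0, 0.0])
    S_hat = np.array([[2.0, 1.0, 5.0], [4.0, 0.0, -1.0], [0.0, 2.0, 7.0]])  # each row . (1,2) = 4
    verdicts = rf.biologically_possible([S_hat], v)
    assert verdicts[0].possible
    assert verdicts[0].alpha == pytest.approx(4.0)
    assert not verdicts[0].alpha_near_zero


def test_toy_scenarios_impossible_for_unit_fluxes(toy):
    verdicts = rf.biologically_possible([toy.S_hat], np.array([1.0, 1.0]))
    assert not verdicts[0].possible
    np.testing.assert_allclose(verdicts[0].scenario_values, [-0.3, 0.0, 0.3], atol=1e-12)


def test_zero_spread_always_possible(chain):
    scen = build_model3(chain, 0.0)
    v = rf.solve_fba(chain).v
    verdicts = rf.biologically_possible(scen, v, network=chain)
    assert all(r.possible for r in verdicts)
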