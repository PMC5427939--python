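"""Scenario builders: digit rule, scaled/proportional/tail-mass variants."""

import numpy as np
import pytest
from scipy.stats import norm

import rampfba.scenarios as sc
from rampfba import fixtures
from rampfba.exceptions import ParameterError, ScenarioError


@pytest.fixture(scope="module")
def biomass_net():
    """Network whose biomass carries the two canonical printed growth
    coefficients: +53.95 (ADP, an output) and -0.000223 (a trace input)."""
    return fixtures.build_network(
        ["ADP", "OHPH", "SRC", "BM"],
        [
            ("EX_SRC", {"SRC": 1.0}, 0.0, 10.0, ""),
            ("MK_OHPH", {"SRC": -1.0, "OHPH": 1.0}, 0.0, 1000.0, ""),
            ("GROWTH", {"SRC": -1.0, "ADP": 53.95, "OHPH": -0.000223, "BM": 1.0}, 0.0, 1000.0, ""),
            ("DM_ADP", {"ADP": -1.0}, 0.0, 100000.0, ""),
            ("DM_BM", {"BM": -1.0}, 0.0, 1000.0, ""),
        ],
        "GROWTH",
    )


TEXTS = {"ADP": "53.95", "OHPH": "-0.000223", "SRC": "1", "BM": "1"}


@pytest.mark.parametrize(
    "text,step",
    [("53.95", 1e-3), ("−0.000223", 1e-7), ("-0.000223", 1e-7), ("2", 0.1), ("45.73", 1e-3)],
)
def test_digit_step(text, step):
    assert sc.infer_digit_step(text) == pytest.approx(step, rel=1e-12)


def test_digit_step_rejects_non_numeric():
    with pytest.raises(ParameterError):
        sc.infer_digit_step("abc")


def test_model1_printed_scenarios(biomass_net):
    scen = sc.build_model1(biomass_net, coefficient_texts=TEXTS)
    i_adp = biomass_net.met_index("ADP")
    i_ohph = biomass_net.met_index("OHPH")
    np.testing.assert_allclose(
        scen.growth_scenarios[i_adp], [53.948, 53.949, 53.95, 53.951, 53.952], atol=1e-12
    )
    np.testing.assert_allclose(
        scen.growth_scenarios[i_ohph],
        [-0.0002232, -0.0002231, -0.000223, -0.0002229, -0.0002228],
        atol=1e-15,
    )
    np.testing.assert_array_equal(scen.probabilities, [0.0351, 0.2389, 0.4520, 0.2389, 0.0351])
    assert scen.probabilities.sum() == pytest.approx(1.0, abs=0)
    assert scen.delta == 3.0


def test_model1_zero_coefficients_get_no_spread(chain):
    # metabolites absent from the growth reaction have no unspecified digit
    scen = sc.build_model1(chain)
    spread = scen.row_spread()
    assert spread[chain.met_index("A0")] == 0.0
    assert spread[chain.met_index("A1")] > 0.0


def test_model1_coverage_error(biomass_net):
    with pytest.raises(ScenarioError, match="missing"):
        sc.build_model1(biomass_net, coefficient_texts={"ADP": "53.95"})


def test_model2_scaling(biomass_net):
    scen = sc.build_model2(biomass_net, rho=2, coefficient_texts=TEXTS)
    i_adp = biomass_net.met_index("ADP")
    assert scen.growth_scenarios[i_adp][0] == pytest.approx(53.946, abs=1e-12)
    assert scen.growth_scenarios[i_adp][-1] == pytest.approx(53.954, abs=1e-12)
    # rho = 1 is the identity scaling
    m1 = sc.build_model1(biomass_net, coefficient_texts=TEXTS)
    m2 = sc.build_model2(biomass_net, rho=1, coefficient_texts=TEXTS)
    np.testing.assert_array_equal(m1.growth_scenarios, m2.growth_scenarios)
    with pytest.raises(ParameterError):
        sc.build_model2(biomass_net, rho=10, coefficient_texts=TEXTS)


@pytest.mark.parametrize("rho", range(1, 10))
def test_model2_preserves_signs_on_printed_coefficients(biomass_net, rho):
    scen = sc.build_model2(biomass_net, rho=rho, coefficient_texts=TEXTS)
    base = biomass_net.growth_column
    for mid in ("ADP", "OHPH"):  # the printed digit-rule examples
        i = biomass_net.met_index(mid)
        assert np.all(np.sign(scen.growth_scenarios[i]) == np.sign(base[i]))


def test_model3_arithmetic(biomass_net):
    scen = sc.build_model3(biomass_net, sigma=0.2)
    i = biomass_net.met_index("OHPH")
    c = -0.000223
    # multipliers ascend 1-sigma .. 1+sigma; the family is symmetric about c
    np.testing.assert_allclose(
        scen.growth_scenarios[i], [c * 0.8, c * 0.9, c, c * 1.1, c * 1.2], atol=1e-18
    )
    np.testing.assert_allclose(
        np.sort(scen.growth_scenarios[i]), [-0.0002676, -0.0002453, -0.000223, -0.0002007, -0.0001784], atol=1e-18
    )
    zero = sc.build_model3(biomass_net, sigma=0.0)
    assert zero.row_spread().max() == 0.0
    with pytest.raises(ParameterError):
        sc.build_model3(biomass_net, sigma=-0.1)


def test_model4_delta_from_tail_mass(biomass_net):
    assert sc.build_model4(biomass_net, epsilon2=0.0027, coefficient_texts=TEXTS).delta == pytest.approx(3.000, abs=5e-4)
    assert sc.build_model4(biomass_net, epsilon2=0.3173, coefficient_texts=TEXTS).delta == pytest.approx(1.000, abs=5e-4)
    deltas = [
        sc.build_model4(biomass_net, epsilon2=e, coefficient_texts=TEXTS).delta
        for e in (0.01, 0.1, 0.5, 0.9)
    ]
    assert all(a > b for a, b in zip(deltas, deltas[1:]))
    for bad in (0.0, 1.0, -0.5):
        with pytest.raises(ParameterError):
            sc.build_model4(biomass_net, epsilon2=bad, coefficient_texts=TEXTS)


def test_single_coefficient_targets_one_row(biomass_net):
    scen = sc.build_single_coefficient(biomass_net, "ADP", sigma=0.1)
    spread = scen.row_spread()
    i = biomass_net.met_index("ADP")
    assert spread[i] > 0
    others = np.delete(spread, i)
    assert np.all(others == 0.0)
    np.testing.assert_allclose(
        scen.growth_scenarios[i] / 53.95, [0.9, 0.95, 1.0, 1.05, 1.1], atol=1e-12
    )
    assert sc.build_single_coefficient(biomass_net, "ADP", sigma=0.0).row_spread().max() == 0.0


def test_single_coefficient_requires_biomass_membership(chain):
    with pytest.raises(LookupError):
        sc.build_single_coefficient(chain, "A0", sigma=0.1)  # not in the growth reaction
    with pytest.raises(LookupError):
        sc.build_single_coefficient(chain, "nope", sigma=0.1)


@pytest.mark.parametrize("builder", ["m1", "m2", "m3", "m4", "single"])
def test_scenario_mean_reproduces_base_row(biomass_net, builder):
    """All families are symmetric: the weighted mean equals the FBA coefficient."""
    scen = {
        "m1": lambda: sc.build_model1(biomass_net, coefficient_texts=TEXTS),
        "m2": lambda: sc.build_model2(biomass_net, rho=5, coefficient_texts=TEXTS),
        "m3": lambda: sc.build_model3(biomass_net, sigma=0.25),
        "m4": lambda: sc.build_model4(biomass_net, epsilon2=0.1, coefficient_texts=TEXTS),
        "single": lambda: sc.build_single_coefficient(biomass_net, "ADP", sigma=0.3),
    }[builder]()
    np.testing.assert_allclose(scen.row_means(), biomass_net.growth_column, atol=1e-12)
    # scenario values are monotone in the scenario index
    diffs = np.diff(scen.growth_scenarios, axis=1)
    assert np.all((diffs >= -1e-15).all(axis=1) | (diffs <= 1e-15).all(axis=1))


def test_invalid_probabilities_rejected(biomass_net):
    with pytest.raises(ScenarioError):
        sc.build_model1(biomass_net, coefficient_texts=TEXTS, probabilities=np.array([0.5, 0.5, 0.1, 0.2, 0.2]))


def test_normal_band_probabilities_sum_to_one():
    p = sc.normal_band_probabilities()
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(p, [0.0668, 0.2417, 0.3829, 0.2417, 0.0668], atol=5e-5)


def test_spec_round_trip_and_build(biomass_net, tmp_path):
    spec = sc.ScenarioSpec(model="model3", sigma=0.2)
    assert spec.model == "model3_proportional"
    import json

    path = tmp_path / "spec.json"
    path.write_text(json.dumps(spec.to_json_dict()))
    again = sc.ScenarioSpec.from_json(path)
    assert again.to_json_dict() == spec.to_json_dict()
    scen = again.build(biomass_net)
    assert scen.q == 5
    with pytest.raises(ParameterError):
        sc.ScenarioSpec(model="model2")  # rho missing


def test_scenario_table_written(biomass_net, tmp_path):
    import pandas as pd

    scen = sc.build_model1(biomass_net, coefficient_texts=TEXTS)
    path = tmp_path / "table.tsv"
    sc.write_scenario_table(scen, biomass_net, path)
    df = pd.read_csv(path, sep="\t")
    assert list(df.columns[:2]) == ["metabolite", "base"]
    assert df.iloc[-1, 0] == "probability"
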