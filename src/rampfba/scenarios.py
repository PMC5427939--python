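"""Discrete scenario sets for uncertain biomass stoichiometry.

Each metabolite row i of the stoichiometric matrix gets ``q`` scenarios for
its growth-column coefficient, a shared probability vector ``p``, and the
standard-normal percentile ``delta`` that scales the scenario standard
deviation inside the robust constraint. Four scenario families are provided:

* digit model - perturb the first unspecified decimal digit by 0, +/-1, +/-2
  steps of ``10**-(d+1)`` where ``d`` is the number of printed decimals;
* scaled digit model - the same steps magnified by an integer ``rho``;
* proportional model - multiplicative scenarios ``c * (1 + eta*sigma)`` with
  ``eta`` in {-1, -1/2, 0, 1/2, 1};
* tail-mass model - digit scenarios with ``delta`` recomputed from a total
  two-sided tail mass ``2*epsilon``;

plus a single-coefficient variant in which only one chosen metabolite row is
uncertain (the proportional scenarios), used by the maximal-sigma search.

All families are symmetric about the base coefficient, so the probability-
weighted scenario mean reproduces the deterministic FBA row exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, InvalidOperation
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ParameterError, ScenarioError
from .network import MetabolicNetwork

__all__ = [
    "MODEL1_PROBABILITIES",
    "normal_band_probabilities",
    "ScenarioSet",
    "ScenarioSpec",
    "infer_digit_step",
    "default_coefficient_texts",
    "build_model1",
    "build_model2",
    "build_model3",
    "build_model4",
    "build_single_coefficient",
    "write_scenario_table",
]

#: Scenario probabilities as printed in the source model description
#: (extreme, inner, central, inner, extreme); they sum to exactly 1.
MODEL1_PROBABILITIES = np.array([0.0351, 0.2389, 0.4520, 0.2389, 0.0351])

#: Perturbation multipliers for the five digit-model scenarios, in order.
_DIGIT_ETAS = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
#: Multipliers for the proportional scenarios.
_PROP_ETAS = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])


def normal_band_probabilities() -> np.ndarray:
    """Literal standard-normal band masses for cut points -3/2, -1/2, 1/2, 3/2.

    These are (0.0668, 0.2417, 0.3829, 0.2417, 0.0668); an alternative to the
    printed constants of :data:`MODEL1_PROBABILITIES` for users who want the
    exact band interpretation.
    """
    cuts = np.array([-np.inf, -1.5, -0.5, 0.5, 1.5, np.inf])
    return np.diff(norm.cdf(cuts))


@dataclass
class ScenarioSet:
    """Per-metabolite-row scenarios for the growth-column coefficient.

    ``growth_scenarios`` is an (m, q) array; rows without uncertainty carry q
    copies of the base coefficient. ``base_column`` is the index of the
    uncertain reaction column (the growth reaction by construction).
    """

    q: int
    probabilities: np.ndarray
    growth_scenarios: np.ndarray
    delta: float
    base_column: int

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.growth_scenarios = np.atleast_2d(np.asarray(self.growth_scenarios, dtype=float))
        if self.q < 1:
            raise ScenarioError("scenario count q must be >= 1")
        if self.probabilities.shape != (self.q,):
            raise ScenarioError("probability vector length must equal q")
        if np.any(self.probabilities <= 0):
            raise ScenarioError("scenario probabilities must be positive")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ScenarioError("scenario probabilities must sum to 1 (tol 1e-9)")
        if self.growth_scenarios.shape[1] != self.q:
            raise ScenarioError("growth_scenarios must have q columns")
        if not self.delta > 0:
            raise ScenarioError("delta must be positive")

    @property
    def m(self) -> int:
        return self.growth_scenarios.shape[0]

    def row_means(self) -> np.ndarray:
        """Probability-weighted scenario mean of each row's growth coefficient."""
        return self.growth_scenarios @ self.probabilities

    def row_spread(self) -> np.ndarray:
        return self.growth_scenarios.max(axis=1) - self.growth_scenarios.min(axis=1)

    def scenario_rows(self, network: MetabolicNetwork, i: int) -> np.ndarray:
        """The full (q, n) scenario matrix for metabolite row i.

        Only the growth column varies; every other coefficient is replicated
        across scenarios.
        """
        rows = np.tile(network.S[i], (self.q, 1))
        rows[:, self.base_column] = self.growth_scenarios[i]
        return rows


@dataclass
class ScenarioSpec:
    """Declarative scenario configuration (JSON round-trippable)."""

    model: str
    rho: Optional[int] = None
    sigma: Optional[float] = None
    epsilon2: Optional[float] = None
    target: Optional[str] = None
    probabilities: Optional[List[float]] = None
    delta: Optional[float] = None

    _ALIASES = {
        "model1": "model1_digit",
        "model2": "model2_digit_scaled",
        "model3": "model3_proportional",
        "model4": "model4_epsilon",
        "single": "single_coefficient",
    }

    def __post_init__(self) -> None:
        self.model = self._ALIASES.get(self.model, self.model)
        required = {
            "model1_digit": (),
            "model2_digit_scaled": ("rho",),
            "model3_proportional": ("sigma",),
            "model4_epsilon": ("epsilon2",),
            "single_coefficient": ("sigma", "target"),
        }
        if self.model not in required:
            raise ParameterError(f"unknown scenario model {self.model!r}")
        for name in required[self.model]:
            if getattr(self, name) is None:
                raise ParameterError(f"scenario model {self.model!r} requires {name!r}")

    @classmethod
    def from_json(cls, path) -> "ScenarioSpec":
        return cls(**json.loads(open(path).read()))

    def to_json_dict(self) -> dict:
        d = {"model": self.model}
        for key in ("rho", "sigma", "epsilon2", "target", "probabilities", "delta"):
            if getattr(self, key) is not None:
                d[key] = getattr(self, key)
        return d

    def build(self, network: MetabolicNetwork) -> ScenarioSet:
        probs = None if self.probabilities is None else np.asarray(self.probabilities)
        if self.model == "model1_digit":
            out = build_model1(network, probabilities=probs)
        elif self.model == "model2_digit_scaled":
            out = build_model2(network, rho=self.rho, probabilities=probs)
        elif self.model == "model3_proportional":
            out = build_model3(network, sigma=self.sigma, probabilities=probs)
        elif self.model == "model4_epsilon":
            out = build_model4(network, epsilon2=self.epsilon2, probabilities=probs)
        else:
            out = build_single_coefficient(network, target=self.target, sigma=self.sigma)
        if self.delta is not None:
            out.delta = float(self.delta)
        return out


# -- digit-step inference ---------------------------------------------------

def infer_digit_step(coefficient_text: str) -> float:
    """Step size ``10**-(d+1)`` for the first unspecified decimal digit.

    ``d`` is the number of digits printed after the decimal point; an integer
    has d = 0, hence step 0.1. E.g. "53.95" -> 0.001, "-0.000223" -> 1e-7.
    """
    text = str(coefficient_text).strip().replace("−", "-")
    try:
        dec = Decimal(text)
    except InvalidOperation:
        raise ParameterError(f"not a finite decimal: {coefficient_text!r}") from None
    if not dec.is_finite():
        raise ParameterError(f"not a finite decimal: {coefficient_text!r}")
    exponent = dec.as_tuple().exponent
    decimals = max(-int(exponent), 0)
    return 10.0 ** (-(decimals + 1))


def default_coefficient_texts(network: MetabolicNetwork) -> Dict[str, str]:
    """Shortest round-trip decimal text for each nonzero growth coefficient.

    Model files store binary floats, so the printed decimal is approximated by
    Python's shortest repr; override per coefficient when the source document
    states the value explicitly.
    """
    col = network.growth_column
    return {
        network.metabolite_ids[i]: repr(float(col[i]))
        for i in np.nonzero(col)[0]
    }


def _resolve_texts(network: MetabolicNetwork, coefficient_texts: Optional[Dict[str, str]]) -> Dict[str, str]:
    if coefficient_texts is None:
        return default_coefficient_texts(network)
    col = network.growth_column
    missing = [
        network.metabolite_ids[i]
        for i in np.nonzero(col)[0]
        if network.metabolite_ids[i] not in coefficient_texts
    ]
    if missing:
        raise ScenarioError(f"coefficient texts missing for growth metabolites: {missing}")
    return coefficient_texts


def _digit_scenarios(network: MetabolicNetwork, texts: Dict[str, str], scale: float) -> np.ndarray:
    col = network.growth_column
    scen = np.tile(col[:, None], (1, 5))
    for i in np.nonzero(col)[0]:
        step = infer_digit_step(texts[network.metabolite_ids[i]]) * scale
        scen[i] = col[i] + step * _DIGIT_ETAS
    return scen


def _probs(probabilities: Optional[np.ndarray]) -> np.ndarray:
    return MODEL1_PROBABILITIES.copy() if probabilities is None else np.asarray(probabilities, float)


# -- builders ---------------------------------------------------------------

def build_model1(
    network: MetabolicNetwork,
    coefficient_texts: Optional[Dict[str, str]] = None,
    probabilities: Optional[np.ndarray] = None,
) -> ScenarioSet:
    """Default digit model: five scenarios ``c + eta * 10**-(d+1)``, eta in 0, +/-1, +/-2.

    Zero growth coefficients have no unspecified digit and receive no
    scenarios (all five copies equal zero).
    """
    texts = _resolve_texts(network, coefficient_texts)
    return ScenarioSet(
        q=5,
        probabilities=_probs(probabilities),
        growth_scenarios=_digit_scenarios(network, texts, scale=1.0),
        delta=3.0,
        base_column=network.growth_index,
    )


def build_model2(
    network: MetabolicNetwork,
    rho: int,
    coefficient_texts: Optional[Dict[str, str]] = None,
    probabilities: Optional[np.ndarray] = None,
) -> ScenarioSet:
    """Digit model with steps magnified by an integer ``rho`` (1..9).

    Integers beyond 9 flip coefficient signs on realistic biomass rows and
    are rejected; rho = 1 reduces to the default digit model.
    """
    if int(rho) != rho or not (1 <= int(rho) <= 9):
        raise ParameterError(f"rho must be an integer in 1..9, got {rho!r}")
    texts = _resolve_texts(network, coefficient_texts)
    return ScenarioSet(
        q=5,
        probabilities=_probs(probabilities),
        growth_scenarios=_digit_scenarios(network, texts, scale=float(rho)),
        delta=3.0,
        base_column=network.growth_index,
    )


def build_model3(
    network: MetabolicNetwork,
    sigma: float,
    probabilities: Optional[np.ndarray] = None,
) -> ScenarioSet:
    """Proportional model: scenarios ``c * (1 + eta*sigma)``, eta in {0, +/-1/2, +/-1}.

    sigma = 0 is the degenerate zero-spread family used in the FBA-limit
    tests.
    """
    if sigma < 0:
        raise ParameterError(f"sigma must be nonnegative, got {sigma!r}")
    col = network.growth_column
    scen = col[:, None] * (1.0 + sigma * _PROP_ETAS)[None, :]
    return ScenarioSet(
        q=5,
        probabilities=_probs(probabilities),
        growth_scenarios=scen,
        delta=3.0,
        base_column=network.growth_index,
    )


def build_model4(
    network: MetabolicNetwork,
    epsilon2: float,
    coefficient_texts: Optional[Dict[str, str]] = None,
    probabilities: Optional[np.ndarray] = None,
) -> ScenarioSet:
    """Digit scenarios with delta set from the total tail mass ``2*epsilon``.

    ``delta = Phi^{-1}(1 - epsilon2/2)``; e.g. 2*epsilon = 0.0027 gives
    delta = 3.000 and 2*epsilon = 0.3173 gives delta = 1.000.
    """
    if not (0.0 < epsilon2 < 1.0):
        raise ParameterError(f"epsilon2 (total tail mass) must lie in (0, 1), got {epsilon2!r}")
    texts = _resolve_texts(network, coefficient_texts)
    return ScenarioSet(
        q=5,
        probabilities=_probs(probabilities),
        growth_scenarios=_digit_scenarios(network, texts, scale=1.0),
        delta=float(norm.ppf(1.0 - epsilon2 / 2.0)),
        base_column=network.growth_index,
    )


def build_single_coefficient(
    network: MetabolicNetwork,
    target: str,
    sigma: float,
    probabilities: Optional[np.ndarray] = None,
) -> ScenarioSet:
    """Uncertainty in a single growth coefficient only.

    The target metabolite's coefficient gets the proportional scenarios
    ``c * (1 + eta*sigma)``; every other row has zero spread.
    """
    if sigma < 0:
        raise ParameterError(f"sigma must be nonnegative, got {sigma!r}")
    i = network.met_index(target)
    col = network.growth_column
    if col[i] == 0:
        raise LookupError(f"metabolite {target!r} has no growth-column coefficient")
    scen = np.tile(col[:, None], (1, 5))
    scen[i] = col[i] * (1.0 + sigma * _PROP_ETAS)
    return ScenarioSet(
        q=5,
        probabilities=_probs(probabilities),
        growth_scenarios=scen,
        delta=3.0,
        base_column=network.growth_index,
    )


def write_scenario_table(scenarios: ScenarioSet, network: MetabolicNetwork, path) -> None:
    """Audit TSV: metabolite, base coefficient, the q scenario values, then a
    final row with the shared probabilities."""
    cols = [f"scenario{k + 1}" for k in range(scenarios.q)]
    df = pd.DataFrame(scenarios.growth_scenarios, columns=cols)
    df.insert(0, "metabolite", network.metabolite_ids)
    df.insert(1, "base", network.growth_column)
    prob_row = {"metabolite": "probability", "base": np.nan}
    prob_row.update(dict(zip(cols, scenarios.probabilities)))
    df = pd.concat([df, pd.DataFrame([prob_row])], ignore_index=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
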