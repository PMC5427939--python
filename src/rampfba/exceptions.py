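"""Exception hierarchy for rampfba."""


class RampError(Exception):
    """Base class for all rampfba errors."""


class ModelFormatError(RampError):
    """A model file could not be parsed under the named standard."""


class ModelError(RampError):
    """A parsed model violates a structural invariant (bounds, objective...)."""


class GPRParseError(RampError):
    """A gene-protein-reaction rule is malformed."""


class ScenarioError(RampError):
    """Scenario construction failed (coverage, shapes, probabilities)."""


class ParameterError(RampError, ValueError):
    """A parameter is outside its admissible range."""


class UnsupportedStructureError(RampError):
    """The linearized path was asked to handle uncertainty it cannot express.

    Uncertainty outside the growth column (or a growth flux that may be
    negative) requires the second-order-cone path.
    """


class SolverStatusError(RampError):
    """An optimization that must succeed returned a non-optimal status."""


class ScreenError(RampError):
    """A knockout screen could not be run (e.g. infeasible wild type)."""


class ScoringError(RampError):
    """Prediction scoring is undefined (no labeled genes, zero totals)."""


class FixtureError(RampError):
    """A synthetic fixture could not be constructed."""
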