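"""Gene-essentiality screening and its comparison with experiment.

A gene is called essential when its in-silico knockout drops the optimal
growth rate below a threshold fraction (default 50%) of wild type. Screens
run under plain FBA or under the robust model; in the robust case the slack
bounds M are fitted once on the wild-type network (L1-minimal, anchored to
the FBA optimum) and held fixed across knockouts, so every mutant is judged
against the same robust geometry.

Also implements the maximal-multiplier search: for a single uncertain growth
coefficient, find the largest proportional scenario half-width sigma at which
the robust screen still returns exactly the FBA essential-gene set (doubling
from 1e-4 until mismatch, then bisection to a stated accuracy, with a cap for
coefficients that never produce a mismatch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Set, Union

import numpy as np
import pandas as pd

from .core import assemble_linear_ramp, fit_M, solve_ramp
from .exceptions import ParameterError, ScoringError, ScreenError, SolverStatusError
from .network import MetabolicNetwork, apply_knockout, solve_fba
from .scenarios import ScenarioSet, build_single_coefficient

__all__ = [
    "KnockoutScreen",
    "ConfusionMatrix",
    "SigmaSearchResult",
    "screen_knockouts",
    "compare_to_experiment",
    "predictive_power",
    "max_sigma_search",
]

log = logging.getLogger(__name__)


@dataclass
class KnockoutScreen:
    """Per-gene knockout outcomes for one method."""

    method: str
    threshold: float
    wild_type_growth: float
    knockout_growth: Dict[str, float] = field(default_factory=dict)
    ratio: Dict[str, float] = field(default_factory=dict)
    essential: Dict[str, bool] = field(default_factory=dict)

    @property
    def essential_set(self) -> Set[str]:
        return {g for g, e in self.essential.items() if e}

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.knockout_growth)
        return pd.DataFrame(
            {
                "gene": genes,
                "wt_growth": [self.wild_type_growth] * len(genes),
                "ko_growth": [self.knockout_growth[g] for g in genes],
                "ratio": [self.ratio[g] for g in genes],
                "essential": [int(self.essential[g]) for g in genes],
            }
        )


@dataclass
class ConfusionMatrix:
    """Counts of essentiality calls against experimental labels."""

    tp: int
    fp: int
    fn: int
    tn: int
    unlabeled: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": ["true_positive", "false_positive", "false_negative", "true_negative"],
                "count": [self.tp, self.fp, self.fn, self.tn],
            }
        )


@dataclass
class SigmaSearchResult:
    coefficient: str
    sigma_max: float
    bounded: bool
    iterations: int
    mismatch_at_floor: bool = False


def _growth_of(state) -> float:
    """Growth rate of a solve, with non-optimal outcomes scored as zero."""
    if state.status != "optimal" or state.objective is None:
        return 0.0
    return max(float(state.objective), 0.0)


def screen_knockouts(
    network: MetabolicNetwork,
    method: str = "fba",
    scenarios: Optional[ScenarioSet] = None,
    M: Optional[np.ndarray] = None,
    threshold: float = 0.5,
    refit_m: bool = False,
) -> KnockoutScreen:
    """Knock out each gene in turn and score growth against wild type.

    For the robust method, M defaults to the L1 fit on the wild type at the
    FBA optimum and is held fixed across knockouts; ``refit_m=True`` instead
    re-anchors M to each mutant's own FBA optimum (which erases much of the
    FBA/robust contrast and is off by default).
    """
    method = method.lower()
    if method not in {"fba", "ramp"}:
        raise ParameterError(f"method must be 'fba' or 'ramp', got {method!r}")
    if method == "ramp" and scenarios is None:
        raise ParameterError("the robust screen requires a scenario set")

    wt_fba = solve_fba(network)
    if wt_fba.status != "optimal" or wt_fba.objective is None or wt_fba.objective <= 0:
        raise ScreenError(f"wild-type FBA solve failed (status {wt_fba.status}) or has zero growth")
    gamma_star = float(wt_fba.objective)

    if method == "ramp":
        if M is None:
            M = fit_M(network, scenarios, gamma_star)
        wt_growth = _growth_of(solve_ramp(assemble_linear_ramp(network, scenarios, M)))
        if wt_growth <= 0:
            raise ScreenError("wild-type robust solve has zero growth")
    else:
        wt_growth = gamma_star

    screen = KnockoutScreen(method=method, threshold=threshold, wild_type_growth=wt_growth)
    for gene in network.gene_ids:
        mutant = apply_knockout(network, {gene})
        if method == "fba":
            growth = _growth_of(solve_fba(mutant))
        else:
            M_used = M
            if refit_m:
                mut_fba = solve_fba(mutant)
                try:
                    M_used = fit_M(mutant, scenarios, _growth_of(mut_fba))
                except SolverStatusError:
                    M_used = M
            growth = _growth_of(solve_ramp(assemble_linear_ramp(mutant, scenarios, M_used)))
        ratio = growth / wt_growth
        screen.knockout_growth[gene] = growth
        screen.ratio[gene] = ratio
        # a 1e-9 guard keeps knife-edge knockouts (ratio == threshold up to LP
        # round-off) classified identically by the FBA and robust paths
        screen.essential[gene] = ratio < threshold - 1e-9
    return screen


def _as_bool_label(value) -> bool:
    if isinstance(value, str):
        v = value.strip().lower()
        if v in {"essential", "1", "true", "yes"}:
            return True
        if v in {"nonessential", "non-essential", "0", "false", "no"}:
            return False
        raise ScoringError(f"unrecognized essentiality label {value!r}")
    return bool(value)


def compare_to_experiment(
    screen: KnockoutScreen, labels: Mapping[str, Union[str, bool, int]]
) -> ConfusionMatrix:
    """Tabulate predicted vs experimental essentiality.

    Genes without a label are excluded from the counts but tallied in
    ``unlabeled``.
    """
    tp = fp = fn = tn = 0
    unlabeled = 0
    scored = 0
    for gene, predicted in screen.essential.items():
        if gene not in labels:
            unlabeled += 1
            continue
        actual = _as_bool_label(labels[gene])
        scored += 1
        if predicted and actual:
            tp += 1
        elif predicted and not actual:
            fp += 1
        elif not predicted and actual:
            fn += 1
        else:
            tn += 1
    if scored == 0:
        raise ScoringError("no screened gene carries an experimental label")
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn, unlabeled=unlabeled)


def predictive_power(cm: ConfusionMatrix) -> float:
    """(TP + TN) / total scored genes."""
    if cm.total == 0:
        raise ScoringError("predictive power undefined for an empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def max_sigma_search(
    network: MetabolicNetwork,
    coefficient: str,
    reference_essential_set: Optional[Set[str]] = None,
    accuracy: float = 1e-4,
    cap: float = 1e26,
    threshold: float = 0.5,
    sigma_start: float = 1e-4,
) -> SigmaSearchResult:
    """Largest single-coefficient multiplier keeping the robust screen == FBA.

    Doubles sigma from ``sigma_start`` until the robust essential-gene set no
    longer equals the FBA reference set (exact set equality), then bisects the
    bracket down to ``accuracy``. If doubling exceeds ``cap`` without any
    mismatch, only a lower bound exists and ``bounded`` is False.
    """
    wt = solve_fba(network)
    if wt.status != "optimal" or wt.objective is None or wt.objective <= 0:
        raise ScreenError("sigma search needs a feasible wild type with positive growth")
    gamma_star = float(wt.objective)
    if reference_essential_set is None:
        reference_essential_set = screen_knockouts(network, "fba", threshold=threshold).essential_set

    iterations = 0

    def matches(sigma: float) -> bool:
        nonlocal iterations
        iterations += 1
        scen = build_single_coefficient(network, coefficient, sigma)
        M = fit_M(network, scen, gamma_star)
        screen = screen_knockouts(network, "ramp", scenarios=scen, M=M, threshold=threshold)
        return screen.essential_set == reference_essential_set

    if not matches(sigma_start):
        return SigmaSearchResult(coefficient, 0.0, True, iterations, mismatch_at_floor=True)

    lo = sigma_start
    hi = None
    sigma = sigma_start * 2.0
    while sigma <= cap:
        if matches(sigma):
            lo = sigma
            sigma *= 2.0
        else:
            hi = sigma
            break
    if hi is None:
        log.info("sigma search for %s hit the cap %.3g without a mismatch", coefficient, cap)
        return SigmaSearchResult(coefficient, lo, False, iterations)

    while hi - lo > accuracy and iterations < 300:
        mid = 0.5 * (lo + hi)
        if matches(mid):
            lo = mid
        else:
            hi = mid
    return SigmaSearchResult(coefficient, lo, True, iterations)
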