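"""Deterministic constraint-based model core.

Reads genome-scale models (SBML level 3 + fbc, or COBRA-style JSON), holds the
stoichiometric system, evaluates gene-protein-reaction (GPR) rules, applies
gene knockouts, and solves the baseline flux balance analysis (FBA) linear
program

    max  v_Growth
    s.t. S v = 0,  L <= v <= U,

where ``S`` is the metabolites-by-reactions stoichiometric matrix and
``L``/``U`` are flux bounds in mmol/gDW/h.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np

from . import _lp
from ._lp import INFEASIBLE, NUMERIC_FAILURE, OPTIMAL, UNBOUNDED  # re-export for callers
from .exceptions import GPRParseError, ModelError, ModelFormatError

__all__ = [
    "MetabolicNetwork",
    "FluxState",
    "load_model",
    "save_json_model",
    "evaluate_gpr",
    "gpr_genes",
    "apply_knockout",
    "apply_environment",
    "solve_fba",
    "OPTIMAL",
    "INFEASIBLE",
    "UNBOUNDED",
    "NUMERIC_FAILURE",
]

#: Replacement for infinite/absent flux bounds (COBRA convention).
DEFAULT_BIG_BOUND = 1000.0


@dataclass
class FluxState:
    """A flux vector with its objective value and solver status."""

    v: Optional[np.ndarray]
    objective: Optional[float]
    status: str

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL


@dataclass
class MetabolicNetwork:
    """A stoichiometric system with bounds, a growth reaction and gene rules.

    The growth (biomass) column follows the usual sign convention: consumed
    precursors negative, products positive, the biomass pseudo-metabolite +1.
    A reaction is reversible iff ``L[j] < 0 < U[j]``; a fixed flux (ATP
    maintenance style) has ``L[j] == U[j]``.
    """

    metabolite_ids: List[str]
    reaction_ids: List[str]
    S: np.ndarray
    L: np.ndarray
    U: np.ndarray
    growth_index: int
    gpr: List[str] = field(default_factory=list)
    gene_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 2:
            self.S = np.atleast_2d(self.S)
        self.L = np.asarray(self.L, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        if not self.gpr:
            self.gpr = [""] * len(self.reaction_ids)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n(self) -> int:
        return len(self.reaction_ids)

    @property
    def growth_column(self) -> np.ndarray:
        return self.S[:, self.growth_index]

    def met_index(self, met_id: str) -> int:
        try:
            return self.metabolite_ids.index(met_id)
        except ValueError:
            raise LookupError(f"unknown metabolite id {met_id!r}") from None

    def rxn_index(self, rxn_id: str) -> int:
        try:
            return self.reaction_ids.index(rxn_id)
        except ValueError:
            raise LookupError(f"unknown reaction id {rxn_id!r}") from None

    def validate(self) -> None:
        m, n = self.S.shape
        if m != len(self.metabolite_ids) or n != len(self.reaction_ids):
            raise ModelError(
                f"S is {self.S.shape} but ids imply "
                f"({len(self.metabolite_ids)}, {len(self.reaction_ids)})"
            )
        if self.L.shape != (n,) or self.U.shape != (n,):
            raise ModelError("bound vectors must have one entry per reaction")
        bad = np.nonzero(self.L > self.U)[0]
        if bad.size:
            j = int(bad[0])
            raise ModelError(
                f"lower bound exceeds upper bound for reaction "
                f"{self.reaction_ids[j]!r} ({self.L[j]} > {self.U[j]})"
            )
        if not (0 <= self.growth_index < n):
            raise ModelError(f"growth_index {self.growth_index} out of range")
        if len(self.gpr) != n:
            raise ModelError("one GPR string (possibly empty) required per reaction")
        known = set(self.gene_ids)
        for rule in self.gpr:
            missing = gpr_genes(rule) - known
            if missing:
                raise ModelError(f"GPR references unknown genes: {sorted(missing)}")

    def copy(self) -> "MetabolicNetwork":
        return replace(
            self,
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            L=self.L.copy(),
            U=self.U.copy(),
            gpr=list(self.gpr),
            gene_ids=list(self.gene_ids),
        )

    # -- serialization -----------------------------------------------------
    def to_json_dict(self) -> dict:
        """COBRA-style JSON dialect (readable by cobrapy)."""
        reactions = []
        for j, rid in enumerate(self.reaction_ids):
            mets = {
                self.metabolite_ids[i]: float(self.S[i, j])
                for i in np.nonzero(self.S[:, j])[0]
            }
            reactions.append(
                {
                    "id": rid,
                    "name": rid,
                    "metabolites": mets,
                    "lower_bound": float(self.L[j]),
                    "upper_bound": float(self.U[j]),
                    "gene_reaction_rule": self.gpr[j],
                    "objective_coefficient": 1.0 if j == self.growth_index else 0.0,
                }
            )
        return {
            "id": "rampfba_model",
            "metabolites": [
                {"id": mid, "name": mid, "compartment": "c"} for mid in self.metabolite_ids
            ],
            "reactions": reactions,
            "genes": [{"id": g, "name": g} for g in self.gene_ids],
            "compartments": {"c": "cytosol"},
            "version": "1",
        }


def save_json_model(network: MetabolicNetwork, path) -> None:
    Path(path).write_text(json.dumps(network.to_json_dict(), indent=1))


def _from_cobra(model, big_bound: float) -> MetabolicNetwork:
    from cobra.util.array import create_stoichiometric_matrix

    objective_rxns = [
        j for j, r in enumerate(model.reactions) if getattr(r, "objective_coefficient", 0.0)
    ]
    if not objective_rxns:
        raise ModelError("model declares no objective (growth) reaction")
    S = create_stoichiometric_matrix(model)
    L = np.array([r.lower_bound for r in model.reactions], dtype=float)
    U = np.array([r.upper_bound for r in model.reactions], dtype=float)
    L[np.isneginf(L)] = -big_bound
    U[np.isposinf(U)] = big_bound
    L[np.isposinf(L)] = big_bound  # degenerate but keep finite
    U[np.isneginf(U)] = -big_bound
    return MetabolicNetwork(
        metabolite_ids=[x.id for x in model.metabolites],
        reaction_ids=[r.id for r in model.reactions],
        S=S,
        L=L,
        U=U,
        growth_index=objective_rxns[0],
        gpr=[r.gene_reaction_rule or "" for r in model.reactions],
        gene_ids=[g.id for g in model.genes],
    )


def load_model(path, format: Optional[str] = None, big_bound: float = DEFAULT_BIG_BOUND) -> MetabolicNetwork:
    """Read a genome-scale model from SBML (L3+fbc) or COBRA-style JSON.

    Infinite bounds are replaced by ``+/-big_bound``. The growth reaction is
    the (first) reaction with a nonzero objective coefficient.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"model file not found: {path}")
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    try:
        if format == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        elif format == "json":
            model = cobra.io.load_json_model(str(path))
        else:
            raise ModelFormatError(f"unknown model format {format!r}")
    except ModelFormatError:
        raise
    except Exception as exc:  # parser errors vary by backend
        raise ModelFormatError(f"could not parse {path.name} as {format}: {exc}") from exc
    return _from_cobra(model, big_bound)


# -- gene rules ------------------------------------------------------------

def _parse_gpr(rule: str):
    import warnings

    from cobra.core.gene import GPR

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # cobra downgrades parse errors to warnings
            gpr = GPR.from_string(rule)
    except Exception as exc:
        raise GPRParseError(f"malformed GPR rule {rule!r}: {exc}") from exc
    if gpr.body is None:  # cobra returns an empty GPR for unparseable rules
        raise GPRParseError(f"malformed GPR rule {rule!r}")
    return gpr


def gpr_genes(rule: str) -> Set[str]:
    """The set of gene ids referenced by a rule (empty rule -> empty set)."""
    if not rule or not rule.strip():
        return set()
    return set(_parse_gpr(rule).genes)


def evaluate_gpr(rule: str, knocked_out: Iterable[str], known_genes: Optional[Set[str]] = None) -> bool:
    """Evaluate a boolean AND/OR gene rule.

    Knocked-out genes evaluate False, all other genes True; an empty rule is
    True (the reaction needs no gene product).
    """
    if not rule or not rule.strip():
        return True
    gpr = _parse_gpr(rule)
    if known_genes is not None:
        missing = set(gpr.genes) - set(known_genes)
        if missing:
            raise GPRParseError(f"GPR references unknown genes: {sorted(missing)}")
    return bool(gpr.eval(knocked_out))


def apply_knockout(network: MetabolicNetwork, genes: Iterable[str]) -> MetabolicNetwork:
    """Return a copy in which reactions disabled by the knockout have L=U=0.

    Columns are kept (bounds zeroed, not deleted) so indexing stays stable
    across wild type and mutants.
    """
    genes = set(genes)
    unknown = genes - set(network.gene_ids)
    if unknown:
        raise LookupError(f"unknown gene ids: {sorted(unknown)}")
    out = network.copy()
    if not genes:
        return out
    for j, rule in enumerate(out.gpr):
        if rule and not evaluate_gpr(rule, genes):
            out.L[j] = 0.0
            out.U[j] = 0.0
    return out


def apply_environment(
    network: MetabolicNetwork,
    profile: Dict[str, Tuple[Optional[float], Optional[float]]],
) -> MetabolicNetwork:
    """Apply an environment preset: per-reaction bound overrides.

    ``profile`` maps reaction ids to ``(lower, upper)``; ``None`` leaves the
    respective bound unchanged. A minimal-medium profile (e.g. M9-style with a
    glucose uptake cap of 10 mmol/gDW/h and unlimited oxygen) is expressed as
    overrides on the exchange reactions.
    """
    out = network.copy()
    for rid, (lb, ub) in profile.items():
        j = out.rxn_index(rid)
        if lb is not None:
            out.L[j] = float(lb)
        if ub is not None:
            out.U[j] = float(ub)
    out.validate()
    return out


def minimal_medium_profile(
    carbon_exchange: str,
    oxygen_exchange: Optional[str] = None,
    uptake: float = 10.0,
    big_bound: float = DEFAULT_BIG_BOUND,
) -> Dict[str, Tuple[Optional[float], Optional[float]]]:
    """Bound overrides for a single-carbon-source, oxygen-unlimited medium."""
    profile: Dict[str, Tuple[Optional[float], Optional[float]]] = {
        carbon_exchange: (-uptake, None)
    }
    if oxygen_exchange is not None:
        profile[oxygen_exchange] = (-big_bound, None)
    return profile


# -- FBA -------------------------------------------------------------------

def solve_fba(network: MetabolicNetwork) -> FluxState:
    """Maximize the growth flux subject to S v = 0 and the flux bounds.

    Infeasible/unbounded outcomes are reported in the returned status, never
    raised.
    """
    n = network.n
    c = np.zeros(n)
    c[network.growth_index] = -1.0
    status, x, _ = _lp.solve_lp(
        c,
        A_eq=network.S,
        b_eq=np.zeros(network.m),
        bounds=list(zip(network.L, network.U)),
    )
    if status != OPTIMAL:
        return FluxState(v=None, objective=None, status=status)
    return FluxState(v=x, objective=float(x[network.growth_index]), status=OPTIMAL)
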