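"""Synthetic networks and labels so every module is testable with no download.

Includes the fully printed two-flux worked example (one metabolite, two
fluxes, three scenarios), deterministic small networks (linear chains,
parallel pathways, a free-exchange variant), seeded random networks with a
guaranteed positive FBA optimum, and seeded essentiality labels with a known
flip rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import RampProblem, deviation_matrix, mean_row
from .exceptions import FixtureError, ParameterError
from .network import MetabolicNetwork, save_json_model, solve_fba

__all__ = [
    "ToyExample",
    "toy_example",
    "build_network",
    "chain_network",
    "parallel_paths_network",
    "free_exchange_network",
    "random_network",
    "random_essentiality_labels",
    "write_labels",
    "make_fixture",
]

BIG = 1000.0


# -- the printed two-flux worked example -----------------------------------

@dataclass
class ToyExample:
    """The two-flux system with one uncertain row and three scenarios.

    Base row (1, -1) on fluxes bounded by [-1, 1]^2; scenario rows
    (0.9, -1.2), (1, -1), (1.1, -0.8) with probabilities (1/4, 1/2, 1/4);
    delta = 3 and slack bound M = 0.2. Its deviation matrix is
    [[-0.15, -0.30], [0, 0], [0.15, 0.30]].
    """

    p: np.ndarray = field(default_factory=lambda: np.array([0.25, 0.5, 0.25]))
    S_hat: np.ndarray = field(
        default_factory=lambda: np.array([[0.9, -1.2], [1.0, -1.0], [1.1, -0.8]])
    )
    delta: float = 3.0
    M: float = 0.2

    @property
    def network(self) -> MetabolicNetwork:
        return MetabolicNetwork(
            metabolite_ids=["X"],
            reaction_ids=["v1", "v2"],
            S=np.array([[1.0, -1.0]]),
            L=np.array([-1.0, -1.0]),
            U=np.array([1.0, 1.0]),
            growth_index=0,  # objective is the first flux
        )

    @property
    def mean(self) -> np.ndarray:
        return mean_row(self.p, self.S_hat)

    @property
    def R(self) -> np.ndarray:
        return deviation_matrix(self.p, self.S_hat, self.delta)

    def problem(self) -> RampProblem:
        return RampProblem.from_rows(
            self.network, [self.p], [self.S_hat], self.delta, np.array([self.M])
        )


def toy_example() -> ToyExample:
    return ToyExample()


# -- deterministic constructions -------------------------------------------

def build_network(
    metabolites: Sequence[str],
    reactions: Sequence[Tuple[str, Dict[str, float], float, float, str]],
    growth_id: str,
    gene_ids: Optional[Sequence[str]] = None,
) -> MetabolicNetwork:
    """Assemble a network from (id, stoichiometry, lb, ub, gpr) tuples."""
    metabolites = list(metabolites)
    rxn_ids = [r[0] for r in reactions]
    S = np.zeros((len(metabolites), len(reactions)))
    L = np.zeros(len(reactions))
    U = np.zeros(len(reactions))
    gpr = []
    for j, (rid, stoich, lb, ub, rule) in enumerate(reactions):
        for met, coef in stoich.items():
            S[metabolites.index(met), j] = coef
        L[j], U[j] = lb, ub
        gpr.append(rule)
    if gene_ids is None:
        genes: List[str] = []
        for rule in gpr:
            for token in rule.replace("(", " ").replace(")", " ").split():
                if token not in {"and", "or", "AND", "OR"} and token not in genes:
                    genes.append(token)
        gene_ids = genes
    return MetabolicNetwork(
        metabolite_ids=metabolites,
        reaction_ids=rxn_ids,
        S=S,
        L=L,
        U=U,
        growth_index=rxn_ids.index(growth_id),
        gpr=gpr,
        gene_ids=list(gene_ids),
    )


def chain_network(n_intermediates: int = 2, uptake: float = 10.0, with_genes: bool = True) -> MetabolicNetwork:
    """Linear chain: uptake -> A1 -> ... -> Ak -> biomass, unit stoichiometry.

    The FBA optimum equals the uptake cap. Each conversion is gated by its own
    gene g1..gk when ``with_genes`` is set, so every one is essential.
    """
    mets = [f"A{i}" for i in range(n_intermediates)] + ["BM"]
    reactions = [("EX_A0", {"A0": 1.0}, 0.0, uptake, "")]
    for i in range(n_intermediates - 1):
        rule = f"g{i + 1}" if with_genes else ""
        reactions.append((f"C{i}", {f"A{i}": -1.0, f"A{i + 1}": 1.0}, 0.0, BIG, rule))
    reactions.append(("GROWTH", {f"A{n_intermediates - 1}": -1.0, "BM": 1.0}, 0.0, BIG, ""))
    reactions.append(("DM_BM", {"BM": -1.0}, 0.0, BIG, ""))
    return build_network(mets, reactions, "GROWTH")


def parallel_paths_network(alt_capacity: float = 4.5, uptake: float = 10.0) -> MetabolicNetwork:
    """Two gene-gated routes to the biomass precursor with unequal capacity.

    Knocking out the main route (gA) leaves growth at ``alt_capacity``; with
    the default 4.5 vs wild-type 10 the FBA knockout ratio is 0.45, just below
    the 50% essentiality threshold. Under the robust model the slack fitted to
    the wild type lets the mutant grow a little more, so the gA call flips from
    essential to nonessential at a finite single-coefficient sigma - the
    transition the maximal-sigma search must locate.
    """
    mets = ["A", "P", "BM"]
    reactions = [
        ("EX_A", {"A": 1.0}, 0.0, uptake, ""),
        ("PA", {"A": -1.0, "P": 1.0}, 0.0, BIG, "gA"),
        ("PB", {"A": -1.0, "P": 1.0}, 0.0, alt_capacity, "gB"),
        ("GROWTH", {"P": -1.0, "BM": 1.0}, 0.0, BIG, ""),
        ("DM_BM", {"BM": -1.0}, 0.0, BIG, ""),
    ]
    return build_network(mets, reactions, "GROWTH")


def free_exchange_network(alt_capacity: float = 4.0, uptake: float = 10.0) -> MetabolicNetwork:
    """A biomass precursor that is freely exchangeable with the environment.

    The metabolite X enters the growth reaction but can be imported or
    exported at no metabolic cost, so its steady-state row absorbs arbitrary
    scenario spread: the robust screen matches FBA for any sigma, and the
    maximal-sigma search can only report a lower bound.
    """
    mets = ["A", "P", "X", "BM"]
    reactions = [
        ("EX_A", {"A": 1.0}, 0.0, uptake, ""),
        ("EX_X", {"X": 1.0}, -BIG, BIG, ""),
        ("PA", {"A": -1.0, "P": 1.0}, 0.0, BIG, "gA"),
        ("PB", {"A": -1.0, "P": 1.0}, 0.0, alt_capacity, "gB"),
        ("GROWTH", {"P": -1.0, "X": -0.5, "BM": 1.0}, 0.0, BIG, ""),
        ("DM_BM", {"BM": -1.0}, 0.0, BIG, ""),
    ]
    return build_network(mets, reactions, "GROWTH")


# -- seeded random networks ------------------------------------------------

def _random_gpr(rng: np.random.Generator, genes: Sequence[str]) -> str:
    kind = rng.integers(0, 4)
    if kind == 0 or len(genes) < 2:
        return str(rng.choice(genes))
    a, b = rng.choice(len(genes), size=2, replace=False)
    op = "and" if kind == 1 else "or"
    return f"({genes[a]} {op} {genes[b]})"


def _random_network_attempt(n_metabolites: int, n_reactions: int, rng: np.random.Generator) -> MetabolicNetwork:
    n_inter = n_metabolites - 1  # last metabolite is the biomass pseudo-metabolite
    mets = [f"M{i}" for i in range(n_inter)] + ["BM"]
    n_genes = max(3, n_reactions // 2)
    genes = [f"g{i + 1}" for i in range(n_genes)]

    reactions: List[Tuple[str, Dict[str, float], float, float, str]] = [
        ("EX_M0", {"M0": 1.0}, 0.0, 10.0, "")
    ]
    # backbone chain through all intermediates, each step gene-gated
    for i in range(n_inter - 1):
        reactions.append(
            (f"C{i}", {f"M{i}": -1.0, f"M{i + 1}": 1.0}, 0.0, BIG, _random_gpr(rng, genes))
        )
    # biomass drain with non-integer coefficients over a random precursor subset
    n_prec = min(n_inter, int(rng.integers(1, 4)))
    precursors = sorted(rng.choice(n_inter, size=n_prec, replace=False).tolist())
    if (n_inter - 1) not in precursors:
        precursors[-1] = n_inter - 1  # always drain the chain end
    stoich: Dict[str, float] = {"BM": 1.0}
    for i in precursors:
        dp = int(rng.integers(1, 7))  # 1-6 printed decimals
        value = round(float(rng.uniform(0.5, 60.0)) * 10.0 ** -int(rng.integers(0, 4)), dp)
        stoich[f"M{i}"] = -(value if value > 0 else 10.0 ** -dp)
    reactions.append(("GROWTH", stoich, 0.0, BIG, ""))
    reactions.append(("DM_BM", {"BM": -1.0}, 0.0, BIG, ""))
    # ATP-maintenance-like fixed flux on the first intermediate, budget permitting
    if len(reactions) < n_reactions:
        reactions.append(("ATPM", {"M0": -1.0}, 0.1, 0.1, ""))

    while len(reactions) < n_reactions and n_inter >= 2:
        a, b = rng.choice(n_inter, size=2, replace=False)
        coef_a = float(rng.integers(1, 4))
        coef_b = float(rng.integers(1, 4))
        reversible = rng.random() < 0.3
        reactions.append(
            (
                f"S{len(reactions)}",
                {f"M{a}": -coef_a, f"M{b}": coef_b},
                -BIG if reversible else 0.0,
                BIG,
                _random_gpr(rng, genes),
            )
        )
    return build_network(mets, reactions, "GROWTH", gene_ids=genes)


def random_network(n_metabolites: int, n_reactions: int, seed: int) -> MetabolicNetwork:
    """Seeded random network with a guaranteed positive FBA optimum.

    Built around a gene-gated backbone chain from a capped uptake into a
    biomass drain with non-integer coefficients (1-6 decimal places), plus
    random integer-stoichiometry side reactions (some reversible) and a fixed
    maintenance flux. Retries internally with derived seeds until the FBA
    optimum is positive.
    """
    if n_metabolites < 2 or n_reactions < n_metabolites + 1:
        raise ParameterError(
            "need at least 2 metabolites and n_metabolites + 1 reactions "
            "(uptake, chain, growth, biomass drain)"
        )
    if n_metabolites > 50 or n_reactions > 100:
        raise ParameterError("random fixtures are limited to 50 x 100")
    for attempt in range(20):
        rng = np.random.default_rng((seed + 10007 * attempt) % (2**31))
        net = _random_network_attempt(n_metabolites, n_reactions, rng)
        fba = solve_fba(net)
        if fba.status == "optimal" and fba.objective is not None and fba.objective > 1e-6:
            return net
    raise FixtureError(
        f"could not build a feasible random network for seed {seed} "
        f"({n_metabolites} x {n_reactions})"
    )


def random_essentiality_labels(
    network: MetabolicNetwork, seed: int, flip_rate: float = 0.0, threshold: float = 0.5
) -> Dict[str, str]:
    """FBA-screen truth with independent label flips at ``flip_rate``.

    With flip rate 0 the labels reproduce the FBA screen exactly (so the
    confusion matrix has no off-diagonal counts); with rate f each gene's
    label is inverted independently with probability f.
    """
    if not (0.0 <= flip_rate <= 1.0):
        raise ParameterError("flip_rate must lie in [0, 1]")
    from .essentiality import screen_knockouts

    screen = screen_knockouts(network, "fba", threshold=threshold)
    rng = np.random.default_rng(seed)
    labels = {}
    for gene in network.gene_ids:
        truth = screen.essential[gene]
        if rng.random() < flip_rate:
            truth = not truth
        labels[gene] = "essential" if truth else "nonessential"
    return labels


def write_labels(labels: Dict[str, str], path) -> None:
    df = pd.DataFrame(
        {"gene_id": list(labels), "essential": [int(v == "essential") for v in labels.values()]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_labels(path) -> Dict[str, bool]:
    df = pd.read_csv(path, sep="\t")
    return {str(g): bool(int(e)) for g, e in zip(df["gene_id"], df["essential"])}


def make_fixture(seed: int, out_dir, n_metabolites: int = 8, n_reactions: int = 14,
                 flip_rate: float = 0.1) -> Tuple[Path, Path]:
    """Write a COBRA-style JSON model plus a TSV label file; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    net = random_network(n_metabolites, n_reactions, seed)
    labels = random_essentiality_labels(net, seed + 1, flip_rate)
    model_path = out_dir / "model.json"
    labels_path = out_dir / "labels.tsv"
    save_json_model(net, model_path)
    write_labels(labels, labels_path)
    return model_path, labels_path
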