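"""Robust (chance-constrained) counterpart of the FBA steady-state system.

Each steady-state equality ``S_i v = 0`` is replaced by the two-sided robust
constraint

    ||R_i v|| - M_i  <=  p_i^T S_hat_i v  <=  M_i - ||R_i v||,

where ``p_i`` are scenario probabilities, ``S_hat_i`` the (q, n) matrix of
scenario rows, ``R_i = delta * sqrt(P_i) (I - e p_i^T) S_hat_i`` the deviation
matrix (so ``||R_i v|| = delta * std(S_i v)`` over scenarios), and ``M_i >= 0``
the permitted magnitude of deviation from steady state.

Two assembled forms are supported:

* linear form - when uncertainty is confined to the growth column and the
  growth flux is nonnegative, ``||R_i v||`` collapses to ``r_i * v_Growth``
  with a scalar ``r_i``, giving an ordinary LP (the default path; stable at
  genome scale);
* cone form - the general second-order-cone system, solved here by a
  cutting-plane loop over LPs (intended for small instances and cross-checks).

``fit_M`` chooses the slack bounds by L1 minimization so that the robust model
reproduces a target growth rate, typically the FBA optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import _lp
from ._lp import NUMERIC_FAILURE, OPTIMAL
from .exceptions import ParameterError, SolverStatusError, UnsupportedStructureError
from .network import FluxState, MetabolicNetwork
from .scenarios import ScenarioSet

__all__ = [
    "mean_row",
    "deviation_matrix",
    "growth_norm_coefficient",
    "RampProblem",
    "ConstraintAudit",
    "assemble_linear_ramp",
    "assemble_socp_ramp",
    "solve_ramp",
    "fit_M",
    "audit_feasibility",
    "sample_uncertainty_constraint",
    "biologically_possible",
    "RowPossibility",
]


# -- elementary constructions ----------------------------------------------

def _check_prob(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("probability vector must be 1-D")
    return p


def mean_row(p: np.ndarray, S_hat: np.ndarray) -> np.ndarray:
    """Probability-weighted mean row ``p^T S_hat`` of the scenario rows."""
    p = _check_prob(p)
    S_hat = np.atleast_2d(np.asarray(S_hat, dtype=float))
    if S_hat.shape[0] != p.shape[0]:
        raise ValueError(f"shape mismatch: p has {p.shape[0]} entries, S_hat has {S_hat.shape[0]} rows")
    return p @ S_hat


def deviation_matrix(p: np.ndarray, S_hat: np.ndarray, delta: float) -> np.ndarray:
    """``R = delta * diag(sqrt(p)) (I - e p^T) S_hat``.

    For any flux vector v, ``||R v||`` equals ``delta`` times the standard
    deviation of the scenario values ``S_k v`` under p.
    """
    p = _check_prob(p)
    S_hat = np.atleast_2d(np.asarray(S_hat, dtype=float))
    if S_hat.shape[0] != p.shape[0]:
        raise ValueError("p and S_hat disagree on the scenario count")
    if not delta > 0:
        raise ParameterError("delta must be positive")
    centered = S_hat - mean_row(p, S_hat)  # (I - e p^T) S_hat
    return delta * np.sqrt(p)[:, None] * centered


def growth_norm_coefficient(p: np.ndarray, growth_scenarios: Sequence[float], delta: float) -> float:
    """Scalar ``r = ||delta sqrt(P)(I - e p^T) s||`` for a single uncertain column.

    With scenarios s for that column alone, ``||R v|| = r * |v_col|``.
    """
    p = _check_prob(p)
    s = np.asarray(growth_scenarios, dtype=float)
    return float(np.linalg.norm(delta * np.sqrt(p) * (s - p @ s)))


# -- assembled problems ----------------------------------------------------

@dataclass
class RampProblem:
    """A robust constraint system ready for a solver.

    ``form`` is "linear" (growth-norm scalars) or "socp" (full per-row
    deviation matrices). ``mean_rows`` replaces S; for the symmetric scenario
    families it equals S exactly.
    """

    network: MetabolicNetwork
    mean_rows: np.ndarray
    M: np.ndarray
    form: str
    scenarios: Optional[ScenarioSet] = None
    growth_norm: Optional[np.ndarray] = None
    R_rows: Optional[List[np.ndarray]] = None
    p_rows: Optional[List[np.ndarray]] = None
    S_hat_rows: Optional[List[np.ndarray]] = None

    def __post_init__(self) -> None:
        self.mean_rows = np.atleast_2d(np.asarray(self.mean_rows, dtype=float))
        self.M = np.broadcast_to(np.asarray(self.M, dtype=float), (self.mean_rows.shape[0],)).copy()
        if np.any(self.M < 0):
            raise ParameterError("slack bounds M must be nonnegative")
        if self.form not in {"linear", "socp"}:
            raise ParameterError(f"unknown problem form {self.form!r}")

    @property
    def m(self) -> int:
        return self.mean_rows.shape[0]

    @property
    def n(self) -> int:
        return self.mean_rows.shape[1]

    def deviations(self, v: np.ndarray) -> np.ndarray:
        """Per-row ``||R_i v||`` for a flux vector."""
        v = np.asarray(v, dtype=float)
        if self.form == "linear":
            return self.growth_norm * abs(v[self.network.growth_index])
        return np.array([np.linalg.norm(R @ v) for R in self.R_rows])

    def to_json_dict(self) -> dict:
        """Dump the assembled linear system (mean rows as sparse triplets,
        growth norms, slack bounds, flux bounds)."""
        if self.form != "linear":
            raise ParameterError("only linear-form problems serialize to JSON")
        rows, cols = np.nonzero(self.mean_rows)
        return {
            "form": "linear",
            "m": self.m,
            "n": self.n,
            "growth_index": self.network.growth_index,
            "metabolite_ids": list(self.network.metabolite_ids),
            "reaction_ids": list(self.network.reaction_ids),
            "mean_triplets": [
                [int(i), int(j), float(self.mean_rows[i, j])] for i, j in zip(rows, cols)
            ],
            "growth_norm": self.growth_norm.tolist(),
            "M": self.M.tolist(),
            "L": self.network.L.tolist(),
            "U": self.network.U.tolist(),
        }

    @classmethod
    def from_json_dict(cls, data: dict) -> "RampProblem":
        if data.get("form") != "linear":
            raise ParameterError("only linear-form problem dumps are supported")
        mean = np.zeros((data["m"], data["n"]))
        for i, j, val in data["mean_triplets"]:
            mean[i, j] = val
        net = MetabolicNetwork(
            metabolite_ids=list(data["metabolite_ids"]),
            reaction_ids=list(data["reaction_ids"]),
            S=mean,
            L=np.asarray(data["L"], float),
            U=np.asarray(data["U"], float),
            growth_index=int(data["growth_index"]),
        )
        return cls(
            network=net,
            mean_rows=mean,
            M=np.asarray(data["M"], float),
            form="linear",
            growth_norm=np.asarray(data["growth_norm"], float),
        )

    @classmethod
    def from_rows(
        cls,
        network: MetabolicNetwork,
        p_rows: Sequence[np.ndarray],
        S_hat_rows: Sequence[np.ndarray],
        delta: float,
        M: Union[float, np.ndarray],
    ) -> "RampProblem":
        """General cone-form problem from explicit per-row (p_i, S_hat_i)."""
        p_rows = [np.asarray(p, float) for p in p_rows]
        S_hat_rows = [np.atleast_2d(np.asarray(S, float)) for S in S_hat_rows]
        means = np.vstack([mean_row(p, S) for p, S in zip(p_rows, S_hat_rows)])
        R_rows = [deviation_matrix(p, S, delta) for p, S in zip(p_rows, S_hat_rows)]
        return cls(
            network=network,
            mean_rows=means,
            M=M,
            form="socp",
            growth_norm=None,
            R_rows=R_rows,
            p_rows=p_rows,
            S_hat_rows=S_hat_rows,
        )


def _scenario_means_matrix(network: MetabolicNetwork, scenarios: ScenarioSet) -> np.ndarray:
    means = network.S.copy()
    means[:, scenarios.base_column] = scenarios.row_means()
    return means


def assemble_linear_ramp(
    network: MetabolicNetwork,
    scenarios: ScenarioSet,
    M: Union[float, np.ndarray],
) -> RampProblem:
    """Linearized robust system (default computational path).

    Requires uncertainty confined to the growth column and a nonnegative
    growth flux lower bound, under which ``||R_i v|| = r_i * v_Growth`` with
    ``r_i = ||delta sqrt(P)(I - e p^T) s_i||``.
    """
    if scenarios.base_column != network.growth_index:
        raise UnsupportedStructureError(
            "linear path requires the uncertain column to be the growth reaction; "
            "use the cone (socp) path for general uncertainty"
        )
    if network.L[network.growth_index] < 0:
        raise UnsupportedStructureError(
            "linear path requires a nonnegative growth flux (L_Growth >= 0); "
            "use the cone (socp) path otherwise"
        )
    if scenarios.m != network.m:
        raise ValueError("scenario set and network disagree on the metabolite count")
    r = np.array(
        [
            growth_norm_coefficient(scenarios.probabilities, scenarios.growth_scenarios[i], scenarios.delta)
            for i in range(network.m)
        ]
    )
    return RampProblem(
        network=network,
        mean_rows=_scenario_means_matrix(network, scenarios),
        M=M,
        form="linear",
        scenarios=scenarios,
        growth_norm=r,
    )


def assemble_socp_ramp(
    network: MetabolicNetwork,
    scenarios: ScenarioSet,
    M: Union[float, np.ndarray],
) -> RampProblem:
    """Full second-order-cone system from a scenario set (small instances)."""
    if scenarios.m != network.m:
        raise ValueError("scenario set and network disagree on the metabolite count")
    p = scenarios.probabilities
    S_hat_rows = [scenarios.scenario_rows(network, i) for i in range(network.m)]
    prob = RampProblem.from_rows(network, [p] * network.m, S_hat_rows, scenarios.delta, M)
    prob.scenarios = scenarios
    return prob


# -- LP assembly helpers ---------------------------------------------------

def _linear_constraint_rows(problem: RampProblem):
    """Scaled inequality rows for the linear form.

    Each metabolite row contributes
        (mean_i + r_i e_g) v <= M_i   and   (-mean_i + r_i e_g) v <= M_i,
    both divided by d_i = max(1, r_i). Row scaling is an exact reformulation;
    it keeps the huge growth norms arising in extreme sigma regimes benign.
    """
    net = problem.network
    g = net.growth_index
    r = problem.growth_norm
    d = np.maximum(1.0, r)
    upper = problem.mean_rows.copy()
    upper[:, g] += r
    lower = -problem.mean_rows
    lower[:, g] += r
    A = np.vstack([upper / d[:, None], lower / d[:, None]])
    b = np.concatenate([problem.M / d, problem.M / d])
    return A, b, d


def _objective(problem: RampProblem) -> np.ndarray:
    c = np.zeros(problem.n)
    c[problem.network.growth_index] = -1.0
    return c


def _solve_linear(problem: RampProblem) -> FluxState:
    net = problem.network
    A, b, _ = _linear_constraint_rows(problem)
    status, x, _ = _lp.solve_lp(_objective(problem), A_ub=A, b_ub=b, bounds=list(zip(net.L, net.U)))
    if status != OPTIMAL:
        return FluxState(v=None, objective=None, status=status)
    return FluxState(v=x, objective=float(x[net.growth_index]), status=OPTIMAL)


def _solve_socp_cutting_plane(problem: RampProblem, tol: float = 1e-9, max_rounds: int = 100) -> FluxState:
    """Kelley-style cutting planes: the robust constraint is the intersection
    of the linear cuts ``(±mean_i + u^T R_i) v <= M_i`` over the unit ball of
    u; violated cuts at the current iterate (u aligned with R_i v) are added
    until feasibility."""
    net = problem.network
    c = _objective(problem)
    bounds = list(zip(net.L, net.U))
    A_rows = [problem.mean_rows, -problem.mean_rows]
    b_rows = [problem.M, problem.M]
    for _ in range(max_rounds):
        A = np.vstack(A_rows)
        b = np.concatenate(b_rows)
        status, x, _ = _lp.solve_lp(c, A_ub=A, b_ub=b, bounds=bounds)
        if status != OPTIMAL:
            return FluxState(v=None, objective=None, status=status)
        violated = False
        mu = problem.mean_rows @ x
        for i, R in enumerate(problem.R_rows):
            Rv = R @ x
            dev = float(np.linalg.norm(Rv))
            if dev <= tol:
                continue
            u = Rv / dev
            cut = u @ R  # u^T R_i
            if mu[i] + dev > problem.M[i] + tol:
                A_rows.append((problem.mean_rows[i] + cut)[None, :])
                b_rows.append(problem.M[i : i + 1])
                violated = True
            if -mu[i] + dev > problem.M[i] + tol:
                A_rows.append((-problem.mean_rows[i] + cut)[None, :])
                b_rows.append(problem.M[i : i + 1])
                violated = True
        if not violated:
            return FluxState(v=x, objective=float(x[net.growth_index]), status=OPTIMAL)
    return FluxState(v=None, objective=None, status=NUMERIC_FAILURE)


def solve_ramp(problem: RampProblem) -> FluxState:
    """Maximize the growth flux subject to the robust constraints and bounds."""
    if problem.form == "linear":
        return _solve_linear(problem)
    return _solve_socp_cutting_plane(problem)


# -- M fitting (L1-minimal slack bounds) -----------------------------------

def fit_M(network: MetabolicNetwork, scenarios: ScenarioSet, gamma_star: float) -> np.ndarray:
    """L1-minimal slack bounds that let the robust model reach ``gamma_star``.

    Solves the joint LP over (v, M):
        min sum_i M_i
        s.t. |mean_i v| <= M_i - r_i v_Growth,  v_Growth >= gamma_star,
             L <= v <= U,  M >= 0,
    so the sum of permissible deviations from steady state is as small as
    possible while the growth target (typically the FBA optimum) is attained.
    """
    from .network import solve_fba  # local import to avoid a cycle

    fba = solve_fba(network)
    if fba.status != OPTIMAL or gamma_star > fba.objective * (1 + 1e-9) + 1e-9:
        raise SolverStatusError(
            f"growth target {gamma_star!r} is not attainable by FBA on the mean system "
            f"(FBA status {fba.status}, optimum {fba.objective!r})"
        )
    template = assemble_linear_ramp(network, scenarios, M=np.zeros(network.m))
    A, _, d = _linear_constraint_rows(template)
    m, n = network.m, network.n
    # variables: v (n) then scaled slacks M' = M / d (m)
    A_full = np.zeros((2 * m + 1, n + m))
    A_full[: 2 * m, :n] = A
    A_full[:m, n:] = -np.eye(m)
    A_full[m : 2 * m, n:] = -np.eye(m)
    A_full[2 * m, network.growth_index] = -1.0  # -v_g <= -gamma*
    b_full = np.zeros(2 * m + 1)
    b_full[2 * m] = -gamma_star
    bounds = list(zip(network.L, network.U)) + [(0.0, None)] * m
    # normalized objective (same argmin as sum d_i M'_i = ||M||_1)
    w = d / d.max()
    c = np.concatenate([np.zeros(n), w])
    status, x, fun = _lp.solve_lp(c, A_ub=A_full, b_ub=b_full, bounds=bounds)
    if status != OPTIMAL:
        raise SolverStatusError(f"M fit at growth target {gamma_star!r} ended with status {status}")
    # When the growth norms span many orders of magnitude, weights below the
    # solver's tolerance are effectively zero and the corresponding M_i come
    # back non-minimal. A second lexicographic stage pins the normalized
    # objective at its optimum and re-minimizes just those rows.
    small = w < 1e-9
    if small.any() and not small.all():
        A_lex = np.vstack([A_full, c[None, :]])
        b_lex = np.concatenate([b_full, [fun + 1e-9 * max(1.0, abs(fun))]])
        c2 = np.concatenate([np.zeros(n), small.astype(float)])
        status2, x2, _ = _lp.solve_lp(c2, A_ub=A_lex, b_ub=b_lex, bounds=bounds)
        if status2 == OPTIMAL:
            x = x2
    # The LP is solved to a primal feasibility tolerance, so components of M
    # smaller than that tolerance can come back as zero even though any point
    # with growth gamma* needs M_i >= |mean_i v| + r_i v_Growth exactly.
    # Clip up to the exact requirement at the returned v so the fitted system
    # attains the growth target in exact arithmetic, not just within solver
    # tolerance.
    v = x[:n]
    M_lp = np.maximum(d * x[n:], 0.0)
    required = np.abs(template.mean_rows @ v) + template.growth_norm * v[network.growth_index]
    return np.maximum(M_lp, required)


# -- audits and the uncertainty set ----------------------------------------

@dataclass
class ConstraintAudit:
    """Per-row feasibility report for a flux vector against a robust system."""

    mu: np.ndarray
    deviation: np.ndarray
    lower_slack: np.ndarray
    upper_slack: np.ndarray
    bounds_ok: bool
    tolerance: float
    metabolite_ids: List[str] = field(default_factory=list)

    @property
    def rows_ok(self) -> np.ndarray:
        return (self.lower_slack >= -self.tolerance) & (self.upper_slack >= -self.tolerance)

    @property
    def feasible(self) -> bool:
        return bool(self.bounds_ok and self.rows_ok.all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metabolite": self.metabolite_ids or list(range(len(self.mu))),
                "mu": self.mu,
                "deviation": self.deviation,
                "lower_slack": self.lower_slack,
                "upper_slack": self.upper_slack,
                "verdict": np.where(self.rows_ok, "feasible", "infeasible"),
            }
        )


def audit_feasibility(v: np.ndarray, problem: RampProblem, tolerance: float = 1e-9) -> ConstraintAudit:
    """Evaluate ``||R_i v|| - M_i <= mean_i v <= M_i - ||R_i v||`` row by row."""
    v = np.asarray(v, dtype=float)
    if v.shape != (problem.n,):
        raise ValueError(f"flux vector has length {v.shape}, expected {problem.n}")
    net = problem.network
    mu = problem.mean_rows @ v
    dev = problem.deviations(v)
    lower_slack = mu - (dev - problem.M)
    upper_slack = (problem.M - dev) - mu
    bounds_ok = bool(np.all(v >= net.L - tolerance) and np.all(v <= net.U + tolerance))
    return ConstraintAudit(
        mu=mu,
        deviation=dev,
        lower_slack=lower_slack,
        upper_slack=upper_slack,
        bounds_ok=bounds_ok,
        tolerance=tolerance,
        metabolite_ids=list(net.metabolite_ids),
    )


def sample_uncertainty_constraint(
    p: np.ndarray, S_hat: np.ndarray, delta: float, u: np.ndarray
) -> np.ndarray:
    """One member ``p^T S_hat + u^T R`` of the row uncertainty set (||u|| <= 1)."""
    u = np.asarray(u, dtype=float)
    if np.linalg.norm(u) > 1.0 + 1e-12:
        raise ParameterError("u must lie in the unit ball (||u|| <= 1)")
    return mean_row(p, S_hat) + u @ deviation_matrix(p, S_hat, delta)


# -- biologically possible scenarios ---------------------------------------

@dataclass
class RowPossibility:
    """Verdict for one constraint row: are its scenarios compatible with v_hat
    remaining optimal as the chance constraints tighten?"""

    row: int
    possible: bool
    alpha: float
    alpha_near_zero: bool
    scenario_values: np.ndarray


def biologically_possible(
    scenarios: Union[ScenarioSet, Sequence[np.ndarray]],
    v_hat: np.ndarray,
    tolerance: float = 1e-9,
    network: Optional[MetabolicNetwork] = None,
) -> List[RowPossibility]:
    """Identical-components test for scenario compatibility with a flux state.

    For each row the q scenario values ``S_ik . v_hat`` are computed over the
    nonzero components of ``v_hat``; the row's scenarios are possible iff all
    q values agree (within tolerance), in which case the common value alpha is
    reported. Rows whose alpha is itself ~0 are flagged rather than rejected,
    since steady-state feasibility of the mean row already forces the weighted
    alpha to vanish.
    """
    v_hat = np.asarray(v_hat, dtype=float)
    if isinstance(scenarios, ScenarioSet):
        if network is None:
            raise ValueError("a network is required to expand a ScenarioSet into rows")
        rows = [scenarios.scenario_rows(network, i) for i in range(scenarios.m)]
    else:
        rows = [np.atleast_2d(np.asarray(S, float)) for S in scenarios]
    nz = np.abs(v_hat) > tolerance
    out: List[RowPossibility] = []
    for i, S_hat in enumerate(rows):
        vals = S_hat[:, nz] @ v_hat[nz]
        spread = float(vals.max() - vals.min()) if vals.size else 0.0
        alpha = float(vals.mean()) if vals.size else 0.0
        out.append(
            RowPossibility(
                row=i,
                possible=spread <= tolerance,
                alpha=alpha,
                alpha_near_zero=abs(alpha) <= tolerance,
                scenario_values=vals,
            )
        )
    return out
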