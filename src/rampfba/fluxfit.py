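"""Quadratic flux fitting against experimentally measured fluxes.

Given measured fluxes for a subset of reactions, find the feasible flux
vector closest (least squares over the measured coordinates) to the
measurements, subject to a growth floor ``v_Growth >= theta * gamma*`` with
``gamma*`` the FBA optimum. Two constraint regimes:

* strict steady state (``S v = 0``) - the FBA fit;
* the robust linearized system with fitted slack bounds M - the robust fit.

Fits are scored by mean square error over the measured coordinates,
``MSE = ||v_fit - v_exp||^2 / N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, minimize

from .core import RampProblem, assemble_linear_ramp, fit_M, solve_ramp, _linear_constraint_rows
from .exceptions import ScoringError, SolverStatusError
from .network import FluxState, MetabolicNetwork, solve_fba

__all__ = [
    "FluxMeasurement",
    "read_flux_measurements",
    "fit_fluxes_fba",
    "fit_fluxes_ramp",
    "mse",
    "fit_summary",
]


@dataclass
class FluxMeasurement:
    reaction_id: str
    flux: float
    sd: Optional[float] = None


def read_flux_measurements(path) -> List[FluxMeasurement]:
    """TSV with columns reaction_id, flux and optionally sd."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        sd = float(row["sd"]) if "sd" in df.columns and pd.notna(row.get("sd")) else None
        out.append(FluxMeasurement(str(row["reaction_id"]), float(row["flux"]), sd))
    return out


def _measurement_arrays(network: MetabolicNetwork, measurements: Sequence[FluxMeasurement]):
    idx = np.array([network.rxn_index(m.reaction_id) for m in measurements], dtype=int)
    target = np.array([m.flux for m in measurements], dtype=float)
    return idx, target


def _solve_qp(
    network: MetabolicNetwork,
    idx: np.ndarray,
    target: np.ndarray,
    x0: np.ndarray,
    A_eq: Optional[np.ndarray] = None,
    A_ub: Optional[np.ndarray] = None,
    b_ub: Optional[np.ndarray] = None,
    growth_floor: Optional[float] = None,
    weights: Optional[np.ndarray] = None,
) -> FluxState:
    """Minimize the (optionally weighted) squared residual over the measured
    coordinates subject to linear constraints, via trust-region SQP."""
    n = network.n
    w = np.ones_like(target) if weights is None else np.asarray(weights, float)

    H = np.zeros((n, n))
    H[idx, idx] = 2.0 * w

    def fun(v):
        r = v[idx] - target
        return float(np.dot(w * r, r))

    def jac(v):
        g = np.zeros(n)
        g[idx] = 2.0 * w * (v[idx] - target)
        return g

    lin_constraints = []
    if A_eq is not None and len(A_eq):
        lin_constraints.append((np.asarray(A_eq, float), 0.0, 0.0))
    if A_ub is not None and len(A_ub):
        lin_constraints.append((np.asarray(A_ub, float), -np.inf, np.asarray(b_ub, float)))
    if growth_floor is not None:
        row = np.zeros(n)
        row[network.growth_index] = 1.0
        lin_constraints.append((row[None, :], growth_floor, np.inf))

    # active-set SQP resolves the quadratic exactly on these small systems
    slsqp_cons = []
    for A, lo, hi in lin_constraints:
        if np.isscalar(lo) and np.isscalar(hi) and lo == hi:
            slsqp_cons.append({"type": "eq", "fun": lambda v, A=A, lo=lo: A @ v - lo, "jac": lambda v, A=A: A})
        else:
            if np.any(np.isfinite(np.atleast_1d(hi))):
                slsqp_cons.append({"type": "ineq", "fun": lambda v, A=A, hi=hi: hi - A @ v, "jac": lambda v, A=A: -A})
            if np.any(np.isfinite(np.atleast_1d(lo))):
                slsqp_cons.append({"type": "ineq", "fun": lambda v, A=A, lo=lo: A @ v - lo, "jac": lambda v, A=A: A})
    res = minimize(
        fun,
        x0,
        jac=jac,
        method="SLSQP",
        constraints=slsqp_cons,
        bounds=Bounds(network.L, network.U),
        options={"ftol": 1e-14, "maxiter": 500},
    )
    if not res.success:  # fall back to the interior trust-region method
        res = minimize(
            fun,
            x0,
            jac=jac,
            hess=lambda v: H,
            method="trust-constr",
            constraints=[LinearConstraint(A, lo, hi) for A, lo, hi in lin_constraints],
            bounds=Bounds(network.L, network.U),
            options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 2000},
        )
        if res.status not in (1, 2):
            return FluxState(v=np.asarray(res.x, float), objective=float(fun(res.x)), status="numeric_failure")
    v = np.asarray(res.x, dtype=float)
    return FluxState(v=v, objective=float(fun(v)), status="optimal")


def _growth_target(network: MetabolicNetwork) -> float:
    fba = solve_fba(network)
    if fba.status != "optimal" or fba.objective is None:
        raise SolverStatusError(f"FBA solve needed for the growth floor failed ({fba.status})")
    return float(fba.objective)


def fit_fluxes_fba(
    network: MetabolicNetwork,
    measurements: Sequence[FluxMeasurement],
    theta: float = 0.9,
    weighted: bool = False,
) -> FluxState:
    """Least-squares fit under strict steady state and a growth floor.

    ``theta`` scales the FBA optimum down (default 0.9) because measured
    cultures need not be growth-optimal.
    """
    idx, target = _measurement_arrays(network, measurements)
    gamma_star = _growth_target(network)
    fba = solve_fba(network)
    weights = _weights(measurements) if weighted else None
    return _solve_qp(
        network,
        idx,
        target,
        x0=fba.v,
        A_eq=network.S,
        growth_floor=theta * gamma_star,
        weights=weights,
    )


def fit_fluxes_ramp(
    network: MetabolicNetwork,
    scenarios,
    measurements: Sequence[FluxMeasurement],
    M: Optional[np.ndarray] = None,
    theta: float = 0.9,
    weighted: bool = False,
) -> FluxState:
    """Least-squares fit under the robust linearized constraints.

    M defaults to the L1 fit at the FBA optimum, so the robust region is
    calibrated to reach the same growth rate as FBA before fitting.
    """
    idx, target = _measurement_arrays(network, measurements)
    gamma_star = _growth_target(network)
    if M is None:
        M = fit_M(network, scenarios, gamma_star)
    problem = assemble_linear_ramp(network, scenarios, M)
    A, b, _ = _linear_constraint_rows(problem)
    start = solve_ramp(problem)
    if start.status != "optimal":
        raise SolverStatusError(f"robust region is {start.status}; cannot fit fluxes")
    weights = _weights(measurements) if weighted else None
    return _solve_qp(
        network,
        idx,
        target,
        x0=start.v,
        A_ub=A,
        b_ub=b,
        growth_floor=theta * gamma_star,
        weights=weights,
    )


def _weights(measurements: Sequence[FluxMeasurement]) -> np.ndarray:
    """Inverse-variance weights where standard deviations are given."""
    return np.array(
        [1.0 / (m.sd ** 2) if m.sd not in (None, 0) else 1.0 for m in measurements]
    )


def mse(fitted: Union[FluxState, np.ndarray], network: MetabolicNetwork, measurements: Sequence[FluxMeasurement]) -> float:
    """Mean square error over the measured coordinates, ``||v - v_exp||^2 / N``."""
    if not measurements:
        raise ScoringError("no measurements to score against")
    v = fitted.v if isinstance(fitted, FluxState) else np.asarray(fitted, float)
    idx, target = _measurement_arrays(network, measurements)
    resid = v[idx] - target
    return float(np.dot(resid, resid) / len(measurements))


def fit_summary(
    network: MetabolicNetwork,
    scenarios,
    measurements: Sequence[FluxMeasurement],
    theta: float = 0.9,
) -> dict:
    """Run both fits and report {mse_ramp, mse_fba, relative_mse}."""
    ramp_fit = fit_fluxes_ramp(network, scenarios, measurements, theta=theta)
    fba_fit = fit_fluxes_fba(network, measurements, theta=theta)
    mse_ramp = mse(ramp_fit, network, measurements)
    mse_fba = mse(fba_fit, network, measurements)
    return {
        "mse_ramp": mse_ramp,
        "mse_fba": mse_fba,
        "relative_mse": mse_ramp / mse_fba if mse_fba > 0 else float("nan"),
    }
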