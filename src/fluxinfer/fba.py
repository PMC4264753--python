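"""Flux balance analysis via linear programming.

Steady-state fluxes ``v`` satisfy mass balance ``S v = 0`` with per-reaction
bounds ``lb <= v <= ub``; FBA maximizes the biomass objective ``c . v`` over
that polytope. Both the primary biomass maximization and the optional
secondary minimization of total absolute flux (a pFBA-style canonicalization
of degenerate optima) are solved with scipy's HiGHS backend, which is
deterministic for a fixed model — all replicate-to-replicate variation in a
simulation therefore comes from impurity sampling, never from the solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "FluxSolution",
    "FbaError",
    "solve_fba",
    "minimize_total_flux",
    "compute_viability_threshold",
]

#: mass-balance residual allowed on an optimal solution
MASS_BALANCE_TOL = 1e-6
#: two-sided tolerance when pinning biomass in the secondary LP
BIOMASS_EQ_TOL = 1e-9

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


class FbaError(RuntimeError):
    pass


@dataclass
class FluxSolution:
    """Result of one LP solve.

    ``fluxes`` is None unless ``status == "optimal"``; ``biomass`` is the
    objective value (growth-proxy units, hr^-1 for genome-scale models).
    """

    fluxes: np.ndarray | None
    biomass: float
    status: str
    objective: float | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, model: MetabolicModel, reaction_id: str) -> float:
        if self.fluxes is None:
            raise FbaError(f"no flux vector: solution status is {self.status}")
        return float(self.fluxes[model.reaction_index(reaction_id)])


def solve_fba(model: MetabolicModel) -> FluxSolution:
    """Maximize the biomass objective over {v : S v = 0, lb <= v <= ub}.

    Returns a :class:`FluxSolution` with status ``"infeasible"`` or
    ``"unbounded"`` (and no flux vector) instead of raising, so batch
    simulations can record failures and continue.
    """
    res = linprog(
        c=-model.objective_coeffs,
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        bounds=list(zip(model.lower_bounds, model.upper_bounds)),
        method="highs",
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxSolution(fluxes=None, biomass=0.0, status=status)
    v = np.asarray(res.x)
    biomass = float(model.objective_coeffs @ v)
    return FluxSolution(fluxes=v, biomass=biomass, status="optimal", objective=biomass)


def minimize_total_flux(model: MetabolicModel, biomass_star: float) -> FluxSolution:
    """Minimize sum |v_i| at (near-)fixed optimal biomass.

    The absolute values are linearized by splitting each flux into positive and
    negative parts ``v = v+ - v-`` with ``v+, v- >= 0``; minimizing
    ``sum(v+ + v-)`` drives one part of every pair to zero. Biomass is pinned to
    ``biomass_star`` by an equality row (the solver's own primal feasibility
    tolerance supplies the slack), which makes the minimization idempotent.

    Raises
    ------
    FbaError
        If the LP is infeasible. The message distinguishes a biomass value the
        model cannot attain at all (structural) from one just outside tolerance.
    """
    n = model.n_reactions
    lb, ub = model.lower_bounds, model.upper_bounds
    # v+ in [max(lb,0), max(ub,0)], v- in [max(-ub,0), max(-lb,0)]
    pos_bounds = list(zip(np.maximum(lb, 0.0), np.maximum(ub, 0.0)))
    neg_bounds = list(zip(np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)))
    c_obj = model.objective_coeffs
    A_eq = sparse.vstack(
        [
            sparse.hstack([model.S, -model.S]),
            sparse.hstack([sparse.csr_matrix(c_obj), sparse.csr_matrix(-c_obj)]),
        ],
        format="csr",
    )
    b_eq = np.append(np.zeros(model.n_metabolites), biomass_star)
    res = linprog(
        c=np.ones(2 * n),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=pos_bounds + neg_bounds,
        method="highs",
    )
    if res.status != 0:
        probe = solve_fba(model)
        if not probe.optimal or probe.biomass < biomass_star - BIOMASS_EQ_TOL:
            raise FbaError(
                f"biomass {biomass_star} is structurally unattainable "
                f"(max achievable: {probe.biomass if probe.optimal else 'none'})"
            )
        raise FbaError(
            f"flux minimization infeasible at biomass {biomass_star} within "
            f"tolerance {BIOMASS_EQ_TOL}"
        )
    v = np.asarray(res.x[:n] - res.x[n:])
    return FluxSolution(
        fluxes=v,
        biomass=float(c_obj @ v),
        status="optimal",
        objective=float(res.fun),
    )


def compute_viability_threshold(biomass_values, k_sd: float = 3.0) -> float:
    """Viability cutoff: mean minus ``k_sd`` sample standard deviations.

    Observations with biomass at or below this value are treated as
    non-growing and dropped from downstream datasets.
    """
    b = np.asarray(list(biomass_values), dtype=float)
    if b.size < 2:
        raise ValueError("need at least 2 biomass values to estimate a threshold")
    return float(b.mean() - k_sd * b.std(ddof=1))
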