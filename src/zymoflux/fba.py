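"""Flux balance analysis (FBA) and flux variability analysis (FVA).

FBA solves max/min v_obj subject to S v = 0 and per-reaction flux bounds,
where S is the internal-metabolite stoichiometric matrix.  The linear
programs are solved with scipy's HiGHS interface using deterministic
settings, so repeated runs agree bit-for-bit.

FVA re-solves two LPs per reaction with the objective pinned to (a fraction
of) its optimum; it is the audit used to prove that reported scenario flux
distributions are unique optima rather than one vertex of a degenerate face.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, stoichiometric_matrix

__all__ = [
    "ConstraintSet",
    "FluxDistribution",
    "FVAResult",
    "solve_fba",
    "flux_variability",
    "steady_state_residual",
]

#: primal/dual feasibility tolerance for the LP solver
SOLVER_TOL = 1e-9

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


@dataclass
class ConstraintSet:
    """Scenario constraints on top of the model's default bounds.

    ``fixed`` pins a reaction's flux (lower = upper = value); these are the
    measured exchange rates a scenario prescribes.  ``bounds_override``
    replaces a reaction's (lower, upper) interval.
    """

    fixed: dict[str, float] = field(default_factory=dict)
    bounds_override: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self, model: MetabolicModel) -> None:
        for rid, value in self.fixed.items():
            rxn = model.reaction(rid)  # KeyError if unknown
            if not (rxn.lower_bound - 1e-12 <= value <= rxn.upper_bound + 1e-12):
                raise ValueError(
                    f"fixed flux {rid}={value} outside default bounds "
                    f"[{rxn.lower_bound}, {rxn.upper_bound}]"
                )
        for rid, (lo, hi) in self.bounds_override.items():
            model.reaction(rid)
            if lo > hi:
                raise ValueError(f"bounds override for {rid}: {lo} > {hi}")


@dataclass
class FluxDistribution:
    """An FBA solution: the flux vector v with objective value and status."""

    fluxes: dict[str, float]
    objective_value: float | None
    status: str

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAResult:
    """Per-reaction flux ranges at a fixed fraction of the optimal objective."""

    ranges: dict[str, tuple[float, float]]
    fraction_of_optimum: float

    def width(self, rid: str) -> float:
        lo, hi = self.ranges[rid]
        return hi - lo

    def max_width(self) -> float:
        return max(hi - lo for lo, hi in self.ranges.values())


def _effective_bounds(
    model: MetabolicModel, constraints: ConstraintSet | None
) -> list[tuple[float, float]]:
    bounds = {r.id: (r.lower_bound, r.upper_bound) for r in model.reactions}
    if constraints is not None:
        constraints.validate(model)
        for rid, bnds in constraints.bounds_override.items():
            bounds[rid] = bnds
        for rid, value in constraints.fixed.items():
            bounds[rid] = (value, value)
    return [bounds[rid] for rid in model.reaction_ids]


def _solve(
    S: np.ndarray,
    bounds: list[tuple[float, float]],
    c: np.ndarray,
):
    return linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": SOLVER_TOL,
            "dual_feasibility_tolerance": SOLVER_TOL,
        },
    )


def solve_fba(
    model: MetabolicModel,
    constraints: ConstraintSet | None,
    objective: str,
    maximize: bool = True,
) -> FluxDistribution:
    """Optimize one reaction flux at steady state.

    Returns a FluxDistribution whose status is "optimal", "infeasible" or
    "unbounded"; fluxes are empty unless optimal.
    """
    if objective not in model.reaction_ids:
        raise KeyError(f"objective reaction {objective!r} not in model")
    S_df = stoichiometric_matrix(model)
    S = S_df.to_numpy()
    bounds = _effective_bounds(model, constraints)
    c = np.zeros(S.shape[1])
    c[S_df.columns.get_loc(objective)] = -1.0 if maximize else 1.0
    res = _solve(S, bounds, c)
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return FluxDistribution(fluxes={}, objective_value=None, status=status)
    fluxes = dict(zip(S_df.columns, res.x))
    return FluxDistribution(
        fluxes=fluxes, objective_value=fluxes[objective], status="optimal"
    )


def flux_variability(
    model: MetabolicModel,
    constraints: ConstraintSet | None,
    objective: str,
    fraction_of_optimum: float = 1.0,
    maximize: bool = True,
    reactions: list[str] | None = None,
) -> FVAResult:
    """Min/max each reaction flux with the objective held at
    ``fraction_of_optimum`` times its optimum (two LPs per reaction)."""
    if not 0 < fraction_of_optimum <= 1:
        raise ValueError("fraction_of_optimum must be in (0, 1]")
    base = solve_fba(model, constraints, objective, maximize=maximize)
    if not base.optimal:
        raise RuntimeError(f"FBA not optimal (status {base.status}); cannot run FVA")
    opt = base.objective_value
    S_df = stoichiometric_matrix(model)
    S = S_df.to_numpy()
    bounds = _effective_bounds(model, constraints)
    obj_idx = S_df.columns.get_loc(objective)
    lo, hi = bounds[obj_idx]
    # pin the objective to at least (at most, if minimizing) its optimum
    if maximize:
        bounds[obj_idx] = (max(lo, fraction_of_optimum * opt), hi)
    else:
        bounds[obj_idx] = (lo, min(hi, fraction_of_optimum * opt))
    targets = reactions if reactions is not None else list(S_df.columns)
    ranges: dict[str, tuple[float, float]] = {}
    for rid in targets:
        idx = S_df.columns.get_loc(rid)
        c = np.zeros(S.shape[1])
        c[idx] = 1.0
        lo_res = _solve(S, bounds, c)
        c[idx] = -1.0
        hi_res = _solve(S, bounds, c)
        if lo_res.status != 0 or hi_res.status != 0:
            raise RuntimeError(f"FVA subproblem for {rid} not optimal")
        ranges[rid] = (lo_res.x[idx], hi_res.x[idx])
    return FVAResult(ranges=ranges, fraction_of_optimum=fraction_of_optimum)


def steady_state_residual(
    model: MetabolicModel, fluxes: dict[str, float]
) -> float:
    """Max over internal metabolites of |S v| for a given flux vector.

    The flux map must cover every reaction in the model.
    """
    missing = set(model.reaction_ids) - set(fluxes)
    if missing:
        raise KeyError(f"fluxes missing for reactions: {sorted(missing)}")
    S_df = stoichiometric_matrix(model)
    v = np.array([fluxes[rid] for rid in S_df.columns])
    residual = S_df.to_numpy() @ v
    return float(np.max(np.abs(residual))) if residual.size else 0.0
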