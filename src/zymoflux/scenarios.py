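"""Acetaldehyde-production scenario analyses.

Five named scenarios, all maximizing acetaldehyde export at a fixed glucose
uptake of 1 mol (EX_glc = -1.00) and fixed biomass export of 0.01:

  A  wild-type-constrained: ethanol/acetate/acetoin exports fixed at the
     measured aerobic batch values (0.68 / 0.07 / 0.06),
  B  theoretical optimum: no by-products (all three fixed at 0),
  C  ADH knock-down: alcohol dehydrogenase flux fixed below wild type,
  D  ADH knockout: ADH fixed at 0,
  E  forced respiration: O2 uptake fixed at the scenario-D optimum with
     ADH left free — respiration alone withdraws the NADH that would
     otherwise be re-oxidized by ethanol formation.

Each scenario's reported flux distribution is audited by FVA: a result is
returned as point values only when every reaction's flux range at the fixed
optimum has width below a tolerance, proving the optimum is unique.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .fba import ConstraintSet, FluxDistribution, flux_variability, solve_fba
from .model import MetabolicModel

__all__ = [
    "Scenario",
    "InfeasibleScenarioError",
    "DegenerateOptimumError",
    "make_scenario",
    "run_scenario",
    "adh_sweep",
    "oxygen_forcing",
    "theoretical_maximum",
    "percent_of_theoretical",
    "scenario_flux_table",
    "round_half_away",
]

OBJECTIVE = "EX_acetaldehyde"
GLUCOSE_UPTAKE = -1.00
BIOMASS_EXPORT = 0.01
WILD_TYPE_EXPORTS = {"EX_ethanol": 0.68, "EX_acetate": 0.07, "EX_acetoin": 0.06}
FVA_WIDTH_TOL = 1e-6

#: row order of the published flux table (our exchange ids)
TABLE_ROW_ORDER = [
    "GLK", "PGI", "G6PDH_nadp", "PGL", "EDD", "KDPGA", "GAPDH", "PGK",
    "PGM", "ENO", "PYK", "PDC", "ADH", "ACDH_nad", "RNDH_nadh",
    "RNDH_nadph", "UO", "TKT2", "RPE", "RPI", "PDH", "EX_glc", "EX_o2",
    "EX_biomass", "EX_co2", "EX_e4p", "EX_ethanol", "EX_acetate",
    "EX_acetoin", "EX_acetaldehyde",
]


class InfeasibleScenarioError(RuntimeError):
    """The scenario's fixed fluxes admit no steady state."""


class DegenerateOptimumError(RuntimeError):
    """The optimum is not unique: some reaction has nonzero FVA width."""


@dataclass
class Scenario:
    """A named constraint set optimized for acetaldehyde export."""

    label: str
    constraints: ConstraintSet
    objective: str = OBJECTIVE
    description: str = ""

    def __post_init__(self) -> None:
        fixed = self.constraints.fixed
        if fixed.get("EX_glc") != GLUCOSE_UPTAKE or fixed.get("EX_biomass") != BIOMASS_EXPORT:
            raise ValueError(
                "every scenario must fix EX_glc = -1.00 and EX_biomass = 0.01"
            )


def _base_fixed(**extra: float) -> dict[str, float]:
    fixed = {"EX_glc": GLUCOSE_UPTAKE, "EX_biomass": BIOMASS_EXPORT}
    fixed.update(extra)
    return fixed


def make_scenario(
    label: str,
    adh: float | None = None,
    o2_uptake: float | None = None,
    model: MetabolicModel | None = None,
) -> Scenario:
    """Build one of the named scenarios A-E.

    C requires ``adh`` (the fixed ADH flux).  E fixes the O2 uptake; if
    ``o2_uptake`` is not given, it is computed as the optimal O2 uptake of
    scenario D on ``model`` (which must then be supplied) — the unrounded
    value, since the E distribution equals D's row for row.
    """
    if label == "A":
        return Scenario(
            "A",
            ConstraintSet(fixed=_base_fixed(**WILD_TYPE_EXPORTS)),
            description="wild-type-constrained by-product exports",
        )
    if label == "B":
        return Scenario(
            "B",
            ConstraintSet(
                fixed=_base_fixed(EX_ethanol=0.0, EX_acetate=0.0, EX_acetoin=0.0)
            ),
            description="theoretical optimum (no by-products)",
        )
    if label == "C":
        if adh is None or adh < 0:
            raise ValueError("scenario C requires a fixed ADH flux >= 0")
        return Scenario(
            "C",
            ConstraintSet(
                fixed=_base_fixed(ADH=adh, EX_acetate=0.07, EX_acetoin=0.06)
            ),
            description=f"ADH knock-down (ADH = {adh})",
        )
    if label == "D":
        return Scenario(
            "D",
            ConstraintSet(
                fixed=_base_fixed(ADH=0.0, EX_acetate=0.07, EX_acetoin=0.06)
            ),
            description="ADH knockout",
        )
    if label == "E":
        if o2_uptake is None:
            if model is None:
                raise ValueError("scenario E needs o2_uptake or a model to derive it")
            sol_d = run_scenario(model, make_scenario("D"), audit=False)
            o2_uptake = -sol_d["EX_o2"]
        return Scenario(
            "E",
            ConstraintSet(
                fixed=_base_fixed(
                    EX_o2=-abs(o2_uptake), EX_acetate=0.07, EX_acetoin=0.06
                )
            ),
            description=f"forced respiration (O2 uptake = {abs(o2_uptake):g})",
        )
    raise ValueError(f"unknown scenario label {label!r}")


def run_scenario(
    model: MetabolicModel, scenario: Scenario, audit: bool = True
) -> FluxDistribution:
    """Solve a scenario; optionally audit optimum uniqueness by FVA.

    Raises InfeasibleScenarioError (naming the fixed constraints) if the
    constraint set admits no steady state, and DegenerateOptimumError if
    the audit finds a reaction with flux range wider than 1e-6 at the
    fixed optimum.
    """
    sol = solve_fba(model, scenario.constraints, scenario.objective, maximize=True)
    if sol.status == "infeasible":
        raise InfeasibleScenarioError(
            f"scenario {scenario.label} infeasible under fixed fluxes "
            f"{scenario.constraints.fixed}"
        )
    if sol.status != "optimal":
        raise RuntimeError(f"scenario {scenario.label}: solver status {sol.status}")
    if audit:
        fva = flux_variability(
            model, scenario.constraints, scenario.objective, fraction_of_optimum=1.0
        )
        if fva.max_width() > FVA_WIDTH_TOL:
            wide = {
                rid: rng for rid, rng in fva.ranges.items()
                if rng[1] - rng[0] > FVA_WIDTH_TOL
            }
            raise DegenerateOptimumError(
                f"scenario {scenario.label}: non-unique optimum, ranges {wide}"
            )
    return sol


def adh_sweep(
    model: MetabolicModel, adh_values: list[float], audit: bool = False
) -> pd.DataFrame:
    """Optimal acetaldehyde yield at each fixed ADH flux (scenario-C runs).

    Infeasible values are reported with status "infeasible" and NaN yield
    rather than aborting the sweep.
    """
    rows = []
    for value in adh_values:
        if value < 0:
            raise ValueError("ADH flux values must be >= 0")
        scenario = (
            make_scenario("D") if value == 0 else make_scenario("C", adh=value)
        )
        try:
            sol = run_scenario(model, scenario, audit=audit)
            rows.append(
                {"adh": value, "acetaldehyde_yield": sol.objective_value,
                 "status": "optimal"}
            )
        except InfeasibleScenarioError:
            rows.append(
                {"adh": value, "acetaldehyde_yield": math.nan,
                 "status": "infeasible"}
            )
    return pd.DataFrame(rows)


def oxygen_forcing(
    model: MetabolicModel, o2_uptake: float, audit: bool = False
) -> FluxDistribution:
    """Maximize acetaldehyde export with O2 uptake pinned (scenario-E style).

    Acetate/acetoin exports stay at the wild-type values 0.07/0.06 and ADH
    is left free; above the redox-supply maximum the LP is infeasible.
    """
    if o2_uptake < 0:
        raise ValueError("o2_uptake must be >= 0")
    scenario = make_scenario("E", o2_uptake=o2_uptake)
    return run_scenario(model, scenario, audit=audit)


def theoretical_maximum(model: MetabolicModel) -> float:
    """The scenario-B optimum: maximal acetaldehyde yield with no by-products."""
    sol = run_scenario(model, make_scenario("B"), audit=False)
    return sol.objective_value


def percent_of_theoretical(model: MetabolicModel, yield_value: float) -> float:
    """A measured molar yield as a percentage of the scenario-B optimum.

    The 100% reference is computed from the model, never hard-coded.
    """
    if yield_value < 0:
        raise ValueError("yield_value must be >= 0")
    return 100.0 * yield_value / theoretical_maximum(model)


def round_half_away(x: float, digits: int = 2) -> float:
    """Round half away from zero (matching the flux table's presentation)."""
    factor = 10 ** digits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x) + 0.0


def scenario_flux_table(
    model: MetabolicModel, digits: int = 2, audit: bool = True
) -> pd.DataFrame:
    """The full multi-scenario flux table: rows = reactions with subsystem,
    columns = A, B, C(0.60), C(0.40), C(0.20), D, E, rounded to 2 decimals.

    Uptake fluxes keep their negative sign (EX_glc = -1.00).
    """
    scenarios = [
        ("A", make_scenario("A")),
        ("B", make_scenario("B")),
        ("C(0.60)", make_scenario("C", adh=0.60)),
        ("C(0.40)", make_scenario("C", adh=0.40)),
        ("C(0.20)", make_scenario("C", adh=0.20)),
        ("D", make_scenario("D")),
        ("E", make_scenario("E", model=model)),
    ]
    columns: dict[str, dict[str, float]] = {}
    for name, scenario in scenarios:
        sol = run_scenario(model, scenario, audit=audit)
        columns[name] = {
            rid: round_half_away(sol[rid], digits) for rid in TABLE_ROW_ORDER
        }
    table = pd.DataFrame(columns, index=TABLE_ROW_ORDER)
    table.insert(0, "pathway", [model.reaction(rid).subsystem for rid in TABLE_ROW_ORDER])
    table.index.name = "reaction"
    return table
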