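"""Stoichiometric network of *Zymomonas mobilis* aerobic central metabolism.

The model covers the Entner-Doudoroff (ED) glycolytic route, fermentative
branches (ethanol, acetate, acetoin), the energetically uncoupled
respiratory chain (type II NADH dehydrogenase, NADPH dehydrogenase,
ubiquinol oxidase), the non-oxidative pentose phosphate branch, a truncated
TCA entry (pyruvate dehydrogenase), a lumped biomass drain, an ATP
maintenance sink, and exchange reactions.  Fluxes are glucose-normalized
(mol per mol glucose consumed), with the convention that negative exchange
flux is uptake.

Protons, water, inorganic phosphate and CoA are not tracked: this is a
central-carbon model and no balanced flux depends on them.  Cofactor pairs
(NAD/NADH, NADP/NADPH, Q/QH2, ATP/ADP) are tracked as conserved moieties.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "ModelParseError",
    "build_reference_model",
    "stoichiometric_matrix",
    "check_carbon_balance",
    "read_model",
    "write_model",
    "model_hash",
]

DEFAULT_BOUND = 1000.0

SUBSYSTEMS = (
    "ED pathway",
    "Fermentation",
    "Respiration",
    "PPP",
    "TCA",
    "Export",
    "Maintenance",
    "Biomass",
)


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


class ModelParseError(ValueError):
    """A model file is malformed."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species tracked by the network.

    carbon_count is the number of carbon atoms; cofactors carry 0 and the
    BIOMASS pseudo-metabolite carries the summed carbon of its precursors.
    """

    id: str
    name: str = ""
    carbon_count: int = 0
    compartment: str = "internal"
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        if self.carbon_count < 0:
            raise ModelValidationError(
                f"metabolite {self.id!r}: carbon_count must be >= 0"
            )
        if self.compartment not in ("internal", "external"):
            raise ModelValidationError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}"
            )


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds.

    stoichiometry maps metabolite id to signed coefficient (negative =
    consumed in the positive flux direction).  Exchange reactions have a
    single entry with coefficient -1, so positive flux exports the species
    and negative flux imports it.
    """

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    subsystem: str = "Export"

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not self.reversible and self.lower_bound < 0:
            raise ModelValidationError(
                f"reaction {self.id!r}: irreversible but lower_bound < 0"
            )

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1


@dataclass
class MetabolicModel:
    """Metabolites plus reactions; owner of the stoichiometric matrix S."""

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- indexing helpers -------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if m.compartment == "internal"]

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        mids = self.metabolite_ids
        if len(set(mids)) != len(mids):
            dupes = sorted({m for m in mids if mids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dupes}")
        rids = self.reaction_ids
        if len(set(rids)) != len(rids):
            dupes = sorted({r for r in rids if rids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dupes}")
        known = set(mids)
        for rxn in self.reactions:
            for mid in rxn.stoichiometry:
                if mid not in known:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                    )

    def dead_end_metabolites(self, include_cofactors: bool = True) -> list[str]:
        """Internal non-pseudo metabolites lacking a producer or a consumer.

        A reversible reaction counts in both directions; an exchange open
        for uptake counts as a producer of its metabolite.
        """
        producible: set[str] = set()
        consumable: set[str] = set()
        for rxn in self.reactions:
            for mid, coeff in rxn.stoichiometry.items():
                forward_possible = rxn.upper_bound > 0
                backward_possible = rxn.lower_bound < 0
                if coeff > 0:
                    if forward_possible:
                        producible.add(mid)
                    if backward_possible:
                        consumable.add(mid)
                elif coeff < 0:
                    if forward_possible:
                        consumable.add(mid)
                    if backward_possible:
                        producible.add(mid)
        dead = []
        for m in self.internal_metabolites:
            if m.is_pseudo:
                continue
            if not include_cofactors and m.carbon_count == 0:
                continue
            if m.id not in producible or m.id not in consumable:
                dead.append(m.id)
        return dead


# ---------------------------------------------------------------------------
# Reference network
# ---------------------------------------------------------------------------

_REFERENCE_METABOLITES: list[tuple[str, str, int]] = [
    ("GLC", "D-glucose", 6),
    ("G6P", "glucose 6-phosphate", 6),
    ("F6P", "fructose 6-phosphate", 6),
    ("PGL6", "6-phosphogluconolactone", 6),
    ("PG6", "6-phosphogluconate", 6),
    ("KDPG", "2-keto-3-deoxy-6-phosphogluconate", 6),
    ("GAP", "glyceraldehyde 3-phosphate", 3),
    ("BPG13", "1,3-bisphosphoglycerate", 3),
    ("PG3", "3-phosphoglycerate", 3),
    ("PG2", "2-phosphoglycerate", 3),
    ("PEP", "phosphoenolpyruvate", 3),
    ("PYR", "pyruvate", 3),
    ("ACALD", "acetaldehyde", 2),
    ("ETOH", "ethanol", 2),
    ("ACT", "acetate", 2),
    ("ACTN", "acetoin", 4),
    ("ACCOA", "acetyl-CoA (C2 unit)", 2),
    ("CO2", "carbon dioxide", 1),
    ("O2", "molecular oxygen", 0),
    ("E4P", "erythrose 4-phosphate", 4),
    ("X5P", "xylulose 5-phosphate", 5),
    ("RU5P", "ribulose 5-phosphate", 5),
    ("R5P", "ribose 5-phosphate", 5),
    ("NAD", "NAD+", 0),
    ("NADH", "NADH", 0),
    ("NADP", "NADP+", 0),
    ("NADPH", "NADPH", 0),
    ("Q", "ubiquinone", 0),
    ("QH2", "ubiquinol", 0),
    ("ATP", "ATP", 0),
    ("ADP", "ADP", 0),
]

# (id, name, subsystem, reversible, stoichiometry)
_REFERENCE_REACTIONS: list[tuple[str, str, str, bool, dict[str, float]]] = [
    ("GLK", "glucokinase", "ED pathway", False,
     {"GLC": -1, "ATP": -1, "G6P": 1, "ADP": 1}),
    ("PGI", "glucose-6-phosphate isomerase", "ED pathway", True,
     {"G6P": -1, "F6P": 1}),
    ("G6PDH_nadp", "glucose-6-phosphate dehydrogenase (NADP)", "ED pathway", False,
     {"G6P": -1, "NADP": -1, "PGL6": 1, "NADPH": 1}),
    ("PGL", "6-phosphogluconolactonase", "ED pathway", False,
     {"PGL6": -1, "PG6": 1}),
    ("EDD", "6-phosphogluconate dehydratase", "ED pathway", False,
     {"PG6": -1, "KDPG": 1}),
    ("KDPGA", "KDPG aldolase", "ED pathway", False,
     {"KDPG": -1, "PYR": 1, "GAP": 1}),
    ("GAPDH", "glyceraldehyde-3-phosphate dehydrogenase", "ED pathway", False,
     {"GAP": -1, "NAD": -1, "BPG13": 1, "NADH": 1}),
    ("PGK", "phosphoglycerate kinase", "ED pathway", True,
     {"BPG13": -1, "ADP": -1, "PG3": 1, "ATP": 1}),
    ("PGM", "phosphoglycerate mutase", "ED pathway", True,
     {"PG3": -1, "PG2": 1}),
    ("ENO", "enolase", "ED pathway", True,
     {"PG2": -1, "PEP": 1}),
    ("PYK", "pyruvate kinase", "ED pathway", False,
     {"PEP": -1, "ADP": -1, "PYR": 1, "ATP": 1}),
    ("PDC", "pyruvate decarboxylase", "Fermentation", False,
     {"PYR": -1, "ACALD": 1, "CO2": 1}),
    ("ADH", "alcohol dehydrogenase", "Fermentation", True,
     {"ACALD": -1, "NADH": -1, "ETOH": 1, "NAD": 1}),
    ("ACDH_nad", "acetaldehyde dehydrogenase (NAD)", "Fermentation", False,
     {"ACALD": -1, "NAD": -1, "ACT": 1, "NADH": 1}),
    # Lumped carboligase: the unique acetoin stoichiometry consistent with
    # the network's CO2 export and pyruvate balance.
    ("ACTNS", "acetoin synthesis (carboligase, lumped)", "Fermentation", False,
     {"PYR": -1, "ACALD": -1, "ACTN": 1, "CO2": 1}),
    ("PDH", "pyruvate dehydrogenase", "TCA", False,
     {"PYR": -1, "NAD": -1, "ACCOA": 1, "CO2": 1, "NADH": 1}),
    ("RNDH_nadh", "respiratory NADH dehydrogenase (type II)", "Respiration", False,
     {"NADH": -1, "Q": -1, "NAD": 1, "QH2": 1}),
    ("RNDH_nadph", "respiratory NADPH dehydrogenase", "Respiration", False,
     {"NADPH": -1, "Q": -1, "NADP": 1, "QH2": 1}),
    # Counted per mole O2, so the UO flux equals the O2 uptake flux.
    ("UO", "ubiquinol oxidase", "Respiration", False,
     {"QH2": -2, "O2": -1, "Q": 2}),
    # Positive direction X5P+E4P -> F6P+GAP; biosynthetic operation is the
    # reverse (negative flux).
    ("TKT2", "transketolase", "PPP", True,
     {"X5P": -1, "E4P": -1, "F6P": 1, "GAP": 1}),
    ("RPE", "ribulose-phosphate epimerase", "PPP", True,
     {"X5P": -1, "RU5P": 1}),
    ("RPI", "ribose-5-phosphate isomerase", "PPP", True,
     {"RU5P": -1, "R5P": 1}),
    ("ATPM", "ATP maintenance (ATPase sink)", "Maintenance", False,
     {"ATP": -1, "ADP": 1}),
    ("BIOMASS_RXN", "biomass synthesis (lumped precursor drain)", "Biomass", False,
     {"R5P": -1, "PG3": -2, "PEP": -2, "PYR": -4, "ACCOA": -3,
      "NADPH": -22, "ATP": -30,
      "BIOMASS": 1, "NADP": 22, "ADP": 30}),
]

# (exchange id, metabolite, uptake allowed)
_REFERENCE_EXCHANGES: list[tuple[str, str, bool]] = [
    ("EX_glc", "GLC", True),
    ("EX_o2", "O2", True),
    ("EX_co2", "CO2", False),
    ("EX_ethanol", "ETOH", False),
    ("EX_acetate", "ACT", False),
    ("EX_acetoin", "ACTN", False),
    ("EX_acetaldehyde", "ACALD", False),
    ("EX_e4p", "E4P", False),
    ("EX_biomass", "BIOMASS", False),
]


def build_reference_model() -> MetabolicModel:
    """Build the reference central-metabolism network (24 internal
    reactions + 9 exchanges).

    Default bounds are ±1000 for reversible and [0, 1000] for irreversible
    reactions; all exchanges are open for export, and the glucose and
    oxygen exchanges are additionally open for uptake.  The biomass drain
    consumes 1 R5P + 2 PG3 + 2 PEP + 4 PYR + 3 ACCOA (35 carbon atoms)
    plus 22 NADPH and 30 ATP per unit of the BIOMASS pseudo-metabolite.
    """
    mets = [Metabolite(i, n, c) for i, n, c in _REFERENCE_METABOLITES]
    mets.append(
        Metabolite("BIOMASS", "biomass (pseudo-metabolite)", 35, is_pseudo=True)
    )
    rxns = []
    for rid, name, subsystem, rev, stoich in _REFERENCE_REACTIONS:
        rxns.append(
            Reaction(
                id=rid,
                name=name,
                subsystem=subsystem,
                reversible=rev,
                lower_bound=-DEFAULT_BOUND if rev else 0.0,
                upper_bound=DEFAULT_BOUND,
                stoichiometry=dict(stoich),
            )
        )
    for rid, mid, uptake in _REFERENCE_EXCHANGES:
        rxns.append(
            Reaction(
                id=rid,
                name=f"{mid} exchange",
                subsystem="Export",
                reversible=uptake,
                lower_bound=-DEFAULT_BOUND if uptake else 0.0,
                upper_bound=DEFAULT_BOUND,
                stoichiometry={mid: -1.0},
            )
        )
    return MetabolicModel(metabolites=mets, reactions=rxns)


# ---------------------------------------------------------------------------
# Matrix and quality control
# ---------------------------------------------------------------------------


def stoichiometric_matrix(model: MetabolicModel) -> pd.DataFrame:
    """Stoichiometric matrix S (internal metabolites x reactions).

    External metabolites are excluded, so exchange reactions appear as
    single-ended columns.  Returned as a DataFrame indexed by metabolite
    and reaction ids.
    """
    model.validate()
    rows = [m.id for m in model.internal_metabolites]
    cols = model.reaction_ids
    S = pd.DataFrame(0.0, index=rows, columns=cols)
    for rxn in model.reactions:
        for mid, coeff in rxn.stoichiometry.items():
            if mid in S.index:
                S.loc[mid, rxn.id] = float(coeff)
    return S


def check_carbon_balance(model: MetabolicModel) -> dict[str, float]:
    """Carbon imbalance per non-exchange reaction; offenders only.

    Each entry is the net carbon change (products minus substrates,
    in C atoms per unit flux) of a reaction that fails to balance.
    A clean network returns an empty dict.
    """
    carbon = {m.id: m.carbon_count for m in model.metabolites}
    offenders: dict[str, float] = {}
    for rxn in model.reactions:
        if rxn.is_exchange:
            continue
        imbalance = sum(
            coeff * carbon[mid] for mid, coeff in rxn.stoichiometry.items()
        )
        if abs(imbalance) > 1e-9:
            offenders[rxn.id] = imbalance
    return offenders


def moiety_imbalances(
    model: MetabolicModel,
    pairs: tuple[tuple[str, str], ...] = (
        ("NAD", "NADH"),
        ("NADP", "NADPH"),
        ("Q", "QH2"),
        ("ATP", "ADP"),
    ),
) -> dict[str, dict[str, float]]:
    """Net change of each conserved cofactor pair per reaction (offenders only)."""
    offenders: dict[str, dict[str, float]] = {}
    for rxn in model.reactions:
        bad = {}
        for a, b in pairs:
            net = rxn.stoichiometry.get(a, 0.0) + rxn.stoichiometry.get(b, 0.0)
            if abs(net) > 1e-9:
                bad[f"{a}/{b}"] = net
        if bad:
            offenders[rxn.id] = bad
    return offenders


# ---------------------------------------------------------------------------
# Serialization: JSON (single file) and TSV (metabolites.tsv + reactions.tsv)
# ---------------------------------------------------------------------------


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "carbon_count": m.carbon_count,
                "compartment": m.compartment,
                "is_pseudo": m.is_pseudo,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "subsystem": r.subsystem,
                "reversible": r.reversible,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "stoichiometry": r.stoichiometry,
            }
            for r in model.reactions
        ],
    }


def _model_from_dict(payload: dict) -> MetabolicModel:
    try:
        mets = [
            Metabolite(
                id=d["id"],
                name=d.get("name", ""),
                carbon_count=int(d.get("carbon_count", 0)),
                compartment=d.get("compartment", "internal"),
                is_pseudo=bool(d.get("is_pseudo", False)),
            )
            for d in payload["metabolites"]
        ]
        rxns = [
            Reaction(
                id=d["id"],
                name=d.get("name", ""),
                subsystem=d.get("subsystem", "Export"),
                reversible=bool(d.get("reversible", False)),
                lower_bound=float(d["lower_bound"]),
                upper_bound=float(d["upper_bound"]),
                stoichiometry={k: float(v) for k, v in d["stoichiometry"].items()},
            )
            for d in payload["reactions"]
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelParseError(f"malformed model definition: {exc}") from exc
    try:
        return MetabolicModel(metabolites=mets, reactions=rxns)
    except ModelValidationError as exc:
        raise ModelParseError(str(exc)) from exc


def _parse_stoichiometry(text: str, rid: str) -> dict[str, float]:
    stoich: dict[str, float] = {}
    for pair in text.split(";"):
        pair = pair.strip()
        if not pair:
            continue
        if ":" not in pair:
            raise ModelParseError(
                f"reaction {rid!r}: malformed stoichiometry entry {pair!r}"
            )
        mid, _, val = pair.rpartition(":")
        try:
            stoich[mid.strip()] = float(val)
        except ValueError as exc:
            raise ModelParseError(
                f"reaction {rid!r}: non-numeric coefficient in {pair!r}"
            ) from exc
    return stoich


def _format_stoichiometry(stoich: dict[str, float]) -> str:
    return ";".join(f"{mid}:{coeff:g}" for mid, coeff in stoich.items())


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model as single-file JSON (``*.json``) or as a directory
    containing ``metabolites.tsv`` and ``reactions.tsv``."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1) + "\n")
        return
    path.mkdir(parents=True, exist_ok=True)
    mets = pd.DataFrame(_model_to_dict(model)["metabolites"])
    mets.to_csv(path / "metabolites.tsv", sep="\t", index=False)
    rxns = pd.DataFrame(
        [
            {
                "id": r.id,
                "name": r.name,
                "subsystem": r.subsystem,
                "reversible": r.reversible,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "stoichiometry": _format_stoichiometry(r.stoichiometry),
            }
            for r in model.reactions
        ]
    )
    rxns.to_csv(path / "reactions.tsv", sep="\t", index=False)


def read_model(path: str | Path) -> MetabolicModel:
    """Read a model written by :func:`write_model` (JSON file or TSV directory)."""
    path = Path(path)
    if path.is_file():
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"{path}: invalid JSON: {exc}") from exc
        return _model_from_dict(payload)
    met_path = path / "metabolites.tsv"
    rxn_path = path / "reactions.tsv"
    if not met_path.exists() or not rxn_path.exists():
        raise ModelParseError(
            f"{path}: expected metabolites.tsv and reactions.tsv"
        )
    mets = pd.read_csv(met_path, sep="\t")
    rxns = pd.read_csv(rxn_path, sep="\t")
    payload = {
        "metabolites": mets.fillna({"name": ""}).to_dict("records"),
        "reactions": [
            {
                "id": row["id"],
                "name": row["name"] if pd.notna(row["name"]) else "",
                "subsystem": row["subsystem"],
                "reversible": bool(row["reversible"]),
                "lower_bound": row["lower_bound"],
                "upper_bound": row["upper_bound"],
                "stoichiometry": _parse_stoichiometry(
                    str(row["stoichiometry"]), str(row["id"])
                ),
            }
            for _, row in rxns.iterrows()
        ],
    }
    return _model_from_dict(payload)


def model_hash(model: MetabolicModel) -> str:
    """SHA-256 of the canonical JSON form, for run provenance logs."""
    canonical = json.dumps(_model_to_dict(model), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
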