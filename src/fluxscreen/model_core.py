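"""Domain types for metabolic networks and gene-protein-reaction (GPR) rules.

A :class:`MetabolicModel` is the in-memory form of a constraint-based
metabolic reconstruction: metabolites, reactions with stoichiometry and flux
bounds, boolean GPR rules linking genes to reactions, and named objective
reactions (a biomass drain for proliferation, an ATP-maintenance hydrolysis
for resting energy balance).

Two on-disk formats are supported: SBML Level 3 with the FBC package (via
python-libsbml) and a compact JSON dialect used for fixtures and for
serialising extracted context models::

    {
      "model_id": "toy",
      "metabolites": [{"id": "glc_e", "compartment": "e"}, ...],
      "reactions": [
        {"id": "R1", "stoich": {"glc_e": -1, "glc_c": 1},
         "lb": 0, "ub": 1000, "gpr": "g1 or g2"},
        ...
      ],
      "biomass": "BIOMASS",
      "atp_maintenance": "ATPM"
    }

Sign conventions follow SBML-FBC practice: exchange flux > 0 is secretion,
< 0 is uptake; an exchange reaction touches exactly one metabolite.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "GprExpression",
    "GprParseError",
    "ModelValidationError",
    "Reaction",
    "MetabolicModel",
    "parse_gpr",
    "render_gpr",
    "evaluate_gpr",
    "inactivate_for_genes",
    "read_model",
    "write_model",
]


class GprParseError(ValueError):
    """Raised when a GPR rule string cannot be parsed."""


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GprExpression:
    """Normalized boolean AND/OR tree over gene identifiers.

    ``kind`` is one of ``"GENE"``, ``"AND"``, ``"OR"`` or ``"EMPTY"``.
    GENE nodes carry ``gene_id``; AND/OR nodes carry ≥ 2 children.  The
    EMPTY expression denotes a reaction with no gene association; it
    evaluates to True under any knockout, i.e. the reaction can never be
    inactivated by gene deletion.
    """

    kind: str
    gene_id: str | None = None
    children: tuple["GprExpression", ...] = ()

    def is_empty(self) -> bool:
        return self.kind == "EMPTY"

    def genes(self) -> frozenset[str]:
        """All gene ids referenced by this expression."""
        if self.kind == "GENE":
            return frozenset((self.gene_id,))
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return frozenset(out)


EMPTY_GPR = GprExpression(kind="EMPTY")

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<and>&&|&)|(?P<or>\|\||\|)"
    r"|(?P<ident>[A-Za-z0-9_.:\-]+))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            raise GprParseError(f"unexpected character {text[pos]!r} at position {pos}")
        if m.lastgroup == "ident":
            word = m.group("ident")
            lowered = word.lower()
            if lowered == "and":
                tokens.append(("AND", word, m.start("ident")))
            elif lowered == "or":
                tokens.append(("OR", word, m.start("ident")))
            else:
                tokens.append(("GENE", word, m.start("ident")))
        elif m.lastgroup == "and":
            tokens.append(("AND", m.group(), m.start()))
        elif m.lastgroup == "or":
            tokens.append(("OR", m.group(), m.start()))
        elif m.lastgroup == "lpar":
            tokens.append(("LPAR", "(", m.start()))
        else:
            tokens.append(("RPAR", ")", m.start()))
        pos = m.end()
    return tokens


class _GprParser:
    """Recursive-descent parser; OR has lowest precedence, AND binds tighter."""

    def __init__(self, tokens: list[tuple[str, str, int]], text: str):
        self.tokens = tokens
        self.text = text
        self.i = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str, int] | None:
        tok = self.peek()
        if tok is not None:
            self.i += 1
        return tok

    def parse(self) -> GprExpression:
        expr = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise GprParseError(
                f"unexpected token {tok[1]!r} at position {tok[2]} in {self.text!r}"
            )
        return expr

    def parse_or(self) -> GprExpression:
        children = [self.parse_and()]
        while (tok := self.peek()) is not None and tok[0] == "OR":
            self.next()
            children.append(self.parse_and())
        return _combine("OR", children)

    def parse_and(self) -> GprExpression:
        children = [self.parse_atom()]
        while (tok := self.peek()) is not None and tok[0] == "AND":
            self.next()
            children.append(self.parse_atom())
        return _combine("AND", children)

    def parse_atom(self) -> GprExpression:
        tok = self.next()
        if tok is None:
            raise GprParseError(f"dangling operator at end of {self.text!r}")
        kind, value, pos = tok
        if kind == "GENE":
            return GprExpression(kind="GENE", gene_id=value)
        if kind == "LPAR":
            expr = self.parse_or()
            closing = self.next()
            if closing is None or closing[0] != "RPAR":
                raise GprParseError(
                    f"unbalanced parenthesis opened at position {pos} in {self.text!r}"
                )
            return expr
        raise GprParseError(f"unexpected token {value!r} at position {pos} in {self.text!r}")


def _combine(kind: str, children: list[GprExpression]) -> GprExpression:
    """Flatten associative chains; a single child collapses to itself."""
    if len(children) == 1:
        return children[0]
    flat: list[GprExpression] = []
    for child in children:
        if child.kind == kind:
            flat.extend(child.children)
        else:
            flat.append(child)
    return GprExpression(kind=kind, children=tuple(flat))


def parse_gpr(rule_text: str | None) -> GprExpression:
    """Parse a GPR rule string into a normalized boolean tree.

    Accepts identifiers, parentheses, case-insensitive ``and``/``or`` and the
    ``&&``/``||`` (and single ``&``/``|``) synonyms.  Empty or whitespace-only
    text yields the EMPTY expression.  Associative chains are flattened, so
    ``a or b or c`` becomes a single OR node with three children.
    """
    if rule_text is None or not rule_text.strip():
        return EMPTY_GPR
    tokens = _tokenize(rule_text)
    return _GprParser(tokens, rule_text).parse()


def render_gpr(expr: GprExpression) -> str:
    """Render a GPR tree back to rule text (inverse of :func:`parse_gpr`)."""
    if expr.kind == "EMPTY":
        return ""
    if expr.kind == "GENE":
        return expr.gene_id  # type: ignore[return-value]
    joiner = " and " if expr.kind == "AND" else " or "
    parts = []
    for child in expr.children:
        text = render_gpr(child)
        # OR children under AND need parentheses; AND under OR also kept
        # parenthesised for readability and unambiguous round-trips.
        if child.kind in ("AND", "OR"):
            text = f"({text})"
        parts.append(text)
    return joiner.join(parts)


def evaluate_gpr(expr: GprExpression, inactive_genes: Iterable[str]) -> bool:
    """Evaluate a GPR rule under a set of knocked-out genes.

    A GENE leaf is False iff its gene is inactive; AND/OR combine with the
    usual boolean semantics; the EMPTY expression is always True.
    """
    inactive = inactive_genes if isinstance(inactive_genes, (set, frozenset)) else set(inactive_genes)
    return _eval(expr, inactive)


def _eval(expr: GprExpression, inactive: set[str] | frozenset[str]) -> bool:
    if expr.kind == "EMPTY":
        return True
    if expr.kind == "GENE":
        return expr.gene_id not in inactive
    if expr.kind == "AND":
        return all(_eval(c, inactive) for c in expr.children)
    return any(_eval(c, inactive) for c in expr.children)


# ---------------------------------------------------------------------------
# Model types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction with flux bounds and an optional GPR rule.

    Stoichiometry maps metabolite id to a signed coefficient (negative =
    consumed). Bounds are fluxes in nominal mmol·gDW⁻¹·h⁻¹. ``is_exchange``
    marks boundary reactions (single-metabolite stoichiometry).
    """

    reaction_id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float
    upper_bound: float
    gpr: GprExpression = EMPTY_GPR
    is_exchange: bool = False

    def with_bounds(self, lb: float, ub: float) -> "Reaction":
        return replace(self, lower_bound=lb, upper_bound=ub)


@dataclass
class Metabolite:
    metabolite_id: str
    compartment: str = "c"


@dataclass
class MetabolicModel:
    """A genome-scale (or toy) metabolic network.

    Invariants (enforced by :meth:`validate`): stoichiometry references only
    declared metabolites; lb ≤ ub for every reaction; the named objective
    reactions exist when set; every gene in a GPR is in ``genes``.
    """

    model_id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: list[str] = field(default_factory=list)
    biomass_reaction: str | None = None
    atp_maintenance_reaction: str | None = None
    provenance: dict | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ----------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.reaction_id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.metabolite_id for m in self.metabolites]

    @property
    def exchange_reactions(self) -> set[str]:
        return {r.reaction_id for r in self.reactions if r.is_exchange}

    def reaction(self, reaction_id: str) -> Reaction:
        try:
            return self._rxn_index[reaction_id]
        except KeyError:
            raise KeyError(f"no reaction {reaction_id!r} in model {self.model_id!r}") from None

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.metabolite_id for m in self.metabolites]
        met_set = set(met_ids)
        if len(met_set) != len(met_ids):
            raise ModelValidationError(f"duplicate metabolite ids in {self.model_id!r}")
        rxn_ids = [r.reaction_id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelValidationError(f"duplicate reaction ids in {self.model_id!r}")
        gene_set = set(self.genes)
        for rxn in self.reactions:
            unknown = set(rxn.stoichiometry) - met_set
            if unknown:
                raise ModelValidationError(
                    f"reaction {rxn.reaction_id!r} references undeclared metabolites {sorted(unknown)}"
                )
            if not rxn.lower_bound <= rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rxn.reaction_id!r} has lower bound {rxn.lower_bound} "
                    f"> upper bound {rxn.upper_bound}"
                )
            if rxn.is_exchange and len(rxn.stoichiometry) != 1:
                raise ModelValidationError(
                    f"exchange reaction {rxn.reaction_id!r} must touch exactly one metabolite"
                )
            missing = rxn.gpr.genes() - gene_set
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.reaction_id!r} GPR references undeclared genes {sorted(missing)}"
                )
        for name, objective in (
            ("biomass", self.biomass_reaction),
            ("atp_maintenance", self.atp_maintenance_reaction),
        ):
            if objective is not None and objective not in set(rxn_ids):
                raise ModelValidationError(
                    f"{name} objective {objective!r} is not a declared reaction"
                )
        self._rxn_index = {r.reaction_id: r for r in self.reactions}

    # -- derived views -----------------------------------------------------
    def subset(self, keep_reactions: Iterable[str], model_id: str | None = None,
               provenance: dict | None = None) -> "MetabolicModel":
        """Submodel restricted to ``keep_reactions`` (metabolites pruned)."""
        keep = set(keep_reactions)
        unknown = keep - set(self.reaction_ids)
        if unknown:
            raise KeyError(f"cannot subset on unknown reactions {sorted(unknown)}")
        reactions = [r for r in self.reactions if r.reaction_id in keep]
        used_mets = {m for r in reactions for m in r.stoichiometry}
        metabolites = [m for m in self.metabolites if m.metabolite_id in used_mets]
        used_genes = set().union(*(r.gpr.genes() for r in reactions)) if reactions else set()
        return MetabolicModel(
            model_id=model_id or self.model_id,
            metabolites=metabolites,
            reactions=reactions,
            genes=[g for g in self.genes if g in used_genes],
            biomass_reaction=self.biomass_reaction if self.biomass_reaction in keep else None,
            atp_maintenance_reaction=(
                self.atp_maintenance_reaction
                if self.atp_maintenance_reaction in keep else None
            ),
            provenance=provenance,
        )


def inactivate_for_genes(model: MetabolicModel, inactive_genes: Iterable[str]) -> set[str]:
    """Reaction ids to shut when ``inactive_genes`` are knocked out.

    A reaction is shut exactly when its (non-empty) GPR evaluates False.
    Gene ids absent from the model are ignored. The model is not mutated.
    """
    inactive = set(inactive_genes)
    shut: set[str] = set()
    for rxn in model.reactions:
        if rxn.gpr.is_empty():
            continue
        if not evaluate_gpr(rxn.gpr, inactive):
            shut.add(rxn.reaction_id)
    return shut


# ---------------------------------------------------------------------------
# IO: compact JSON dialect
# ---------------------------------------------------------------------------

def _detect_exchange(stoich: Mapping[str, float], annotated: bool | None) -> bool:
    if annotated is not None:
        return bool(annotated)
    return len(stoich) == 1


def _model_from_dict(data: dict) -> MetabolicModel:
    try:
        raw_mets = data["metabolites"]
        raw_rxns = data["reactions"]
    except KeyError as exc:
        raise ModelValidationError(f"model JSON missing required key {exc}") from None
    metabolites = []
    for met in raw_mets:
        if isinstance(met, str):
            metabolites.append(Metabolite(metabolite_id=met))
        else:
            metabolites.append(
                Metabolite(metabolite_id=met["id"], compartment=met.get("compartment", "c"))
            )
    reactions = []
    genes: set[str] = set()
    for raw in raw_rxns:
        gpr = parse_gpr(raw.get("gpr", ""))
        genes |= gpr.genes()
        stoich = {k: float(v) for k, v in raw["stoich"].items()}
        reactions.append(
            Reaction(
                reaction_id=raw["id"],
                stoichiometry=stoich,
                lower_bound=float(raw.get("lb", 0.0)),
                upper_bound=float(raw.get("ub", 1000.0)),
                gpr=gpr,
                is_exchange=_detect_exchange(stoich, raw.get("is_exchange")),
            )
        )
    declared_genes = data.get("genes")
    gene_list = list(declared_genes) if declared_genes else sorted(genes)
    return MetabolicModel(
        model_id=data.get("model_id", "model"),
        metabolites=metabolites,
        reactions=reactions,
        genes=gene_list,
        biomass_reaction=data.get("biomass"),
        atp_maintenance_reaction=data.get("atp_maintenance"),
        provenance=data.get("provenance"),
    )


def _model_to_dict(model: MetabolicModel) -> dict:
    data: dict = {
        "model_id": model.model_id,
        "metabolites": [
            {"id": m.metabolite_id, "compartment": m.compartment} for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.reaction_id,
                "stoich": dict(r.stoichiometry),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": render_gpr(r.gpr),
                "is_exchange": r.is_exchange,
            }
            for r in model.reactions
        ],
        "genes": list(model.genes),
        "biomass": model.biomass_reaction,
        "atp_maintenance": model.atp_maintenance_reaction,
    }
    if model.provenance is not None:
        data["provenance"] = model.provenance
    return data


# ---------------------------------------------------------------------------
# IO: SBML Level 3 FBC
# ---------------------------------------------------------------------------

def _gpr_from_fbc_association(assoc) -> GprExpression:
    import libsbml

    if assoc is None:
        return EMPTY_GPR
    if isinstance(assoc, libsbml.GeneProductRef):
        return GprExpression(kind="GENE", gene_id=assoc.getGeneProduct())
    if isinstance(assoc, libsbml.FbcAnd):
        children = [
            _gpr_from_fbc_association(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        ]
        return _combine("AND", children)
    if isinstance(assoc, libsbml.FbcOr):
        children = [
            _gpr_from_fbc_association(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        ]
        return _combine("OR", children)
    raise ModelValidationError(f"unsupported FBC association node {type(assoc).__name__}")


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelValidationError(f"SBML parse error in {path}: {err.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelValidationError(f"{path} contains no SBML model")
    fbc = sbml_model.getPlugin("fbc")

    metabolites = [
        Metabolite(
            metabolite_id=sbml_model.getSpecies(i).getId(),
            compartment=sbml_model.getSpecies(i).getCompartment() or "c",
        )
        for i in range(sbml_model.getNumSpecies())
    ]
    genes: list[str] = []
    if fbc is not None:
        genes = [fbc.getGeneProduct(i).getId() for i in range(fbc.getNumGeneProducts())]

    def bound_value(param_id: str, default: float) -> float:
        param = sbml_model.getParameter(param_id) if param_id else None
        return param.getValue() if param is not None else default

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        rplug = rxn.getPlugin("fbc")
        lb, ub = -math.inf, math.inf
        gpr = EMPTY_GPR
        if rplug is not None:
            lb = bound_value(rplug.getLowerFluxBound(), -1000.0)
            ub = bound_value(rplug.getUpperFluxBound(), 1000.0)
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                gpr = _gpr_from_fbc_association(gpa.getAssociation())
        reactions.append(
            Reaction(
                reaction_id=rxn.getId(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                is_exchange=len(stoich) == 1,
            )
        )

    biomass = None
    atp_maintenance = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            biomass = active.getFluxObjective(0).getReaction()
    rxn_ids = {r.reaction_id for r in reactions}
    for candidate in ("ATPM", "atpm", "ATP_maintenance"):
        if candidate in rxn_ids:
            atp_maintenance = candidate
            break
    return MetabolicModel(
        model_id=sbml_model.getId() or path.stem,
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        biomass_reaction=biomass if biomass in rxn_ids else None,
        atp_maintenance_reaction=atp_maintenance,
    )


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(re.sub(r"[^A-Za-z0-9_]", "_", model.model_id) or "model")
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites}) or ["c"]
    for comp_id in compartments:
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(met.metabolite_id)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    for gene in model.genes:
        gp = mplug.createGeneProduct()
        gp.setId(gene)
        gp.setLabel(gene)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            param = sbml_model.createParameter()
            param.setId(pid)
            param.setValue(value)
            param.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        sr = sbml_model.createReaction()
        sr.setId(rxn.reaction_id)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for met_id, coeff in rxn.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if not rxn.gpr.is_empty():
            gpa = rplug.createGeneProductAssociation()
            gpa.setAssociation(render_gpr(rxn.gpr))

    if model.biomass_reaction is not None:
        objective = mplug.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        fo = objective.createFluxObjective()
        fo.setReaction(model.biomass_reaction)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


# ---------------------------------------------------------------------------
# Public IO entry points
# ---------------------------------------------------------------------------

def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a metabolic model from disk.

    ``format`` is ``"json"`` or ``"sbml"``; when None it is inferred from the
    file suffix (.json vs .xml/.sbml).
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "sbml")
    if fmt == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelValidationError(f"malformed model JSON {path}: {exc}") from exc
        return _model_from_dict(data)
    if fmt == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write a metabolic model to disk in the JSON dialect or SBML-FBC."""
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "sbml")
    if fmt == "json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1, sort_keys=False) + "\n")
    elif fmt == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
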