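"""Metabolic-model data structures, JSON/SBML-FBC I/O and GPR rule handling.

The canonical internal format is a small JSON dialect::

    {
      "metabolites": ["A", "B", ...],
      "reactions": [
        {"id": "R1", "stoich": {"A": -1, "B": 1}, "lb": 0, "ub": 1000,
         "gpr": "g1 and g2", "exchange": false},
        ...
      ],
      "objective": "biomass"
    }

SBML Level 3 + FBC files are imported through python-libsbml, mapping
``fbc:geneProductAssociation`` trees onto :class:`GPRExpression`.

Default bounds when a reaction omits them follow the COBRA community
convention: irreversible ``[0, 1000]``, reversible ``[-1000, 1000]``
mmol h^-1 gDW^-1.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

DEFAULT_UPPER = 1000.0
DEFAULT_LOWER = -1000.0


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed; names the offending element."""


class ModelValidationError(ValueError):
    """Raised when a parsed model violates a structural invariant."""


class GPRParseError(ValueError):
    """Raised for malformed gene-protein-reaction rule strings."""


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPRExpression:
    """Boolean tree over gene identifiers.

    ``op`` is one of ``"gene"`` (leaf; ``gene`` holds the id), ``"and"`` or
    ``"or"`` (internal node; ``children`` holds >= 2 subtrees). AND encodes an
    enzyme complex (all subunits required), OR encodes isozymes.
    """

    op: str
    gene: str | None = None
    children: tuple["GPRExpression", ...] = ()

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene:
                raise GPRParseError("GPR leaf must carry a nonempty gene id")
        elif self.op in ("and", "or"):
            if len(self.children) < 2:
                raise GPRParseError(f"GPR {self.op!r} node needs >= 2 children")
        else:
            raise GPRParseError(f"unknown GPR node type {self.op!r}")

    def genes(self) -> set[str]:
        """All gene ids appearing in the tree."""
        if self.op == "gene":
            return {self.gene}  # type: ignore[arg-type]
        return set().union(*(c.genes() for c in self.children))

    def evaluate(self, active: dict[str, bool]) -> bool:
        """Boolean evaluation: is the reaction enabled under this on/off map?

        Genes absent from ``active`` count as off.
        """
        if self.op == "gene":
            return bool(active.get(self.gene, False))
        vals = (c.evaluate(active) for c in self.children)
        return all(vals) if self.op == "and" else any(vals)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            # parenthesize OR children under AND to preserve precedence
            if self.op == "and" and c.op == "or":
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(rule: str) -> GPRExpression:
    """Parse a GPR rule string into a :class:`GPRExpression`.

    Accepts gene ids, parentheses and the keywords ``and`` / ``or``
    (case-insensitive; ``&&`` / ``||`` / ``&`` / ``|`` also tolerated).
    Precedence: AND binds tighter than OR; parentheses override.
    """
    if rule is None or not rule.strip():
        raise GPRParseError("empty GPR rule")
    tokens = _GPR_TOKEN.findall(rule)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def is_kw(tok: str | None, kw: str) -> bool:
        if tok is None:
            return False
        low = tok.lower()
        if kw == "and":
            return low in ("and", "&", "&&")
        return low in ("or", "|", "||")

    def parse_atom() -> GPRExpression:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of rule: {rule!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in {rule!r}")
            take()
            return node
        if tok == ")" or is_kw(tok, "and") or is_kw(tok, "or"):
            raise GPRParseError(f"unexpected token {tok!r} in {rule!r}")
        take()
        return GPRExpression("gene", gene=tok)

    def parse_and() -> GPRExpression:
        terms = [parse_atom()]
        while is_kw(peek(), "and"):
            take()
            terms.append(parse_atom())
        if len(terms) == 1:
            return terms[0]
        return GPRExpression("and", children=tuple(terms))

    def parse_or() -> GPRExpression:
        terms = [parse_and()]
        while is_kw(peek(), "or"):
            take()
            terms.append(parse_and())
        if len(terms) == 1:
            return terms[0]
        return GPRExpression("or", children=tuple(terms))

    expr = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens after position {pos} in {rule!r}")
    return expr


# ---------------------------------------------------------------------------
# Metabolic model
# ---------------------------------------------------------------------------

@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: GPRExpression | None = None
    exchange: bool = False

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class MetabolicModel:
    """Stoichiometric network with bounds, GPR rules and a biomass objective.

    Rates are in mmol h^-1 gDW^-1. ``exchange``-flagged reactions (and any
    reaction without a GPR) are exempt from expression constraints.
    """

    metabolite_ids: list[str]
    reactions: list[Reaction]
    objective_reaction: str

    _rxn_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- accessors ---------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rid]]
        except KeyError:
            raise KeyError(f"unknown reaction {rid!r}") from None

    def __iter__(self) -> Iterator[Reaction]:
        return iter(self.reactions)

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S, metabolites x reactions."""
        met_index = {m: i for i, m in enumerate(self.metabolite_ids)}
        S = np.zeros((len(self.metabolite_ids), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoich.items():
                S[met_index[met], j] = coef
        return S

    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions:
            if rxn.gpr is not None:
                out |= rxn.gpr.genes()
        return out

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reactions=[
                Reaction(r.id, dict(r.stoich), r.lower_bound, r.upper_bound,
                         r.gpr, r.exchange)
                for r in self.reactions
            ],
            objective_reaction=self.objective_reaction,
        )


@dataclass
class FluxDistribution:
    """One steady-state flux vector (mmol h^-1 gDW^-1) and its biomass rate."""

    fluxes: "pd.Series"
    objective_value: float
    sample_id: str = ""

    def __getitem__(self, rid: str) -> float:
        return float(self.fluxes[rid])


def validate_model(model: MetabolicModel) -> list[str]:
    """Return a list of invariant-violation descriptions (empty iff valid)."""
    violations: list[str] = []
    mets = set(model.metabolite_ids)
    if len(mets) != len(model.metabolite_ids):
        violations.append("duplicate metabolite ids")
    rids = model.reaction_ids
    if len(set(rids)) != len(rids):
        violations.append("duplicate reaction ids")
    if model.objective_reaction not in set(rids):
        violations.append(
            f"objective reaction {model.objective_reaction!r} not in reaction_ids")
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            violations.append(
                f"reaction {rxn.id!r}: lower_bound {rxn.lower_bound} > "
                f"upper_bound {rxn.upper_bound}")
        for met, coef in rxn.stoich.items():
            if met not in mets:
                violations.append(
                    f"reaction {rxn.id!r}: stoichiometry references "
                    f"undeclared metabolite {met!r}")
            if coef == 0:
                violations.append(
                    f"reaction {rxn.id!r}: zero stoichiometric coefficient "
                    f"for {met!r}")
    return violations


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_from_dict(data: dict) -> MetabolicModel:
    try:
        metabolites = list(data["metabolites"])
        raw_reactions = data["reactions"]
        objective = data["objective"]
    except KeyError as exc:
        raise ModelParseError(f"missing top-level key {exc.args[0]!r}") from None
    reactions = []
    for raw in raw_reactions:
        if "id" not in raw:
            raise ModelParseError("reaction without an 'id' field")
        rid = raw["id"]
        if "stoich" not in raw:
            raise ModelParseError(f"reaction {rid!r} lacks 'stoich'")
        stoich = {m: float(c) for m, c in raw["stoich"].items()}
        lb = raw.get("lb")
        ub = raw.get("ub")
        if ub is None:
            ub = DEFAULT_UPPER
        if lb is None:
            # reversible flag, if present, selects the default lower bound
            lb = DEFAULT_LOWER if raw.get("reversible", False) else 0.0
        gpr_str = raw.get("gpr")
        gpr = parse_gpr(gpr_str) if gpr_str else None
        reactions.append(Reaction(rid, stoich, float(lb), float(ub), gpr,
                                  bool(raw.get("exchange", False))))
    model = MetabolicModel(metabolites, reactions, objective)
    violations = validate_model(model)
    if violations:
        raise ModelValidationError("; ".join(violations))
    return model


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "metabolites": list(model.metabolite_ids),
        "reactions": [
            {
                "id": r.id,
                "stoich": dict(r.stoich),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": r.gpr.to_string() if r.gpr is not None else None,
                "exchange": r.exchange,
            }
            for r in model.reactions
        ],
        "objective": model.objective_reaction,
    }


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC import
# ---------------------------------------------------------------------------

def _sbml_association_to_gpr(assoc) -> GPRExpression:
    import libsbml

    if assoc is None:
        raise ModelParseError("empty geneProductAssociation")
    if isinstance(assoc, libsbml.GeneProductRef):
        gid = assoc.getGeneProduct()
        model = assoc.getSBMLDocument().getModel()
        fbc = model.getPlugin("fbc")
        gp = fbc.getGeneProduct(gid)
        label = gp.getLabel() if gp is not None and gp.getLabel() else gid
        return GPRExpression("gene", gene=_strip_sbml_prefix(label, "G_"))
    if isinstance(assoc, (libsbml.FbcAnd, libsbml.FbcOr)):
        op = "and" if isinstance(assoc, libsbml.FbcAnd) else "or"
        children = tuple(
            _sbml_association_to_gpr(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        )
        if len(children) == 1:
            return children[0]
        return GPRExpression(op, children=children)
    raise ModelParseError(f"unsupported gene association node {type(assoc)}")


def _strip_sbml_prefix(sid: str, prefix: str) -> str:
    # SBML convention ("R_", "M_", "G_" sigils) used by most writers
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _load_sbml(path: str) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"SBML parse error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError("SBML document has no <model> element")

    metabolites = [_strip_sbml_prefix(sbml_model.getSpecies(i).getId(), "M_")
                   for i in range(sbml_model.getNumSpecies())
                   if not sbml_model.getSpecies(i).getBoundaryCondition()]
    met_set = set(metabolites)

    def param_value(pid: str) -> float:
        p = sbml_model.getParameter(pid)
        if p is None:
            raise ModelParseError(f"bound parameter {pid!r} not found")
        return p.getValue()

    objective = None
    fbc = sbml_model.getPlugin("fbc")
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        if active.getNumFluxObjectives() > 0:
            objective = _strip_sbml_prefix(
                active.getFluxObjective(0).getReaction(), "R_")

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            sid = _strip_sbml_prefix(ref.getSpecies(), "M_")
            if sid in met_set:
                stoich[sid] = stoich.get(sid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            sid = _strip_sbml_prefix(ref.getSpecies(), "M_")
            if sid in met_set:
                stoich[sid] = stoich.get(sid, 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0}

        rfbc = sr.getPlugin("fbc")
        if rfbc is not None and rfbc.isSetLowerFluxBound():
            lb = param_value(rfbc.getLowerFluxBound())
            ub = param_value(rfbc.getUpperFluxBound())
        else:
            ub = DEFAULT_UPPER
            lb = DEFAULT_LOWER if sr.getReversible() else 0.0

        gpr = None
        if rfbc is not None and rfbc.isSetGeneProductAssociation():
            gpa = rfbc.getGeneProductAssociation()
            gpr = _sbml_association_to_gpr(gpa.getAssociation())

        rid = _strip_sbml_prefix(sr.getId(), "R_")
        # exchange: reaction touching no internal metabolite on one side
        is_exchange = len(stoich) <= 1 or rid.startswith("EX_")
        reactions.append(Reaction(rid, stoich, lb, ub, gpr, is_exchange))

    if objective is None:
        raise ModelParseError("SBML-FBC model declares no flux objective")
    model = MetabolicModel(metabolites, reactions, objective)
    violations = validate_model(model)
    if violations:
        raise ModelValidationError("; ".join(violations))
    return model


# ---------------------------------------------------------------------------
# Public load/save
# ---------------------------------------------------------------------------

def load_model(path, format: str = "json") -> MetabolicModel:
    """Load and validate a metabolic model from ``path``.

    ``format`` is ``"json"`` (the canonical dialect) or ``"sbml"``
    (Level 3 + FBC).
    """
    if format == "json":
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelParseError(f"invalid JSON in {path}: {exc}") from None
        return model_from_dict(data)
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def save_model(model: MetabolicModel, path) -> None:
    """Serialize a model to the JSON dialect."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")
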