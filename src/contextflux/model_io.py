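"""Genome-scale metabolic model container, GPR rules, and SBML/JSON I/O.

The central data structure is :class:`MetabolicModel`: metabolites, reactions
with flux bounds (mmol/gDW/h) and stoichiometry, gene–protein–reaction (GPR)
boolean rules, and an optional objective reaction.  SBML Level 3 with the FBC
extension is read and written through COBRApy/libsbml; a compact JSON dialect
is provided for fixtures and round-trip-stable storage.

GPR rules are boolean trees over gene identifiers with ``and`` binding tighter
than ``or`` (the COBRA community convention).  Besides boolean evaluation the
trees support numeric aggregation (AND -> min, OR -> max), which is how
expression is mapped onto reactions downstream.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GPRExpression",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelFormatError",
    "ModelValidationError",
    "GPRParseError",
    "parse_gpr",
    "read_model",
    "write_model",
    "stoichiometric_matrix",
    "to_cobra",
    "from_cobra",
]

DEFAULT_BOUND = 1000.0


class ModelFormatError(ValueError):
    """Unparseable model file; the message names the first offending element."""


class ModelValidationError(ValueError):
    """Structurally parsed model that violates an invariant."""


class GPRParseError(ValueError):
    """Malformed GPR rule text.

    Attributes
    ----------
    offset : int
        Character offset of the first offending token.
    """

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPRExpression:
    """Boolean tree over gene ids: internal nodes 'and'/'or', leaves 'gene'."""

    op: str  # 'gene' | 'and' | 'or'
    gene: str | None = None
    children: tuple["GPRExpression", ...] = ()

    def __post_init__(self):
        if self.op == "gene":
            if not self.gene or self.children:
                raise ValueError("gene leaf must carry a gene id and no children")
        elif self.op in ("and", "or"):
            if len(self.children) < 2 or self.gene is not None:
                raise ValueError(f"{self.op!r} node needs >= 2 children")
        else:
            raise ValueError(f"unknown GPR node type {self.op!r}")

    def genes(self) -> frozenset[str]:
        if self.op == "gene":
            return frozenset([self.gene])
        return frozenset().union(*(c.genes() for c in self.children))

    def evaluate(self, active) -> bool:
        """Boolean evaluation; ``active`` maps gene id -> bool."""
        if self.op == "gene":
            return bool(active[self.gene])
        vals = (c.evaluate(active) for c in self.children)
        return all(vals) if self.op == "and" else any(vals)

    def aggregate(self, values, and_op=min, or_op=max) -> float:
        """Numeric evaluation; ``values`` maps gene id -> score."""
        if self.op == "gene":
            return values[self.gene]
        vals = [c.aggregate(values, and_op, or_op) for c in self.children]
        return and_op(vals) if self.op == "and" else or_op(vals)

    def to_string(self) -> str:
        return self._fmt(top=True)

    def _fmt(self, top: bool = False) -> str:
        if self.op == "gene":
            return self.gene
        body = f" {self.op} ".join(c._fmt() for c in self.children)
        return body if top else f"({body})"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_GPR_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize_gpr(rule: str):
    tokens = []
    pos = 0
    while pos < len(rule):
        m = _GPR_TOKEN.match(rule, pos)
        if m is None:
            break
        tok = m.group(1)
        tokens.append((tok, m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(rule: str) -> GPRExpression | None:
    """Parse GPR text into a boolean tree; empty/whitespace text -> ``None``.

    Grammar (case-insensitive keywords)::

        expr   := term ('or' term)*
        term   := factor ('and' factor)*
        factor := '(' expr ')' | GENE

    ``and`` binds tighter than ``or`` when parentheses are absent.  Raises
    :class:`GPRParseError` with a character offset on malformed input.
    """
    tokens = _tokenize_gpr(rule)
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, len(rule))

    def expr():
        nonlocal pos
        terms = [term()]
        while peek()[0] is not None and peek()[0].lower() == "or":
            pos += 1
            terms.append(term())
        if len(terms) == 1:
            return terms[0]
        return GPRExpression("or", children=tuple(terms))

    def term():
        nonlocal pos
        factors = [factor()]
        while peek()[0] is not None and peek()[0].lower() == "and":
            pos += 1
            factors.append(factor())
        if len(factors) == 1:
            return factors[0]
        return GPRExpression("and", children=tuple(factors))

    def factor():
        nonlocal pos
        tok, off = peek()
        if tok is None:
            raise GPRParseError("dangling operator: expected gene or '('", off)
        if tok == "(":
            pos += 1
            node = expr()
            tok2, off2 = peek()
            if tok2 != ")":
                raise GPRParseError("unbalanced parentheses: expected ')'", off2)
            pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r}", off)
        pos += 1
        return GPRExpression("gene", gene=tok)

    tree = expr()
    tok, off = peek()
    if tok is not None:
        raise GPRParseError(f"unexpected trailing token {tok!r}", off)
    return tree


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    id: str
    name: str = ""
    subsystem: str = ""
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    stoichiometry: dict[str, float] = field(default_factory=dict)
    gpr: GPRExpression | None = None

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def gene_ids(self) -> frozenset[str]:
        return self.gpr.genes() if self.gpr is not None else frozenset()

    def is_exchange(self) -> bool:
        """Boundary reaction touching exactly one metabolite."""
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return Reaction(
            self.id, self.name, self.subsystem, self.lower_bound,
            self.upper_bound, dict(self.stoichiometry), self.gpr,
        )


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    objective_id: str | None = None
    id: str = "model"

    # -- lookups -----------------------------------------------------------
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in model {self.id!r}")

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange()]

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        """Check all container invariants; raise ModelValidationError."""
        met_ids = self.metabolite_ids()
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = self.reaction_ids()
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        met_set = set(met_ids)
        gene_set = set(self.genes)
        bad_bounds = [r.id for r in self.reactions if r.lower_bound > r.upper_bound]
        if bad_bounds:
            raise ModelValidationError(
                f"lower_bound > upper_bound for reactions: {bad_bounds}")
        for r in self.reactions:
            missing = set(r.stoichiometry) - met_set
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references undeclared metabolites {sorted(missing)}")
            undeclared = r.gene_ids() - gene_set
            if undeclared:
                raise ModelValidationError(
                    f"reaction {r.id!r} GPR uses undeclared genes {sorted(undeclared)}")
        if self.objective_id is not None and self.objective_id not in set(rxn_ids):
            raise ModelValidationError(
                f"objective {self.objective_id!r} is not a reaction id")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            objective_id=self.objective_id,
            id=self.id,
        )

    def subset(self, reaction_ids, model_id: str | None = None) -> "MetabolicModel":
        """Restrict to the given reactions, dropping orphan metabolites/genes."""
        keep = set(reaction_ids)
        unknown = keep - set(self.reaction_ids())
        if unknown:
            raise KeyError(f"unknown reaction ids: {sorted(unknown)}")
        reactions = [r.copy() for r in self.reactions if r.id in keep]
        used_mets = set().union(*(set(r.stoichiometry) for r in reactions)) if reactions else set()
        used_genes = set().union(*(r.gene_ids() for r in reactions)) if reactions else set()
        return MetabolicModel(
            metabolites=[m for m in self.metabolites if m.id in used_mets],
            reactions=reactions,
            genes=[g for g in self.genes if g in used_genes],
            objective_id=self.objective_id if self.objective_id in keep else None,
            id=model_id or self.id,
        )


def stoichiometric_matrix(model: MetabolicModel) -> pd.DataFrame:
    """Dense stoichiometric matrix S (metabolites x reactions).

    Entry (m, r) is the coefficient of metabolite ``m`` in reaction ``r``
    (negative = consumed), zero where the metabolite does not participate.
    """
    model.validate()
    met_ids = model.metabolite_ids()
    rxn_ids = model.reaction_ids()
    S = np.zeros((len(met_ids), len(rxn_ids)))
    met_index = {m: i for i, m in enumerate(met_ids)}
    for j, r in enumerate(model.reactions):
        for met, coef in r.stoichiometry.items():
            S[met_index[met], j] = coef
    return pd.DataFrame(S, index=met_ids, columns=rxn_ids)


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "subsystem": r.subsystem,
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "stoich": dict(r.stoichiometry),
                "gpr": r.gpr.to_string() if r.gpr is not None else "",
            }
            for r in model.reactions
        ],
        "genes": list(model.genes),
        "objective": model.objective_id or "",
    }


def _model_from_dict(doc: dict) -> MetabolicModel:
    try:
        mets = [
            Metabolite(m["id"], m.get("name", ""), m.get("compartment", ""))
            for m in doc["metabolites"]
        ]
        rxns = []
        for r in doc["reactions"]:
            try:
                gpr = parse_gpr(r.get("gpr", ""))
            except GPRParseError as e:
                raise ModelFormatError(
                    f"reaction {r.get('id', '?')!r}: bad GPR: {e}") from e
            rxns.append(Reaction(
                id=r["id"],
                name=r.get("name", ""),
                subsystem=r.get("subsystem", ""),
                lower_bound=float(r["lb"]),
                upper_bound=float(r["ub"]),
                stoichiometry={k: float(v) for k, v in r["stoich"].items()},
                gpr=gpr,
            ))
    except (KeyError, TypeError) as e:
        raise ModelFormatError(f"malformed model JSON near {e}") from e
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=list(doc.get("genes", [])),
        objective_id=doc.get("objective") or None,
        id=doc.get("id", "model"),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# COBRApy bridge (SBML L3 + FBC)
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    """Convert to a cobra.Model (used for SBML I/O and LP solving)."""
    import cobra

    model.validate()
    cm = cobra.Model(model.id)
    cmets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        cmets[m.id] = cmet
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name,
                            lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.subsystem = r.subsystem
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r in model.reactions:
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({cmets[k]: v for k, v in r.stoichiometry.items()})
        if r.gpr is not None:
            cr.gene_reaction_rule = r.gpr.to_string()
    if model.objective_id is not None:
        cm.objective = model.objective_id
    return cm


def from_cobra(cm) -> MetabolicModel:
    """Convert a cobra.Model into the package container (ids verbatim)."""
    mets = [Metabolite(m.id, m.name or "", m.compartment or "") for m in cm.metabolites]
    rxns = []
    objective_id = None
    for cr in cm.reactions:
        rule = cr.gene_reaction_rule or ""
        try:
            gpr = parse_gpr(rule)
        except GPRParseError as e:
            raise ModelFormatError(f"reaction {cr.id!r}: bad GPR: {e}") from e
        rxns.append(Reaction(
            id=cr.id,
            name=cr.name or "",
            subsystem=cr.subsystem or "",
            lower_bound=float(cr.lower_bound),
            upper_bound=float(cr.upper_bound),
            stoichiometry={m.id: float(v) for m, v in cr.metabolites.items()},
            gpr=gpr,
        ))
        if cr.objective_coefficient:
            objective_id = cr.id
    genes = sorted(set().union(*(r.gene_ids() for r in rxns)) if rxns else set())
    model = MetabolicModel(metabolites=mets, reactions=rxns, genes=genes,
                           objective_id=objective_id, id=cm.id or "model")
    model.validate()
    return model


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

def _infer_format(path: str) -> str:
    p = str(path).lower()
    if p.endswith(".json"):
        return "json"
    return "sbml"


def read_model(path, format: str | None = None) -> MetabolicModel:
    """Read a metabolic model from SBML (L3/FBC) or the JSON dialect.

    Counts of metabolites/reactions/genes equal those declared in the file;
    identifiers are preserved verbatim.  Raises :class:`ModelFormatError` on
    unparseable input and :class:`ModelValidationError` on invariant
    violations (e.g. a reaction with lower bound above its upper bound).
    """
    fmt = format or _infer_format(path)
    if fmt == "json":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as e:
                raise ModelFormatError(f"invalid JSON in {path}: {e}") from e
        return _model_from_dict(doc)
    if fmt == "sbml":
        from cobra.io import read_sbml_model
        try:
            cm = read_sbml_model(str(path))
        except Exception as e:  # libsbml raises a zoo of error types
            raise ModelFormatError(f"cannot parse SBML {path}: {e}") from e
        return from_cobra(cm)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path, format: str | None = None) -> None:
    """Write to SBML (L3V1 + FBC v2, via libsbml) or the JSON dialect."""
    fmt = format or _infer_format(path)
    model.validate()
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=False)
            fh.write("\n")
        return
    if fmt == "sbml":
        from cobra.io import write_sbml_model
        write_sbml_model(to_cobra(model), str(path))
        return
    raise ValueError(f"unknown model format {fmt!r}")
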