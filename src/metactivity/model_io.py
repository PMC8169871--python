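"""Metabolic network models: containers, GPR rules, and SBML/JSON input-output.

A genome-scale metabolic model (GEM) is a stoichiometry-based, mass-balanced
reconstruction of the biochemical reactions of a cell.  Each reaction carries
flux bounds and, optionally, a gene-protein-reaction (GPR) rule: a boolean
expression over gene identifiers in which ``or`` encodes isoenzymes (any one
gene suffices) and ``and`` encodes enzyme complexes (all genes required).
Subcellular localization is represented by compartment tags on metabolites and
by separate reactions per compartment.

Two on-disk formats are supported:

* SBML Level 3 with the ``fbc`` package (flux bounds and gene-product
  associations), read and written through cobrapy/libsbml;
* a plain JSON dialect documented in ``docs/json_model_schema.md`` with
  top-level keys ``metabolites`` / ``reactions`` / ``genes``.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping

logger = logging.getLogger(__name__)

DEFAULT_LOWER_BOUND = -1000.0
DEFAULT_UPPER_BOUND = 1000.0


class GprParseError(ValueError):
    """Raised for malformed GPR rule text; carries the offending position."""


class ModelLoadError(ValueError):
    """Raised when a model file is malformed or internally inconsistent."""


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GprExpression:
    """Boolean tree over gene identifiers.

    ``op`` is one of ``"gene"`` (leaf), ``"and"`` or ``"or"``.  Internal nodes
    hold two or more children; same-operator nesting is flattened at parse
    time so the representation is canonical up to child order.
    """

    op: str
    gene: str | None = None
    children: tuple["GprExpression", ...] = ()

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene:
                raise ValueError("gene leaf requires a nonempty identifier")
        elif self.op in ("and", "or"):
            if len(self.children) < 2:
                raise ValueError(f"'{self.op}' node requires >=2 children")
        else:
            raise ValueError(f"unknown GPR operator {self.op!r}")

    def genes(self) -> frozenset[str]:
        """All gene identifiers appearing as leaves."""
        if self.op == "gene":
            return frozenset([self.gene])  # type: ignore[list-item]
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return frozenset(out)

    def evaluate(
        self,
        values: Mapping[str, float],
        or_op: Callable[[Iterable[float]], float] = max,
        and_op: Callable[[Iterable[float]], float] = min,
    ) -> float:
        """Evaluate the tree over per-gene values.

        With the defaults this is the isoenzyme/complex mapping used to put
        expression onto reactions: OR -> max over genes, AND -> min.
        Raises ``KeyError`` for a gene absent from ``values``.
        """
        if self.op == "gene":
            return values[self.gene]  # type: ignore[index]
        vals = [c.evaluate(values, or_op, and_op) for c in self.children]
        return or_op(vals) if self.op == "or" else and_op(vals)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        sep = f" {self.op} "
        parts = []
        for child in self.children:
            text = child.to_string()
            # parenthesize an OR nested under AND to preserve precedence
            if self.op == "and" and child.op == "or":
                text = f"({text})"
            parts.append(text)
        return sep.join(parts)

    def canonical(self) -> "GprExpression":
        """Order-normalized form: children sorted by rendered text."""
        if self.op == "gene":
            return self
        kids = tuple(sorted((c.canonical() for c in self.children),
                            key=lambda c: c.to_string()))
        return GprExpression(self.op, children=kids)


_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise GprParseError(
                    f"unexpected character {text[pos]!r} at position {pos}")
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(text: str | None) -> GprExpression | None:
    """Parse an infix GPR rule string into a :class:`GprExpression`.

    Grammar: ``expr := term ('or' term)*``, ``term := factor ('and' factor)*``,
    ``factor := GENE | '(' expr ')'``.  Operators are case-insensitive and
    ``and`` binds tighter than ``or``.  Empty or whitespace-only text returns
    ``None`` (no gene association).
    """
    if text is None or not text.strip():
        return None
    tokens = _tokenize(text)
    idx = 0

    def peek() -> str | None:
        return tokens[idx][0] if idx < len(tokens) else None

    def err(msg: str) -> GprParseError:
        pos = tokens[idx][1] if idx < len(tokens) else len(text)
        return GprParseError(f"{msg} at position {pos} in {text!r}")

    def parse_expr() -> GprExpression:
        nonlocal idx
        node = parse_term()
        parts = [node]
        while peek() is not None and peek().lower() == "or":
            idx += 1
            parts.append(parse_term())
        if len(parts) == 1:
            return parts[0]
        return GprExpression("or", children=_flatten("or", parts))

    def parse_term() -> GprExpression:
        nonlocal idx
        parts = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            idx += 1
            parts.append(parse_factor())
        if len(parts) == 1:
            return parts[0]
        return GprExpression("and", children=_flatten("and", parts))

    def parse_factor() -> GprExpression:
        nonlocal idx
        tok = peek()
        if tok is None:
            raise err("dangling operator or empty factor")
        if tok == "(":
            idx += 1
            node = parse_expr()
            if peek() != ")":
                raise err("unbalanced parentheses: expected ')'")
            idx += 1
            return node
        if tok == ")":
            raise err("unbalanced parentheses: unexpected ')'")
        if tok.lower() in ("and", "or"):
            raise err(f"dangling operator {tok!r}")
        idx += 1
        return GprExpression("gene", gene=tok)

    tree = parse_expr()
    if idx != len(tokens):
        raise err(f"unexpected trailing token {tokens[idx][0]!r}")
    return tree


def _flatten(op: str, parts: list[GprExpression]) -> tuple[GprExpression, ...]:
    out: list[GprExpression] = []
    for p in parts:
        if p.op == op:
            out.extend(p.children)
        else:
            out.append(p)
    return tuple(out)


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass(frozen=True)
class Reaction:
    """One reaction: stoichiometry (negative = consumed), bounds, GPR."""

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = DEFAULT_LOWER_BOUND
    upper_bound: float = DEFAULT_UPPER_BOUND
    gpr: GprExpression | None = None
    subsystem: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        """Boundary reaction: at most one metabolite in its stoichiometry."""
        return len(self.stoichiometry) <= 1


@dataclass(frozen=True)
class MetabolicModel:
    """In-memory metabolic network: metabolites, reactions, genes.

    Invariants (checked by :meth:`validate`): ids unique per namespace;
    stoichiometries reference declared metabolites only; GPR leaves reference
    declared genes only.
    """

    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    genes: tuple[str, ...]
    name: str = ""
    version: str = ""
    annotations: Mapping[str, object] = field(default_factory=dict)

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        for label, ids in (("metabolite", met_ids), ("reaction", rxn_ids),
                           ("gene", list(self.genes))):
            dupes = {i for i in ids if ids.count(i) > 1}
            if dupes:
                raise ModelLoadError(f"duplicate {label} ids: {sorted(dupes)}")
        met_set, gene_set = set(met_ids), set(self.genes)
        for rxn in self.reactions:
            unknown = set(rxn.stoichiometry) - met_set
            if unknown:
                raise ModelLoadError(
                    f"reaction {rxn.id} references undeclared metabolites "
                    f"{sorted(unknown)}")
            if not rxn.stoichiometry and not rxn.is_exchange:
                raise ModelLoadError(f"reaction {rxn.id} has no stoichiometry")
            if rxn.gpr is not None:
                missing = rxn.gpr.genes() - gene_set
                if missing:
                    raise ModelLoadError(
                        f"reaction {rxn.id} GPR references undeclared genes "
                        f"{sorted(missing)}")

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    @property
    def metabolite_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.metabolites)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)


# ---------------------------------------------------------------------------
# Reaction selection and bound editing
# ---------------------------------------------------------------------------

def reactions_for_genes(model: MetabolicModel,
                        genes: Iterable[str]) -> tuple[str, ...]:
    """Reactions whose GPR contains at least one of ``genes`` as a leaf.

    This is the "reactions controlled by a gene list" query used to restrict
    a network comparison to, e.g., cholesterol-pathway enzymes.  Unknown gene
    ids match nothing (logged).  Returns reaction ids sorted alphabetically.
    """
    gene_list = list(genes)
    if not gene_list:
        raise ValueError("gene list must be nonempty")
    query = set(gene_list)
    unknown = query - set(model.genes)
    if unknown:
        logger.info("genes absent from model ignored: %s", sorted(unknown))
    hits = {r.id for r in model.reactions
            if r.gpr is not None and r.gpr.genes() & query}
    return tuple(sorted(hits))


def cholesterol_gene_list(path: str | Path | None = None,
                          categories: Iterable[str] | None = None,
                          ) -> tuple[str, ...]:
    """The a priori cholesterol-homeostasis gene panel (editable config).

    Reads the TSV shipped at ``data/cholesterol_genes.tsv`` (columns
    ``gene``, ``category``) — 31 enzymes spanning de novo biosynthesis,
    enzymatic catabolism (oxysterol synthesis) and esterification — or a
    user-supplied file of the same layout.  ``categories`` restricts the
    panel to a subset of category labels.  Combine with
    :func:`reactions_for_genes` to select the controlled reaction set of a
    genome-scale model.
    """
    if path is None:
        from importlib.resources import files
        path = files("metactivity").joinpath("data/cholesterol_genes.tsv")
    genes: list[tuple[str, str]] = []
    with open(str(path)) as fh:
        header = fh.readline().strip().split("\t")
        gi, ci = header.index("gene"), header.index("category")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            genes.append((fields[gi], fields[ci]))
    if categories is not None:
        wanted = set(categories)
        genes = [(g, c) for g, c in genes if c in wanted]
    return tuple(g for g, _ in genes)


def apply_media_constraints(
    model: MetabolicModel,
    constraints: Iterable[tuple[str, float]],
) -> MetabolicModel:
    """Return a copy of ``model`` with the listed lower bounds replaced.

    Used to force uptake/synthesis activity: e.g. glucose-like and oxygen-like
    uptakes at 0.01 and a macromolecule-synthesis sink at 0.0001, leaving all
    other reactions unconstrained.
    """
    updates = dict(constraints)
    known = set(model.reaction_ids)
    for rxn_id in updates:
        if rxn_id not in known:
            raise KeyError(f"unknown reaction id in media constraints: {rxn_id}")
    new_reactions = []
    for rxn in model.reactions:
        if rxn.id in updates:
            new_lb = float(updates[rxn.id])
            if new_lb > rxn.upper_bound:
                raise ValueError(
                    f"media constraint on {rxn.id}: new lower bound {new_lb} "
                    f"exceeds upper bound {rxn.upper_bound}")
            rxn = replace(rxn, lower_bound=new_lb)
        new_reactions.append(rxn)
    return replace(model, reactions=tuple(new_reactions))


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "name": model.name,
        "version": model.version,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr.to_string() if r.gpr else "",
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "genes": list(model.genes),
    }


def _model_from_dict(data: Mapping, source: str = "<json>") -> MetabolicModel:
    try:
        mets = tuple(
            Metabolite(id=m["id"], name=m.get("name", ""),
                       compartment=m.get("compartment", ""))
            for m in data["metabolites"]
        )
        rxns = []
        for r in data["reactions"]:
            lb = r.get("lower_bound")
            ub = r.get("upper_bound")
            if lb is None or ub is None:
                logger.warning(
                    "reaction %s in %s lacks bounds; defaulting", r["id"], source)
                lb = DEFAULT_LOWER_BOUND if lb is None else lb
                ub = DEFAULT_UPPER_BOUND if ub is None else ub
            rxns.append(Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                lower_bound=float(lb),
                upper_bound=float(ub),
                gpr=parse_gpr(r.get("gene_reaction_rule", "")),
                subsystem=r.get("subsystem", ""),
            ))
        genes = tuple(data.get("genes") or sorted(
            {g for r in rxns if r.gpr for g in r.gpr.genes()}))
    except (KeyError, TypeError) as exc:
        raise ModelLoadError(f"malformed model file {source}: {exc}") from exc
    model = MetabolicModel(
        metabolites=mets, reactions=tuple(rxns), genes=genes,
        name=data.get("name", ""), version=data.get("version", ""))
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML via cobrapy (fbc bounds + gene-product associations)
# ---------------------------------------------------------------------------

def _from_cobra(cmodel) -> MetabolicModel:
    mets = tuple(
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "")
        for m in cmodel.metabolites
    )
    rxns = []
    for r in cmodel.reactions:
        lb = r.lower_bound
        ub = r.upper_bound
        if lb is None or ub is None:  # pragma: no cover - cobra fills defaults
            logger.warning("reaction %s lacks bounds; defaulting", r.id)
            lb = DEFAULT_LOWER_BOUND if lb is None else lb
            ub = DEFAULT_UPPER_BOUND if ub is None else ub
        rxns.append(Reaction(
            id=r.id,
            name=r.name or "",
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(lb),
            upper_bound=float(ub),
            gpr=parse_gpr(r.gene_reaction_rule),
            subsystem=r.subsystem or "",
        ))
    genes = tuple(sorted(g.id for g in cmodel.genes))
    model = MetabolicModel(
        metabolites=mets, reactions=tuple(rxns), genes=genes,
        name=cmodel.name or cmodel.id or "", version="")
    model.validate()
    return model


def _to_cobra(model: MetabolicModel):
    import cobra

    cmodel = cobra.Model(model.name or "model")
    compartments = {m.compartment or "c" for m in model.metabolites}
    cmodel.compartments = {c: c for c in compartments}
    cmets = {}
    for m in model.metabolites:
        cm = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        cmets[m.id] = cm
    cmodel.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name,
                            lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.subsystem = r.subsystem
        crxns.append(cr)
    cmodel.add_reactions(crxns)
    for r in model.reactions:
        cr = cmodel.reactions.get_by_id(r.id)
        cr.add_metabolites({cmets[k]: v for k, v in r.stoichiometry.items()})
        if r.gpr is not None:
            cr.gene_reaction_rule = r.gpr.to_string()
    return cmodel


def _guess_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ValueError(f"cannot infer model format from {path.name}; pass format=")


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a metabolic model from SBML (L3 + fbc) or the JSON dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _guess_format(path, format)
    if fmt == "json":
        try:
            with open(path) as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelLoadError(f"malformed JSON model {path}: {exc}") from exc
        return _model_from_dict(data, source=str(path))
    if fmt == "sbml":
        from cobra.io import read_sbml_model
        try:
            cmodel = read_sbml_model(str(path))
        except Exception as exc:
            raise ModelLoadError(f"malformed SBML model {path}: {exc}") from exc
        return _from_cobra(cmodel)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: str | Path,
                format: str | None = None) -> None:
    """Write a model to SBML (L3 + fbc) or the JSON dialect."""
    path = Path(path)
    fmt = _guess_format(path, format)
    model.validate()
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    if fmt == "sbml":
        from cobra.io import write_sbml_model
        write_sbml_model(_to_cobra(model), str(path))
        return
    raise ValueError(f"unknown model format {fmt!r}")
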