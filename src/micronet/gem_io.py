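"""Reading, validating and deconstructing genome-scale metabolic models (GEMs).

A GEM is the full reaction network reconstructed from an organism's annotated
genome.  This module parses GEMs from SBML Level 3 and from a simple tabular
reaction-list dialect, classifies every reaction as internal, exchange
(boundary flow of a single extracellular compound) or transport (movement
between compartments), and exposes the metabolite / reaction / pathway
inventories that the downstream graph analysis consumes.

Design notes
------------
* Metabolite identity is ``(base id, compartment)``; ids are compared
  verbatim after lowercasing.  No cross-database harmonisation (KEGG /
  BIGG / MetaNetX mapping) is attempted; an optional synonym table can be
  applied by the caller before comparison.
* Stoichiometric coefficients are parsed and stored, but every graph
  algorithm in this package is purely topological and ignores them.
* A metabolite appearing on both sides of an internal reaction is removed
  from both sides with a logged warning: such self-loops carry no
  reachability information and would break the substrate/product
  disjointness invariant.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from lxml import etree

logger = logging.getLogger(__name__)

#: Compartment labels treated as extracellular when a model does not
#: declare its own extracellular set.  Covers the common AGORA / CarveMe /
#: BIGG conventions.
DEFAULT_EXTRACELLULAR = frozenset({"e", "e0", "ce", "c_e", "extracellular", "extracellular space"})

VALID_KINDS = ("internal", "exchange", "transport")


class GEMValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class GEMParseError(ValueError):
    """Raised when an input file cannot be parsed."""


@dataclass
class Metabolite:
    met_id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    is_extracellular: bool = False

    def __post_init__(self) -> None:
        if not self.met_id:
            raise GEMValidationError("metabolite id must be non-empty")
        self.met_id = self.met_id.lower()


@dataclass
class Reaction:
    """One reaction with substrate/product maps ``met_id -> coefficient > 0``."""

    rxn_id: str
    name: str = ""
    substrates: dict[str, float] = field(default_factory=dict)
    products: dict[str, float] = field(default_factory=dict)
    reversible: bool = False
    kind: str = "internal"
    subsystem: str | None = None

    def __post_init__(self) -> None:
        if not self.rxn_id:
            raise GEMValidationError("reaction id must be non-empty")
        self.rxn_id = self.rxn_id.lower()
        self.substrates = {m.lower(): c for m, c in self.substrates.items()}
        self.products = {m.lower(): c for m, c in self.products.items()}

    @property
    def participants(self) -> set[str]:
        return set(self.substrates) | set(self.products)


@dataclass
class GEModel:
    model_id: str
    taxon_id: str | None = None
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    properties: dict[str, str] = field(default_factory=dict)
    extracellular_compartments: set[str] = field(default_factory=lambda: set(DEFAULT_EXTRACELLULAR))
    has_exchange_or_transport: bool = False

    def add_metabolite(self, met: Metabolite) -> None:
        if met.met_id in self.metabolites:
            raise GEMValidationError(f"duplicate metabolite id {met.met_id!r} in model {self.model_id!r}")
        met.is_extracellular = met.compartment.lower() in self.extracellular_compartments
        self.metabolites[met.met_id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.rxn_id in self.reactions:
            raise GEMValidationError(f"duplicate reaction id {rxn.rxn_id!r} in model {self.model_id!r}")
        self.reactions[rxn.rxn_id] = rxn

    def validate(self) -> None:
        """Check referential integrity; raise with the offending ids."""
        if not self.metabolites:
            raise GEMValidationError(f"model {self.model_id!r} declares no metabolites")
        unknown = sorted(
            {m for r in self.reactions.values() for m in r.participants if m not in self.metabolites}
        )
        if unknown:
            raise GEMValidationError(
                f"model {self.model_id!r}: reactions reference unknown metabolites: {', '.join(unknown)}"
            )

    def reaction_ids(self) -> set[str]:
        return set(self.reactions)

    def canonical(self) -> "GEModel":
        """Return a copy with metabolites and reactions in sorted-id order."""
        out = GEModel(
            model_id=self.model_id,
            taxon_id=self.taxon_id,
            properties=dict(self.properties),
            extracellular_compartments=set(self.extracellular_compartments),
            has_exchange_or_transport=self.has_exchange_or_transport,
        )
        for mid in sorted(self.metabolites):
            out.metabolites[mid] = self.metabolites[mid]
        for rid in sorted(self.reactions):
            out.reactions[rid] = self.reactions[rid]
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GEModel):
            return NotImplemented
        return (
            self.model_id == other.model_id
            and self.metabolites == other.metabolites
            and self.reactions == other.reactions
        )


# ---------------------------------------------------------------------------
# reaction classification


def _drop_both_sides(rxn: Reaction) -> None:
    both = set(rxn.substrates) & set(rxn.products)
    if both:
        logger.warning(
            "reaction %s: metabolites %s appear on both sides; dropped from both",
            rxn.rxn_id,
            sorted(both),
        )
        for m in both:
            rxn.substrates.pop(m, None)
            rxn.products.pop(m, None)


def classify_reactions(model: GEModel) -> GEModel:
    """Assign every reaction a kind in {internal, exchange, transport}.

    Rules (total, idempotent):
    * exactly one distinct participating metabolite, extracellular -> exchange
    * participants spanning >= 2 distinct compartments -> transport
    * otherwise -> internal (a metabolite on both sides is dropped first)

    Also recomputes ``has_exchange_or_transport`` from scratch; the flag is
    never trusted from input.
    """
    for rxn in model.reactions.values():
        parts = rxn.participants
        mets = [model.metabolites[m] for m in parts if m in model.metabolites]
        compartments = {m.compartment.lower() for m in mets}
        if len(parts) == 1 and mets and mets[0].is_extracellular:
            rxn.kind = "exchange"
        elif len(compartments) >= 2:
            rxn.kind = "transport"
        else:
            rxn.kind = "internal"
            _drop_both_sides(rxn)
    model.has_exchange_or_transport = any(
        r.kind != "internal" for r in model.reactions.values()
    )
    return model


def model_summary(model: GEModel) -> dict:
    """Counts of metabolites, reactions and distinct subsystems (pathways)."""
    subsystems = {r.subsystem for r in model.reactions.values() if r.subsystem}
    return {
        "model_id": model.model_id,
        "n_metabolites": len(model.metabolites),
        "n_reactions": len(model.reactions),
        "n_subsystems": len(subsystems),
        "has_exchange_or_transport": model.has_exchange_or_transport,
    }


def write_summary_json(model: GEModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_summary(model), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# SBML Level 3


_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
_SBML_NS_V2 = "http://www.sbml.org/sbml/level3/version2/core"
_SBML_L2 = "http://www.sbml.org/sbml/level2"


def _localname(el: etree._Element) -> str:
    return etree.QName(el).localname


def _findall(parent: etree._Element, *path: str) -> list[etree._Element]:
    """Namespace-agnostic nested find: each step matches on local name."""
    current = [parent]
    for step in path:
        nxt: list[etree._Element] = []
        for el in current:
            nxt.extend(ch for ch in el if isinstance(ch.tag, str) and _localname(ch) == step)
        current = nxt
    return current


def read_sbml(
    path: str | Path,
    model_id: str | None = None,
    extracellular_compartments: Iterable[str] | None = None,
) -> GEModel:
    """Parse an SBML Level 3 (or Level 2) GEM file into a :class:`GEModel`.

    Reversibility is taken from the ``reversible`` attribute; compartments
    are preserved and a compartment is flagged extracellular when its id is
    in the extracellular set or its name contains "extracellular".
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise GEMParseError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    models = _findall(root, "model")
    if not models:
        raise GEMParseError(f"{path}: no <model> element found")
    mnode = models[0]

    extra = set(s.lower() for s in (extracellular_compartments or DEFAULT_EXTRACELLULAR))
    for comp in _findall(mnode, "listOfCompartments", "compartment"):
        cname = (comp.get("name") or "").lower()
        if "extracellular" in cname:
            extra.add((comp.get("id") or "").lower())

    model = GEModel(
        model_id=(model_id or mnode.get("id") or path.stem).lower(),
        extracellular_compartments=extra,
    )

    species = _findall(mnode, "listOfSpecies", "species")
    if not species:
        raise GEMParseError(f"{path}: model declares an empty species list")
    for sp in species:
        sid = sp.get("id") or ""
        model.add_metabolite(
            Metabolite(
                met_id=sid,
                name=sp.get("name") or sid,
                compartment=(sp.get("compartment") or "c").lower(),
            )
        )

    for rx in _findall(mnode, "listOfReactions", "reaction"):
        rid = rx.get("id") or ""
        subs: dict[str, float] = {}
        prods: dict[str, float] = {}
        for ref in _findall(rx, "listOfReactants", "speciesReference"):
            subs[(ref.get("species") or "").lower()] = float(ref.get("stoichiometry") or 1.0)
        for ref in _findall(rx, "listOfProducts", "speciesReference"):
            prods[(ref.get("species") or "").lower()] = float(ref.get("stoichiometry") or 1.0)
        subsystem = None
        for note in rx.iter():
            if isinstance(note.tag, str) and _localname(note) == "p" and note.text:
                m = re.match(r"\s*SUBSYSTEM:\s*(.+)", note.text)
                if m:
                    subsystem = m.group(1).strip()
        model.add_reaction(
            Reaction(
                rxn_id=rid,
                name=rx.get("name") or rid,
                substrates=subs,
                products=prods,
                reversible=(rx.get("reversible") or "false").lower() in ("true", "1"),
                subsystem=subsystem,
            )
        )

    model.validate()
    return classify_reactions(model)


def write_sbml(model: GEModel, path: str | Path) -> None:
    """Write a minimal, deterministic SBML Level 3 serialisation."""
    nsmap = {None: _SBML_NS}
    sbml = etree.Element(f"{{{_SBML_NS}}}sbml", nsmap=nsmap, level="3", version="1")
    mnode = etree.SubElement(sbml, f"{{{_SBML_NS}}}model", id=model.model_id)

    comps = sorted({m.compartment for m in model.metabolites.values()})
    lc = etree.SubElement(mnode, f"{{{_SBML_NS}}}listOfCompartments")
    for c in comps:
        name = "extracellular" if c.lower() in model.extracellular_compartments else c
        etree.SubElement(lc, f"{{{_SBML_NS}}}compartment", id=c, name=name, constant="true")

    ls = etree.SubElement(mnode, f"{{{_SBML_NS}}}listOfSpecies")
    for mid in sorted(model.metabolites):
        met = model.metabolites[mid]
        etree.SubElement(
            ls,
            f"{{{_SBML_NS}}}species",
            id=met.met_id,
            name=met.name or met.met_id,
            compartment=met.compartment,
            hasOnlySubstanceUnits="false",
            boundaryCondition="false",
            constant="false",
        )

    lr = etree.SubElement(mnode, f"{{{_SBML_NS}}}listOfReactions")
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        rnode = etree.SubElement(
            lr,
            f"{{{_SBML_NS}}}reaction",
            id=rxn.rxn_id,
            name=rxn.name or rxn.rxn_id,
            reversible="true" if rxn.reversible else "false",
            fast="false",
        )
        if rxn.subsystem:
            notes = etree.SubElement(rnode, f"{{{_SBML_NS}}}notes")
            body = etree.SubElement(notes, "{http://www.w3.org/1999/xhtml}body")
            p = etree.SubElement(body, "{http://www.w3.org/1999/xhtml}p")
            p.text = f"SUBSYSTEM: {rxn.subsystem}"
        if rxn.substrates:
            lre = etree.SubElement(rnode, f"{{{_SBML_NS}}}listOfReactants")
            for m in sorted(rxn.substrates):
                etree.SubElement(
                    lre, f"{{{_SBML_NS}}}speciesReference",
                    species=m, stoichiometry=repr(rxn.substrates[m]), constant="true",
                )
        if rxn.products:
            lpr = etree.SubElement(rnode, f"{{{_SBML_NS}}}listOfProducts")
            for m in sorted(rxn.products):
                etree.SubElement(
                    lpr, f"{{{_SBML_NS}}}speciesReference",
                    species=m, stoichiometry=repr(rxn.products[m]), constant="true",
                )

    Path(path).write_bytes(
        etree.tostring(sbml, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    )


# ---------------------------------------------------------------------------
# tabular reaction-list dialect
#
# TSV columns: rxn_id, equation[, subsystem].  Equations look like
# "a_c + 2 b_c -> c_c" or "a_e <=> a_c"; the suffix after the final "_"
# is the compartment, "_e" marking extracellular.  A boundary (exchange)
# equation has an empty right-hand side and a rxn_id starting with "ex_".

_ARROWS = ("<=>", "<->", "-->", "->")


def _parse_side(side: str, row: str) -> dict[str, float]:
    out: dict[str, float] = {}
    side = side.strip()
    if not side:
        return out
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise GEMParseError(f"row {row!r}: empty term in equation")
        m = re.match(r"^(?:(\d+(?:\.\d+)?)\s+)?([A-Za-z0-9_\-\[\]]+)$", term)
        if not m:
            raise GEMParseError(f"row {row!r}: cannot parse term {term!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        out[m.group(2).lower()] = out.get(m.group(2).lower(), 0.0) + coef
    return out


def parse_equation(rxn_id: str, equation: str) -> tuple[dict[str, float], dict[str, float], bool]:
    arrow = next((a for a in _ARROWS if a in equation), None)
    if arrow is None:
        raise GEMParseError(f"row {rxn_id!r}: equation {equation!r} has no reaction arrow")
    lhs, rhs = equation.split(arrow, 1)
    reversible = arrow in ("<=>", "<->")
    subs = _parse_side(lhs, rxn_id)
    prods = _parse_side(rhs, rxn_id)
    if not subs and not prods:
        raise GEMParseError(f"row {rxn_id!r}: equation is empty on both sides")
    is_exchange_marked = rxn_id.lower().startswith("ex_")
    if (not subs or not prods) and not is_exchange_marked:
        raise GEMParseError(
            f"row {rxn_id!r}: one-sided equation {equation!r} is only allowed for "
            f"exchange reactions (rxn_id prefix 'ex_')"
        )
    return subs, prods, reversible


def _compartment_of(met_id: str) -> str:
    if "_" in met_id:
        return met_id.rsplit("_", 1)[1]
    return "c"


def read_reaction_table(path: str | Path, model_id: str | None = None) -> GEModel:
    """Read a GEM from the tabular reaction-list dialect."""
    path = Path(path)
    model = GEModel(model_id=(model_id or path.stem).lower())
    seen_mets: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["rxn_id", "equation"]:
            raise GEMParseError(f"{path}: expected header columns rxn_id, equation; got {header}")
        has_subsystem = len(header) > 2 and header[2] == "subsystem"
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) < 2:
                raise GEMParseError(f"{path} line {lineno}: expected at least 2 columns")
            rxn_id, equation = cells[0].strip(), cells[1].strip()
            subsystem = cells[2].strip() if has_subsystem and len(cells) > 2 and cells[2].strip() else None
            try:
                subs, prods, reversible = parse_equation(rxn_id, equation)
            except GEMParseError as exc:
                raise GEMParseError(f"{path} line {lineno}: {exc}") from exc
            for m in set(subs) | set(prods):
                if m not in seen_mets:
                    seen_mets.add(m)
                    model.add_metabolite(Metabolite(met_id=m, compartment=_compartment_of(m)))
            model.add_reaction(
                Reaction(
                    rxn_id=rxn_id,
                    substrates=subs,
                    products=prods,
                    reversible=reversible,
                    subsystem=subsystem,
                )
            )
    if not model.metabolites:
        raise GEMParseError(f"{path}: table contains no reactions")
    model.validate()
    return classify_reactions(model)


def format_equation(rxn: Reaction) -> str:
    def side(d: Mapping[str, float]) -> str:
        terms = []
        for m in sorted(d):
            c = d[m]
            terms.append(m if c == 1.0 else f"{c:g} {m}")
        return " + ".join(terms)

    arrow = "<=>" if rxn.reversible else "->"
    return f"{side(rxn.substrates)} {arrow} {side(rxn.products)}".strip()


def write_reaction_table(model: GEModel, path: str | Path) -> None:
    """Write the tabular dialect; inverse of :func:`read_reaction_table`
    on canonicalised models."""
    lines = ["rxn_id\tequation\tsubsystem"]
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        lines.append(f"{rxn.rxn_id}\t{format_equation(rxn)}\t{rxn.subsystem or ''}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path: str | Path, fmt: str | None = None, model_id: str | None = None) -> GEModel:
    """Dispatch on format: 'sbml' (.xml/.sbml) or 'table' (.tsv)."""
    path = Path(path)
    if fmt is None:
        fmt = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "table"
    if fmt == "sbml":
        return read_sbml(path, model_id=model_id)
    if fmt == "table":
        return read_reaction_table(path, model_id=model_id)
    raise ValueError(f"unknown model format {fmt!r}")
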