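"""SBML subset reader/writer.

Reads SBML Level 2 (version >= 3) and Level 3 core documents covering the
kinetic-model subset the toolkit handles (compartments, species,
parameters, reactions with kinetic laws, rate rules, assignment rules) and
writes Level 3 Version 2.  Unsupported constructs (events, constraints,
function definitions, initial assignments, algebraic rules) are reported
as warnings and dropped rather than refused: database models frequently
carry them even when they are irrelevant to the hybrid pipeline.

Normalizations on read:

* ``initialAmount`` converts to a concentration using the compartment size;
* kinetic-law local parameters are hoisted to global parameters named
  ``<reactionId>__<localId>`` (the flat-namespace convention of
  :mod:`hybkit.model`).
"""

from __future__ import annotations

import io
from typing import Optional, Union

from lxml import etree

from . import expressions as ex
from .expressions import Expr, MathMLError
from .model import (AssignmentRule, Compartment, KineticModel, Parameter,
                    RateRule, Reaction, Species, SpeciesRef,
                    check_consistency, topo_order_assignments)
from .report import ValidationReport

SBML_L3V2_NS = "http://www.sbml.org/sbml/level3/version2/core"
SBML_L3V1_NS = "http://www.sbml.org/sbml/level3/version1/core"
_SBML_L2_NS = ["http://www.sbml.org/sbml/level2/version3",
               "http://www.sbml.org/sbml/level2/version4",
               "http://www.sbml.org/sbml/level2/version5"]
KNOWN_NS = [SBML_L3V2_NS, SBML_L3V1_NS] + _SBML_L2_NS
XHTML_NS = "http://www.w3.org/1999/xhtml"

#: elements we acknowledge but do not model
_UNSUPPORTED = {"listOfEvents", "listOfConstraints", "listOfFunctionDefinitions",
                "listOfInitialAssignments", "listOfUnitDefinitions",
                "algebraicRule"}

Source = Union[str, bytes]


class SbmlError(ValueError):
    pass


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _parse_xml(xml: Source) -> etree._Element:
    data = xml.encode() if isinstance(xml, str) else xml
    try:
        return etree.parse(io.BytesIO(data)).getroot()
    except etree.XMLSyntaxError as exc:
        raise SbmlError(f"not well-formed XML: {exc}") from exc


def _bool(value: Optional[str], default: bool) -> bool:
    if value is None:
        return default
    return value in ("true", "1")


def _float(value: Optional[str], default: Optional[float]) -> Optional[float]:
    if value is None:
        return default
    return float(value)


def _find(parent: etree._Element, name: str) -> Optional[etree._Element]:
    for child in parent:
        if _local(child.tag) == name:
            return child
    return None


def _findall(parent: etree._Element, name: str) -> list[etree._Element]:
    return [c for c in parent if _local(c.tag) == name]


def _notes_text(el: etree._Element) -> str:
    notes = _find(el, "notes")
    if notes is None:
        return ""
    return " ".join("".join(notes.itertext()).split())


def _math_expr(parent: etree._Element, location: str, rep: ValidationReport) -> Optional[Expr]:
    math = _find(parent, "math")
    if math is None:
        rep.error("MISSING_MATH", location, "element has no <math> child")
        return None
    try:
        return ex.parse_mathml(math)
    except MathMLError as exc:
        rep.error("BAD_MATH", location, str(exc))
        return None


_ORIGIN_TAGS = {"ml-weight", "ml-bias", "ml-scaling", "ml-node"}


def _origin_from_notes(text: str) -> str:
    for tag in _ORIGIN_TAGS:
        if tag in text:
            return tag
    return "mechanistic"


def _read_model(root: etree._Element, rep: ValidationReport) -> KineticModel:
    ns = etree.QName(root).namespace if root.tag.startswith("{") else None
    if _local(root.tag) != "sbml" or ns not in KNOWN_NS:
        raise SbmlError(f"root element is not SBML (namespace {ns!r})")
    model_el = _find(root, "model")
    if model_el is None:
        raise SbmlError("document has no <model> element")

    m = KineticModel(id=model_el.get("id", "model"),
                     name=model_el.get("name", ""),
                     notes=_notes_text(model_el))

    for name in _UNSUPPORTED:
        for el in _findall(model_el, name):
            rep.warn("UNSUPPORTED_DROPPED", f"model/{name}",
                     f"unsupported element <{name}> dropped")

    loc_comp = _find(model_el, "listOfCompartments")
    for c in _findall(loc_comp, "compartment") if loc_comp is not None else []:
        cid = c.get("id")
        if cid is None:
            raise SbmlError("compartment without required attribute 'id' (model/listOfCompartments)")
        size = _float(c.get("size"), None)
        if size is None:
            size = _float(c.get("volume"), 1.0)  # SBML L1 spelling, rare
        m.compartments.append(Compartment(id=cid, size=size, name=c.get("name", ""),
                                          constant=_bool(c.get("constant"), True)))

    comp_size = {c.id: c.size for c in m.compartments}
    los = _find(model_el, "listOfSpecies")
    for s in _findall(los, "species") if los is not None else []:
        sid = s.get("id")
        comp = s.get("compartment")
        if sid is None or comp is None:
            raise SbmlError("species without required attribute 'id'/'compartment' "
                            "(model/listOfSpecies)")
        conc = _float(s.get("initialConcentration"), None)
        if conc is None:
            amount = _float(s.get("initialAmount"), None)
            if amount is not None:
                conc = amount / comp_size.get(comp, 1.0)
            else:
                conc = 0.0
        m.species.append(Species(id=sid, compartment=comp, initial_concentration=conc,
                                 name=s.get("name", ""),
                                 boundary=_bool(s.get("boundaryCondition"), False),
                                 constant=_bool(s.get("constant"), False)))

    lop = _find(model_el, "listOfParameters")
    for p in _findall(lop, "parameter") if lop is not None else []:
        pid = p.get("id")
        if pid is None:
            raise SbmlError("parameter without required attribute 'id' (model/listOfParameters)")
        m.parameters.append(Parameter(id=pid, value=_float(p.get("value"), 0.0) or 0.0,
                                      constant=_bool(p.get("constant"), True),
                                      origin=_origin_from_notes(_notes_text(p)),
                                      name=p.get("name", "")))

    lor = _find(model_el, "listOfReactions")
    for r in _findall(lor, "reaction") if lor is not None else []:
        rid = r.get("id")
        if rid is None:
            raise SbmlError("reaction without required attribute 'id' (model/listOfReactions)")
        rxn = Reaction(id=rid, reversible=_bool(r.get("reversible"), False),
                       name=r.get("name", ""))
        for role, attr in (("listOfReactants", "reactants"), ("listOfProducts", "products")):
            lst = _find(r, role)
            for ref in _findall(lst, "speciesReference") if lst is not None else []:
                sp = ref.get("species")
                if sp is None:
                    raise SbmlError(f"speciesReference without 'species' (reaction {rid})")
                getattr(rxn, attr).append(
                    SpeciesRef(species=sp, stoichiometry=_float(ref.get("stoichiometry"), 1.0) or 1.0))
        kl = _find(r, "kineticLaw")
        if kl is not None:
            law = _math_expr(kl, f"reaction:{rid}/kineticLaw", rep)
            # hoist local parameters into the global namespace
            locals_el = _find(kl, "listOfLocalParameters")
            if locals_el is None:
                locals_el = _find(kl, "listOfParameters")
            rename: dict[str, str] = {}
            if locals_el is not None:
                for lp in list(locals_el):
                    if _local(lp.tag) not in ("localParameter", "parameter"):
                        continue
                    lid = lp.get("id")
                    if lid is None:
                        raise SbmlError(f"local parameter without 'id' (reaction {rid})")
                    gid = f"{rid}__{lid}"
                    rename[lid] = gid
                    m.parameters.append(Parameter(id=gid, value=_float(lp.get("value"), 0.0) or 0.0,
                                                  constant=True, name=lp.get("name", "")))
            if law is not None and rename:
                law = law.rename_symbols(rename)
            rxn.kinetic_law = law
        m.reactions.append(rxn)

    lorules = _find(model_el, "listOfRules")
    for rule in list(lorules) if lorules is not None else []:
        tag = _local(rule.tag)
        if tag == "assignmentRule":
            var = rule.get("variable")
            if var is None:
                raise SbmlError("assignmentRule without required attribute 'variable'")
            expr = _math_expr(rule, f"assignment_rule:{var}", rep)
            if expr is not None:
                m.assignment_rules.append(AssignmentRule(variable=var, expression=expr))
        elif tag == "rateRule":
            var = rule.get("variable")
            if var is None:
                raise SbmlError("rateRule without required attribute 'variable'")
            expr = _math_expr(rule, f"rate_rule:{var}", rep)
            if expr is not None:
                m.rate_rules.append(RateRule(variable=var, expression=expr))
        elif tag == "algebraicRule":
            rep.warn("UNSUPPORTED_DROPPED", "model/listOfRules",
                     "unsupported element <algebraicRule> dropped")
        else:
            rep.warn("UNSUPPORTED_DROPPED", "model/listOfRules",
                     f"unsupported rule <{tag}> dropped")
    return m


def read_sbml(xml: Source) -> tuple[KineticModel, ValidationReport]:
    """Read an SBML document into a :class:`KineticModel`.

    Raises :class:`SbmlError` for fatal problems (not XML, wrong
    namespace, missing required attributes); recoverable issues (bad math,
    dropped unsupported elements) land in the returned report.
    """
    rep = ValidationReport()
    root = _parse_xml(xml)
    m = _read_model(root, rep)
    return m, rep.sorted()


def validate_sbml_structure(xml: Source) -> ValidationReport:
    """Structural + referential validation of an SBML document.

    Never raises: fatal problems become ERROR entries (codes ``NOT_XML``,
    ``NOT_SBML``, ``MISSING_ATTRIBUTE``), then the read model is checked
    semantically (duplicate ids, dangling references, ...).  An empty
    report means the file reads cleanly with no warnings.
    """
    rep = ValidationReport()
    try:
        root = _parse_xml(xml)
    except SbmlError as exc:
        rep.error("NOT_XML", "document", str(exc))
        return rep.sorted()
    try:
        m = _read_model(root, rep)
    except SbmlError as exc:
        code = "NOT_SBML" if "not SBML" in str(exc) or "no <model>" in str(exc) \
            else "MISSING_ATTRIBUTE"
        rep.error(code, "document", str(exc))
        return rep.sorted()
    rep.extend(check_consistency(m))
    return rep.sorted()


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    return ex.format_number(v)


def _set_notes(el: etree._Element, text: str) -> None:
    notes = etree.SubElement(el, f"{{{SBML_L3V2_NS}}}notes")
    body = etree.SubElement(notes, f"{{{XHTML_NS}}}body", nsmap={None: XHTML_NS})
    p = etree.SubElement(body, f"{{{XHTML_NS}}}p")
    p.text = text


def write_sbml(m: KineticModel) -> bytes:
    """Serialize a consistent model to SBML Level 3 Version 2.

    Refuses inconsistent models (raises :class:`SbmlError` carrying the
    consistency report).  Assignment rules are emitted in topological
    order; parameters of machine-learning origin carry a notes tag naming
    that origin so it survives the round trip.
    """
    rep = check_consistency(m)
    if rep.has_errors():
        raise SbmlError("refusing to write inconsistent model:\n" + str(rep))

    nsmap = {None: SBML_L3V2_NS}
    root = etree.Element(f"{{{SBML_L3V2_NS}}}sbml", nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "2")
    model_el = etree.SubElement(root, f"{{{SBML_L3V2_NS}}}model")
    model_el.set("id", m.id)
    if m.name:
        model_el.set("name", m.name)
    if m.notes:
        _set_notes(model_el, m.notes)

    def sub(parent, tag):
        return etree.SubElement(parent, f"{{{SBML_L3V2_NS}}}{tag}")

    if m.compartments:
        loc = sub(model_el, "listOfCompartments")
        for c in m.compartments:
            el = sub(loc, "compartment")
            el.set("id", c.id)
            if c.name:
                el.set("name", c.name)
            el.set("size", _fmt(c.size))
            el.set("constant", "true" if c.constant else "false")

    if m.species:
        los = sub(model_el, "listOfSpecies")
        for s in m.species:
            el = sub(los, "species")
            el.set("id", s.id)
            if s.name:
                el.set("name", s.name)
            el.set("compartment", s.compartment)
            el.set("initialConcentration", _fmt(s.initial_concentration))
            el.set("hasOnlySubstanceUnits", "false")
            el.set("boundaryCondition", "true" if s.boundary else "false")
            el.set("constant", "true" if s.constant else "false")

    if m.parameters:
        lop = sub(model_el, "listOfParameters")
        for p in m.parameters:
            el = sub(lop, "parameter")
            el.set("id", p.id)
            if p.name:
                el.set("name", p.name)
            el.set("value", _fmt(p.value))
            el.set("constant", "true" if p.constant else "false")
            if p.origin != "mechanistic":
                _set_notes(el, f"machine-learning constant ({p.origin})")

    rules = [("assignmentRule", a.variable, a.expression) for a in topo_order_assignments(m)] + \
            [("rateRule", r.variable, r.expression) for r in m.rate_rules]
    if rules:
        lorules = sub(model_el, "listOfRules")
        for tag, var, expr in rules:
            el = sub(lorules, tag)
            el.set("variable", var)
            el.append(ex.write_mathml(expr))

    if m.reactions:
        lor = sub(model_el, "listOfReactions")
        for r in m.reactions:
            el = sub(lor, "reaction")
            el.set("id", r.id)
            if r.name:
                el.set("name", r.name)
            el.set("reversible", "true" if r.reversible else "false")
            for role, refs in (("listOfReactants", r.reactants), ("listOfProducts", r.products)):
                if refs:
                    lst = sub(el, role)
                    for ref in refs:
                        sr = sub(lst, "speciesReference")
                        sr.set("species", ref.species)
                        sr.set("stoichiometry", _fmt(ref.stoichiometry))
                        sr.set("constant", "true")
            if r.kinetic_law is not None:
                kl = sub(el, "kineticLaw")
                kl.append(ex.write_mathml(r.kinetic_law))

    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
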