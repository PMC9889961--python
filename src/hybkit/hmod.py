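"""HMOD: a block-structured ASCII format for kinetic models with an
optional machine-learning component.

HMOD aggregates everything a hybrid semiparametric model needs in one
diff-friendly text file: the mechanistic blocks (compartments, species,
parameters, reactions, rate rules, assignment rules) followed by an
optional ``[ML]`` block carrying a feedforward network's weights and its
input/output wiring.  A document without an ``[ML]`` block is a pure
mechanistic model.  ``HMOD-SPEC.md`` at the repository root is the
normative grammar; this module is its reference implementation.

Blocks appear in a fixed order so that every identifier is defined before
first use in a single pass.  Serialization is canonical (stable field
order, one space after separators, shortest round-tripping numerals), so
serializing the same model twice is byte-identical.
"""

from __future__ import annotations

import re
from typing import Optional

from ._linefmt import LineFormatError, Record, format_record, parse_record, strip_comment
from .ann import AnnSpec, annspec_to_records, records_to_annspec
from .expressions import (Expr, ExprError, IDENTIFIER_RE, format_number,
                          parse_infix, write_infix)
from .model import (AssignmentRule, Compartment, KineticModel, Parameter,
                    RateRule, Reaction, Species, SpeciesRef, PARAM_ORIGINS,
                    check_consistency)
from .report import ValidationReport

HMOD_VERSION = "HMOD/1"

#: canonical block order (definition-before-use is checkable in one pass)
BLOCK_ORDER = ["HMOD", "COMPARTMENTS", "SPECIES", "PARAMETERS", "REACTIONS",
               "RATE_RULES", "ASSIGNMENT_RULES", "ML"]
_MECHANISTIC_BLOCKS = BLOCK_ORDER[1:7]

_BLOCK_RE = re.compile(r"\[([A-Z_]+)\]\Z")
_TERM_RE = re.compile(r"(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?([A-Za-z_][A-Za-z0-9_]*)\Z")


class HmodError(ValueError):
    pass


def _parse_species_refs(text: str) -> list[SpeciesRef]:
    """Parse a reactant/product list like ``2 A + B`` ('' means none)."""
    text = text.strip()
    if not text:
        return []
    refs = []
    for term in text.split("+"):
        m = _TERM_RE.match(term.strip())
        if not m:
            raise HmodError(f"bad species term {term.strip()!r} (expected '[stoich] id')")
        stoich = float(m.group(1)) if m.group(1) else 1.0
        refs.append(SpeciesRef(species=m.group(2), stoichiometry=stoich))
    return refs


def _format_species_refs(refs: list[SpeciesRef]) -> str:
    parts = []
    for ref in refs:
        if ref.stoichiometry == 1.0:
            parts.append(ref.species)
        else:
            parts.append(f"{format_number(ref.stoichiometry)} {ref.species}")
    return " + ".join(parts)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

class _Ctx:
    def __init__(self) -> None:
        self.rep = ValidationReport()
        self.model = KineticModel()
        self.ml_records: list[Record] = []
        self.saw_header = False
        self.saw_ml = False


def _fnum(ctx: _Ctx, loc: str, text: str) -> Optional[float]:
    try:
        return float(text)
    except ValueError:
        ctx.rep.error("BAD_NUMBER", loc, f"cannot parse number {text!r}")
        return None


def _fbool(ctx: _Ctx, loc: str, text: str, default: bool) -> bool:
    if text == "true":
        return True
    if text == "false":
        return False
    ctx.rep.error("BAD_BOOLEAN", loc, f"expected true/false, got {text!r}")
    return default


def _fexpr(ctx: _Ctx, loc: str, text: str) -> Optional[Expr]:
    try:
        return parse_infix(text)
    except ExprError as exc:
        ctx.rep.error("BAD_EXPRESSION", loc, str(exc))
        return None


def _check_id(ctx: _Ctx, loc: str, ident: str) -> bool:
    if not IDENTIFIER_RE.match(ident):
        ctx.rep.error("BAD_IDENTIFIER", loc, f"invalid identifier {ident!r}")
        return False
    return True


_FIELDS = {
    "HMOD/format": {"version"},
    "HMOD/model": {"id", "name", "notes"},
    "COMPARTMENTS": {"size", "constant", "name"},
    "SPECIES": {"compartment", "init", "boundary", "constant", "name"},
    "PARAMETERS": {"value", "constant", "origin", "name"},
    "REACTIONS": {"reactants", "products", "reversible", "law", "name"},
    "RATE_RULES": {"expr"},
    "ASSIGNMENT_RULES": {"expr"},
}


def _check_fields(ctx: _Ctx, loc: str, rec: Record, key: str) -> None:
    allowed = _FIELDS[key]
    for f in rec.fields:
        if f not in allowed:
            ctx.rep.error("UNKNOWN_FIELD", loc, f"unknown field {f!r} in {key} record")


def _handle_record(ctx: _Ctx, block: str, rec: Record, loc: str) -> None:
    fields = rec.fields
    if block == "HMOD":
        if rec.id == "format":
            _check_fields(ctx, loc, rec, "HMOD/format")
            version = fields.get("version", "")
            ctx.saw_header = True  # header present even if the version is rejected
            if not version.startswith("HMOD/1"):
                ctx.rep.error("UNKNOWN_VERSION", loc,
                              f"unsupported format version {version!r} (this parser reads HMOD/1)")
        elif rec.id == "model":
            _check_fields(ctx, loc, rec, "HMOD/model")
            ctx.model.id = fields.get("id", "model")
            ctx.model.name = fields.get("name", "")
            ctx.model.notes = fields.get("notes", "")
            _check_id(ctx, loc, ctx.model.id)
        else:
            ctx.rep.error("BAD_RECORD", loc, f"unknown record {rec.id!r} in [HMOD] block")
    elif block == "COMPARTMENTS":
        _check_fields(ctx, loc, rec, block)
        if not _check_id(ctx, loc, rec.id):
            return
        size = _fnum(ctx, loc, fields["size"]) if "size" in fields else 1.0
        ctx.model.compartments.append(Compartment(
            id=rec.id, size=size if size is not None else 1.0,
            name=fields.get("name", ""),
            constant=_fbool(ctx, loc, fields.get("constant", "true"), True)))
    elif block == "SPECIES":
        _check_fields(ctx, loc, rec, block)
        if not _check_id(ctx, loc, rec.id):
            return
        if "compartment" not in fields:
            ctx.rep.error("MISSING_FIELD", loc, f"species {rec.id!r} lacks field 'compartment'")
            return
        init = _fnum(ctx, loc, fields.get("init", "0"))
        ctx.model.species.append(Species(
            id=rec.id, compartment=fields["compartment"],
            initial_concentration=init if init is not None else 0.0,
            name=fields.get("name", ""),
            boundary=_fbool(ctx, loc, fields.get("boundary", "false"), False),
            constant=_fbool(ctx, loc, fields.get("constant", "false"), False)))
    elif block == "PARAMETERS":
        _check_fields(ctx, loc, rec, block)
        if not _check_id(ctx, loc, rec.id):
            return
        value = _fnum(ctx, loc, fields.get("value", "0"))
        origin = fields.get("origin", "mechanistic")
        if origin not in PARAM_ORIGINS:
            ctx.rep.error("BAD_RECORD", loc, f"unknown parameter origin {origin!r}")
            origin = "mechanistic"
        ctx.model.parameters.append(Parameter(
            id=rec.id, value=value if value is not None else 0.0,
            constant=_fbool(ctx, loc, fields.get("constant", "true"), True),
            origin=origin, name=fields.get("name", "")))
    elif block == "REACTIONS":
        _check_fields(ctx, loc, rec, block)
        if not _check_id(ctx, loc, rec.id):
            return
        if "law" not in fields:
            ctx.rep.error("MISSING_FIELD", loc, f"reaction {rec.id!r} lacks field 'law'")
            return
        law = _fexpr(ctx, loc, fields["law"])
        try:
            reactants = _parse_species_refs(fields.get("reactants", ""))
            products = _parse_species_refs(fields.get("products", ""))
        except HmodError as exc:
            ctx.rep.error("BAD_RECORD", loc, str(exc))
            return
        if law is None:
            return
        ctx.model.reactions.append(Reaction(
            id=rec.id, reactants=reactants, products=products, kinetic_law=law,
            reversible=_fbool(ctx, loc, fields.get("reversible", "false"), False),
            name=fields.get("name", "")))
    elif block in ("RATE_RULES", "ASSIGNMENT_RULES"):
        _check_fields(ctx, loc, rec, block)
        if not _check_id(ctx, loc, rec.id):
            return
        if "expr" not in fields:
            ctx.rep.error("MISSING_FIELD", loc, f"rule {rec.id!r} lacks field 'expr'")
            return
        expr = _fexpr(ctx, loc, fields["expr"])
        if expr is None:
            return
        if block == "RATE_RULES":
            ctx.model.rate_rules.append(RateRule(variable=rec.id, expression=expr))
        else:
            ctx.model.assignment_rules.append(AssignmentRule(variable=rec.id, expression=expr))


def parse_hmod(text: str) -> tuple[Optional[KineticModel], Optional[AnnSpec], ValidationReport]:
    """Parse an HMOD document.

    Never raises: all problems are report entries.  With an ERROR-free
    report the fully resolved model is returned (plus the AnnSpec if an
    ``[ML]`` block is present); otherwise ``(None, None, report)``.
    """
    ctx = _Ctx()
    block: Optional[str] = None
    block_idx = -1

    for no, raw in enumerate(text.splitlines(), start=1):
        if any(ord(ch) > 127 for ch in raw):
            ctx.rep.error("NON_ASCII", f"line {no}",
                          "HMOD files must be pure ASCII")
            continue
        line = strip_comment(raw).strip()
        if not line:
            continue
        if line.startswith("["):
            m = _BLOCK_RE.match(line)
            name = m.group(1) if m else None
            if name is None or name not in BLOCK_ORDER:
                ctx.rep.error("UNKNOWN_BLOCK", f"line {no}", f"unknown block header {line!r}")
                block = None
                continue
            idx = BLOCK_ORDER.index(name)
            if idx <= block_idx:
                ctx.rep.error("ORDER_VIOLATION", f"line {no}",
                              f"block [{name}] out of order (canonical order: "
                              + " ".join(f"[{b}]" for b in BLOCK_ORDER) + ")")
                block = None
                continue
            block_idx = idx
            block = name
            if name == "ML":
                ctx.saw_ml = True
            continue
        if block is None:
            ctx.rep.error("ORDER_VIOLATION", f"line {no}",
                          "record appears outside any block")
            continue
        try:
            rec = parse_record(line, no)
        except LineFormatError as exc:
            ctx.rep.error("BAD_RECORD", f"{block}:line {no}", str(exc))
            continue
        if block == "ML":
            ctx.ml_records.append(rec)
        else:
            _handle_record(ctx, block, rec, f"{block}:line {no}")

    if not ctx.saw_header:
        ctx.rep.error("BAD_HEADER", "line 1",
                      f"missing [HMOD] block with 'format : version=\"{HMOD_VERSION}\"'")

    ann: Optional[AnnSpec] = None
    if ctx.saw_ml:
        ann = records_to_annspec(ctx.ml_records, ctx.rep, loc_prefix="ML")
        if ann is not None:
            model_ids = set(ctx.model.all_ids())
            for inp in ann.inputs:
                if inp.id not in model_ids:
                    ctx.rep.error("DANGLING_REF", "ML",
                                  f"ANN input references undefined id {inp.id!r}")
            for out in ann.outputs:
                pool = set(ctx.model.reaction_ids()) if out.kind == "reaction-rate" \
                    else set(ctx.model.parameter_ids())
                if out.target not in pool:
                    ctx.rep.error("DANGLING_REF", "ML",
                                  f"ANN output targets undefined {out.kind} {out.target!r}")

    ctx.rep.extend(check_consistency(ctx.model))
    rep = ctx.rep.sorted()
    if rep.has_errors():
        return None, None, rep
    return ctx.model, ann, rep


def validate_hmod(text: str) -> ValidationReport:
    """Full syntactic + semantic validation; empty report iff
    :func:`parse_hmod` succeeds without entries."""
    return parse_hmod(text)[2]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _clean_text(text: str) -> str:
    return " ".join(text.replace('"', "'").split())


def serialize_hmod(m: KineticModel, ann: Optional[AnnSpec] = None) -> str:
    """Serialize to canonical HMOD text (byte-deterministic).

    Refuses inconsistent models (raises :class:`HmodError` with the
    consistency report); a supplied AnnSpec is validated and written as
    the ``[ML]`` block.
    """
    rep = check_consistency(m)
    if rep.has_errors():
        raise HmodError("refusing to serialize inconsistent model:\n" + str(rep))
    if ann is not None:
        ann.validate()

    lines: list[str] = ["[HMOD]",
                        format_record("format", [("version", HMOD_VERSION)])]
    model_fields = [("id", m.id)]
    if m.name:
        model_fields.append(("name", _clean_text(m.name)))
    if m.notes:
        model_fields.append(("notes", _clean_text(m.notes)))
    lines.append(format_record("model", model_fields))

    lines.append("")
    lines.append("[COMPARTMENTS]")
    for c in m.compartments:
        fields = [("size", format_number(c.size)),
                  ("constant", "true" if c.constant else "false")]
        if c.name:
            fields.append(("name", _clean_text(c.name)))
        lines.append(format_record(c.id, fields))

    lines.append("")
    lines.append("[SPECIES]")
    for s in m.species:
        fields = [("compartment", s.compartment),
                  ("init", format_number(s.initial_concentration)),
                  ("boundary", "true" if s.boundary else "false"),
                  ("constant", "true" if s.constant else "false")]
        if s.name:
            fields.append(("name", _clean_text(s.name)))
        lines.append(format_record(s.id, fields))

    lines.append("")
    lines.append("[PARAMETERS]")
    for p in m.parameters:
        fields = [("value", format_number(p.value)),
                  ("constant", "true" if p.constant else "false"),
                  ("origin", p.origin)]
        if p.name:
            fields.append(("name", _clean_text(p.name)))
        lines.append(format_record(p.id, fields))

    lines.append("")
    lines.append("[REACTIONS]")
    for r in m.reactions:
        assert r.kinetic_law is not None
        fields = [("reactants", _format_species_refs(r.reactants)),
                  ("products", _format_species_refs(r.products)),
                  ("reversible", "true" if r.reversible else "false"),
                  ("law", write_infix(r.kinetic_law))]
        if r.name:
            fields.append(("name", _clean_text(r.name)))
        lines.append(format_record(r.id, fields))

    lines.append("")
    lines.append("[RATE_RULES]")
    for rr in m.rate_rules:
        lines.append(format_record(rr.variable, [("expr", write_infix(rr.expression))]))

    lines.append("")
    lines.append("[ASSIGNMENT_RULES]")
    for ar in m.assignment_rules:
        lines.append(format_record(ar.variable, [("expr", write_infix(ar.expression))]))

    if ann is not None:
        lines.append("")
        lines.append("[ML]")
        for rid, fields in annspec_to_records(ann):
            lines.append(format_record(rid, fields))

    return "\n".join(lines) + "\n"
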