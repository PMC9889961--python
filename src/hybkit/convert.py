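"""High-level converters between the SBML and HMOD representations.

These compose the format modules into the two pipeline directions:
``sbml_to_hmod`` (database model in, editable text out) and
``hmod_to_sbml`` (text in — with the machine-learning block compiled into
parameters and assignment rules — standard SBML out).
"""

from __future__ import annotations

from typing import Optional

from .ann import hybridize, HybridizationPlan
from .hmod import parse_hmod, serialize_hmod
from .report import ValidationReport
from .sbml import read_sbml, write_sbml


class ConversionError(ValueError):
    def __init__(self, message: str, report: Optional[ValidationReport] = None):
        super().__init__(message)
        self.report = report or ValidationReport()


def sbml_to_hmod(xml: str | bytes) -> tuple[str, ValidationReport]:
    """SBML document -> canonical HMOD text (plus the read report).

    An already-hybrid SBML model converts verbatim: its compiled
    assignment rules stay as mechanistic blocks.
    """
    m, rep = read_sbml(xml)
    return serialize_hmod(m), rep


def hmod_to_sbml(text: str) -> tuple[bytes, ValidationReport, Optional[HybridizationPlan]]:
    """HMOD text -> SBML L3V2 document.

    A document with an ``[ML]`` block is compiled on the way out: the
    network becomes constant parameters plus assignment rules wired to
    the targeted reaction rates.  Raises :class:`ConversionError`
    (carrying the report) if the document does not validate.
    """
    m, ann, rep = parse_hmod(text)
    if m is None:
        raise ConversionError("HMOD document failed validation", rep)
    plan = None
    if ann is not None:
        m, plan = hybridize(m, ann)
    return write_sbml(m), rep, plan
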