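"""Structured validation reports shared by all validators.

Validators never raise on bad input; every problem becomes an :class:`Issue`
inside a :class:`ValidationReport`.  Reports sort deterministically (by
location, then code) so serialized output is byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator


class Severity(str, Enum):
    ERROR = "ERROR"
    WARN = "WARN"


@dataclass(frozen=True)
class Issue:
    """One validation finding.

    ``code`` is a short stable machine identifier (e.g. ``DANGLING_REF``);
    ``location`` names the block/element/line the issue was found at.
    """

    severity: Severity
    code: str
    location: str
    message: str

    def format_line(self) -> str:
        """Tab-separated machine-readable rendering (one issue per line)."""
        return f"{self.severity.value}\t{self.code}\t{self.location}\t{self.message}"


@dataclass
class ValidationReport:
    entries: list[Issue] = field(default_factory=list)

    def add(self, severity: Severity, code: str, location: str, message: str) -> None:
        self.entries.append(Issue(severity, code, location, message))

    def error(self, code: str, location: str, message: str) -> None:
        self.add(Severity.ERROR, code, location, message)

    def warn(self, code: str, location: str, message: str) -> None:
        self.add(Severity.WARN, code, location, message)

    def extend(self, other: "ValidationReport") -> None:
        self.entries.extend(other.entries)

    def sorted(self) -> "ValidationReport":
        return ValidationReport(sorted(self.entries, key=lambda i: (i.location, i.code, i.message)))

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.entries if i.severity is Severity.ERROR]

    @property
    def warnings(self) -> list[Issue]:
        return [i for i in self.entries if i.severity is Severity.WARN]

    def has_errors(self) -> bool:
        return any(i.severity is Severity.ERROR for i in self.entries)

    def is_empty(self) -> bool:
        return not self.entries

    def codes(self) -> set[str]:
        return {i.code for i in self.entries}

    def __iter__(self) -> Iterator[Issue]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __str__(self) -> str:
        if not self.entries:
            return "(no issues)"
        return "\n".join(i.format_line() for i in self.sorted())


def merge(reports: Iterable[ValidationReport]) -> ValidationReport:
    out = ValidationReport()
    for r in reports:
        out.extend(r)
    return out
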