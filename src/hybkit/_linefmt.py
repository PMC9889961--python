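"""Line grammar shared by HMOD blocks and the ANN weight container.

One record per line: ``id : field=value, field=value``.  Values are bare
tokens (no spaces, commas or quotes) or double-quoted strings; ``#``
starts a comment; blank lines are ignored.  Serialization is canonical:
exactly one space around ``:``, one space after each comma.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_BARE_VALUE_RE = re.compile(r"[A-Za-z0-9_.+\-]+\Z")
_FIELD_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")


class LineFormatError(ValueError):
    pass


@dataclass
class Record:
    id: str
    fields: dict[str, str] = field(default_factory=dict)
    line_no: int = 0  # 1-based line in the source document, 0 if synthetic


def strip_comment(line: str) -> str:
    """Remove a ``#`` comment, respecting double quotes."""
    out = []
    in_quote = False
    for ch in line:
        if ch == '"':
            in_quote = not in_quote
        if ch == "#" and not in_quote:
            break
        out.append(ch)
    return "".join(out).rstrip()


def parse_record(line: str, line_no: int = 0) -> Record:
    """Parse one record line; raises :class:`LineFormatError` on bad grammar."""
    if ":" not in line:
        raise LineFormatError("record must have the form 'id : field=value, ...'")
    head, _, rest = line.partition(":")
    rid = head.strip()
    if not rid:
        raise LineFormatError("record id is empty")
    fields: dict[str, str] = {}
    for key, value in _split_fields(rest):
        if key in fields:
            raise LineFormatError(f"duplicate field {key!r}")
        fields[key] = value
    return Record(rid, fields, line_no)


def _split_fields(text: str):
    pos, n = 0, len(text)
    while pos < n:
        while pos < n and text[pos] in " \t":
            pos += 1
        if pos >= n:
            break
        eq = text.find("=", pos)
        if eq < 0:
            raise LineFormatError(f"expected field=value near {text[pos:pos + 20]!r}")
        key = text[pos:eq].strip()
        if not _FIELD_RE.match(key):
            raise LineFormatError(f"invalid field name {key!r}")
        pos = eq + 1
        while pos < n and text[pos] in " \t":
            pos += 1
        if pos < n and text[pos] == '"':
            end = text.find('"', pos + 1)
            if end < 0:
                raise LineFormatError("unterminated quoted value")
            value = text[pos + 1:end]
            pos = end + 1
        else:
            end = pos
            while end < n and text[end] not in ", \t":
                end += 1
            value = text[pos:end]
            if not value:
                raise LineFormatError(f"empty value for field {key!r}")
            if not _BARE_VALUE_RE.match(value):
                raise LineFormatError(f"bare value {value!r} contains forbidden characters")
            pos = end
        yield key, value
        while pos < n and text[pos] in " \t":
            pos += 1
        if pos < n:
            if text[pos] != ",":
                raise LineFormatError(f"expected ',' between fields near {text[pos:pos + 20]!r}")
            pos += 1


def format_value(value: str) -> str:
    if _BARE_VALUE_RE.match(value):
        return value
    if '"' in value:
        raise LineFormatError("values may not contain double quotes")
    return f'"{value}"'


def format_record(rid: str, fields: list[tuple[str, str]]) -> str:
    body = ", ".join(f"{k}={format_value(v)}" for k, v in fields)
    return f"{rid} : {body}"
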