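"""ICD-10 code normalisation, range expansion and code-set matching.

Code sets mix two granularities: a listed 3-character category (``F10``)
matches every subcode beneath it, while a listed 4-character code (``F100``,
i.e. F10.0) matches only itself and its own extensions.  Ranges such as
``C01-C06`` or ``S00-Y91`` span the letter-number grid of 3-character
categories, the letter carrying over (S00-Y91 covers S, T, ..., Y).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources

_CATEGORY_RE = re.compile(r"^[A-Z][0-9]{2}$")


def icd_normalize(code: str) -> str:
    """Upper-case, strip whitespace, drop the dot: ``"F10.0" -> "F100"``."""
    out = str(code).strip().upper().replace(".", "").replace("·", "")
    if not out:
        raise ValueError("empty ICD code")
    return out


def icd_expand_range(start: str, end: str) -> set[str]:
    """All 3-character categories between ``start`` and ``end`` inclusive."""
    start, end = icd_normalize(start), icd_normalize(end)
    for c in (start, end):
        if not _CATEGORY_RE.match(c):
            raise ValueError(f"range endpoint {c!r} is not a 3-character category")
    if end < start:
        raise ValueError(f"range end {end!r} precedes start {start!r}")
    out = set()
    for letter in (chr(o) for o in range(ord(start[0]), ord(end[0]) + 1)):
        lo = int(start[1:]) if letter == start[0] else 0
        hi = int(end[1:]) if letter == end[0] else 99
        out.update(f"{letter}{i:02d}" for i in range(lo, hi + 1))
    return out


@dataclass
class ICDCodeSet:
    """A named set of code prefixes plus category ranges."""

    name: str
    codes: set[str] = field(default_factory=set)
    ranges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = {icd_normalize(c) for c in self.codes}
        self.ranges = [(icd_normalize(a), icd_normalize(b)) for a, b in self.ranges]
        for a, b in self.ranges:
            if b < a:
                raise ValueError(f"range {a}-{b} is reversed")

    def __contains__(self, code: str) -> bool:
        return bool(icd_match(code, self))


def icd_match(code: str, codeset: ICDCodeSet) -> int:
    """1 if the code's normalised form matches the set (prefix or range)."""
    norm = icd_normalize(code)
    if any(norm.startswith(prefix) for prefix in codeset.codes):
        return 1
    category = norm[:3]
    # letter+2-digit categories compare correctly as strings
    return int(any(a <= category <= b for a, b in codeset.ranges))


def load_codesets() -> dict[str, ICDCodeSet]:
    """Code sets shipped with the package (editable JSON resources)."""
    raw = json.loads(
        resources.files("dfyears").joinpath("data/codesets.json").read_text()
    )
    return {
        name: ICDCodeSet(name=name, codes=set(d["codes"]), ranges=[tuple(r) for r in d["ranges"]])
        for name, d in raw.items()
    }
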