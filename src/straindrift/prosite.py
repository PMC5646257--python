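"""PROSITE pattern parsing and motif scanning.

Implements the standard PROSITE pattern syntax: elements separated by
``-``; ``x`` is a wildcard; ``[ABC]`` an allowed set; ``{ABC}`` an
exclusion set; ``(n)`` / ``(n,m)`` repeat counts; ``<`` and ``>``
anchor the match to the N or C terminus.  Scanning reports every match
at every offset (overlaps allowed) with 1-based inclusive coordinates,
which mirrors how repeat positions are reported for RTX-type proteins
(e.g. a nonamer at residues 2852-2860).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

from .errors import PatternSyntaxError

__all__ = [
    "PatternElement",
    "PrositePattern",
    "MotifHit",
    "parse_prosite_pattern",
    "scan_pattern",
    "load_ps00330",
]

_ELEMENT_RE = re.compile(
    r"^(?P<body>x|[A-Za-z]|\[[A-Za-z]+\]|\{[A-Za-z]+\})"
    r"(?:\((?P<lo>\d+)(?:,(?P<hi>\d+))?\))?$"
)

_AMINO = frozenset("ABCDEFGHIKLMNPQRSTUVWXYZ")


@dataclass(frozen=True)
class PatternElement:
    """One position matcher: an allowed-set (or exclusion) with a repeat range."""

    kind: str  # "any" | "include" | "exclude"
    residues: frozenset[str]
    min_rep: int
    max_rep: int

    def matches(self, aa: str) -> bool:
        if self.kind == "any":
            return aa in _AMINO
        if self.kind == "include":
            return aa in self.residues
        return aa in _AMINO and aa not in self.residues


@dataclass(frozen=True)
class PrositePattern:
    raw: str
    elements: tuple[PatternElement, ...]
    n_anchor: bool = False
    c_anchor: bool = False

    @property
    def min_span(self) -> int:
        return sum(e.min_rep for e in self.elements)

    @property
    def max_span(self) -> int:
        return sum(e.max_rep for e in self.elements)


@dataclass(frozen=True)
class MotifHit:
    """A pattern occurrence; ``start``/``end`` are 1-based inclusive."""

    protein_id: str
    start: int
    end: int
    matched: str


def parse_prosite_pattern(raw: str) -> PrositePattern:
    """Parse a PROSITE-syntax pattern into a :class:`PrositePattern`.

    Raises :class:`PatternSyntaxError` (with the character position of
    the offending token) on malformed input.
    """
    text = raw.strip().rstrip(".")
    if not text:
        raise PatternSyntaxError("empty pattern", 0)
    n_anchor = c_anchor = False
    offset = 0
    if text.startswith("<"):
        n_anchor = True
        text = text[1:]
        offset = 1
    if text.endswith(">"):
        c_anchor = True
        text = text[:-1]
    if "<" in text or ">" in text:
        raise PatternSyntaxError(
            "anchors are only supported at the pattern ends",
            raw.index("<", 1) if "<" in text else raw.rindex(">"),
        )
    elements: list[PatternElement] = []
    pos = offset
    for token in text.split("-"):
        m = _ELEMENT_RE.match(token)
        if m is None:
            raise PatternSyntaxError(f"malformed element {token!r}", pos)
        body = m.group("body")
        lo = int(m.group("lo")) if m.group("lo") else 1
        hi = int(m.group("hi")) if m.group("hi") else lo
        if lo < 1 or hi < lo:
            raise PatternSyntaxError(f"bad repeat range in {token!r}", pos)
        if body == "x":
            elem = PatternElement("any", frozenset(), lo, hi)
        elif body.startswith("["):
            elem = PatternElement("include", frozenset(body[1:-1].upper()), lo, hi)
        elif body.startswith("{"):
            elem = PatternElement("exclude", frozenset(body[1:-1].upper()), lo, hi)
        else:
            elem = PatternElement("include", frozenset(body.upper()), lo, hi)
        elements.append(elem)
        pos += len(token) + 1
    return PrositePattern(raw, tuple(elements), n_anchor, c_anchor)


def _match_exact(fragment: str, elements: tuple[PatternElement, ...]) -> bool:
    """True iff the whole fragment is consumed by the element list."""
    n = len(fragment)
    reachable = {0}
    for elem in elements:
        nxt: set[int] = set()
        for start in reachable:
            i = start
            # consume the mandatory repeats
            ok = True
            for _ in range(elem.min_rep):
                if i >= n or not elem.matches(fragment[i]):
                    ok = False
                    break
                i += 1
            if not ok:
                continue
            nxt.add(i)
            for _ in range(elem.max_rep - elem.min_rep):
                if i >= n or not elem.matches(fragment[i]):
                    break
                i += 1
                nxt.add(i)
        if not nxt:
            return False
        reachable = nxt
    return n in reachable


def scan_pattern(seq: str, pattern: PrositePattern, protein_id: str = "") -> list[MotifHit]:
    """All occurrences of ``pattern`` in ``seq`` (case-insensitive).

    Every (start, end) span that matches is reported, so overlapping
    hits and, for variable-length patterns, multiple spans from the
    same offset all appear.
    """
    s = seq.upper()
    n = len(s)
    lo, hi = pattern.min_span, pattern.max_span
    hits: list[MotifHit] = []
    starts = [0] if pattern.n_anchor else range(n)
    for start in starts:
        for length in range(lo, min(hi, n - start) + 1):
            if pattern.c_anchor and start + length != n:
                continue
            frag = s[start : start + length]
            if _match_exact(frag, pattern.elements):
                hits.append(MotifHit(protein_id, start + 1, start + length, frag))
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def load_ps00330() -> PrositePattern:
    """The hemolysin-type calcium-binding region signature, shipped as a
    replaceable config datum (update it from the current PROSITE release
    by editing ``data/ps00330.txt``)."""
    text = resources.files("straindrift.data").joinpath("ps00330.txt").read_text()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            return parse_prosite_pattern(line)
    raise PatternSyntaxError("no pattern found in bundled ps00330.txt", 0)
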