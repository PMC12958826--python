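"""Degenerate consensus-motif compilation, scanning and conservation calls.

Patterns are short linear consensus strings such as ``(S/T)xx(S/T)`` or
``[ST]xx[ST]``; all bracket/slash/dash dialects compile identically.
Scanning reports every matching window including overlapping ones, with
1-based inclusive coordinates.  ``X`` in a sequence never matches a class;
matching is case-insensitive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, Sequence

from .alignments import (
    GAP,
    Alignment,
    SequenceRecord,
    map_columns_to_reference,
)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: A pattern element: a frozenset of allowed residues, or None for wildcard.
Element = Optional[frozenset]


@dataclass(frozen=True)
class MotifPattern:
    name: str
    elements: tuple[Element, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("malformed consensus")
        for el in self.elements:
            if el is not None and (not el or not el <= STANDARD_AA):
                raise ValueError("malformed consensus")

    @property
    def length(self) -> int:
        return len(self.elements)

    def matches(self, window: str) -> bool:
        """True if ``window`` (length == pattern length) satisfies the pattern."""
        if len(window) != self.length:
            return False
        for ch, el in zip(window.upper(), self.elements):
            if el is not None and ch not in el:
                return False
        return True


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int
    end: int
    peptide: str
    pattern_name: str


@dataclass(frozen=True)
class ConservedMotifCall:
    hit: MotifHit
    ortholog_fraction: float
    conserved: bool


def _class_from_token(token: str) -> Element:
    letters = [c for c in token.upper() if c != "/"]
    if not letters:
        raise ValueError("malformed consensus")
    for c in letters:
        if c not in STANDARD_AA:
            raise ValueError("malformed consensus")
    return frozenset(letters)


def compile_pattern(consensus: str, name: Optional[str] = None) -> MotifPattern:
    """Compile a consensus string into a :class:`MotifPattern`.

    Accepted dialects (all equivalent): ``[ST]xx[ST]``, ``(S/T)xx(S/T)``
    and ``S/T-x-x-S/T``.  ``x``/``X`` is a wildcard position.
    """
    text = consensus.strip()
    if not text:
        raise ValueError("malformed consensus")
    elements: list[Element] = []
    if "-" in text:
        for token in text.split("-"):
            token = token.strip()
            if token in ("x", "X"):
                elements.append(None)
            elif token:
                elements.append(_class_from_token(token))
            else:
                raise ValueError("malformed consensus")
        return MotifPattern(name or consensus, tuple(elements))
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in "([":
            closer = ")" if ch == "(" else "]"
            j = text.find(closer, i + 1)
            if j == -1:
                raise ValueError("malformed consensus")
            elements.append(_class_from_token(text[i + 1 : j]))
            i = j + 1
        elif ch in "xX":
            elements.append(None)
            i += 1
        elif ch.upper() in STANDARD_AA:
            elements.append(frozenset(ch.upper()))
            i += 1
        else:
            raise ValueError("malformed consensus")
    return MotifPattern(name or consensus, tuple(elements))


def scan_sequence(
    seq: SequenceRecord,
    pattern: MotifPattern,
    region: Optional[tuple[int, int]] = None,
) -> list[MotifHit]:
    """All (overlapping) pattern matches, sorted by start position.

    A hit is reported when its start position lies inside ``region`` and
    the full window fits within the sequence; the window may extend past
    the region's right edge.
    """
    n = len(seq)
    if region is None:
        lo, hi = 1, n
    else:
        lo, hi = region
        if n == 0 or not (1 <= lo <= hi <= n):
            raise ValueError("region out of range")
    hits = []
    residues = seq.residues
    m = pattern.length
    for start in range(lo, hi + 1):
        if start + m - 1 > n:
            break
        window = residues[start - 1 : start - 1 + m]
        if pattern.matches(window):
            hits.append(MotifHit(seq.id, start, start + m - 1, window, pattern.name))
    return hits


def scan_alignment_conservation(
    aln: Alignment,
    pattern: MotifPattern,
    threshold: float = 0.5,
    slack: int = 2,
) -> list[ConservedMotifCall]:
    """Classify each reference motif hit by its conservation in other rows.

    For every hit on the (ungapped) reference, the alignment columns
    spanning the hit are extended by ``slack`` columns on each side; the
    corresponding window of each non-reference row is ungapped and
    re-scanned.  ``ortholog_fraction`` is the fraction of non-reference
    rows with at least one match inside that window.
    """
    ref_seq = aln.reference.ungapped()
    hits = scan_sequence(ref_seq, pattern)
    refmap = map_columns_to_reference(aln)
    others = [r for r in aln.rows if r.id != aln.reference_id]
    calls = []
    for hit in hits:
        col_start = max(1, refmap.column_of(hit.start) - slack)
        col_end = min(aln.n_cols, refmap.column_of(hit.end) + slack)
        matching = 0
        for row in others:
            window = row.residues[col_start - 1 : col_end].replace(GAP, "")
            if _window_has_match(window, pattern):
                matching += 1
        fraction = matching / len(others) if others else 0.0
        calls.append(ConservedMotifCall(hit, fraction, fraction >= threshold))
    return calls


def _window_has_match(window: str, pattern: MotifPattern) -> bool:
    m = pattern.length
    for i in range(len(window) - m + 1):
        if pattern.matches(window[i : i + m]):
            return True
    return False


def hits_to_tsv(
    hits: Sequence[MotifHit],
    fractions: Optional[Sequence[Optional[float]]] = None,
) -> str:
    buf = io.StringIO()
    buf.write("seq_id\tstart\tend\tpeptide\tpattern\tortholog_fraction\n")
    for i, h in enumerate(hits):
        frac = ""
        if fractions is not None and fractions[i] is not None:
            frac = f"{fractions[i]:.4f}"
        buf.write(f"{h.seq_id}\t{h.start}\t{h.end}\t{h.peptide}\t{h.pattern_name}\t{frac}\n")
    return buf.getvalue()
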