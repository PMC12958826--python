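"""Multiple-sequence-alignment conservation analysis.

Reads aligned FASTA / Clustal alignments, profiles per-column conservation,
maps alignment columns to reference-sequence numbering, detects conserved
sequence boxes and computes reference-vs-row identity/similarity.

Conventions
-----------
* All residue coordinates are 1-based and ranges are inclusive.
* A column is *strictly conserved* only if every row carries the same
  residue and the column contains no gaps.
* ``identity_fraction`` of a column uses the total row count as the
  denominator (gaps count as mismatches).  Pairwise identity between two
  rows instead uses only co-aligned (both non-gap) columns.  The two
  conventions are intentionally different.
"""

from __future__ import annotations

import io
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: Residues outside the 20-letter alphabet are coerced to X on input.
AMBIGUOUS_MAP = {"B": "X", "Z": "X", "U": "X", "O": "X", "J": "X", "*": "X"}

#: Default physico-chemical similarity groups (configurable everywhere they
#: are used).  Single-member groups make group membership total over the
#: standard alphabet.
DEFAULT_SIMILARITY_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("AVLIM"),
    frozenset("FWY"),
    frozenset("KRH"),
    frozenset("DE"),
    frozenset("STNQ"),
    frozenset("G"),
    frozenset("P"),
    frozenset("C"),
)


def same_similarity_group(
    a: str, b: str, groups: Sequence[frozenset[str]] = DEFAULT_SIMILARITY_GROUPS
) -> bool:
    """True if residues ``a`` and ``b`` share a similarity group."""
    return any(a in g and b in g for g in groups)


def _clean_residues(residues: str, *, allow_gap: bool, context: str = "") -> str:
    out = []
    for ch in residues.upper():
        if ch == ".":
            ch = GAP
        if ch in AMBIGUOUS_MAP:
            logger.warning("non-standard residue %r in %s mapped to X", ch, context or "sequence")
            ch = AMBIGUOUS_MAP[ch]
        if ch == GAP:
            if not allow_gap:
                raise ValueError(f"gap character not allowed in ungapped sequence {context}")
        elif ch not in STANDARD_AA and ch != "X":
            raise ValueError(f"illegal residue {ch!r} in {context or 'sequence'}")
        out.append(ch)
    return "".join(out)


@dataclass(frozen=True)
class SequenceRecord:
    """An ungapped protein sequence with 1-based residue positions."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residues", _clean_residues(self.residues, allow_gap=False, context=self.id)
        )

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"position {position} outside sequence {self.id!r}")
        return self.residues[position - 1]


@dataclass(frozen=True)
class AlignedRow:
    """A gapped alignment row."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residues", _clean_residues(self.residues, allow_gap=True, context=self.id)
        )

    def ungapped(self) -> SequenceRecord:
        return SequenceRecord(self.id, self.residues.replace(GAP, ""), self.description)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """Equal-length gapped rows with a designated reference row."""

    rows: list[AlignedRow]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("no rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("ragged alignment")
        if self.reference_id not in {r.id for r in self.rows}:
            raise KeyError("reference row not found")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def reference(self) -> AlignedRow:
        return next(r for r in self.rows if r.id == self.reference_id)

    def row(self, row_id: str) -> AlignedRow:
        for r in self.rows:
            if r.id == row_id:
                return r
        raise KeyError(f"row {row_id!r} not found")

    def column(self, col: int) -> str:
        """Column content (1-based) as a string, one character per row."""
        if not 1 <= col <= self.n_cols:
            raise IndexError(f"column {col} out of range")
        return "".join(r.residues[col - 1] for r in self.rows)


@dataclass(frozen=True)
class ColumnProfile:
    column: int
    residue_counts: Mapping[str, int]
    gap_count: int
    identity_fraction: float
    strictly_conserved: bool
    group_conserved: bool


@dataclass(frozen=True)
class ConservedBox:
    ref_start: int
    ref_end: int
    mean_identity: float
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_start > self.ref_end:
            raise ValueError("ref_start > ref_end")


@dataclass(frozen=True)
class PairwiseSimilarity:
    row_id: str
    identity_pct: Optional[float]
    similarity_pct: Optional[float]


@dataclass(frozen=True)
class ReferenceMap:
    """Two-way mapping between alignment columns and reference numbering."""

    col_to_ref: Mapping[int, int]
    ref_to_col: Mapping[int, int]

    def column_of(self, ref_pos: int) -> int:
        return self.ref_to_col[ref_pos]

    def ref_of(self, col: int) -> Optional[int]:
        return self.col_to_ref.get(col)


# ---------------------------------------------------------------------------
# reading


def _parse_fasta_rows(text: str) -> list[AlignedRow]:
    rows: list[AlignedRow] = []
    header: Optional[str] = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                name, _, desc = header.partition(" ")
                rows.append(AlignedRow(name, "".join(chunks), desc))
            header = line[1:].strip()
            chunks = []
        elif header is not None:
            chunks.append(line)
    if header is not None:
        name, _, desc = header.partition(" ")
        rows.append(AlignedRow(name, "".join(chunks), desc))
    return rows


def _parse_clustal_rows(text: str) -> list[AlignedRow]:
    order: list[str] = []
    parts: dict[str, list[str]] = {}
    lines = text.splitlines()
    for line in lines[1:]:  # skip the CLUSTAL header line
        if not line.strip() or line.startswith((" ", "\t")):
            continue  # conservation line or blank
        fields = line.split()
        if len(fields) < 2:
            continue
        name, seq = fields[0], fields[1]
        if set(seq) <= set("*:. "):
            continue
        if name not in parts:
            order.append(name)
            parts[name] = []
        parts[name].append(seq)
    return [AlignedRow(name, "".join(parts[name])) for name in order]


def read_alignment(path: str | Path, reference_id: str) -> Alignment:
    """Read an aligned-FASTA or Clustal file; format is auto-detected.

    Raises ``ValueError("ragged alignment")`` for unequal row lengths,
    ``ValueError("unrecognized alignment format")`` for unknown content and
    ``KeyError("reference row not found")`` for a missing reference id.
    """
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith(">"):
        rows = _parse_fasta_rows(text)
    elif stripped[:7].upper().startswith(("CLUSTAL", "MUSCLE")):
        rows = _parse_clustal_rows(text)
    else:
        raise ValueError("unrecognized alignment format")
    if not rows:
        raise ValueError("unrecognized alignment format")
    return Alignment(rows=rows, reference_id=reference_id)


def write_alignment_fasta(aln: Alignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for row in aln.rows:
            header = f">{row.id}" + (f" {row.description}" if row.description else "")
            fh.write(header + "\n")
            for i in range(0, len(row.residues), width):
                fh.write(row.residues[i : i + width] + "\n")


def write_alignment_clustal(aln: Alignment, path: str | Path, width: int = 60) -> None:
    name_w = max(len(r.id) for r in aln.rows) + 3
    with open(path, "w") as fh:
        fh.write("CLUSTAL W multiple sequence alignment\n\n")
        for start in range(0, aln.n_cols, width):
            for row in aln.rows:
                fh.write(f"{row.id:<{name_w}}{row.residues[start:start + width]}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# conservation


def column_profiles(
    aln: Alignment, groups: Sequence[frozenset[str]] = DEFAULT_SIMILARITY_GROUPS
) -> list[ColumnProfile]:
    """One :class:`ColumnProfile` per column.

    ``identity_fraction`` = (count of most common residue) / (number of
    rows); gaps never count toward the numerator.
    """
    profiles = []
    n = aln.n_rows
    for col in range(1, aln.n_cols + 1):
        chars = aln.column(col)
        gap_count = chars.count(GAP)
        counts = Counter(c for c in chars if c != GAP)
        top = max(counts.values()) if counts else 0
        strictly = gap_count == 0 and len(counts) == 1
        residues = set(counts)
        group_conserved = (
            gap_count == 0
            and bool(residues)
            and any(residues <= g for g in groups)
        )
        profiles.append(
            ColumnProfile(
                column=col,
                residue_counts=dict(counts),
                gap_count=gap_count,
                identity_fraction=top / n,
                strictly_conserved=strictly,
                group_conserved=group_conserved,
            )
        )
    return profiles


def map_columns_to_reference(aln: Alignment) -> ReferenceMap:
    """Map each non-gap reference column to the reference residue number."""
    col_to_ref: dict[int, int] = {}
    ref_to_col: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(aln.reference.residues, start=1):
        if ch != GAP:
            pos += 1
            col_to_ref[col] = pos
            ref_to_col[pos] = col
    return ReferenceMap(col_to_ref=col_to_ref, ref_to_col=ref_to_col)


def count_fully_conserved(
    aln: Alignment, ref_region: Optional[tuple[int, int]] = None
) -> int:
    """Number of strictly conserved columns, optionally restricted to the
    columns whose reference residue number lies in ``ref_region``."""
    profiles = column_profiles(aln)
    if ref_region is None:
        return sum(p.strictly_conserved for p in profiles)
    start, end = ref_region
    ref_len = len(aln.reference.ungapped())
    if not (1 <= start <= end <= ref_len):
        raise ValueError("region out of range")
    refmap = map_columns_to_reference(aln)
    total = 0
    for p in profiles:
        ref_pos = refmap.ref_of(p.column)
        if ref_pos is not None and start <= ref_pos <= end and p.strictly_conserved:
            total += 1
    return total


def detect_conserved_boxes(
    aln: Alignment,
    min_identity: float = 0.7,
    min_length: int = 3,
    max_below_run: int = 2,
) -> list[ConservedBox]:
    """Maximal runs of columns with identity >= ``min_identity``.

    Runs may bridge up to ``max_below_run`` consecutive sub-threshold
    columns; runs begin and end on above-threshold columns.  Boxes are
    reported in reference numbering and must span at least ``min_length``
    reference residues.  Labels are assigned alphabetically by position.
    """
    if not 0.0 <= min_identity <= 1.0:
        raise ValueError("min_identity must be within [0, 1]")
    if min_length < 1 or max_below_run < 0:
        raise ValueError("invalid box-detection thresholds")
    profiles = column_profiles(aln)
    above = [p.identity_fraction >= min_identity for p in profiles]
    runs: list[tuple[int, int]] = []  # 0-based column index ranges, inclusive
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        start = i
        end = i
        j = i + 1
        gap_run = 0
        while j < n:
            if above[j]:
                end = j
                gap_run = 0
            else:
                gap_run += 1
                if gap_run > max_below_run:
                    break
            j += 1
        runs.append((start, end))
        i = end + 1

    refmap = map_columns_to_reference(aln)
    boxes: list[ConservedBox] = []
    for start, end in runs:
        ref_positions = [
            refmap.ref_of(c) for c in range(start + 1, end + 2) if refmap.ref_of(c) is not None
        ]
        if not ref_positions:
            continue
        ref_start, ref_end = min(ref_positions), max(ref_positions)
        if ref_end - ref_start + 1 < min_length:
            continue
        identities = [profiles[c].identity_fraction for c in range(start, end + 1)]
        boxes.append(
            ConservedBox(
                ref_start=ref_start,
                ref_end=ref_end,
                mean_identity=sum(identities) / len(identities),
                label=None,
            )
        )
    boxes.sort(key=lambda b: b.ref_start)
    labelled = []
    for k, box in enumerate(boxes):
        label = "Box" + (chr(ord("A") + k) if k < 26 else str(k + 1))
        labelled.append(ConservedBox(box.ref_start, box.ref_end, box.mean_identity, label))
    return labelled


def pairwise_identity_similarity(
    aln: Alignment, groups: Sequence[frozenset[str]] = DEFAULT_SIMILARITY_GROUPS
) -> list[PairwiseSimilarity]:
    """Reference vs every other row, in percent.

    Identity: matching columns / co-aligned columns.  Similarity
    additionally counts columns whose residues share a similarity group.
    Pairs with zero co-aligned columns report missing values (None).
    """
    if aln.n_rows < 2:
        raise ValueError("need at least 2 rows")
    ref = aln.reference.residues
    out = []
    for row in aln.rows:
        if row.id == aln.reference_id:
            continue
        ident = simil = co = 0
        for a, b in zip(ref, row.residues):
            if a == GAP or b == GAP:
                continue
            co += 1
            if a == b:
                ident += 1
                simil += 1
            elif same_similarity_group(a, b, groups):
                simil += 1
        if co == 0:
            out.append(PairwiseSimilarity(row.id, None, None))
        else:
            out.append(PairwiseSimilarity(row.id, 100.0 * ident / co, 100.0 * simil / co))
    return out


# ---------------------------------------------------------------------------
# export


def profiles_to_tsv(aln: Alignment, profiles: Sequence[ColumnProfile]) -> str:
    refmap = map_columns_to_reference(aln)
    ref_row = aln.reference.residues
    buf = io.StringIO()
    buf.write("column\tref_pos\tref_aa\tidentity_fraction\tstrictly_conserved\tgroup_conserved\n")
    for p in profiles:
        ref_pos = refmap.ref_of(p.column)
        ref_aa = ref_row[p.column - 1]
        buf.write(
            f"{p.column}\t{ref_pos if ref_pos is not None else ''}\t"
            f"{ref_aa}\t{p.identity_fraction:.6g}\t"
            f"{int(p.strictly_conserved)}\t{int(p.group_conserved)}\n"
        )
    return buf.getvalue()


def boxes_to_json(boxes: Iterable[ConservedBox]) -> str:
    return json.dumps(
        [
            {
                "label": b.label,
                "ref_start": b.ref_start,
                "ref_end": b.ref_end,
                "mean_identity": round(b.mean_identity, 6),
            }
            for b in boxes
        ],
        indent=2,
    )
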