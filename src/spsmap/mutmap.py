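"""Mutation parsing/validation, structural neighborhoods and chain interfaces.

Mutant structures are never modeled: neighborhood reports describe the
wild-type environment of a mutated site.  A packaged catalog of the curated
sensor-complex mutants (with phenotype tags) ships with the package.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .alignments import SequenceRecord
from .structcontacts import (
    HYDROPHOBIC_AA,
    InteractionEdge,
    Residue,
    StructureModel,
    _edge,
    _min_pair_distance,
    _polar_atoms,
    detect_pipi,
    detect_salt_bridges,
    residue_min_distance,
)

PHENOTYPES = ("gain_of_function", "loss_of_function", "hypo_responsive", "other")

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True)
class MutationSpec:
    wt_aa: str
    position: int
    mut_aa: str
    phenotype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise ValueError("bad mutation syntax: wild-type equals mutant residue")
        if self.position < 1:
            raise ValueError("bad mutation syntax: non-positive position")
        if self.phenotype is not None and self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class ValidationEntry:
    spec: MutationSpec
    valid: bool
    observed: Optional[str]  # residue actually found at the position


@dataclass(frozen=True)
class ValidationReport:
    seq_id: str
    entries: tuple[ValidationEntry, ...]

    @property
    def n_valid(self) -> int:
        return sum(e.valid for e in self.entries)

    @property
    def invalid(self) -> tuple[ValidationEntry, ...]:
        return tuple(e for e in self.entries if not e.valid)


@dataclass(frozen=True)
class Neighbor:
    residue: tuple[str, int, str]
    distance: float
    edges: tuple[InteractionEdge, ...]


@dataclass(frozen=True)
class NeighborhoodReport:
    center: tuple[str, int, str]
    radius: float
    neighbors: tuple[Neighbor, ...]


@dataclass(frozen=True)
class InterfaceReport:
    chain_pair: tuple[str, str]
    cross_edges: tuple[InteractionEdge, ...]
    interface_residues: dict  # chain -> sorted residue number list


def parse_mutation(text: str, phenotype: Optional[str] = None) -> MutationSpec:
    """Parse a point-mutation label such as ``T382K``."""
    m = _MUTATION_RE.match(text.strip())
    if not m:
        raise ValueError(f"bad mutation syntax: {text!r}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return MutationSpec(wt, pos, mut, phenotype)


def load_mutant_catalog() -> list[dict]:
    """The packaged mutant annotation table.

    Rows have keys ``protein``, ``label`` (may be empty for site-only
    entries), ``site`` (1-based position), ``phenotype``.
    """
    text = resources.files("spsmap.data").joinpath("mutant_catalog.tsv").read_text()
    rows = []
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    for line in lines[1:]:
        rows.append(dict(zip(header, line.split("\t"))))
    for row in rows:
        row["site"] = int(row["site"])
        row["spec"] = parse_mutation(row["label"], row["phenotype"]) if row["label"] else None
    return rows


def validate_mutations(
    specs: Sequence[MutationSpec], seq: SequenceRecord
) -> ValidationReport:
    """Mark each spec valid iff the sequence carries the stated wild-type
    residue at the stated position.  Out-of-range positions are flagged,
    not fatal."""
    entries = []
    for spec in specs:
        if spec.position > len(seq):
            entries.append(ValidationEntry(spec, False, None))
        else:
            observed = seq.residue(spec.position)
            entries.append(ValidationEntry(spec, observed == spec.wt_aa, observed))
    return ValidationReport(seq.id, tuple(entries))


def _min_sidechain_distance(a: Residue, b: Residue) -> float:
    """Min side-chain heavy-atom distance, falling back to all heavy atoms
    for residues without side-chain atoms (Gly)."""
    atoms_a = a.side_chain_atoms() or a.atoms
    atoms_b = b.side_chain_atoms() or b.atoms
    d, _ = _min_pair_distance(atoms_a, atoms_b)
    return d


def _classify_pair(a: Residue, b: Residue) -> InteractionEdge:
    """Type a residue pair with the contact classifiers, in priority order
    salt bridge > H-bond > pi-pi > hydrophobic > generic."""
    from .structcontacts import ACIDIC_AA, BASIC_AA, CHARGED_GROUP_ATOMS

    if {a.aa1, b.aa1} & set(BASIC_AA) and {a.aa1, b.aa1} & set(ACIDIC_AA):
        basic, acidic = (a, b) if a.aa1 in BASIC_AA else (b, a)
        atoms_b = {n: basic.atoms[n] for n in CHARGED_GROUP_ATOMS[basic.aa1] if n in basic.atoms}
        atoms_a = {n: acidic.atoms[n] for n in CHARGED_GROUP_ATOMS[acidic.aa1] if n in acidic.atoms}
        if atoms_b and atoms_a:
            d, pair = _min_pair_distance(atoms_b, atoms_a)
            if d <= 4.5:
                return _edge("salt_bridge", basic, acidic, d, pair)
    pa, pb = _polar_atoms(a), _polar_atoms(b)
    if pa and pb:
        d, pair = _min_pair_distance(pa, pb)
        if d <= 3.6:
            return _edge("hbond", a, b, d, pair)
    ca, cb = a.ring_centroid(), b.ring_centroid()
    if ca is not None and cb is not None:
        d = float(np.linalg.norm(ca - cb))
        if d <= 5.5:
            return _edge("pipi", a, b, d, ("centroid", "centroid"))
    d, pair = _min_pair_distance(a.atoms, b.atoms)
    kind = "hydrophobic_contact" if a.aa1 in HYDROPHOBIC_AA and b.aa1 in HYDROPHOBIC_AA else "generic"
    return _edge(kind, a, b, d, pair)


def neighborhood(
    model: StructureModel, position, radius: float = 5.0
) -> NeighborhoodReport:
    """Residues within ``radius`` of a center residue by min side-chain
    heavy-atom distance (all-heavy fallback for Gly), each annotated with
    the typed contact it shares with the center."""
    center = model.residue(position)
    neighbors = []
    for res in model.residues:
        if res.key == center.key:
            continue
        d = _min_sidechain_distance(center, res)
        if d <= radius:
            edge = _classify_pair(center, res)
            neighbors.append(
                Neighbor((res.chain, res.number, res.aa1), d, (edge,))
            )
    neighbors.sort(key=lambda nb: (nb.residue[0], nb.residue[1]))
    return NeighborhoodReport((center.chain, center.number, center.aa1), radius, tuple(neighbors))


def interface_contacts(
    model: StructureModel, chain_a: str, chain_b: str, cutoff: float = 4.5
) -> InterfaceReport:
    """All cross-chain residue pairs with any-heavy-atom min distance within
    ``cutoff``, typed by the contact classifiers."""
    if len(model.chains) < 2:
        raise ValueError("need two chains")
    res_a = model.chain_residues(chain_a)
    res_b = model.chain_residues(chain_b)
    edges = []
    for a in res_a:
        for b in res_b:
            d, _ = _min_pair_distance(a.atoms, b.atoms)
            if d <= cutoff:
                edges.append(_classify_pair(a, b))
    edges.sort(key=lambda e: (e.residue_a[1], e.residue_b[1]))
    residues_by_chain = {chain_a: set(), chain_b: set()}
    for e in edges:
        for ch, num, _aa in (e.residue_a, e.residue_b):
            if ch in residues_by_chain:
                residues_by_chain[ch].add(num)
    return InterfaceReport(
        chain_pair=(chain_a, chain_b),
        cross_edges=tuple(edges),
        interface_residues={ch: sorted(v) for ch, v in residues_by_chain.items()},
    )


# ---------------------------------------------------------------------------
# export


def validation_to_tsv(report: ValidationReport) -> str:
    buf = io.StringIO()
    buf.write("label\tposition\texpected\tobserved\tvalid\n")
    for e in report.entries:
        buf.write(
            f"{e.spec.label}\t{e.spec.position}\t{e.spec.wt_aa}\t"
            f"{e.observed or ''}\t{int(e.valid)}\n"
        )
    return buf.getvalue()


def neighborhood_to_json(report: NeighborhoodReport) -> str:
    return json.dumps(
        {
            "center": list(report.center),
            "radius": report.radius,
            "neighbors": [
                {
                    "residue": list(nb.residue),
                    "distance": round(nb.distance, 3),
                    "contacts": [
                        {"kind": e.kind, "distance": round(e.distance, 3)} for e in nb.edges
                    ],
                }
                for nb in report.neighbors
            ],
        },
        indent=2,
    )


def interface_to_tsv(report: InterfaceReport) -> str:
    from .structcontacts import edges_to_tsv

    return edges_to_tsv(report.cross_edges)
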