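"""Structure-model parsing, typed contact detection and score-track analysis.

Structures are read from PDB or mmCIF files (first model, heavy atoms only,
author residue numbering).  Contact detectors use distance-only criteria:
the models analysed here carry no hydrogens, so no angle terms are applied.

Atom conventions
----------------
salt bridges   basic-nitrogen set (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2)
               vs acidic-oxygen set (Asp OD1/OD2; Glu OE1/OE2)
H-bond proxy   any N/O heavy-atom pair (side chain and backbone)
pi-pi          aromatic ring-centroid pair (F/Y/W/H)
sulfur pair    Cys SG vs Cys SG
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

CHARGED_GROUP_ATOMS = {
    "K": ("NZ",),
    "R": ("NE", "NH1", "NH2"),
    "H": ("ND1", "NE2"),
    "D": ("OD1", "OD2"),
    "E": ("OE1", "OE2"),
}
BASIC_AA = ("K", "R", "H")
ACIDIC_AA = ("D", "E")

RING_ATOMS = {
    "F": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "Y": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "W": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "H": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

HYDROPHOBIC_AA = set("AVLIMFWYP")

INTERACTION_KINDS = ("salt_bridge", "hbond", "pipi", "hydrophobic_contact", "sulfur_pair", "generic")


@dataclass
class Residue:
    """One residue: author number, names and heavy-atom coordinates."""

    chain: str
    number: int
    aa3: str
    atoms: dict  # atom name -> np.ndarray (3,)
    elements: dict = field(default_factory=dict)  # atom name -> element symbol
    confidence: Optional[float] = None

    @property
    def aa1(self) -> str:
        return AA3_TO_1.get(self.aa3, "X")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.number)

    def side_chain_atoms(self) -> dict:
        return {n: c for n, c in self.atoms.items() if n not in BACKBONE_ATOMS}

    def scoped_atoms(self, scope: str) -> dict:
        """Atom subset for a distance scope; raises on an empty scope."""
        if scope == "all_heavy":
            sel = dict(self.atoms)
        elif scope == "side_chain":
            sel = self.side_chain_atoms()
        elif scope == "charged_group":
            names = CHARGED_GROUP_ATOMS.get(self.aa1, ())
            sel = {n: self.atoms[n] for n in names if n in self.atoms}
        elif scope == "SG_only":
            sel = {n: c for n, c in self.atoms.items() if n == "SG"}
        else:
            raise ValueError(f"unknown atom scope {scope!r}")
        if not sel:
            raise ValueError(f"no atoms in scope {scope!r} for {self.chain}:{self.number}")
        return sel

    def ring_centroid(self) -> Optional[np.ndarray]:
        names = RING_ATOMS.get(self.aa1)
        if names is None:
            return None
        coords = [self.atoms[n] for n in names if n in self.atoms]
        if len(coords) < 3:
            return None
        return np.mean(coords, axis=0)


@dataclass
class StructureModel:
    """Ordered chains of residues with heavy-atom coordinates."""

    residues: list[Residue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty model")
        seen = set()
        for r in self.residues:
            if r.key in seen:
                raise ValueError(f"duplicate residue {r.key}")
            seen.add(r.key)
        self._index = {r.key: r for r in self.residues}

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain not in out:
                out.append(r.chain)
        return out

    def chain_residues(self, chain: str) -> list[Residue]:
        res = [r for r in self.residues if r.chain == chain]
        if not res:
            raise KeyError(f"chain {chain!r} not found")
        return res

    def residue(self, selector: Union[tuple[str, int], int, str]) -> Residue:
        chain, number = self._parse_selector(selector)
        try:
            return self._index[(chain, number)]
        except KeyError:
            raise KeyError(f"residue not found: {chain}:{number}") from None

    def _parse_selector(self, selector) -> tuple[str, int]:
        if isinstance(selector, Residue):
            return selector.key
        if isinstance(selector, tuple):
            return selector
        if isinstance(selector, int):
            if len(self.chains) != 1:
                raise ValueError("bare residue number is ambiguous in a multi-chain model")
            return (self.chains[0], selector)
        if isinstance(selector, str):
            chain, _, num = selector.partition(":")
            if num:
                return (chain, int(num))
            # forms like "E355" on a single-chain model
            if len(self.chains) == 1 and selector[0].isalpha() and selector[1:].isdigit():
                return (self.chains[0], int(selector[1:]))
        raise ValueError(f"cannot parse residue selector {selector!r}")

    def sequence(self, chain: Optional[str] = None) -> str:
        chain = chain or self.chains[0]
        return "".join(r.aa1 for r in self.chain_residues(chain))


@dataclass(frozen=True)
class InteractionEdge:
    kind: str
    residue_a: tuple[str, int, str]  # (chain, number, aa1)
    residue_b: tuple[str, int, str]
    distance: float
    atoms: tuple[str, str]

    def __post_init__(self) -> None:
        if self.kind not in INTERACTION_KINDS:
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if self.distance < 0:
            raise ValueError("negative distance")


@dataclass(frozen=True)
class ResidueCluster:
    kind: str
    members: tuple[tuple[str, int, str], ...]
    max_internal_gap: float


@dataclass(frozen=True)
class ScoreTrack:
    residue_numbers: np.ndarray
    values: np.ndarray
    kind: str  # "disorder" (0-1) or "plddt" (0-100)

    def __post_init__(self) -> None:
        if self.kind not in ("disorder", "plddt"):
            raise ValueError(f"unknown track kind {self.kind!r}")
        nums = np.asarray(self.residue_numbers)
        if len(nums) and np.any(np.diff(nums) <= 0):
            raise ValueError("residue numbering must be strictly increasing")
        lo, hi = (0.0, 1.0) if self.kind == "disorder" else (0.0, 100.0)
        vals = np.asarray(self.values, dtype=float)
        if len(vals) and (vals.min() < lo - 1e-9 or vals.max() > hi + 1e-9):
            raise ValueError(f"values outside the {self.kind} range [{lo}, {hi}]")


@dataclass(frozen=True)
class TrackSegment:
    start: int
    end: int
    mean_score: float


# ---------------------------------------------------------------------------
# reading / writing


def read_structure(path: str | Path, plddt_in_bfactor: bool = False) -> StructureModel:
    """Read a PDB or mmCIF structure (first model, heavy atoms only).

    Author residue numbering is preserved.  When ``plddt_in_bfactor`` is
    set, per-residue confidence is filled from the temperature-factor
    column (the AlphaFold convention).
    """
    import biotite.structure.io.pdb as pdb
    import biotite.structure.io.pdbx as pdbx
    from biotite.structure import get_residue_starts

    path = Path(path)
    text_head = path.read_text(errors="replace")[:4000].lstrip()
    try:
        if path.suffix.lower() in (".cif", ".mmcif") or text_head.startswith("data_"):
            cif = pdbx.CIFFile.read(str(path))
            atoms = pdbx.get_structure(
                cif, model=1, use_author_fields=True, extra_fields=["b_factor"]
            )
        else:
            pdb_file = pdb.PDBFile.read(str(path))
            atoms = pdb_file.get_structure(model=1, extra_fields=["b_factor"])
    except Exception as exc:
        raise ValueError(f"bad structure file: {path}") from exc
    atoms = atoms[atoms.element != "H"]
    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise ValueError(f"bad structure file (no polymer atoms): {path}")

    residues: list[Residue] = []
    starts = list(get_residue_starts(atoms)) + [atoms.array_length()]
    for s, e in zip(starts[:-1], starts[1:]):
        sub = atoms[s:e]
        name3 = sub.res_name[0]
        res = Residue(
            chain=str(sub.chain_id[0]),
            number=int(sub.res_id[0]),
            aa3=str(name3),
            atoms={str(n): np.array(c, dtype=float) for n, c in zip(sub.atom_name, sub.coord)},
            elements={str(n): str(el) for n, el in zip(sub.atom_name, sub.element)},
            confidence=float(np.mean(sub.b_factor)) if plddt_in_bfactor else None,
        )
        residues.append(res)
    return StructureModel(residues)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a minimal single-model PDB file (coordinates to 0.001 A)."""
    serial = 0
    with open(path, "w") as fh:
        for res in model.residues:
            for name, coord in res.atoms.items():
                serial += 1
                element = res.elements.get(name, name[0])
                bfac = res.confidence if res.confidence is not None else 0.0
                atom_field = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {serial:5d} {atom_field}{'':1s}{res.aa3:>3s} "
                    f"{res.chain[:1]}{res.number:4d}    "
                    f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
                    f"{1.00:6.2f}{bfac:6.2f}          {element:>2s}\n"
                )
        fh.write("END\n")


def read_track(path: str | Path, kind: str) -> ScoreTrack:
    """Read a 2-column whitespace-separated (residue, score) track file."""
    nums, vals = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split()[:2]
        nums.append(int(a))
        vals.append(float(b))
    return ScoreTrack(np.array(nums), np.array(vals), kind)


def write_track(track: ScoreTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for n, v in zip(track.residue_numbers, track.values):
            fh.write(f"{int(n)}\t{v:.6f}\n")


def plddt_track(model: StructureModel, chain: Optional[str] = None) -> ScoreTrack:
    """Per-residue confidence track from a model read with pLDDT in B-factor."""
    chain = chain or model.chains[0]
    res = model.chain_residues(chain)
    if any(r.confidence is None for r in res):
        raise ValueError("model has no per-residue confidence; read with plddt_in_bfactor=True")
    return ScoreTrack(
        np.array([r.number for r in res]),
        np.array([r.confidence for r in res]),
        "plddt",
    )


# ---------------------------------------------------------------------------
# distances and detectors


def _min_pair_distance(atoms_a: dict, atoms_b: dict) -> tuple[float, tuple[str, str]]:
    names_a = list(atoms_a)
    names_b = list(atoms_b)
    ca = np.array([atoms_a[n] for n in names_a])
    cb = np.array([atoms_b[n] for n in names_b])
    d2 = ((ca[:, None, :] - cb[None, :, :]) ** 2).sum(axis=-1)
    i, j = np.unravel_index(int(d2.argmin()), d2.shape)
    return float(math.sqrt(d2[i, j])), (names_a[i], names_b[j])


def residue_min_distance(
    model: StructureModel,
    res_a,
    res_b,
    atom_scope: str = "all_heavy",
) -> tuple[float, tuple[str, str]]:
    """Minimum pairwise distance between two residues over an atom scope.

    Scopes: ``all_heavy`` | ``side_chain`` | ``charged_group`` | ``SG_only``.
    Returns ``(distance, (atom_a, atom_b))``.
    """
    a = model.residue(res_a)
    b = model.residue(res_b)
    if a.key == b.key:
        return 0.0, ("", "")
    return _min_pair_distance(a.scoped_atoms(atom_scope), b.scoped_atoms(atom_scope))


def _edge(kind: str, a: Residue, b: Residue, distance: float, atoms: tuple[str, str]) -> InteractionEdge:
    return InteractionEdge(
        kind=kind,
        residue_a=(a.chain, a.number, a.aa1),
        residue_b=(b.chain, b.number, b.aa1),
        distance=distance,
        atoms=atoms,
    )


def detect_salt_bridges(model: StructureModel, cutoff: float = 4.5) -> list[InteractionEdge]:
    """Basic-nitrogen vs acidic-oxygen contacts within ``cutoff``.

    One edge per residue pair, keeping the minimum-distance atom pair.
    """
    basics = [r for r in model.residues if r.aa1 in BASIC_AA]
    acidics = [r for r in model.residues if r.aa1 in ACIDIC_AA]
    edges = []
    for rb in basics:
        atoms_b = {n: rb.atoms[n] for n in CHARGED_GROUP_ATOMS[rb.aa1] if n in rb.atoms}
        if not atoms_b:
            continue
        for ra in acidics:
            atoms_a = {n: ra.atoms[n] for n in CHARGED_GROUP_ATOMS[ra.aa1] if n in ra.atoms}
            if not atoms_a:
                continue
            d, pair = _min_pair_distance(atoms_b, atoms_a)
            if d <= cutoff:
                edges.append(_edge("salt_bridge", rb, ra, d, pair))
    edges.sort(key=lambda e: (e.residue_a, e.residue_b))
    return edges


def _polar_atoms(res: Residue) -> dict:
    return {
        n: c
        for n, c in res.atoms.items()
        if res.elements.get(n, n[0]) in ("N", "O")
    }


def detect_hbond_pairs(
    model: StructureModel,
    pairs: Optional[Sequence[tuple]] = None,
    cutoff: float = 3.6,
    exclude_adjacent: int = 1,
) -> list[InteractionEdge]:
    """N/O donor-acceptor heavy-atom contacts within ``cutoff`` (no angle
    term; the models carry no hydrogens).

    Residues closer than ``exclude_adjacent`` in sequence on the same chain
    are skipped (peptide-bond neighbors trivially satisfy the cutoff).
    When ``pairs`` is given only those residue pairs are evaluated (with no
    adjacency exclusion).
    """
    edges = []
    if pairs is not None:
        for sel_a, sel_b in pairs:
            a, b = model.residue(sel_a), model.residue(sel_b)
            d, atom_pair = _min_pair_distance(_polar_atoms(a), _polar_atoms(b))
            if d <= cutoff:
                edges.append(_edge("hbond", a, b, d, atom_pair))
        return edges
    residues = model.residues
    for i, a in enumerate(residues):
        pa = _polar_atoms(a)
        if not pa:
            continue
        for b in residues[i + 1 :]:
            if b.chain == a.chain and abs(b.number - a.number) <= exclude_adjacent:
                continue
            pb = _polar_atoms(b)
            if not pb:
                continue
            d, atom_pair = _min_pair_distance(pa, pb)
            if d <= cutoff:
                edges.append(_edge("hbond", a, b, d, atom_pair))
    edges.sort(key=lambda e: (e.residue_a, e.residue_b))
    return edges


def detect_pipi(model: StructureModel, centroid_cutoff: float = 5.5) -> list[InteractionEdge]:
    """Aromatic ring-centroid pairs within ``centroid_cutoff``."""
    aromatics = [
        (r, c) for r in model.residues if (c := r.ring_centroid()) is not None
    ]
    edges = []
    for i, (a, ca) in enumerate(aromatics):
        for b, cb in aromatics[i + 1 :]:
            d = float(np.linalg.norm(ca - cb))
            if d <= centroid_cutoff:
                edges.append(_edge("pipi", a, b, d, ("centroid", "centroid")))
    edges.sort(key=lambda e: (e.residue_a, e.residue_b))
    return edges


def detect_clusters(
    model: StructureModel,
    kind: str,
    contact_cutoff: Optional[float] = None,
    min_size: int = 2,
) -> list[ResidueCluster]:
    """Single-linkage residue clusters over side-chain contacts.

    ``hydrophobic``: side-chain heavy atoms of A/V/L/I/M/F/W/Y/P at <= 4.5 A
    (default); ``sulfur``: Cys SG atoms at <= 4.0 A (default).  Clusters are
    ordered (and their members listed) by (chain, residue number).
    """
    if kind == "hydrophobic":
        cutoff = 4.5 if contact_cutoff is None else contact_cutoff
        members = [
            (r, sc) for r in model.residues
            if r.aa1 in HYDROPHOBIC_AA and (sc := r.side_chain_atoms())
        ]
    elif kind == "sulfur":
        cutoff = 4.0 if contact_cutoff is None else contact_cutoff
        members = [
            (r, {"SG": r.atoms["SG"]}) for r in model.residues
            if r.aa1 == "C" and "SG" in r.atoms
        ]
    else:
        raise ValueError(f"unknown cluster kind {kind!r}")

    members.sort(key=lambda m: m[0].key)
    n = len(members)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    dist = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            d, _ = _min_pair_distance(members[i][1], members[j][1])
            dist[i, j] = dist[j, i] = d
            if d <= cutoff:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    clusters = []
    for idxs in groups.values():
        if len(idxs) < min_size:
            continue
        idxs.sort(key=lambda i: members[i][0].key)
        # largest nearest-neighbor distance inside the cluster
        max_gap = 0.0
        for i in idxs:
            nn = min(dist[i, j] for j in idxs if j != i)
            max_gap = max(max_gap, nn)
        clusters.append(
            ResidueCluster(
                kind=kind,
                members=tuple(
                    (members[i][0].chain, members[i][0].number, members[i][0].aa1) for i in idxs
                ),
                max_internal_gap=float(max_gap),
            )
        )
    clusters.sort(key=lambda c: c.members[0][:2])
    return clusters


# ---------------------------------------------------------------------------
# score-track segmentation


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return values.astype(float)
    half = window // 2
    out = np.empty(len(values))
    for i in range(len(values)):
        lo = max(0, i - half)
        hi = min(len(values), i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def segment_track(
    track: ScoreTrack,
    threshold: float,
    direction: str,
    min_length: int = 10,
    smooth_window: int = 1,
) -> list[TrackSegment]:
    """Maximal runs where the moving-average score is strictly on the given
    side of ``threshold`` (``above`` or ``below``), of length >= ``min_length``.

    The moving average uses a centered window (``smooth_window`` odd),
    shrunk at the track edges.  Reported ``mean_score`` is the mean of the
    raw (unsmoothed) scores over the segment.  Breaks in residue numbering
    terminate runs.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    values = np.asarray(track.values, dtype=float)
    nums = np.asarray(track.residue_numbers)
    smoothed = _moving_average(values, smooth_window)
    passing = smoothed > threshold if direction == "above" else smoothed < threshold

    segments = []
    i = 0
    n = len(values)
    while i < n:
        if not passing[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and passing[j + 1] and nums[j + 1] == nums[j] + 1:
            j += 1
        length = int(nums[j] - nums[i] + 1)
        if length >= min_length:
            segments.append(
                TrackSegment(int(nums[i]), int(nums[j]), float(values[i : j + 1].mean()))
            )
        i = j + 1
    return segments


# ---------------------------------------------------------------------------
# export


def edges_to_tsv(edges: Iterable[InteractionEdge]) -> str:
    buf = io.StringIO()
    buf.write("kind\tchain_a\tres_a\taa_a\tchain_b\tres_b\taa_b\tdistance\tatom_a\tatom_b\n")
    for e in edges:
        buf.write(
            f"{e.kind}\t{e.residue_a[0]}\t{e.residue_a[1]}\t{e.residue_a[2]}\t"
            f"{e.residue_b[0]}\t{e.residue_b[1]}\t{e.residue_b[2]}\t"
            f"{e.distance:.3f}\t{e.atoms[0]}\t{e.atoms[1]}\n"
        )
    return buf.getvalue()


def clusters_to_json(clusters: Iterable[ResidueCluster]) -> str:
    return json.dumps(
        [
            {
                "kind": c.kind,
                "members": [f"{ch}:{num}{aa}" for ch, num, aa in c.members],
                "max_internal_gap": round(c.max_internal_gap, 3),
            }
            for c in clusters
        ],
        indent=2,
    )


def segments_to_tsv(segments: Iterable[TrackSegment]) -> str:
    buf = io.StringIO()
    buf.write("start\tend\tmean_score\n")
    for s in segments:
        buf.write(f"{s.start}\t{s.end}\t{s.mean_score:.4f}\n")
    return buf.getvalue()
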