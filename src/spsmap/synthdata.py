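"""Seeded synthetic fixtures with machine-readable planted ground truth.

Generators emit alignments with planted conserved boxes and motif
occurrences, single- and multi-chain structures with residue pairs placed
at requested scoped distances, and step-structured score tracks.  Every
generator is deterministic for a fixed seed, and each returns a
:class:`PlantedTruth` that exactly describes the emitted fixture.

Structure geometry is idealized (single rotamer templates on a widely
spaced backbone line): the goal is controllable geometry, not physical
realism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .alignments import AlignedRow, Alignment, STANDARD_AA
from .motifscan import MotifPattern, compile_pattern, scan_sequence
from .structcontacts import (
    AA1_TO_3,
    CHARGED_GROUP_ATOMS,
    RING_ATOMS,
    Residue,
    StructureModel,
)

AA = STANDARD_AA  # 20 letters

#: Slot spacing along the backbone line; keeps non-planted residue pairs
#: comfortably beyond every detector cutoff.
_SLOT_SPACING = 24.0
_MIN_SEPARATION = 8.0
_DIRECTIONS = (
    np.array([0.0, 1.0, 0.0]),
    np.array([1.0, 0.0, 0.0]),
    np.array([0.0, 0.0, 1.0]),
    np.array([0.0, -1.0, 0.0]),
    np.array([0.0, 0.0, -1.0]),
)


@dataclass(frozen=True)
class PlantedTruth:
    kind: str  # box | motif | contact | interface | segment | mixed
    features: tuple
    params: dict
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "features": list(self.features),
             "params": self.params, "seed": self.seed},
            indent=2,
            default=str,
        )


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json() + "\n")


# ---------------------------------------------------------------------------
# alignments


def _random_peptide(pattern: MotifPattern, rng: np.random.Generator) -> str:
    out = []
    for el in pattern.elements:
        if el is None:
            out.append(AA[rng.integers(len(AA))])
        else:
            choices = sorted(el)
            out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _nonmatching_window(pattern: MotifPattern, rng: np.random.Generator) -> str:
    for _ in range(10_000):
        window = "".join(AA[rng.integers(len(AA))] for _ in range(pattern.length))
        if not pattern.matches(window):
            return window
    raise ValueError("cannot draw a non-matching window for this pattern")


def synth_alignment(
    n_rows: int,
    length: int,
    boxes: Sequence[tuple[int, int, float]] = (),
    motifs: Sequence[tuple] = (),
    seed: int = 0,
    ref_id: str = "ref",
    gap_rate: float = 0.0,
) -> tuple[Alignment, PlantedTruth]:
    """Random-background alignment with planted conserved boxes and motifs.

    ``boxes``: (start, end, identity_level) in reference numbering; box
    columns copy the reference residue with per-row probability
    ``identity_level``.  ``motifs``: (pattern or consensus, ref_start,
    ortholog_fraction); exactly ``round(fraction * (n_rows - 1))``
    non-reference rows carry a match at the planted window, all others are
    guaranteed not to match it.  Optional uniform ``gap_rate`` introduces
    gaps in background columns of non-reference rows.
    """
    if n_rows < 2 or length < 1:
        raise ValueError("need n_rows >= 2 and length >= 1")
    rng = np.random.default_rng(seed)

    compiled = [
        (pat if isinstance(pat, MotifPattern) else compile_pattern(pat), start, frac)
        for pat, start, frac in motifs
    ]

    # claim columns and check plants for contradictions
    claimed = np.zeros(length + 1, dtype=int)  # 0 free, 1 box, 2 motif
    for start, end, level in boxes:
        if not (1 <= start <= end <= length) or not 0.0 <= level <= 1.0:
            raise ValueError("box plant outside alignment or bad identity level")
        if claimed[start : end + 1].any():
            raise ValueError("conflicting plants")
        claimed[start : end + 1] = 1
    for pat, start, frac in compiled:
        end = start + pat.length - 1
        if not (1 <= start and end <= length) or not 0.0 <= frac <= 1.0:
            raise ValueError("motif plant outside alignment or bad fraction")
        if claimed[start : end + 1].any():
            raise ValueError("conflicting plants")
        claimed[start : end + 1] = 2

    # reference sequence: background + planted motif peptides
    ref = [AA[rng.integers(len(AA))] for _ in range(length)]
    for pat, start, _frac in compiled:
        peptide = _random_peptide(pat, rng)
        ref[start - 1 : start - 1 + pat.length] = list(peptide)

    # scrub accidental reference matches of any planted pattern outside the
    # planted windows (so planted truth is the complete hit set)
    from .alignments import SequenceRecord

    planted_starts = {(pat.name, start) for pat, start, _ in compiled}
    for _ in range(1000):
        dirty = False
        for pat, _start, _frac in compiled:
            for hit in scan_sequence(SequenceRecord("ref", "".join(ref)), pat):
                if (pat.name, hit.start) in planted_starts:
                    continue
                free = [c for c in range(hit.start, hit.end + 1) if claimed[c] != 2]
                if not free:
                    raise ValueError("conflicting plants")
                col = free[rng.integers(len(free))]
                ref[col - 1] = AA[rng.integers(len(AA))]
                dirty = True
        if not dirty:
            break
    else:
        raise ValueError("could not scrub accidental reference motif matches")

    # ortholog rows
    n_orth = n_rows - 1
    rows = [["?"] * length for _ in range(n_orth)]
    box_cols = {c for s, e, _ in boxes for c in range(s, e + 1)}
    motif_cols = {
        c for pat, s, _ in compiled for c in range(s, s + pat.length)
    }
    for i in range(n_orth):
        for c in range(1, length + 1):
            if c in box_cols or c in motif_cols:
                continue
            if gap_rate > 0 and rng.random() < gap_rate:
                rows[i][c - 1] = "-"
            else:
                rows[i][c - 1] = AA[rng.integers(len(AA))]
    for start, end, level in boxes:
        for i in range(n_orth):
            for c in range(start, end + 1):
                if rng.random() < level:
                    rows[i][c - 1] = ref[c - 1]
                else:
                    alternatives = [a for a in AA if a != ref[c - 1]]
                    rows[i][c - 1] = alternatives[rng.integers(len(alternatives))]

    motif_truth = []
    for pat, start, frac in compiled:
        k = round(frac * n_orth)
        chosen = sorted(rng.choice(n_orth, size=k, replace=False).tolist()) if k else []
        chosen_set = set(chosen)
        for i in range(n_orth):
            if i in chosen_set:
                window = _random_peptide(pat, rng)
            else:
                window = _nonmatching_window(pat, rng)
            rows[i][start - 1 : start - 1 + pat.length] = list(window)
        motif_truth.append(
            {
                "pattern": pat.name,
                "ref_start": start,
                "ref_end": start + pat.length - 1,
                "planned_fraction": frac,
                "matching_rows": [f"orth{i + 1}" for i in chosen],
                "achieved_fraction": (k / n_orth) if n_orth else 0.0,
            }
        )

    aligned = [AlignedRow(ref_id, "".join(ref))]
    aligned += [AlignedRow(f"orth{i + 1}", "".join(rows[i])) for i in range(n_orth)]
    aln = Alignment(aligned, reference_id=ref_id)
    truth = PlantedTruth(
        kind="motif" if compiled and not boxes else ("box" if boxes and not compiled else "mixed"),
        features=tuple(
            [{"box": [s, e], "identity_level": lv} for s, e, lv in boxes] + motif_truth
        ),
        params={"n_rows": n_rows, "length": length, "gap_rate": gap_rate},
        seed=seed,
    )
    return aln, truth


# ---------------------------------------------------------------------------
# structures

# Idealized heavy-atom templates: CA at the origin, backbone at y <= 0 and
# the side chain extending toward +y.  Bond geometry is approximate by
# design.
_BACKBONE = [("N", "N", (-1.2, -0.8, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
             ("C", "C", (1.2, -0.8, 0.0)), ("O", "O", (1.2, -2.0, 0.0))]

_SIDE_CHAINS: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "G": [],
    "A": [("CB", "C", (0.0, 1.52, 0.0))],
    "V": [("CB", "C", (0.0, 1.52, 0.0)), ("CG1", "C", (0.8, 2.6, 0.0)),
          ("CG2", "C", (-0.8, 2.6, 0.0))],
    "L": [("CB", "C", (0.0, 1.52, 0.0)), ("CG", "C", (0.0, 2.9, 0.0)),
          ("CD1", "C", (1.2, 3.7, 0.0)), ("CD2", "C", (-1.2, 3.7, 0.0))],
    "I": [("CB", "C", (0.0, 1.52, 0.0)), ("CG1", "C", (0.7, 2.8, 0.0)),
          ("CG2", "C", (-1.3, 1.9, 0.0)), ("CD1", "C", (0.7, 4.3, 0.0))],
    "M": [("CB", "C", (0.0, 1.52, 0.0)), ("CG", "C", (0.0, 2.9, 0.0)),
          ("SD", "S", (0.0, 4.6, 0.0)), ("CE", "C", (1.4, 5.5, 0.0))],
    "F": [("CB", "C", (0.0, 1.52, 0.0)), ("CG", "C", (0.0, 2.9, 0.0)),
          ("CD1", "C", (1.2, 3.6, 0.0)), ("CD2", "C", (-1.2, 3.6, 0.0)),
          ("CE1", "C", (1.2, 5.0, 0.0)), ("CE2", "C", (-1.2, 5.0, 0.0)),
          ("CZ", "C", (0.0, 5.7, 0.0))],
    "Y": [("CB", "C", (0.0, 1.52, 0.0)), ("CG", "C", (0.0, 2.9, 0.0)),
          ("CD1", "C", (1.2, 3.6, 0.0)), ("CD2", "C", (-1.2, 3.6, 0.0)),
          ("CE1", "C", (1.2, 5.0, 0.0)), ("CE2", "C", (-1.2, 5.0, 0.0)),
          ("CZ", "C", (0.0, 5.7, 0.0)), ("OH", "O", (0.0, 7.1, 0.0))],
    "W": [("CB", "C", (0.0, 1.52, 0.0)), ("CG", "C", (0.0, 2.9, 0.0)),
          ("CD1", "C", (1.1, 3.7, 0.0)), ("CD2", "C", (-1.0, 3.6, 0.0)),
          ("NE1", "N", (0.8, 5.0, 0.0)), ("CE2", "C", (-0.5, 5.0, 0.0)),
          ("CE3", "C", (-2.4, 3.5, 0.0)), ("CZ2", "C", (-1.3, 6.1, 0.0)),
          ("CZ3", "C", (-3.1, 4.6, 0.0)), ("CH2", "C", (-2.6, 5.9, 0.0))],
    "P": [("CB", "C", (0.9, 1.3, 0.0)), ("CG", "C", (0.2, 2.6, 0.0)),
          ("CD", "C", (-1.2, 2.2, 0.0))],
    "S": [("CB", "C", (0.0, 1.52, 0.0)), ("OG", "O", (0.0, 2.9, 0.0))],
    "T": [("CB", "C", (0.0, 1.52, 0.0)), ("OG1", "O", (0.9, 2.6, 0.0)),
          ("CG2", "C", (-0.9, 2.6, 0.0))],
    "C": [("CB", "C", (0.0, 1.52, 0.0)), ("SG", "S", (0.0, 3.1, 0.0))],
    "N": [("CB", "C", (0.0, 1.52, 0.0)), ("CG", "C", (0.0, 2.9, 0.0)),
          ("OD1", "O", (1.1, 3.6, 0.0)), ("ND2", "N", (-1.1, 3.6, 0.0))],
    "Q": [("CB", "C", (0.0, 1.52, 0.0)), ("CG", "C", (0.0, 2.9, 0.0)),
          ("CD", "C", (0.0, 4.4, 0.0)), ("OE1", "O", (1.1, 5.1, 0.0)),
          ("NE2", "N", (-1.1, 5.1, 0.0))],
    "D": [("CB", "C", (0.0, 1.52, 0.0)), ("CG", "C", (0.0, 2.9, 0.0)),
          ("OD1", "O", (1.1, 3.6, 0.0)), ("OD2", "O", (-1.1, 3.6, 0.0))],
    "E": [("CB", "C", (0.0, 1.52, 0.0)), ("CG", "C", (0.0, 2.9, 0.0)),
          ("CD", "C", (0.0, 4.4, 0.0)), ("OE1", "O", (1.1, 5.1, 0.0)),
          ("OE2", "O", (-1.1, 5.1, 0.0))],
    "K": [("CB", "C", (0.0, 1.52, 0.0)), ("CG", "C", (0.0, 2.9, 0.0)),
          ("CD", "C", (0.0, 4.4, 0.0)), ("CE", "C", (0.0, 5.9, 0.0)),
          ("NZ", "N", (0.0, 7.3, 0.0))],
    "R": [("CB", "C", (0.0, 1.52, 0.0)), ("CG", "C", (0.0, 2.9, 0.0)),
          ("CD", "C", (0.0, 4.4, 0.0)), ("NE", "N", (0.0, 5.8, 0.0)),
          ("CZ", "C", (0.0, 7.1, 0.0)), ("NH1", "N", (1.1, 7.8, 0.0)),
          ("NH2", "N", (-1.1, 7.8, 0.0))],
    "H": [("CB", "C", (0.0, 1.52, 0.0)), ("CG", "C", (0.0, 2.9, 0.0)),
          ("ND1", "N", (1.1, 3.7, 0.0)), ("CD2", "C", (-1.0, 3.8, 0.0)),
          ("CE1", "C", (0.7, 5.0, 0.0)), ("NE2", "N", (-0.4, 5.2, 0.0))],
}

#: Atom scope used to realize each planted contact kind.
_KIND_SCOPE = {
    "salt_bridge": "charged_group",
    "hbond": "polar",
    "pipi": "ring",
    "sulfur_pair": "SG",
    "hydrophobic_contact": "side_chain",
    "generic": "all_heavy",
}


def _template_atoms(aa1: str) -> list[tuple[str, str, np.ndarray]]:
    if aa1 not in _SIDE_CHAINS:
        raise ValueError(f"no residue template for {aa1!r}")
    return [
        (name, el, np.array(xyz)) for name, el, xyz in _BACKBONE + _SIDE_CHAINS[aa1]
    ]


def _rotation_from_y(v: np.ndarray) -> np.ndarray:
    """Rotation matrix sending the +y axis onto unit vector ``v``."""
    y = np.array([0.0, 1.0, 0.0])
    v = v / np.linalg.norm(v)
    c = float(np.dot(y, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(y, v)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + K * s + K @ K * (1 - c)


class _PlacedResidue:
    def __init__(self, aa1: str, chain: str, number: int, origin: np.ndarray):
        self.aa1 = aa1
        self.chain = chain
        self.number = number
        self.rotation = np.eye(3)
        self.origin = origin.astype(float)
        self._template = _template_atoms(aa1)

    def atoms(self) -> dict[str, np.ndarray]:
        return {
            name: self.rotation @ xyz + self.origin for name, _el, xyz in self._template
        }

    def elements(self) -> dict[str, str]:
        return {name: el for name, el, _ in self._template}

    def scoped_points(self, scope: str) -> dict[str, np.ndarray]:
        atoms = self.atoms()
        if scope == "charged_group":
            names = CHARGED_GROUP_ATOMS.get(self.aa1, ())
            sel = {n: atoms[n] for n in names if n in atoms}
        elif scope == "polar":
            elems = self.elements()
            sel = {
                n: c for n, c in atoms.items()
                if n not in ("N", "O") and elems[n] in ("N", "O")
            } or {n: c for n, c in atoms.items() if elems[n] in ("N", "O")}
        elif scope == "ring":
            names = RING_ATOMS.get(self.aa1, ())
            pts = [atoms[n] for n in names if n in atoms]
            if not pts:
                sel = {}
            else:
                sel = {"centroid": np.mean(pts, axis=0)}
        elif scope == "SG":
            sel = {n: c for n, c in atoms.items() if n == "SG"}
        elif scope == "side_chain":
            sel = {n: c for n, c in atoms.items() if n not in ("N", "CA", "C", "O")}
        elif scope == "all_heavy":
            sel = atoms
        else:
            raise ValueError(f"unknown scope {scope!r}")
        if not sel:
            raise ValueError(
                f"unsatisfiable plan: residue {self.aa1}{self.number} has no "
                f"atoms for scope {scope!r}"
            )
        return sel


def _scoped_min(a: _PlacedResidue, b: _PlacedResidue, scope: str) -> float:
    pa = a.scoped_points(scope)
    pb = b.scoped_points(scope)
    return min(
        float(np.linalg.norm(ca - cb)) for ca in pa.values() for cb in pb.values()
    )


def synth_structure(
    residue_plan: Sequence[tuple[str, str, int]],
    contact_plan: Sequence[tuple] = (),
    seed: int = 0,
    chain_gap: float = 100.0,
    plddt: float = 90.0,
) -> tuple[StructureModel, PlantedTruth]:
    """Build a structure with planted residue-pair contacts.

    ``residue_plan``: (one-letter aa, chain, residue number).
    ``contact_plan``: ((chain, num), (chain, num), kind, distance) where the
    distance is realized (to <= 0.01 A) between the atom sets that the
    kind's detector measures.  Non-planted residue pairs from different
    plant components stay >= 8 A apart (all heavy atoms).
    """
    if not residue_plan:
        raise ValueError("empty residue plan")
    chains_seen: list[str] = []
    for _aa, ch, _num in residue_plan:
        if ch not in chains_seen:
            chains_seen.append(ch)

    placed: dict[tuple[str, int], _PlacedResidue] = {}
    slot = {ch: 0 for ch in chains_seen}
    for aa1, ch, num in residue_plan:
        key = (ch, num)
        if key in placed:
            raise ValueError(f"duplicate residue in plan: {key}")
        origin = np.array(
            [slot[ch] * _SLOT_SPACING, 0.0, chains_seen.index(ch) * chain_gap]
        )
        placed[key] = _PlacedResidue(aa1, ch, num, origin)
        slot[ch] += 1

    # union-find over plant components (for the separation check)
    comp = {key: key for key in placed}

    def find(k):
        while comp[k] != k:
            comp[k] = comp[comp[k]]
            k = comp[k]
        return k

    oriented: set[tuple[str, int]] = set()
    moved: set[tuple[str, int]] = set()
    plant_count: dict[tuple[str, int], int] = {}
    truth_features = []

    for entry in contact_plan:
        sel_a, sel_b, kind, distance = entry
        if kind not in _KIND_SCOPE:
            raise ValueError(f"unknown planted contact kind {kind!r}")
        if distance <= 0:
            raise ValueError("unsatisfiable plan: non-positive distance")
        key_a, key_b = tuple(sel_a), tuple(sel_b)
        if key_a not in placed or key_b not in placed:
            raise ValueError(f"plant references unknown residue: {sel_a} / {sel_b}")
        a, b = placed[key_a], placed[key_b]
        scope = _KIND_SCOPE[kind]

        u = _DIRECTIONS[plant_count.get(key_a, 0) % len(_DIRECTIONS)]
        plant_count[key_a] = plant_count.get(key_a, 0) + 1
        plant_count[key_b] = plant_count.get(key_b, 0) + 1

        if key_a not in oriented and key_a not in moved:
            a.rotation = _rotation_from_y(u)
            oriented.add(key_a)
        b.rotation = _rotation_from_y(-u)
        oriented.add(key_b)
        moved.add(key_b)

        # initial placement: scoped point of b at requested distance from a's
        anchor = np.mean(list(a.scoped_points(scope).values()), axis=0)
        b.origin = anchor + u * (distance + 8.0)
        # iterative translation along u until the scoped minimum matches
        for _ in range(200):
            dm = _scoped_min(a, b, scope)
            if abs(dm - distance) <= 1e-9:
                break
            b.origin = b.origin + (distance - dm) * u
        achieved = _scoped_min(a, b, scope)
        if abs(achieved - distance) > 0.01:
            raise ValueError("unsatisfiable plan: could not realize planted distance")
        comp[find(key_a)] = find(key_b)
        truth_features.append(
            {
                "residue_a": list(key_a),
                "residue_b": list(key_b),
                "kind": kind,
                "distance": distance,
                "achieved": round(achieved, 6),
            }
        )

    # separation check between different plant components
    keys = sorted(placed)
    for i, ka in enumerate(keys):
        atoms_a = placed[ka].atoms()
        for kb in keys[i + 1 :]:
            if find(ka) == find(kb):
                continue
            atoms_b = placed[kb].atoms()
            dmin = min(
                float(np.linalg.norm(ca - cb))
                for ca in atoms_a.values()
                for cb in atoms_b.values()
            )
            if dmin < _MIN_SEPARATION:
                raise ValueError(
                    f"unsatisfiable plan: residues {ka} and {kb} collide ({dmin:.2f} A)"
                )

    residues = []
    for aa1, ch, num in residue_plan:
        pr = placed[(ch, num)]
        residues.append(
            Residue(
                chain=ch,
                number=num,
                aa3=AA1_TO_3[aa1],
                atoms=pr.atoms(),
                elements=pr.elements(),
                confidence=plddt,
            )
        )
    model = StructureModel(residues)
    truth = PlantedTruth(
        kind="contact",
        features=tuple(truth_features),
        params={"n_residues": len(residue_plan), "chains": chains_seen},
        seed=seed,
    )
    return model, truth


def synth_complex(
    chain_plans: dict,
    interface_plan: Sequence[tuple] = (),
    seed: int = 0,
) -> tuple[StructureModel, PlantedTruth]:
    """Multi-chain structure with planted cross-chain contacts.

    ``chain_plans``: chain id -> list of (aa, number).  ``interface_plan``:
    ((chain, num), (chain, num), kind, distance) with residues on different
    chains.  Chains without planted cross contacts sit 100 A apart.
    """
    residue_plan = [
        (aa, ch, num) for ch, plan in chain_plans.items() for aa, num in plan
    ]
    for sel_a, sel_b, _kind, _d in interface_plan:
        if sel_a[0] == sel_b[0]:
            raise ValueError("interface plant must cross chains")
    model, truth = synth_structure(residue_plan, interface_plan, seed=seed)
    return model, PlantedTruth("interface", truth.features, truth.params, seed)


# ---------------------------------------------------------------------------
# score tracks


def synth_track(
    segments: Sequence[tuple[int, int, float]],
    length: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    kind: str = "disorder",
    background: float = 0.0,
) -> tuple["ScoreTrack", PlantedTruth]:
    """Piecewise-constant score track plus Gaussian noise, clipped to the
    track kind's value range."""
    from .structcontacts import ScoreTrack

    lo, hi = (0.0, 1.0) if kind == "disorder" else (0.0, 100.0)
    values = np.full(length, float(background))
    for start, end, level in segments:
        if not (1 <= start <= end <= length):
            raise ValueError("segment outside track")
        values[start - 1 : end] = level
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=length)
    values = np.clip(values, lo, hi)
    track = ScoreTrack(np.arange(1, length + 1), values, kind)
    truth = PlantedTruth(
        kind="segment",
        features=tuple({"start": s, "end": e, "level": lv} for s, e, lv in segments),
        params={"length": length, "noise_sd": noise_sd, "background": background,
                "kind": kind},
        seed=seed,
    )
    return track, truth
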