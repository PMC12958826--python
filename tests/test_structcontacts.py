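import math
import random

import numpy as np
import pytest

from spsmap.structcontacts import (
    CHARGED_GROUP_ATOMS,
    RING_ATOMS,
    Residue,
    ScoreTrack,
    StructureModel,
    detect_clusters,
    detect_hbond_pairs,
    detect_pipi,
    detect_salt_bridges,
    plddt_track,
    read_structure,
    read_track,
    residue_min_distance,
    segment_track,
    write_pdb,
    write_track,
)
from spsmap.synthdata import synth_structure

# ---------------------------------------------------------------------------
# oracles (independent naive implementations)


def oracle_min_distance(res_a, res_b, names_a, names_b):
    best = math.inf
    for na in names_a:
        for nb in names_b:
            d = math.dist(res_a.atoms[na], res_b.atoms[nb])
            best = min(best, d)
    return best


def oracle_salt_bridges(model, cutoff=4.5):
    found = set()
    for a in model.residues:
        for b in model.residues:
            if a.aa1 not in "KRH" or b.aa1 not in "DE":
                continue
            na = [n for n in CHARGED_GROUP_ATOMS[a.aa1] if n in a.atoms]
            nb = [n for n in CHARGED_GROUP_ATOMS[b.aa1] if n in b.atoms]
            if not na or not nb:
                continue
            if oracle_min_distance(a, b, na, nb) <= cutoff:
                found.add((a.key, b.key))
    return found


def oracle_hbonds(model, cutoff=3.6, exclude_adjacent=1):
    found = set()
    residues = model.residues
    for i, a in enumerate(residues):
        for b in residues[i + 1 :]:
            if b.chain == a.chain and abs(b.number - a.number) <= exclude_adjacent:
                continue
            na = [n for n in a.atoms if a.elements.get(n, n[0]) in "NO"]
            nb = [n for n in b.atoms if b.elements.get(n, n[0]) in "NO"]
            if not na or not nb:
                continue
            if oracle_min_distance(a, b, na, nb) <= cutoff:
                found.add((a.key, b.key))
    return found


def oracle_pipi(model, cutoff=5.5):
    found = set()
    residues = [r for r in model.residues if r.aa1 in RING_ATOMS]
    for i, a in enumerate(residues):
        for b in residues[i + 1 :]:
            ca = np.mean([a.atoms[n] for n in RING_ATOMS[a.aa1] if n in a.atoms], axis=0)
            cb = np.mean([b.atoms[n] for n in RING_ATOMS[b.aa1] if n in b.atoms], axis=0)
            if math.dist(ca, cb) <= cutoff:
                found.add((a.key, b.key))
    return found


def oracle_segments(nums, values, threshold, direction, min_length):
    passing = [
        (v > threshold) if direction == "above" else (v < threshold) for v in values
    ]
    segments = []
    i = 0
    while i < len(values):
        if not passing[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(values) and passing[j + 1] and nums[j + 1] == nums[j] + 1:
            j += 1
        if nums[j] - nums[i] + 1 >= min_length:
            segments.append((nums[i], nums[j]))
        i = j + 1
    return segments


def random_model(rng, max_residues=30):
    """A random synthetic model: residues on a jittered grid (no plants)."""
    n = rng.randint(4, max_residues)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    plan = [(rng.choice(aas), "A", i + 1) for i in range(n)]
    model, _ = synth_structure(plan, [], seed=0)
    # compress the line so residues actually touch, then jitter
    scale = rng.uniform(0.15, 0.6)
    rnd = random.Random(rng.random())
    for res in model.residues:
        shift = np.array([rnd.uniform(-3, 3) for _ in range(3)])
        for name in res.atoms:
            res.atoms[name] = res.atoms[name] * np.array([scale, 1.0, 1.0]) + shift
    return model


# ---------------------------------------------------------------------------
# reading / writing


class TestReadStructure:
    def test_minimal_handwritten_pdb(self, tmp_path):
        f = tmp_path / "one.pdb"
        f.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 77.00           N\n"
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 77.00           C\n"
            "END\n"
        )
        model = read_structure(f, plddt_in_bfactor=True)
        assert model.chains == ["A"]
        assert len(model.residues) == 1
        assert model.residues[0].aa1 == "A"
        assert model.residues[0].confidence == pytest.approx(77.0)

    def test_roundtrip_preserves_coordinates(self, tmp_path):
        plan = [("K", "A", 1), ("D", "A", 2), ("F", "A", 3)]
        model, _ = synth_structure(plan, [(("A", 1), ("A", 2), "salt_bridge", 3.2)])
        path = tmp_path / "m.pdb"
        write_pdb(model, path)
        back = read_structure(path)
        d0, _ = residue_min_distance(model, ("A", 1), ("A", 2), "charged_group")
        d1, _ = residue_min_distance(back, ("A", 1), ("A", 2), "charged_group")
        assert abs(d0 - d1) <= 1e-3  # PDB coordinate precision

    def test_hydrogens_dropped(self, tmp_path):
        f = tmp_path / "h.pdb"
        f.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  H   ALA A   1       0.500   0.500   0.000  1.00  0.00           H\n"
            "END\n"
        )
        model = read_structure(f)
        assert list(model.residues[0].atoms) == ["N"]

    def test_bad_file(self, tmp_path):
        f = tmp_path / "junk.pdb"
        f.write_text("this is not a structure\n")
        with pytest.raises(ValueError, match="bad structure file"):
            read_structure(f)

    def test_mmcif_roundtrip_via_biotite(self, tmp_path):
        # write a small model as mmCIF with biotite and read it back
        import biotite.structure as struc
        import biotite.structure.io.pdbx as pdbx

        model, _ = synth_structure([("S", "A", 10), ("D", "A", 11)])
        pdb_path = tmp_path / "m.pdb"
        write_pdb(model, pdb_path)
        import biotite.structure.io.pdb as pdbio

        atoms = pdbio.PDBFile.read(str(pdb_path)).get_structure(model=1)
        cif = pdbx.CIFFile()
        pdbx.set_structure(cif, atoms)
        cif_path = tmp_path / "m.cif"
        cif.write(str(cif_path))
        back = read_structure(cif_path)
        assert [r.number for r in back.residues] == [10, 11]  # author numbering kept


class TestResidueMinDistance:
    def test_residue_vs_itself(self):
        model, _ = synth_structure([("A", "A", 1)])
        d, _ = residue_min_distance(model, ("A", 1), ("A", 1))
        assert d == 0.0

    def test_three_four_five_triangle(self):
        res_a = Residue("A", 1, "GLY", {"N": np.array([0.0, 0.0, 0.0])}, {"N": "N"})
        res_b = Residue("A", 2, "GLY", {"N": np.array([3.0, 4.0, 0.0])}, {"N": "N"})
        model = StructureModel([res_a, res_b])
        d, pair = residue_min_distance(model, ("A", 1), ("A", 2))
        assert d == pytest.approx(5.0)
        assert pair == ("N", "N")

    def test_matches_all_pairs_oracle(self, rng):
        model = random_model(rng)
        residues = model.residues
        for _ in range(20):
            a, b = rng.sample(residues, 2)
            d, _ = residue_min_distance(model, a.key, b.key, "all_heavy")
            expected = oracle_min_distance(a, b, list(a.atoms), list(b.atoms))
            assert d == pytest.approx(expected)

    def test_gly_has_no_side_chain(self):
        model, _ = synth_structure([("G", "A", 1), ("A", "A", 2)])
        with pytest.raises(ValueError, match="no atoms in scope"):
            residue_min_distance(model, ("A", 1), ("A", 2), "side_chain")

    def test_missing_residue(self):
        model, _ = synth_structure([("A", "A", 1)])
        with pytest.raises(KeyError, match="residue not found"):
            model.residue(("A", 99))


# ---------------------------------------------------------------------------
# detectors


class TestSaltBridges:
    def test_no_charged_residues(self):
        model, _ = synth_structure([("A", "A", 1), ("L", "A", 2)])
        assert detect_salt_bridges(model) == []

    def test_planted_bridge(self):
        model, _ = synth_structure(
            [("K", "A", 1), ("D", "A", 2)], [(("A", 1), ("A", 2), "salt_bridge", 3.0)]
        )
        edges = detect_salt_bridges(model)
        assert len(edges) == 1
        assert edges[0].distance == pytest.approx(3.0, abs=0.01)
        assert edges[0].kind == "salt_bridge"
        assert {edges[0].atoms[0], edges[0].atoms[1]} <= {"NZ", "OD1", "OD2"}

    def test_matches_oracle_and_cutoff_monotonicity(self, rng):
        for _ in range(10):
            model = random_model(rng)
            got = {(e.residue_a[:2], e.residue_b[:2]) for e in detect_salt_bridges(model)}
            assert got == oracle_salt_bridges(model)
            tight = detect_salt_bridges(model, cutoff=3.0)
            loose = detect_salt_bridges(model, cutoff=6.0)
            tight_keys = {(e.residue_a, e.residue_b) for e in tight}
            loose_keys = {(e.residue_a, e.residue_b) for e in loose}
            assert tight_keys <= loose_keys


class TestHbonds:
    def test_distant_glycines(self):
        model, _ = synth_structure([("G", "A", 1), ("G", "A", 5)])
        assert detect_hbond_pairs(model) == []

    def test_planted_hbond(self):
        model, _ = synth_structure(
            [("S", "A", 1), ("D", "A", 3)], [(("A", 1), ("A", 3), "hbond", 2.8)]
        )
        edges = detect_hbond_pairs(model)
        assert any(
            e.distance == pytest.approx(2.8, abs=0.01)
            and {e.residue_a[1], e.residue_b[1]} == {1, 3}
            for e in edges
        )

    def test_pair_restriction(self):
        model, _ = synth_structure(
            [("S", "A", 1), ("D", "A", 3)], [(("A", 1), ("A", 3), "hbond", 2.8)]
        )
        edges = detect_hbond_pairs(model, pairs=[(("A", 1), ("A", 3))])
        assert len(edges) == 1
        edges = detect_hbond_pairs(model, pairs=[(("A", 1), ("A", 1))])
        assert edges == [] or edges[0].distance == 0  # same residue: distance 0 pair

    def test_matches_oracle(self, rng):
        for _ in range(10):
            model = random_model(rng)
            got = {
                frozenset((e.residue_a[:2], e.residue_b[:2]))
                for e in detect_hbond_pairs(model)
            }
            expected = {frozenset(p) for p in oracle_hbonds(model)}
            assert got == expected


class TestPipi:
    def test_single_aromatic(self):
        model, _ = synth_structure([("F", "A", 1), ("A", "A", 2)])
        assert detect_pipi(model) == []

    def test_planted_stack(self):
        model, _ = synth_structure(
            [("F", "A", 1), ("F", "A", 2)], [(("A", 1), ("A", 2), "pipi", 4.0)]
        )
        edges = detect_pipi(model)
        assert len(edges) == 1
        assert edges[0].distance == pytest.approx(4.0, abs=0.01)
        assert edges[0].atoms == ("centroid", "centroid")

    def test_rings_beyond_cutoff(self):
        model, _ = synth_structure(
            [("F", "A", 1), ("F", "A", 2)], [(("A", 1), ("A", 2), "pipi", 8.0)]
        )
        assert detect_pipi(model) == []

    def test_matches_oracle(self, rng):
        for _ in range(10):
            model = random_model(rng)
            got = {
                frozenset((e.residue_a[:2], e.residue_b[:2])) for e in detect_pipi(model)
            }
            expected = {frozenset(p) for p in oracle_pipi(model)}
            assert got == expected


class TestClusters:
    def test_all_far_apart(self):
        model, _ = synth_structure([("C", "A", i) for i in range(1, 5)])
        assert detect_clusters(model, "sulfur") == []

    def test_three_cys_chain(self):
        model, _ = synth_structure(
            [("C", "A", 1), ("C", "A", 2), ("C", "A", 3)],
            [
                (("A", 1), ("A", 2), "sulfur_pair", 3.5),
                (("A", 2), ("A", 3), "sulfur_pair", 3.5),
            ],
        )
        clusters = detect_clusters(model, "sulfur")
        assert len(clusters) == 1
        assert [m[1] for m in clusters[0].members] == [1, 2, 3]
        assert clusters[0].max_internal_gap == pytest.approx(3.5, abs=0.01)

    def test_hydrophobic_cluster(self):
        model, _ = synth_structure(
            [("F", "A", 1), ("L", "A", 2), ("K", "A", 3)],
            [(("A", 1), ("A", 2), "hydrophobic_contact", 4.0)],
        )
        clusters = detect_clusters(model, "hydrophobic")
        assert len(clusters) == 1
        assert [m[1] for m in clusters[0].members] == [1, 2]

    def test_single_linkage_against_naive_components(self, rng):
        for _ in range(5):
            model = random_model(rng)
            clusters = detect_clusters(model, "hydrophobic", min_size=2)
            # naive: build the contact graph and take connected components
            hydro = [
                r for r in model.residues
                if r.aa1 in "AVLIMFWYP" and r.side_chain_atoms()
            ]
            adj = {r.key: set() for r in hydro}
            for a in hydro:
                for b in hydro:
                    if a.key >= b.key:
                        continue
                    na = [n for n in a.atoms if n not in ("N", "CA", "C", "O", "OXT")]
                    nb = [n for n in b.atoms if n not in ("N", "CA", "C", "O", "OXT")]
                    if oracle_min_distance(a, b, na, nb) <= 4.5:
                        adj[a.key].add(b.key)
                        adj[b.key].add(a.key)
            seen, components = set(), []
            for start in sorted(adj):
                if start in seen:
                    continue
                stack, comp = [start], set()
                while stack:
                    node = stack.pop()
                    if node in comp:
                        continue
                    comp.add(node)
                    stack.extend(adj[node] - comp)
                seen |= comp
                if len(comp) >= 2:
                    components.append(tuple(sorted(comp)))
            got = [tuple(m[:2] for m in c.members) for c in clusters]
            assert sorted(got) == sorted(components)


# ---------------------------------------------------------------------------
# score tracks


class TestTracks:
    def test_step_track_segmentation(self):
        values = [0.8] * 108 + [0.3] * 26 + [0.8] * 126 + [0.2] * 40
        track = ScoreTrack(np.arange(1, len(values) + 1), np.array(values), "disorder")
        segs = segment_track(track, 0.5, "above")
        assert [(s.start, s.end) for s in segs] == [(1, 108), (135, 260)]
        assert segs[0].mean_score == pytest.approx(0.8)

    def test_constant_below_threshold(self):
        track = ScoreTrack(np.arange(1, 51), np.full(50, 0.2), "disorder")
        assert segment_track(track, 0.5, "above") == []

    def test_threshold_below_minimum_gives_whole_track(self):
        track = ScoreTrack(np.arange(1, 31), np.linspace(0.3, 0.9, 30), "disorder")
        segs = segment_track(track, 0.1, "above", min_length=1)
        assert [(s.start, s.end) for s in segs] == [(1, 30)]

    def test_matches_naive_scan(self, rng):
        for _ in range(20):
            n = rng.randint(5, 80)
            values = np.array([rng.random() for _ in range(n)])
            track = ScoreTrack(np.arange(1, n + 1), values, "disorder")
            direction = rng.choice(["above", "below"])
            min_len = rng.randint(1, 5)
            segs = segment_track(track, 0.5, direction, min_length=min_len)
            expected = oracle_segments(
                list(range(1, n + 1)), list(values), 0.5, direction, min_len
            )
            assert [(s.start, s.end) for s in segs] == expected

    def test_smoothing_window_validation(self):
        track = ScoreTrack(np.arange(1, 11), np.full(10, 0.5), "disorder")
        with pytest.raises(ValueError):
            segment_track(track, 0.4, "above", smooth_window=2)

    def test_track_io_roundtrip(self, tmp_path):
        track = ScoreTrack(np.arange(1, 6), np.array([0.1, 0.5, 0.9, 0.2, 0.4]), "disorder")
        path = tmp_path / "t.tsv"
        write_track(track, path)
        back = read_track(path, "disorder")
        assert np.allclose(back.values, track.values)
        assert list(back.residue_numbers) == [1, 2, 3, 4, 5]

    def test_track_range_validation(self):
        with pytest.raises(ValueError):
            ScoreTrack(np.arange(1, 4), np.array([0.1, 1.5, 0.2]), "disorder")

    def test_plddt_track_from_model(self):
        model, _ = synth_structure([("A", "A", 1), ("G", "A", 2)], plddt=63.0)
        track = plddt_track(model)
        assert track.kind == "plddt"
        assert np.allclose(track.values, 63.0)


def test_distance_symmetry(rng):
    model = random_model(rng)
    a, b = model.residues[0], model.residues[-1]
    d_ab, _ = residue_min_distance(model, a.key, b.key)
    d_ba, _ = residue_min_distance(model, b.key, a.key)
    assert d_ab == pytest.approx(d_ba)
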