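import numpy as np
import pytest

import surfpatch.structure_io as sio
from surfpatch import (
    FamilySpec,
    sample_chain,
    write_toy_pdb,
    write_toy_vert,
)
from tests.reference import brute_force_sasa


def _single_ca_residues(coords, types=None, chain_id="A"):
    """Residues with one CA atom each, for surface-selection tests."""
    types = types or ["A"] * len(coords)
    return [
        sio.ResidueAtoms(
            chain_id, i + 1, t,
            [sio.AtomRecord("CA", np.asarray(c, dtype=float))],
        )
        for i, (c, t) in enumerate(zip(coords, types))
    ]


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

class TestReadPdbChains:
    def test_two_chain_roundtrip(self, tmp_path):
        """A two-chain toy file comes back as two chains of the right size."""
        spec = FamilySpec("t", np.full(20, 0.05), size_range=(8, 8))
        a = sample_chain(spec, 1, structure_id="TWO", chain_id="A")
        spec5 = FamilySpec("t", np.full(20, 0.05), size_range=(5, 5))
        b = sample_chain(spec5, 2, structure_id="TWO", chain_id="B")
        pa, pb = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_toy_pdb(a, pa)
        write_toy_pdb(b, pb)
        merged = tmp_path / "two.pdb"
        body = [
            ln for p in (pa, pb) for ln in p.read_text().splitlines()
            if ln.startswith("ATOM") or ln == "TER"
        ]
        merged.write_text("\n".join(body) + "\nEND\n")

        chains = sio.read_pdb_chains(merged)
        assert [(cid, len(res)) for cid, res in chains] == [("A", 8), ("B", 5)]
        got = chains[0][1][0]
        assert got.residue_type == a.residues[0].residue_type
        assert np.array_equal(got.ca_coord, a.residues[0].ca_coord)

    def test_residue_without_ca_is_dropped(self, tmp_path):
        lines = [
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C",
            "ATOM      2  CB  GLY A   2       4.000   5.000   6.000  1.00  0.00           C",
            "END",
        ]
        p = tmp_path / "noca.pdb"
        p.write_text("\n".join(lines) + "\n")
        chains = sio.read_pdb_chains(p)
        assert len(chains) == 1
        assert [r.residue_seq for r in chains[0][1]] == [1]

    def test_mse_remapped_to_methionine(self, tmp_path):
        lines = [
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C",
            "HETATM    2  CA  MSE A   2       3.800   0.000   0.000  1.00  0.00           C",
            "HETATM    3  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O",
            "END",
        ]
        p = tmp_path / "mse.pdb"
        p.write_text("\n".join(lines) + "\n")
        (_cid, residues), = sio.read_pdb_chains(p)
        assert [r.residue_type for r in residues] == ["A", "M"]

    def test_altloc_highest_occupancy_then_lexicographic(self, tmp_path):
        lines = [
            "ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.30  0.00           C",
            "ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.70  0.00           C",
            "ATOM      3  CA AGLY A   2       5.000   0.000   0.000  0.50  0.00           C",
            "ATOM      4  CA BGLY A   2       6.000   0.000   0.000  0.50  0.00           C",
            "END",
        ]
        p = tmp_path / "altloc.pdb"
        p.write_text("\n".join(lines) + "\n")
        (_cid, residues), = sio.read_pdb_chains(p)
        # residue 1: B wins on occupancy; residue 2: tie broken to altloc A
        assert residues[0].ca_coord[0] == 2.0
        assert residues[1].ca_coord[0] == 5.0

    def test_missing_file_and_empty_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            sio.read_pdb_chains(tmp_path / "absent.pdb")
        empty = tmp_path / "empty.pdb"
        empty.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(sio.PDBFormatError, match="empty.pdb"):
            sio.read_pdb_chains(empty)


# ---------------------------------------------------------------------------
# Vertex files
# ---------------------------------------------------------------------------

class TestReadMsmsVertices:
    def _write(self, path, n_declared, body_lines):
        path.write_text(
            "# header\n# header\n"
            f"{n_declared:5d} {n_declared:5d}  1.00  1.40\n"
            + "\n".join(body_lines) + ("\n" if body_lines else "")
        )

    def test_roundtrip_four_vertices(self, tmp_path):
        body = [
            f"{x:9.3f} {0.0:9.3f} {0.0:9.3f} {1.0:9.3f} {0.0:9.3f} {0.0:9.3f} "
            f"{0:7d} {i + 1:7d} {1:2d}"
            for i, x in enumerate([1.0, 2.0, 3.0, 4.0])
        ]
        p = tmp_path / "four.vert"
        self._write(p, 4, body)
        vs = sio.read_msms_vertices(p)
        assert len(vs) == 4
        assert np.allclose(vs.vertices[:, 0], [1, 2, 3, 4])
        assert list(vs.nearest_atom_index) == [1, 2, 3, 4]

    def test_declared_zero_is_an_error(self, tmp_path):
        p = tmp_path / "zero.vert"
        self._write(p, 0, [])
        with pytest.raises(sio.PDBFormatError, match="empty"):
            sio.read_msms_vertices(p)

    def test_count_mismatch_is_an_error(self, tmp_path):
        body = ["  1.0  0.0  0.0  1.0  0.0  0.0       0       1  1"] * 9
        p = tmp_path / "mismatch.vert"
        self._write(p, 10, body)
        with pytest.raises(sio.PDBFormatError, match="10"):
            sio.read_msms_vertices(p)

    def test_non_numeric_coordinate_names_line(self, tmp_path):
        body = ["  1.0  0.0  0.0  1.0  0.0  0.0       0       1  1",
                "  oops 0.0  0.0  1.0  0.0  0.0       0       2  1"]
        p = tmp_path / "bad.vert"
        self._write(p, 2, body)
        with pytest.raises(sio.PDBFormatError, match="line 5"):
            sio.read_msms_vertices(p)


# ---------------------------------------------------------------------------
# Surface selection by vertex ownership
# ---------------------------------------------------------------------------

class TestSelectSurfaceResidues:
    def _shell_setup(self, with_buried=True):
        rng = np.random.default_rng(7)
        dirs = rng.normal(size=(12, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        coords = list(dirs * 10.0)
        if with_buried:
            coords.append(np.zeros(3))
        residues = _single_ca_residues(coords)
        verts = sio.SurfaceVertexSet(vertices=dirs * 11.4)
        return residues, verts

    def test_buried_residue_is_not_surface(self):
        residues, verts = self._shell_setup(with_buried=True)
        sc = sio.select_surface_residues(residues, verts, structure_id="SPH")
        assert len(sc) == 12
        assert 13 not in [r.residue_seq for r in sc.residues]

    def test_all_on_shell_all_surface(self):
        residues, verts = self._shell_setup(with_buried=False)
        sc = sio.select_surface_residues(residues, verts)
        assert len(sc) == 12

    def test_matches_brute_force_ownership_on_lattice(self):
        """Two-layer lattice: vertex ownership equals the hand-enumerated
        nearest-atom assignment."""
        inner = [(x, y, 0.0) for x in range(3) for y in range(3)]
        outer = [(x, y, 4.0) for x in range(3) for y in range(3)]
        coords = [np.array(c, dtype=float) for c in inner + outer]
        residues = _single_ca_residues(coords)
        rng = np.random.default_rng(3)
        verts = np.column_stack([
            rng.uniform(-1, 3, 40), rng.uniform(-1, 3, 40),
            rng.uniform(5.0, 7.0, 40),  # all vertices above the outer layer
        ])
        vs = sio.SurfaceVertexSet(vertices=verts)
        sc = sio.select_surface_residues(residues, vs)

        expected = set()
        for v in verts:
            dists = [np.linalg.norm(v - c) for c in coords]
            expected.add(int(np.argmin(dists)) + 1)  # residue_seq, 1-based
        assert {r.residue_seq for r in sc.residues} == expected
        # vertices sit above the outer layer, so only outer residues qualify
        assert all(seq > 9 for seq in expected)

    def test_invariant_to_atom_order_and_rigid_motion(self):
        residues, verts = self._shell_setup()
        base = {r.residue_seq
                for r in sio.select_surface_residues(residues, verts).residues}

        perm = list(reversed(residues))
        assert {r.residue_seq
                for r in sio.select_surface_residues(perm, verts).residues} == base

        rng = np.random.default_rng(11)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = np.array([5.0, -3.0, 8.0])
        moved = [
            sio.ResidueAtoms(r.chain_id, r.residue_seq, r.residue_type,
                             [sio.AtomRecord(a.name, q @ a.coord + t)
                              for a in r.atoms])
            for r in residues
        ]
        moved_verts = sio.SurfaceVertexSet(vertices=verts.vertices @ q.T + t)
        assert {r.residue_seq
                for r in sio.select_surface_residues(moved, moved_verts).residues} == base

    def test_file_nearest_index_marks_every_toy_residue(self, tmp_path):
        spec = FamilySpec("t", np.full(20, 0.05), size_range=(15, 15))
        chain = sample_chain(spec, 4, structure_id="TOY")
        write_toy_pdb(chain, tmp_path / "toy.pdb")
        write_toy_vert(chain, tmp_path / "toy.vert")
        (_cid, residues), = sio.read_pdb_chains(tmp_path / "toy.pdb")
        verts = sio.read_msms_vertices(tmp_path / "toy.vert")
        sc = sio.select_surface_residues(residues, verts, structure_id="TOY")
        assert len(sc) == len(chain)
        assert all(
            np.array_equal(a.ca_coord, b.ca_coord) and a.residue_type == b.residue_type
            for a, b in zip(sc.residues, chain.residues)
        )

    def test_each_surface_residue_appears_once(self):
        residues, verts = self._shell_setup()
        sc = sio.select_surface_residues(residues, verts)
        seqs = [r.residue_seq for r in sc.residues]
        assert len(seqs) == len(set(seqs))


# ---------------------------------------------------------------------------
# SASA fallback
# ---------------------------------------------------------------------------

class TestSasaFallback:
    def test_isolated_residue_is_fully_exposed(self):
        residues = _single_ca_residues([np.zeros(3)], types=["A"])
        sasa = sio.shrake_rupley_sasa(residues)
        area = 4 * np.pi * (1.7 + 1.4) ** 2  # lone carbon sphere
        assert sasa[0] == pytest.approx(area, rel=1e-12)
        sc = sio.sasa_surface_fallback(residues)
        assert len(sc) == 1

    def test_caged_residue_is_buried(self):
        cage_dirs = sio._fibonacci_sphere(60)
        coords = [np.zeros(3)] + list(cage_dirs * 3.0)
        residues = _single_ca_residues(coords)
        sasa = sio.shrake_rupley_sasa(residues)
        assert sasa[0] == 0.0
        sc = sio.sasa_surface_fallback(residues)
        assert 1 not in [r.residue_seq for r in sc.residues]

    def test_matches_brute_force_point_counting(self, rng):
        coords = rng.uniform(0, 6, size=(5, 3))
        residues = _single_ca_residues(coords, types=list("ACDEF"))
        fast = sio.shrake_rupley_sasa(residues)
        slow = brute_force_sasa(residues, 1.4, sio._SPHERE_POINTS)
        assert np.allclose(fast, slow, atol=1e-9)

    def test_unknown_probe_rejected(self):
        residues = _single_ca_residues([np.zeros(3)])
        with pytest.raises(ValueError):
            sio.sasa_surface_fallback(residues, probe_radius=0.0)


# ---------------------------------------------------------------------------
# TSV serialization
# ---------------------------------------------------------------------------

def test_surface_chain_tsv_roundtrip(tmp_path, uniform_spec):
    chain = sample_chain(uniform_spec, 9, structure_id="SER")
    p = tmp_path / "chain.tsv"
    chain.to_tsv(p)
    back = sio.SurfaceChain.from_tsv(p)
    assert back.structure_id == "SER" and back.chain_id == "A"
    assert len(back) == len(chain)
    assert all(
        a.residue_type == b.residue_type and np.array_equal(a.ca_coord, b.ca_coord)
        for a, b in zip(back.residues, chain.residues)
    )
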