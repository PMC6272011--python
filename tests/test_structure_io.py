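import numpy as np
import pytest

from popshift.structure_io import (Atom, PDBParseError, Structure, StructureError,
                                   apply_torsions, build_torsion_tree, read_ensemble,
                                   read_structure, rotate_torsion, write_ensemble,
                                   write_structure)


def _atom(serial, name, pos, charge=0.0, element="C", atom_type="C",
          resname="LIG", resnum=1, chain="L", record="HETATM", occ=1.0, alt=""):
    return Atom(serial, name, element, atom_type, resname, resnum, chain,
                np.array(pos, dtype=float), charge, occ, alt, record)


def _chain_structure(n=4, spacing=1.45):
    atoms = [_atom(i + 1, f"L{i + 1}", (i * spacing, 0.3 * (i % 2), 0.0))
             for i in range(n)]
    return Structure(atoms, ["ligand"] * n)


PDBQ_3ATOM = """\
HETATM    1  L1  LIG L   1       0.000   0.000   0.000  1.00  0.00     0.200 C
HETATM    2  L2  LIG L   1       1.400   0.000   0.000  1.00  0.00    -0.400 C
HETATM    3  L3  LIG L   1       2.800   0.000   0.000  1.00  0.00     0.200 C
END
"""


class TestReadStructure:
    def test_charged_dialect_echoes_charges(self, tmp_path):
        path = tmp_path / "three.pdbq"
        path.write_text(PDBQ_3ATOM)
        s = read_structure(path, "pdbq_charged")
        assert [a.partial_charge for a in s.atoms] == [0.2, -0.4, 0.2]
        assert s.atom_types == ["C", "C", "C"]
        assert s.role_labels == ["ligand"] * 3

    def test_multi_model_file_directs_to_read_ensemble(self, tmp_path):
        path = tmp_path / "two_models.pdb"
        body = PDBQ_3ATOM.replace("END\n", "")
        path.write_text(f"MODEL 1\n{body}ENDMDL\nMODEL 2\n{body}ENDMDL\nEND\n")
        with pytest.raises(StructureError, match="read_ensemble"):
            read_structure(path)

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("ATOM      1  CA  ALA A   1      bad coordinates here\n")
        with pytest.raises(PDBParseError, match="line 1"):
            read_structure(path)

    def test_alt_loc_collapse_keeps_highest_occupancy(self, tmp_path):
        lines = [
            "ATOM      1  N   ARG B 503       0.000   0.000   0.000  1.00  0.00",
            "ATOM      2  CA AARG B 503       1.400   0.000   0.000  0.60  0.00",
            "ATOM      3  CA BARG B 503       1.600   0.000   0.000  0.40  0.00",
            "END",
        ]
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\n")
        s = read_structure(path)
        assert len(s) == 2
        ca = [a for a in s.atoms if a.name == "CA"][0]
        assert ca.alt_loc == "A"
        assert ca.position[0] == pytest.approx(1.4)

    def test_alt_loc_tie_breaks_alphabetically(self, tmp_path):
        lines = [
            "ATOM      1  CA BARG B 503       1.600   0.000   0.000  0.50  0.00",
            "ATOM      2  CA AARG B 503       1.400   0.000   0.000  0.50  0.00",
            "END",
        ]
        path = tmp_path / "tie.pdb"
        path.write_text("\n".join(lines) + "\n")
        s = read_structure(path)
        assert len(s) == 1
        assert s.atoms[0].alt_loc == "A"


class TestWriteStructure:
    def test_round_trip_both_dialects(self, tmp_path):
        s = _chain_structure()
        for atom, q in zip(s.atoms, (0.25, -0.4567, 0.1, 0.1067)):
            atom.partial_charge = q
        for dialect in ("pdb", "pdbq_charged"):
            path = tmp_path / f"rt.{dialect}"
            write_structure(s, path, dialect)
            back = read_structure(path, dialect)
            assert [a.name for a in back.atoms] == [a.name for a in s.atoms]
            assert [a.residue_name for a in back.atoms] == ["LIG"] * 4
            np.testing.assert_allclose(back.coords, s.coords, atol=5e-4)
            if dialect == "pdbq_charged":
                np.testing.assert_allclose(back.charges, s.charges, atol=5e-4)

    def test_charges_stored_to_three_decimals(self, tmp_path):
        s = _chain_structure(n=2)
        s.atoms[0].partial_charge = -0.4567
        path = tmp_path / "fmt.pdbq"
        write_structure(s, path, "pdbq_charged")
        assert read_structure(path, "pdbq_charged").atoms[0].partial_charge == -0.457

    def test_empty_structure_rejected(self):
        with pytest.raises(StructureError):
            Structure([], [])


class TestReadEnsemble:
    def _write_traj(self, tmp_path, times, n_atoms=3):
        lines = []
        for m, t in enumerate(times, start=1):
            if t is not None:
                lines.append(f"REMARK TIME_PS {t}")
            lines.append(f"MODEL {m}")
            for i in range(n_atoms):
                lines.append(f"HETATM{i + 1:>5}  L{i + 1}  LIG L   1    "
                             f"{float(i):8.3f}{float(m):8.3f}{0.0:8.3f}  1.00  0.00")
            lines.append("ENDMDL")
        lines.append("END")
        path = tmp_path / "traj.pdb"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_times_from_remarks(self, tmp_path):
        path = self._write_traj(tmp_path, [100, 200, 300, 400, 500])
        traj = read_ensemble(path)
        assert traj.n_frames == 5
        np.testing.assert_allclose(traj.times, [100, 200, 300, 400, 500])

    def test_single_model_file(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(PDBQ_3ATOM)
        assert read_ensemble(path).n_frames == 1

    def test_missing_times_warns_and_assigns_unit_spacing(self, tmp_path):
        path = self._write_traj(tmp_path, [None, None, None])
        with pytest.warns(UserWarning, match="TIME_PS"):
            traj = read_ensemble(path)
        np.testing.assert_allclose(traj.times, [0, 1, 2])

    def test_mismatched_atom_counts_rejected(self, tmp_path):
        lines = ["MODEL 1"]
        for i in range(5):
            lines.append(f"HETATM{i + 1:>5}  L{i + 1}  LIG L   1    "
                         f"{float(i):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00")
        lines += ["ENDMDL", "MODEL 2"]
        for i in range(4):
            lines.append(f"HETATM{i + 1:>5}  L{i + 1}  LIG L   1    "
                         f"{float(i):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00")
        lines += ["ENDMDL", "END"]
        path = tmp_path / "bad_traj.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(StructureError, match="model 2"):
            read_ensemble(path)

    def test_write_ensemble_round_trip(self, tmp_path):
        from popshift.structure_io import EnsembleTrajectory
        s = _chain_structure()
        traj = EnsembleTrajectory([(100.0, s), (200.0, s.with_coords(s.coords + 0.5))])
        path = tmp_path / "rt_traj.pdb"
        write_ensemble(traj, path, "pdbq_charged")
        back = read_ensemble(path, "pdbq_charged")
        np.testing.assert_allclose(back.times, [100.0, 200.0])
        np.testing.assert_allclose(back.frames[1][1].coords, s.coords + 0.5, atol=5e-4)


class TestTorsionTree:
    def test_chain_moved_sets(self):
        s = _chain_structure()
        tree = build_torsion_tree(s, [(1, 2)])
        assert tree.n_tor == 1
        assert tree.rotatable_bonds[0] == ((1, 2), frozenset({3}))

    def test_nested_moved_sets_and_root_exclusion(self):
        s = _chain_structure()
        tree = build_torsion_tree(s, [(0, 1), (1, 2)])
        assert tree.n_tor == 2
        moved = {bond: moved for bond, moved in tree.rotatable_bonds}
        assert moved[(0, 1)] == frozenset({2, 3})
        assert moved[(1, 2)] == frozenset({3})
        assert moved[(1, 2)] < moved[(0, 1)]  # properly nested
        union = moved[(0, 1)] | moved[(1, 2)]
        assert not (union & tree.root_atom_indices)

    def test_ring_bond_rejected(self):
        # square ring of four atoms
        atoms = [_atom(i + 1, f"L{i + 1}", pos) for i, pos in enumerate(
            [(0, 0, 0), (1.4, 0, 0), (1.4, 1.4, 0), (0, 1.4, 0)])]
        ring = Structure(atoms, ["ligand"] * 4)
        with pytest.raises(StructureError, match="ring"):
            build_torsion_tree(ring, [(0, 1)])

    def test_disconnected_ligand_rejected(self):
        atoms = [_atom(1, "L1", (0, 0, 0)), _atom(2, "L2", (10, 0, 0))]
        s = Structure(atoms, ["ligand"] * 2)
        with pytest.raises(StructureError, match="disconnected"):
            build_torsion_tree(s, [])

    def test_full_turn_restores_coordinates(self):
        s = _chain_structure()
        tree = build_torsion_tree(s, [(1, 2)])
        turned = rotate_torsion(s.coords, tree, 0, 360.0)
        np.testing.assert_allclose(turned, s.coords, atol=1e-9)

    def test_torsion_moves_only_its_subtree(self):
        s = _chain_structure()
        tree = build_torsion_tree(s, [(1, 2)])
        rotated = apply_torsions(s.coords, tree, [73.0])
        np.testing.assert_allclose(rotated[:3], s.coords[:3], atol=1e-12)
        assert np.linalg.norm(rotated[3] - s.coords[3]) > 0.1
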