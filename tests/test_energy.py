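import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popshift.energy import (EnergyParameters, OutOfBoxError, ParameterError,
                             delta_g_to_ki, dielectric, grid_score, load_grid,
                             make_grid_box, pair_energy, save_grid, score_pose)
from popshift.structure_io import Atom, Structure


def _single_atom_structure(atom_type, charge, pos, role, element=None):
    element = element or atom_type[0]
    record = "HETATM" if role == "ligand" else "ATOM"
    resname = "LIG" if role == "ligand" else "REC"
    atom = Atom(1, "X1", element, atom_type, resname, 1, "A",
                np.array(pos, dtype=float), charge, record=record)
    return Structure([atom], [role])


class TestDielectric:
    def test_contact_value(self, params):
        assert dielectric(0.0, params) == pytest.approx(1.347, abs=1e-3)

    def test_bulk_water_limit(self, params):
        assert dielectric(1e6, params) == pytest.approx(78.4, abs=1e-6)

    def test_monotone_nondecreasing(self, params):
        r = np.linspace(0.0, 50.0, 2000)
        eps = dielectric(r, params)
        assert np.all(np.diff(eps) >= 0)

    def test_negative_distance_rejected(self, params):
        with pytest.raises(ValueError):
            dielectric(-0.1, params)


class TestPairEnergy:
    @pytest.mark.parametrize("ti,tj", [("C", "C"), ("C", "OA"), ("H", "Mg"), ("N", "S")])
    def test_vdw_minimum_reproduces_well_depth(self, params, ti, tj):
        pi, pj = params.require_type(ti), params.require_type(tj)
        r_eq = 0.5 * (pi.r_eq + pj.r_eq)
        eps = math.sqrt(pi.eps * pj.eps)
        vdw, *_ = pair_energy(ti, tj, 0.0, 0.0, r_eq, params)
        assert vdw == pytest.approx(-params.w_vdw * eps, rel=1e-12)

    @pytest.mark.parametrize("ti,tj", [("C", "OA"), ("HD", "OA"), ("H", "Mg")])
    def test_pair_symmetry(self, params, ti, tj):
        a = pair_energy(ti, tj, 0.3, -0.2, 2.7, params)
        b = pair_energy(tj, ti, -0.2, 0.3, 2.7, params)
        assert a == pytest.approx(b)

    def test_hbond_only_for_donor_acceptor_pairs(self, params):
        _, hb_da, _, _ = pair_energy("HD", "OA", 0.0, 0.0, 1.9, params)
        _, hb_cc, _, _ = pair_energy("C", "C", 0.0, 0.0, 1.9, params)
        assert hb_da == pytest.approx(-params.w_hbond * 5.0, rel=1e-12)
        assert hb_cc == 0.0

    def test_zero_charge_kills_electrostatics(self, params):
        _, _, elec, _ = pair_energy("C", "C", 0.0, 0.7, 3.0, params)
        assert elec == 0.0

    def test_desolvation_gaussian_tail(self, params):
        *_, d0 = pair_energy("C", "C", 0.0, 0.0, 1e-2, params)
        *_, dfar = pair_energy("C", "C", 0.0, 0.0, 10 * params.sigma, params)
        assert abs(dfar) < 1e-20 * abs(d0)

    def test_clamped_at_clashes(self, params):
        vdw, hbond, elec, desolv = pair_energy("C", "C", 1.0, 1.0, 1e-6, params)
        for term in (vdw, hbond, elec, desolv):
            assert math.isfinite(term)
            assert term <= params.energy_clamp

    def test_unknown_type_rejected(self, params):
        with pytest.raises(ParameterError, match="XX"):
            pair_energy("XX", "C", 0.0, 0.0, 2.0, params)


class TestScorePose:
    def test_single_pair_closed_form(self, params):
        receptor = _single_atom_structure("C", 0.0, (0, 0, 0), "receptor")
        ligand = _single_atom_structure("C", 0.0, (4.0, 0, 0), "ligand")
        sb = score_pose(receptor, ligand, None, params)
        assert sb.vdw == pytest.approx(-params.w_vdw * 0.15, rel=1e-9)
        assert sb.torsional_penalty == 0.0

    def test_separated_limit(self, toy, params):
        receptor, ligand, tree, *_ = toy
        far = ligand.with_coords(ligand.coords + np.array([500.0, 0, 0]))
        sb = score_pose(receptor, far, tree, params)
        assert abs(sb.total_dg - params.w_tor * tree.n_tor) < 1e-3

    def test_doubling_charges_quadruples_elec_only(self, toy, params):
        receptor, ligand, tree, *_ = toy
        sb1 = score_pose(receptor, ligand, tree, params)
        doubled_lig = ligand.with_coords(ligand.coords)
        doubled_rec = receptor.with_coords(receptor.coords)
        for a in doubled_lig.atoms + doubled_rec.atoms:
            a.partial_charge *= 2.0
        sb2 = score_pose(doubled_rec, doubled_lig, tree, params)
        assert sb2.elec == pytest.approx(4.0 * sb1.elec, rel=1e-9)
        assert sb2.vdw == pytest.approx(sb1.vdw, rel=1e-12)
        assert sb2.desolv == pytest.approx(sb1.desolv, rel=1e-12)

    def test_total_is_sum_of_terms(self, toy, params):
        receptor, ligand, tree, *_ = toy
        sb = score_pose(receptor, ligand, tree, params)
        parts = sb.vdw + sb.hbond + sb.elec + sb.desolv + sb.torsional_penalty
        assert sb.total_dg == pytest.approx(parts, abs=1e-9)

    def test_ions_and_waters_excluded_by_default(self, params):
        rec_atoms = [
            Atom(1, "C1", "C", "C", "REC", 1, "A", np.zeros(3), 0.1),
            Atom(2, "MG", "Mg", "Mg", "MG", 2, "A", np.array([3.0, 0, 0]), 2.0),
            Atom(3, "O", "O", "OA", "HOH", 3, "A", np.array([0, 3.0, 0]), -0.8),
        ]
        receptor = Structure(rec_atoms, ["receptor", "ion", "water"])
        ligand = _single_atom_structure("C", 0.5, (0, 0, 4.0), "ligand")
        base = score_pose(receptor, ligand, None, params)
        with_ion = score_pose(receptor, ligand, None, params, include_ions=True)
        only_protein = score_pose(receptor.subset([0]), ligand, None, params)
        assert base.total_dg == pytest.approx(only_protein.total_dg, abs=1e-12)
        assert with_ion.total_dg != pytest.approx(base.total_dg, abs=1e-6)

    def test_clash_flagged_not_nan(self, params):
        receptor = _single_atom_structure("C", 0.2, (0, 0, 0), "receptor")
        ligand = _single_atom_structure("C", 0.2, (0.001, 0, 0), "ligand")
        sb = score_pose(receptor, ligand, None, params)
        assert math.isfinite(sb.total_dg)
        assert any("clash" in w for w in sb.warnings)


class TestGridBox:
    def test_box_edge_length(self, params):
        receptor = _single_atom_structure("C", 0.0, (0, 0, 0), "receptor")
        box = make_grid_box(receptor, 0.375, (100, 100, 100), params, ["C"])
        for ax in box.axes:
            assert ax[-1] - ax[0] == pytest.approx(37.125)

    def test_geometric_center_rule(self, params):
        atoms = [Atom(1, "C1", "C", "C", "REC", 1, "A", np.zeros(3), 0.0),
                 Atom(2, "C2", "C", "C", "REC", 1, "A", np.array([2.0, 0, 0]), 0.0)]
        receptor = Structure(atoms, ["receptor"] * 2)
        box = make_grid_box(receptor, 0.5, (5, 5, 5), params, ["C"])
        np.testing.assert_allclose(box.center, [1.0, 0.0, 0.0])

    @pytest.mark.parametrize("spacing,npts", [(0.0, (5, 5, 5)), (0.375, (1, 5, 5))])
    def test_invalid_grid_parameters(self, params, spacing, npts):
        receptor = _single_atom_structure("C", 0.0, (0, 0, 0), "receptor")
        with pytest.raises(ParameterError):
            make_grid_box(receptor, spacing, npts, params, ["C"])

    def test_single_atom_node_values_match_pair_energy(self, params):
        receptor = _single_atom_structure("C", 0.4, (0, 0, 0), "receptor")
        box = make_grid_box(receptor, 0.5, (21, 21, 21), params, ["OA"],
                            center=(0, 0, 0))
        node = np.array([box.axes[0][17], box.axes[1][10], box.axes[2][10]])
        r = float(np.linalg.norm(node))
        vdw, hbond, elec, desolv = pair_energy("OA", "C", -0.3, 0.4, r, params)
        probe = _single_atom_structure("OA", -0.3, node, "ligand", element="O")
        sb = grid_score(box, probe, None, params)
        assert sb.vdw == pytest.approx(vdw, abs=1e-9)
        assert sb.elec == pytest.approx(elec, abs=1e-9)
        assert sb.desolv == pytest.approx(desolv, abs=1e-9)

    def test_grid_matches_direct_at_nodes(self, toy, toy_box, params):
        receptor, ligand, tree, *_ = toy
        node = np.array([toy_box.axes[0][40], toy_box.axes[1][28], toy_box.axes[2][35]])
        probe = ligand.subset([0]).with_coords(node[None, :])
        gs = grid_score(toy_box, probe, None, params)
        ds = score_pose(receptor, probe, None, params)
        for key in ("vdw", "hbond", "elec", "desolv"):
            assert getattr(gs, key) == pytest.approx(getattr(ds, key), abs=1e-9)

    def test_out_of_box_names_atom(self, toy, toy_box, params):
        receptor, ligand, *_ = toy
        outside = ligand.with_coords(ligand.coords + np.array([100.0, 0, 0]))
        with pytest.raises(OutOfBoxError, match="L1|atom 1"):
            grid_score(toy_box, outside, None, params)

    def test_grid_persistence_round_trip(self, params, tmp_path):
        receptor = _single_atom_structure("C", 0.4, (0, 0, 0), "receptor")
        box = make_grid_box(receptor, 0.5, (7, 7, 7), params, ["C"])
        path = tmp_path / "maps.grid"
        save_grid(box, path)
        back = load_grid(path)
        assert back.npts == box.npts
        np.testing.assert_allclose(back.elec_map, box.elec_map, rtol=1e-6)
        np.testing.assert_allclose(back.vdw_maps["C"], box.vdw_maps["C"], rtol=1e-6)


class TestKiConversion:
    def test_zero_energy_gives_molar_unity(self):
        assert delta_g_to_ki(0.0) == pytest.approx(1.0)

    def test_round_trip_recovers_dg(self):
        for dg in (-12.51, -8.07, -0.3):
            ki = delta_g_to_ki(dg)
            back = math.log(ki) * 1.9872e-3 * 298.15
            assert back == pytest.approx(dg, abs=1e-12)

    @given(st.floats(min_value=-20.0, max_value=5.0),
           st.floats(min_value=-20.0, max_value=5.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_monotone(self, dg1, dg2):
        if dg1 < dg2 - 1e-9:
            assert delta_g_to_ki(dg1) < delta_g_to_ki(dg2)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            delta_g_to_ki(-5.0, temperature=0.0)
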