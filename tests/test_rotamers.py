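import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from popshift.rotamers import (DihedralSeries, angular_histogram, cluster_rotamers,
                               dihedral, dihedral_rmsd, extract_chi_series,
                               match_to_reference, wrap_angle)
from popshift.structure_io import StructureError
from popshift.synthetic import make_rotamer_trajectory, rotamer_trajectory_as_ensemble


class TestDihedral:
    def test_trans_planar(self):
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (-1, 1, 0)) == pytest.approx(180.0)

    def test_cis_planar(self):
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (1, 1, 0)) == pytest.approx(0.0)

    @pytest.mark.parametrize("angle", [-120.0, -60.0, 60.0, 90.0, 150.0])
    def test_rotation_oracle(self, angle):
        # rotate the cis fourth point about the p2-p3 axis by a known angle
        p1, p2, p3, p4 = map(np.array, ((1.0, 0, 0), (0.0, 0, 0), (0.0, 1, 0),
                                        (1.0, 1, 0)))
        axis = (p3 - p2) / np.linalg.norm(p3 - p2)
        rot = Rotation.from_rotvec(np.radians(angle) * axis)
        p4r = rot.apply(p4 - p3) + p3
        assert dihedral(p1, p2, p3, p4r) == pytest.approx(angle, abs=1e-9)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            dihedral((0, 0, 0), (0, 0, 0), (0, 1, 0), (1, 1, 0))
        with pytest.raises(ValueError):
            dihedral((2, 0, 0), (1, 0, 0), (0, 0, 0), (-1, 0, 0))


class TestExtractChiSeries:
    def test_round_trip_through_template(self):
        mixture = ({"mean": (-70.0, 180.0, 65.0, 90.0), "kappa": 1e6, "weight": 1.0},)
        series, coords, _ = make_rotamer_trajectory(mixture, n_frames=3, seed=4)
        traj = rotamer_trajectory_as_ensemble(series, coords)
        back = extract_chi_series(traj, series.residue_id)
        d = np.abs(wrap_angle(back.chi - series.chi))
        assert d.max() < 0.5

    def test_missing_atom_named_in_error(self):
        series, coords, _ = make_rotamer_trajectory(n_frames=2, seed=0)
        traj = rotamer_trajectory_as_ensemble(series, coords)
        frame = traj.frames[1][1]
        frame.atoms = [a for a in frame.atoms if a.name != "CG"]
        frame.role_labels = frame.role_labels[:len(frame.atoms)]
        traj.topology_constant = False
        with pytest.raises(StructureError, match="CG"):
            extract_chi_series(traj, series.residue_id)

    def test_single_frame_series(self):
        series, coords, _ = make_rotamer_trajectory(n_frames=1, seed=0)
        traj = rotamer_trajectory_as_ensemble(series, coords)
        assert extract_chi_series(traj, series.residue_id).n_frames == 1


class TestAngularHistogram:
    def test_single_peak_at_concentration(self):
        centers, densities, peaks = angular_histogram([-70.0] * 100, 10.0)
        assert len(peaks) == 1
        assert abs(peaks[0] - (-65.0)) <= 5.0  # the bin containing -70
        assert float(densities.sum() * 10.0) == pytest.approx(1.0)

    def test_wraparound_merges_into_single_peak(self):
        angles = [179.0] * 50 + [-179.0] * 50
        _, _, peaks = angular_histogram(angles, 10.0)
        assert len(peaks) == 1
        assert abs(abs(peaks[0]) - 180.0) <= 5.0

    def test_flat_distribution_has_no_peak(self):
        angles = list(np.arange(0.0, 360.0, 10.0))
        _, densities, peaks = angular_histogram(angles, 10.0)
        assert peaks == []
        np.testing.assert_allclose(densities, densities[0])

    def test_peaks_invariant_under_full_turn_shift(self):
        angles = np.array([-70.0] * 60 + [50.0] * 40)
        _, _, p1 = angular_histogram(angles, 10.0)
        _, _, p2 = angular_histogram(angles + 360.0, 10.0)
        assert p1 == p2

    def test_bin_width_must_divide_circle(self):
        with pytest.raises(ValueError):
            angular_histogram([0.0], 7.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            angular_histogram([], 10.0)


class TestDihedralRmsd:
    def test_identity(self):
        assert dihedral_rmsd((10, 20, 30, 40), (10, 20, 30, 40)) == 0.0

    def test_uniform_offset(self):
        assert dihedral_rmsd((0, 0, 0, 0), (10, 10, 10, 10)) == pytest.approx(10.0)

    def test_periodic_difference(self):
        assert dihedral_rmsd((175, 0, 0, 0), (-175, 0, 0, 0)) == pytest.approx(5.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dihedral_rmsd((0, 0), (0, 0, 0))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_metric_on_torus(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.uniform(-180.0, 180.0, size=(3, 4))
        dab = dihedral_rmsd(a, b)
        assert dab == pytest.approx(dihedral_rmsd(b, a))
        assert dab >= 0
        assert dihedral_rmsd(a, c) <= dab + dihedral_rmsd(b, c) + 1e-9


def _series(chi):
    chi = np.asarray(chi, dtype=float)
    return DihedralSeries(("A", 1, "ARG"), chi, np.arange(1, len(chi) + 1, dtype=float),
                          [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
                           ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")])


class TestClusterRotamers:
    def test_two_well_separated_states(self):
        chi = [(-70, 180, 60, 85)] * 10 + [(-170, 60, -80, 0)] * 10
        clustering = cluster_rotamers([_series(chi)], cutoff=30.0)
        assert clustering.n_clusters == 2
        np.testing.assert_allclose(sorted(clustering.populations), [0.5, 0.5])

    def test_all_identical_single_cluster(self):
        clustering = cluster_rotamers([_series([(10, 20, 30, 40)] * 5)], cutoff=40.0)
        assert clustering.n_clusters == 1
        np.testing.assert_allclose(clustering.centroids[0][1], [10, 20, 30, 40])

    def test_partition_invariant_to_frame_order(self, rng):
        base = [(-70, 180, 60, 85)] * 12 + [(-170, 60, -80, 0)] * 6 + [(60, -60, 180, 0)] * 3
        perm = rng.permutation(len(base))
        c1 = cluster_rotamers([_series(base)], cutoff=40.0)
        c2 = cluster_rotamers([_series([base[i] for i in perm])], cutoff=40.0)
        assert c1.n_clusters == c2.n_clusters
        np.testing.assert_allclose(sorted(c1.populations), sorted(c2.populations))
        # frames carried to the same cluster ids after population renumbering
        remapped = np.empty(len(base), dtype=int)
        remapped[perm] = c2.assignments
        assert np.array_equal(remapped, c1.assignments)

    def test_pooling_multiple_series(self):
        s1 = _series([(-70, 180, 60, 85)] * 8)
        s2 = _series([(-170, 60, -80, 0)] * 4)
        clustering = cluster_rotamers([s1, s2], cutoff=30.0)
        assert clustering.n_clusters == 2
        np.testing.assert_allclose(clustering.populations, [8 / 12, 4 / 12])

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            cluster_rotamers([_series([(0, 0, 0, 0)])], cutoff=0.0)


class TestMatchToReference:
    def test_exact_match_distance_zero(self):
        clustering = cluster_rotamers([_series([(10, 20, 30, 40)] * 3)], 40.0)
        out = match_to_reference(clustering, [{"name": "xtal", "chi": (10, 20, 30, 40)}])
        assert out[0]["reference"] == "xtal"
        assert out[0]["dihedral_rmsd_deg"] == pytest.approx(0.0)

    def test_nearer_of_two_references_selected(self):
        clustering = cluster_rotamers([_series([(0, 0, 0, 0)] * 3)], 40.0)
        refs = [{"name": "near", "chi": (5, 5, 5, 5)},
                {"name": "far", "chi": (80, 80, 80, 80)}]
        out = match_to_reference(clustering, refs)
        assert out[0]["reference"] == "near"

    def test_coordinate_metric_reports_displacement(self):
        mixture = ({"mean": (-70.0, 180.0, 65.0, 90.0), "kappa": 1e6, "weight": 1.0},)
        series, coords, _ = make_rotamer_trajectory(mixture, n_frames=3, seed=1)
        clustering = cluster_rotamers([series], 40.0)
        frame = clustering.centroids[0][0]
        shifted = {k: np.asarray(v) + np.array([0.5, 0.0, 0.0])
                   for k, v in coords[frame].items()}
        refs = [{"name": "shifted", "chi": tuple(clustering.centroids[0][1]),
                 "coords": shifted}]
        out = match_to_reference(clustering, refs, centroid_coords=[coords[frame]])
        assert out[0]["cartesian_rmsd_A"] == pytest.approx(0.5, abs=1e-9)

    def test_empty_references_rejected(self):
        clustering = cluster_rotamers([_series([(0, 0, 0, 0)])], 40.0)
        with pytest.raises(ValueError):
            match_to_reference(clustering, [])
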