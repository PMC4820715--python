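"""Superposition RMSD, residue-center distances, hydrogen-bond occupancy and
multi-model PDB round trips."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from quadmsm.featurize import (Structure, Trajectory, backbone_selection,
                               centroid_distances, hbond_occupancy,
                               kabsch_superpose, read_structure,
                               read_trajectory, rmsd_series, write_structure,
                               write_trajectory)

from conftest import make_structure, make_trajectory


def rotate(struct, R, t=np.zeros(3)):
    return struct.with_coords(struct.coords @ np.asarray(R).T + t)


class TestKabsch:
    def test_identical_structures_have_zero_rmsd(self, tetra):
        R, t, rmsd = kabsch_superpose(tetra, tetra)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-8)

    def test_rigid_transform_invariance(self, tetra):
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = rotate(tetra, Rz, t=np.array([3.0, -1.0, 7.0]))
        R, t, rmsd = kabsch_superpose(tetra, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_symmetric_and_rigid_invariant(self, tetra, rng):
        other = tetra.with_coords(tetra.coords + rng.normal(0, 0.8, tetra.coords.shape))
        r_ab = kabsch_superpose(tetra, other)[2]
        r_ba = kabsch_superpose(other, tetra)[2]
        assert r_ab == pytest.approx(r_ba, abs=1e-10)
        for _ in range(5):
            R = Rotation.random(random_state=np.random.RandomState(
                int(rng.integers(2**31)))).as_matrix()
            t = rng.normal(0, 10, 3)
            assert kabsch_superpose(rotate(other, R, t), tetra)[2] == \
                pytest.approx(r_ab, abs=1e-8)

    def test_superposed_rmsd_below_raw_deviation(self, tetra, rng):
        for _ in range(5):
            R = Rotation.random(random_state=np.random.RandomState(
                int(rng.integers(2**31)))).as_matrix()
            other = rotate(tetra.with_coords(
                tetra.coords + rng.normal(0, 0.5, tetra.coords.shape)), R)
            raw = np.sqrt(np.mean(np.sum((other.coords - tetra.coords) ** 2, axis=1)))
            assert kabsch_superpose(other, tetra)[2] <= raw + 1e-12

    def test_matches_rotation_search_oracle(self, tetra, rng):
        """Brute-force search over rotations (grid + polish) as an independent
        check that the returned RMSD is the global minimum."""
        mobile = tetra.with_coords(tetra.coords + rng.normal(0, 1.0, tetra.coords.shape))
        _, _, rmsd = kabsch_superpose(mobile, tetra)
        xm = mobile.coords - mobile.coords.mean(0)
        xr = tetra.coords - tetra.coords.mean(0)

        def cost(rotvec):
            Rm = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(np.mean(np.sum((xm @ Rm.T - xr) ** 2, axis=1)))

        best = np.inf
        grid = np.linspace(-np.pi, np.pi, 7)
        for a in grid:
            for b in grid:
                for c in grid:
                    res = minimize(cost, np.array([a, b, c]), method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-14})
                    best = min(best, res.fun)
        assert rmsd == pytest.approx(best, abs=1e-6)

    def test_mismatched_selection_names_missing_atoms(self, tetra):
        other = make_structure(tetra.coords[:3])
        with pytest.raises(ValueError, match="unmatched"):
            kabsch_superpose(tetra, other)

    def test_collinear_selection_rejected(self):
        line = make_structure([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_copies_of_reference_give_zero_series(self, tetra):
        traj = make_trajectory(np.repeat(tetra.coords[None], 4, axis=0))
        series = rmsd_series(traj, tetra, selection=None)
        assert len(series) == 4
        assert np.allclose(series["rmsd"], 0.0, atol=1e-9)

    def test_framewise_agrees_with_single_superposition(self, tetra, rng):
        frames = tetra.coords[None] + rng.normal(0, 0.7, (6,) + tetra.coords.shape)
        traj = make_trajectory(frames)
        series = rmsd_series(traj, tetra, selection=None)["rmsd"].to_numpy()
        singles = [kabsch_superpose(traj.frame(i), tetra, None)[2] for i in range(6)]
        assert np.allclose(series, singles, atol=1e-9)

    def test_backbone_selection_restricts_atoms(self):
        names = ["P", "O5'", "C5'", "C4'", "C3'", "O3'", "N1", "N9"]
        coords = np.arange(24, dtype=float).reshape(8, 3)
        coords[:, 1] = [0, 1, 0, 2, 1, 3, 9, 9]   # break collinearity
        coords[6:] += 100.0                        # base atoms far off
        s = make_structure(coords, names=names, residues=["G1"] * 8,
                           elements=["P", "O", "C", "C", "C", "O", "N", "N"])
        traj = make_trajectory(np.repeat(coords[None], 2, axis=0), names=names,
                               residues=["G1"] * 8,
                               elements=["P", "O", "C", "C", "C", "O", "N", "N"])
        assert np.allclose(rmsd_series(traj, s, "backbone")["rmsd"], 0.0, atol=1e-9)
        mask = backbone_selection()(s)
        assert mask.sum() == 6 and not mask[6] and not mask[7]


class TestCentroidDistances:
    def test_three_four_five(self):
        s = make_structure([[0, 0, 0], [3, 4, 0]], residues=["G1", "G2"])
        d = centroid_distances(s, [("G1", "G2")])
        assert d["distance"].iloc[0] == pytest.approx(5.0)

    def test_residue_vs_itself_is_zero(self):
        s = make_structure([[1, 2, 3], [4, 5, 6]], residues=["G1", "G2"])
        assert centroid_distances(s, [("G1", "G1")])["distance"].iloc[0] == 0.0

    def test_molecular_center_hand_computed(self):
        # heavy-atom center of the whole molecule at (2, 0, 0);
        # G1 heavy center at (0, 0, 0): distance exactly 2. The hydrogen
        # must not contribute.
        s = make_structure([[0, 0, 0], [4, 0, 0], [99, 99, 99]],
                           residues=["G1", "G2", "G2"],
                           elements=["C", "C", "H"])
        d = centroid_distances(s, [("G1", "C")])
        assert d["distance"].iloc[0] == pytest.approx(2.0)

    def test_unknown_residue_raises(self, tetra):
        with pytest.raises(ValueError, match="unknown residue"):
            centroid_distances(tetra, [("G1", "G99")])

    def test_mass_weighted_center_convention(self):
        # C at origin, O at (2,0,0): geometric center 1.0; mass-weighted
        # center at 2*15.999/(12.011+15.999) = 1.1424 from the carbon.
        s = make_structure([[0, 0, 0], [2, 0, 0], [10, 0, 0]],
                           residues=["G1", "G1", "G2"], elements=["C", "O", "C"])
        geo = centroid_distances(s, [("G1", "G2")])["distance"].iloc[0]
        mw = centroid_distances(s, [("G1", "G2")], mass_weighted=True)["distance"].iloc[0]
        assert geo == pytest.approx(9.0)
        assert mw == pytest.approx(10.0 - 2 * 15.999 / (12.011 + 15.999), abs=1e-6)


def _hbond_frame(da_dist, angle_deg=170.0):
    """Donor N with bonded H, acceptor O at the given distance and
    donor-H-acceptor angle."""
    donor = np.array([0.0, 0, 0])
    h = np.array([1.0, 0, 0])
    # place acceptor so that the angle at H between (donor-h) and (acc-h) is angle_deg
    theta = np.radians(180.0 - angle_deg)
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    acc = h + direction * (da_dist - 1.0)  # approximately da_dist from donor for small theta
    return np.stack([donor, h, acc])


class TestHbondOccupancy:
    names = ["N7", "H7", "O6"]
    residues = ["G1", "G1", "G2"]
    elements = ["N", "H", "O"]

    def frame(self, da_dist, angle=170.0):
        return make_structure(_hbond_frame(da_dist, angle), names=self.names,
                              residues=self.residues, elements=self.elements)

    def test_always_bonded_pair_is_100_percent(self):
        records = hbond_occupancy([self.frame(2.9)] * 100, min_report=50.0)
        assert any(r.donor == "N7@G1" and r.acceptor == "O6@G2"
                   and r.occupancy == 100.0 for r in records)

    def test_distant_pair_absent(self):
        records = hbond_occupancy([self.frame(6.0)] * 10, min_report=0.0)
        assert not any(r.donor == "N7@G1" and r.acceptor == "O6@G2" for r in records)

    def test_partial_occupancy_exact_ratio(self):
        frames = [self.frame(2.9)] * 75 + [self.frame(6.0)] * 25
        records = hbond_occupancy(frames, min_report=50.0)
        rec = next(r for r in records if r.donor == "N7@G1" and r.acceptor == "O6@G2")
        assert rec.occupancy == pytest.approx(75.0)

    def test_angle_criterion_rejects_bent_geometry(self):
        records = hbond_occupancy([self.frame(2.9, angle=90.0)] * 10, min_report=0.0)
        assert not any(r.donor == "N7@G1" and r.acceptor == "O6@G2" for r in records)

    def test_occupancy_permutation_invariant(self, rng):
        frames = [self.frame(2.9)] * 60 + [self.frame(6.0)] * 40
        perm = list(rng.permutation(len(frames)))
        a = hbond_occupancy(frames, min_report=10.0)
        b = hbond_occupancy([frames[i] for i in perm], min_report=10.0)
        assert {(r.donor, r.acceptor, r.occupancy) for r in a} == \
               {(r.donor, r.acceptor, r.occupancy) for r in b}

    def test_distance_only_fallback_without_hydrogens(self):
        s = make_structure([[0, 0, 0], [3.0, 0, 0]], names=["N7", "O6"],
                           residues=["G1", "G2"], elements=["N", "O"])
        records = hbond_occupancy([s] * 5, min_report=50.0)
        assert any(r.donor == "N7@G1" and r.acceptor == "O6@G2"
                   and r.occupancy == 100.0 for r in records)

    def test_empty_structure_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hbond_occupancy([])


class TestPdbIO:
    def test_trajectory_round_trip(self, tmp_path, rng):
        frames = rng.normal(0, 5, (3, 15, 3))
        residues = [f"{b}{i + 1}" for i, b in enumerate("GGTTGGTGTGGTTGG")]
        traj = make_trajectory(frames, names=["C1'"] * 15, residues=residues,
                               elements=["C"] * 15, frame_interval=2.0)
        path = write_trajectory(traj, tmp_path / "traj.pdb")
        back = read_trajectory(path, frame_interval=2.0)
        assert back.n_frames == 3
        assert list(back.residues) == residues
        # PDB coordinate records carry 3 decimals
        assert np.allclose(back.coords, frames, atol=2e-3)

    def test_model_index_selects_frame(self, tmp_path, rng):
        frames = rng.normal(0, 5, (4, 4, 3))
        traj = make_trajectory(frames)
        path = write_trajectory(traj, tmp_path / "multi.pdb")
        third = read_structure(path, model=3)
        assert np.allclose(third.coords, frames[2], atol=2e-3)
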