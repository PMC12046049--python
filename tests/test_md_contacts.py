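"""H-bond geometry, occupancy maps, contact profiles, superposition RMSD."""

import numpy as np
import pytest

from dimeq.errors import ValidationError
from dimeq.md_contacts import (
    HBondCriteria,
    OccupancyMap,
    Trajectory,
    apply_rigid,
    contact_profile,
    detect_hbonds_frame,
    hbond_occupancy,
    kabsch_superpose,
    occupancy_difference,
    surface_saturation_values,
    trajectory_rmsd,
)
from dimeq.synthetic import TrajectorySpec, _rotation_matrix, gen_trajectory

from conftest import make_two_chain_frame


class TestDetection:
    def test_ideal_geometry_detected(self, ideal_hbond_frame):
        bonds = detect_hbonds_frame(ideal_hbond_frame, 0)
        assert len(bonds) == 1
        d, h, a = bonds[0]
        assert ideal_hbond_frame.atom_names[d] == "N"
        assert ideal_hbond_frame.atom_names[a] == "O"

    def test_angle_just_below_cutoff_rejected(self):
        traj = make_two_chain_frame(2.0, angle_deg=149.0)
        assert detect_hbonds_frame(traj, 0) == []

    def test_boundary_distance_and_angle_inclusive(self):
        traj = make_two_chain_frame(3.0, angle_deg=160.0)
        assert len(detect_hbonds_frame(traj, 0)) == 1
        traj = make_two_chain_frame(2.0, angle_deg=150.0)
        assert len(detect_hbonds_frame(traj, 0)) == 1

    def test_distance_beyond_cutoff_rejected(self):
        traj = make_two_chain_frame(3.01, angle_deg=180.0)
        assert detect_hbonds_frame(traj, 0) == []

    def test_missing_hydrogens_is_hard_error(self, ideal_hbond_frame):
        t = ideal_hbond_frame
        keep = t.elements != "H"
        stripped = Trajectory(
            t.coords[:, keep],
            t.chain_ids[keep],
            t.res_ids[keep],
            t.res_names[keep],
            t.atom_names[keep],
            t.elements[keep],
        )
        with pytest.raises(ValidationError, match="hydrogen"):
            detect_hbonds_frame(stripped, 0)

    def test_criteria_validation(self):
        with pytest.raises(ValidationError):
            HBondCriteria(max_dh=-1.0)
        with pytest.raises(ValidationError):
            HBondCriteria(min_angle_dha=181.0)


class TestOccupancy:
    def test_seven_of_ten_frames_is_seventy_pct(self):
        traj, _ = gen_trajectory(TrajectorySpec(pairs=((1, 101, 70.0),), n_frames=10))
        occ = hbond_occupancy(traj)
        assert occ.entries[("A", 1, "B", 101)] == 70.0

    def test_multiple_simultaneous_bonds_count_once(self):
        # two donors on the same residue pointing at the same acceptor
        coords = np.array(
            [
                [0.0, 0.0, 0.0],  # N1
                [1.0, 0.0, 0.0],  # H1
                [0.0, 2.0, 0.0],  # N2 (second donor, same residue)
                [1.0, 2.0, 0.0],  # H2
                [3.0, 1.0, 0.0],  # O accepting from both donors
            ]
        )[None, :, :]
        traj = Trajectory(
            coords,
            np.array(["A", "A", "A", "A", "B"]),
            np.array([1, 1, 1, 1, 9]),
            np.array(["GLY"] * 5),
            np.array(["N", "H1", "N2", "H2", "O"]),
            np.array(["N", "H", "N", "H", "O"]),
        )
        capped = hbond_occupancy(traj)
        assert capped.entries[("A", 1, "B", 9)] == 100.0
        summed = hbond_occupancy(traj, count_multiple=True)
        assert summed.entries[("A", 1, "B", 9)] == 200.0

    def test_no_bonds_absent_from_sparse_map(self):
        traj, _ = gen_trajectory(TrajectorySpec(pairs=((1, 101, 0.0),), n_frames=10))
        occ = hbond_occupancy(traj)
        assert occ.entries == {}

    def test_frame_permutation_invariance(self):
        traj, _ = gen_trajectory(TrajectorySpec(pairs=((1, 101, 40.0),), n_frames=10))
        rng = np.random.default_rng(0)
        perm = rng.permutation(traj.n_frames)
        shuffled = Trajectory(
            traj.coords[perm],
            traj.chain_ids,
            traj.res_ids,
            traj.res_names,
            traj.atom_names,
            traj.elements,
        )
        assert hbond_occupancy(traj).entries == hbond_occupancy(shuffled).entries

    def test_rigid_motion_equivariance(self):
        traj, _ = gen_trajectory(TrajectorySpec(pairs=((1, 101, 55.0),), n_frames=20))
        rng = np.random.default_rng(1)
        moved = apply_rigid(traj, _rotation_matrix(rng), [5.0, -3.0, 11.0])
        assert hbond_occupancy(traj).entries == pytest.approx(
            hbond_occupancy(moved).entries
        )


class TestDifferenceMap:
    def test_identical_maps_give_zero(self):
        m = OccupancyMap({("A", 1, "B", 2): 40.0}, 10)
        d = occupancy_difference(m, m)
        assert d.entries == {("A", 1, "B", 2): 0.0}

    def test_lost_and_gained_contacts(self):
        # an interface bond lost on modification and a new salt bridge gained
        wt = OccupancyMap({("A", 2681, "B", 2683): 71.0}, 100)
        mod = OccupancyMap({("A", 2677, "B", 2690): 26.0}, 100)
        diff = occupancy_difference(wt, mod)
        assert diff.entries[("A", 2681, "B", 2683)] == -71.0
        assert diff.entries[("A", 2677, "B", 2690)] == 26.0

    def test_antisymmetry(self):
        a = OccupancyMap({("A", 1, "B", 2): 63.0, ("A", 3, "B", 4): 10.0}, 10)
        b = OccupancyMap({("A", 1, "B", 2): 1.0, ("A", 5, "B", 6): 38.0}, 10)
        fwd = occupancy_difference(a, b)
        rev = occupancy_difference(b, a)
        assert set(fwd.entries) == set(rev.entries)
        for k in fwd.entries:
            assert fwd.entries[k] == -rev.entries[k]


def brute_force_profile(traj, query, partner):
    """O(n^2) oracle: triple loop over frames, residues and atom pairs."""
    heavy = traj.elements != "H"
    q_idx = [
        i
        for i in range(traj.n_atoms)
        if traj.chain_ids[i] == query and heavy[i]
    ]
    p_idx = [
        i
        for i in range(traj.n_atoms)
        if traj.chain_ids[i] == partner and heavy[i]
    ]
    res_ids = sorted({int(traj.res_ids[i]) for i in q_idx})
    mins, avgs = [], []
    for res in res_ids:
        per_frame = []
        for fi in range(traj.n_frames):
            best = np.inf
            for i in q_idx:
                if traj.res_ids[i] != res:
                    continue
                for j in p_idx:
                    d = np.linalg.norm(traj.coords[fi, i] - traj.coords[fi, j])
                    best = min(best, d)
            per_frame.append(best)
        mins.append(min(per_frame))
        avgs.append(float(np.mean(per_frame)))
    return np.array(res_ids), np.array(mins), np.array(avgs)


class TestContactProfile:
    def test_static_frame_min_equals_avg(self):
        traj = make_two_chain_frame(3.5, angle_deg=180.0)
        prof = contact_profile(traj, "A", "B")
        assert np.allclose(prof.min_shortest, prof.avg_shortest)

    def test_three_frame_min_and_mean(self):
        base = make_two_chain_frame(2.0)
        coords = np.concatenate(
            [
                make_two_chain_frame(d).coords
                for d in (1.0, 3.0, 5.0)  # N-O distances 2, 4, 6 A
            ]
        )
        traj = Trajectory(
            coords, base.chain_ids, base.res_ids, base.res_names,
            base.atom_names, base.elements,
        )
        prof = contact_profile(traj, "A", "B")
        res1 = np.flatnonzero(prof.res_ids == 1)[0]
        assert prof.min_shortest[res1] == pytest.approx(2.0)
        assert prof.avg_shortest[res1] == pytest.approx(4.0)

    def test_matches_brute_force_on_random_trajectory(self):
        rng = np.random.default_rng(7)
        n_atoms, n_frames = 60, 4
        chain_ids = np.array(["A"] * 30 + ["B"] * 30)
        res_ids = np.array([i // 5 + 1 for i in range(30)] + [100 + i // 5 for i in range(30)])
        elements = np.array((["C", "N", "O", "H", "C"] * 12))
        traj = Trajectory(
            rng.normal(0, 8, (n_frames, n_atoms, 3)),
            chain_ids,
            res_ids,
            np.array(["GLY"] * n_atoms),
            np.array(["X"] * n_atoms),
            elements,
        )
        prof = contact_profile(traj, "A", "B")
        res, mins, avgs = brute_force_profile(traj, "A", "B")
        assert np.array_equal(prof.res_ids, res)
        assert np.allclose(prof.min_shortest, mins, atol=1e-9)
        assert np.allclose(prof.avg_shortest, avgs, atol=1e-9)
        assert np.all(prof.min_shortest <= prof.avg_shortest + 1e-12)

    def test_no_heavy_atoms_rejected(self, ideal_hbond_frame):
        t = ideal_hbond_frame
        with pytest.raises(ValidationError):
            contact_profile(t, "A", "C")


class TestSaturation:
    def test_clamps_and_midpoint(self):
        from dimeq.md_contacts import ContactProfile

        prof = ContactProfile(
            res_ids=np.array([1, 2, 3]),
            min_shortest=np.array([1.0, 8.0, 20.0]),
            avg_shortest=np.array([2.0, 9.0, 20.0]),
        )
        sat = surface_saturation_values(prof, d_min=3.0, d_max=15.0)
        assert sat[0] == 1.0
        assert sat[1] == pytest.approx(0.5)
        assert sat[2] == 0.0

    def test_degenerate_range_rejected(self):
        from dimeq.md_contacts import ContactProfile

        prof = ContactProfile(np.array([1]), np.array([2.0]), np.array([2.0]))
        with pytest.raises(ValidationError):
            surface_saturation_values(prof, d_min=5.0, d_max=5.0)


class TestRmsd:
    def test_reference_against_itself_is_zero(self):
        traj, _ = gen_trajectory(TrajectorySpec(n_frames=3))
        assert trajectory_rmsd(traj, 0)[0] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_superposes_to_zero(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(0, 10, (1, 40, 3))
        rot = _rotation_matrix(rng)
        moved = ref @ rot.T + np.array([3.0, -7.0, 1.0])
        traj = Trajectory(
            np.concatenate([ref, moved]),
            np.array(["A"] * 40),
            np.arange(40),
            np.array(["GLY"] * 40),
            np.array(["CA"] * 40),
            np.array(["C"] * 40),
        )
        assert trajectory_rmsd(traj, 0)[1] <= 1e-8

    def test_single_atom_displacement_closed_form(self):
        # 49 symmetric atom pairs + two atoms at the origin; displacing one
        # origin atom by d leaves no net rotation, so the optimal-superposition
        # RMSD is exactly d*sqrt(n-1)/n (translation absorbs d/n).
        rng = np.random.default_rng(0)
        pairs = rng.normal(0, 10, (49, 3))
        ref = np.vstack([pairs, -pairs, [[0.0, 0.0, 0.0]], [[0.0, 0.0, 0.0]]])
        mob = ref.copy()
        mob[-1, 0] += 1.0
        _, rmsd = kabsch_superpose(mob, ref)
        assert rmsd == pytest.approx(np.sqrt(99) / 100, abs=1e-9)

    def test_agrees_with_quaternion_oracle(self):
        mda = pytest.importorskip("MDAnalysis.analysis.rms")
        rng = np.random.default_rng(11)
        ref = rng.normal(0, 10, (80, 3))
        mob = ref + rng.normal(0, 0.5, (80, 3))
        _, mine = kabsch_superpose(mob, ref)
        theirs = mda.rmsd(mob, ref, superposition=True)
        assert mine == pytest.approx(theirs, abs=1e-8)

    def test_empty_selection_rejected(self):
        traj, _ = gen_trajectory(TrajectorySpec(n_frames=2))
        with pytest.raises(ValidationError):
            trajectory_rmsd(traj, 0, np.zeros(traj.n_atoms, dtype=bool))
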