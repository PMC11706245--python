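"""Window-conditioned average structures and inter-base-pair pitch."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from codonpmf import (
    AverageStructure,
    Snapshot,
    Trajectory,
    WindowSpec,
    average_structure,
    base_pair_centers,
    inter_pair_pitch,
    select_snapshots,
)
from codonpmf.dynamics import BEAD_NAMES, _embed_cv_coords


def snap(cv, step=0) -> Snapshot:
    return Snapshot(step=step, coords=_embed_cv_coords(np.asarray(cv))[0], cv=np.asarray(cv, float))


def traj_from_cvs(cvs) -> Trajectory:
    cvs = np.asarray(cvs, dtype=float)
    return Trajectory(
        steps=np.arange(len(cvs)),
        coords=_embed_cv_coords(cvs),
        cv=cvs,
        energy=np.zeros(len(cvs)),
        names=list(BEAD_NAMES),
    )


class TestWindowSelection:
    def test_bound_state_window_membership(self):
        window = WindowSpec(center=(4.5, 4.5, 4.5), half_width=0.25)
        traj = traj_from_cvs([
            (4.5, 4.5, 4.5),    # center: included
            (4.76, 4.5, 4.5),   # just outside on d1: excluded
            (4.25, 4.25, 4.25), # exactly on the lower boundary: included
            (4.75, 4.75, 4.75), # exactly on the upper boundary: included
        ])
        picked = select_snapshots(traj, window)
        assert [int(s.step) for s in picked] == [0, 2, 3]

    def test_empty_selection_names_window_and_nearest(self):
        traj = traj_from_cvs([(8.0, 8.0, 8.0)])
        with pytest.raises(ValueError, match=r"4.5.*8.0"):
            select_snapshots(traj, WindowSpec(center=(4.5, 4.5, 4.5), half_width=0.25))

    def test_window_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            WindowSpec(center=(4.1, 4.5, 4.5), half_width=0.25)


class TestAverageStructure:
    def test_two_snapshot_mean(self):
        s1 = snap((4.0, 5.0, 6.0))
        s2 = snap((6.0, 5.0, 6.0))
        avg = average_structure([s1, s2])
        assert np.allclose(avg.coords[3], (5.0, 0.0, 0.0))
        assert avg.n_snapshots == 2

    def test_single_snapshot_is_identity(self):
        s = snap((4.7, 5.1, 5.6))
        avg = average_structure([s])
        assert np.array_equal(avg.coords, s.coords)

    def test_matches_independent_mean(self, rng):
        cvs = rng.uniform(4.5, 8.5, size=(100, 3))
        snaps = [snap(c, step=i) for i, c in enumerate(cvs)]
        avg = average_structure(snaps)
        direct = np.mean([s.coords for s in snaps], axis=0)
        assert np.array_equal(avg.coords, direct)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no snapshots"):
            average_structure([])

    def test_skew_flag_raised_for_large_fluctuations(self, rng):
        d1 = np.where(np.arange(400) % 2 == 0, 4.3, 8.7)  # +/- 2.2 A hops on d1
        cvs = np.column_stack([d1, np.full(400, 5.0), np.full(400, 5.0)])
        avg = average_structure([snap(c, i) for i, c in enumerate(cvs)])
        assert avg.skew_flags[3]        # anticodon bead 1 rides d1
        assert not avg.skew_flags[0]    # codon beads are pinned in this frame

    def test_selection_average_commutes_with_concatenation(self, rng):
        window = WindowSpec(center=(5.0, 5.0, 5.0), half_width=0.5)
        t1 = traj_from_cvs(rng.uniform(4.5, 6.0, size=(60, 3)))
        t2 = traj_from_cvs(rng.uniform(4.5, 6.0, size=(40, 3)))
        both = Trajectory.concatenate([t1, t2])
        sel = select_snapshots(both, window)
        avg_union = average_structure(sel)
        s1 = select_snapshots(t1, window)
        s2 = select_snapshots(t2, window)
        weighted = (len(s1) * average_structure(s1).coords
                    + len(s2) * average_structure(s2).coords) / (len(s1) + len(s2))
        assert np.allclose(avg_union.coords, weighted, atol=1e-12)
        assert avg_union.n_snapshots == len(s1) + len(s2)


class TestPitch:
    def test_collinear_centers(self):
        centers = np.array([[0, 0, 0], [0, 0, 3.4], [0, 0, 6.8]], dtype=float)
        res = inter_pair_pitch(centers)
        assert res.pitch_12 == pytest.approx(3.4)
        assert res.pitch_23 == pytest.approx(3.4)

    def test_coincident_centers(self):
        centers = np.ones((3, 3))
        res = inter_pair_pitch(centers)
        assert res.pitch_12 == 0.0 and res.pitch_23 == 0.0

    def test_matches_euclidean_norm(self, rng):
        centers = rng.normal(size=(3, 3))
        res = inter_pair_pitch(centers)
        assert res.pitch_12 == pytest.approx(np.linalg.norm(centers[1] - centers[0]))
        assert res.pitch_23 == pytest.approx(np.linalg.norm(centers[2] - centers[1]))

    def test_rigid_motion_invariance(self, rng):
        snaps = [snap(c, i) for i, c in enumerate(rng.uniform(4.5, 6.0, size=(30, 3)))]
        base = inter_pair_pitch(base_pair_centers(average_structure(snaps)))
        rot = Rotation.random(random_state=7).as_matrix()
        shift = np.array([3.0, -2.0, 11.0])
        moved = [Snapshot(step=s.step, coords=s.coords @ rot.T + shift,
                          cv=s.cv) for s in snaps]
        res = inter_pair_pitch(base_pair_centers(average_structure(moved)))
        assert res.pitch_12 == pytest.approx(base.pitch_12, abs=1e-9)
        assert res.pitch_23 == pytest.approx(base.pitch_23, abs=1e-9)

    def test_recovers_known_geometry_from_noisy_snapshots(self, rng):
        """Symmetric noise around an ideal geometry averages out."""
        ideal_cv = np.array([4.6, 4.6, 4.6])
        ideal = _embed_cv_coords(ideal_cv)[0]
        true_pitch = inter_pair_pitch(base_pair_centers(AverageStructure(
            coords=ideal, n_snapshots=1, names=tuple(BEAD_NAMES),
            coord_std=np.zeros((6, 3)), skew_flags=np.zeros(6, bool))))
        snaps = []
        for i in range(2000):
            noisy = ideal + rng.normal(0.0, 0.3, size=(6, 3))
            cv = np.linalg.norm(noisy[:3] - noisy[3:], axis=1)
            snaps.append(Snapshot(step=i, coords=noisy, cv=cv))
        avg = average_structure(snaps)
        res = inter_pair_pitch(base_pair_centers(avg))
        assert res.pitch_12 == pytest.approx(true_pitch.pitch_12, abs=0.05)
        assert res.pitch_23 == pytest.approx(true_pitch.pitch_23, abs=0.05)


class TestCenters:
    def test_midpoint(self):
        s = snap((5.0, 5.0, 5.0))
        centers = base_pair_centers(average_structure([s]))
        assert np.allclose(centers[0], (2.5, 0.0, 0.0))
        assert np.allclose(centers[1], (2.5, 0.0, 3.4))

    def test_degenerate_pair(self):
        coords = np.zeros((6, 3))
        avg = AverageStructure(coords=coords, n_snapshots=1, names=tuple(BEAD_NAMES),
                               coord_std=np.zeros((6, 3)),
                               skew_flags=np.zeros(6, bool))
        assert np.allclose(base_pair_centers(avg), 0.0)

    def test_missing_pair_names_position(self):
        avg = AverageStructure(coords=np.zeros((4, 3)), n_snapshots=1,
                               names=("a", "b", "c", "d"),
                               coord_std=np.zeros((4, 3)),
                               skew_flags=np.zeros(4, bool))
        with pytest.raises(ValueError, match="position 2"):
            base_pair_centers(avg)
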