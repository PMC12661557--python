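"""Superposed RMSD, radius of gyration, alignment, ensemble spread."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cycloscape import (
    Trajectory,
    align_trajectory,
    backbone_rmsd,
    ensemble_spread,
    make_basin,
    make_ring_reference,
    observables,
    radius_of_gyration,
    select_temperature_frames,
)

from conftest import brute_force_rmsd

rng = np.random.default_rng(7)


def random_rigid(coords, rot_rng):
    rot = Rotation.random(rng=rot_rng)
    return rot.apply(coords) + rot_rng.uniform(-10, 10, 3)


class TestBackboneRMSD:
    def test_identical_structures_give_zero(self):
        coords = rng.standard_normal((8, 3))
        assert backbone_rmsd(coords, coords) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        coords = rng.standard_normal((12, 3)) * 3
        rot = Rotation.from_euler("z", 37, degrees=True)
        moved = rot.apply(coords) + np.array([5.0, -3.0, 2.0])
        assert backbone_rmsd(moved, coords) == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_on_displaced_planar_toy(self):
        base = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        frame = base.copy()
        frame[2, 2] += 1.0
        assert backbone_rmsd(frame, base) == pytest.approx(
            brute_force_rmsd(frame, base), abs=1e-3
        )

    def test_never_exceeds_unsuperposed_rmsd(self):
        for _ in range(20):
            a = rng.standard_normal((6, 3)) * 2
            b = rng.standard_normal((6, 3)) * 2
            raw = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
            assert backbone_rmsd(a, b) <= raw + 1e-12

    def test_pseudo_metric_properties(self):
        triples = [rng.standard_normal((5, 3)) * 2 for _ in range(3)]
        a, b, c = triples
        assert backbone_rmsd(a, b) == pytest.approx(backbone_rmsd(b, a), abs=1e-9)
        assert backbone_rmsd(a, c) <= backbone_rmsd(a, b) + backbone_rmsd(b, c) + 1e-9

    def test_mismatched_atom_counts_rejected(self):
        with pytest.raises(ValueError):
            backbone_rmsd(rng.standard_normal((4, 3)), rng.standard_normal((5, 3)))

    def test_backbone_filter_by_labels(self):
        labels = [(0, "N"), (0, "CA"), (0, "CB"), (0, "C"), (0, "O")]
        a = rng.standard_normal((5, 3))
        b = a.copy()
        b[2] += 100.0  # side-chain atom must be ignored
        assert backbone_rmsd(b, a, labels) == pytest.approx(0.0, abs=1e-9)

    def test_cross_check_against_mdtraj(self):
        """Independent oracle: mdtraj's superposed RMSD (nm-based) agrees."""
        md = pytest.importorskip("mdtraj")
        n_res = 5
        top = md.Topology()
        chain = top.add_chain()
        for i in range(n_res):
            res = top.add_residue("GLY", chain)
            for name, el in [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]:
                top.add_atom(name, md.element.get_by_symbol(el), res)
        a = rng.standard_normal((n_res * 4, 3)) * 3
        b = a + rng.standard_normal((n_res * 4, 3)) * 0.5
        t = md.Trajectory(np.stack([a, b]) / 10.0, top)  # Å -> nm
        md_rmsd = md.rmsd(t, t, frame=0)[1] * 10.0
        assert backbone_rmsd(b, a) == pytest.approx(md_rmsd, abs=1e-4)


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert radius_of_gyration(np.array([[1.0, 2, 3]])) == 0.0

    def test_two_atoms_give_half_distance(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(1.5)

    def test_unit_square_closed_form(self):
        square = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        assert radius_of_gyration(square) == pytest.approx(np.sqrt(2) / 2)

    def test_rigid_motion_invariance(self):
        coords = rng.standard_normal((10, 3)) * 4
        moved = random_rigid(coords, np.random.default_rng(3))
        assert radius_of_gyration(moved) == pytest.approx(
            radius_of_gyration(coords), abs=1e-9
        )


class TestObservables:
    def test_skip_fraction_drops_first_tenth(self, ring7):
        traj = Trajectory(
            np.tile(ring7.coordinates, (100, 1, 1)), ring7.atom_labels
        )
        series = observables(traj, ring7.coordinates, skip_fraction=0.10)
        assert len(series) == 90
        assert observables(traj, ring7.coordinates, skip_fraction=0.0).rmsd.size == 100

    def test_reference_copies_give_zero_rmsd_constant_rg(self, ring7):
        traj = Trajectory(np.tile(ring7.coordinates, (20, 1, 1)), ring7.atom_labels)
        series = observables(traj, ring7.coordinates, 0.1)
        assert np.allclose(series.rmsd, 0.0, atol=1e-9)
        assert np.allclose(series.rg, series.rg[0])

    def test_full_skip_rejected(self, ring7):
        # floor(s·n) with s < 1 always keeps at least one frame, so the
        # empty-series error can only arise from an out-of-range fraction
        traj = Trajectory(np.tile(ring7.coordinates, (10, 1, 1)), ring7.atom_labels)
        assert observables(traj, ring7.coordinates, 0.9999).rmsd.size == 1
        with pytest.raises(ValueError):
            observables(traj, ring7.coordinates, 1.0)


class TestAlignTrajectory:
    def test_rotated_copies_collapse_onto_frame_zero(self, ring7):
        rot_rng = np.random.default_rng(5)
        frames = np.stack(
            [ring7.coordinates] + [random_rigid(ring7.coordinates, rot_rng) for _ in range(5)]
        )
        aligned = align_trajectory(Trajectory(frames, ring7.atom_labels))
        for f in aligned.frames:
            assert np.abs(f - aligned.frames[0]).max() < 1e-7

    def test_already_aligned_is_noop(self, ring7):
        frames = np.tile(ring7.coordinates, (4, 1, 1))
        aligned = align_trajectory(Trajectory(frames, ring7.atom_labels))
        assert np.abs(aligned.frames - frames).max() < 1e-9

    def test_post_alignment_rmsd_matches_superposed(self, ring7):
        rot_rng = np.random.default_rng(6)
        noisy = ring7.coordinates + rot_rng.standard_normal(ring7.coordinates.shape)
        frames = np.stack([ring7.coordinates, random_rigid(noisy, rot_rng)])
        traj = Trajectory(frames, ring7.atom_labels)
        aligned = align_trajectory(traj)
        raw_after = np.sqrt(np.mean(np.sum((aligned.frames[1] - aligned.frames[0]) ** 2, axis=1)))
        assert raw_after == pytest.approx(
            backbone_rmsd(frames[1], frames[0]), abs=1e-6
        )

    def test_bad_index_rejected(self, ring7):
        traj = Trajectory(ring7.coordinates[None], ring7.atom_labels)
        with pytest.raises(ValueError):
            align_trajectory(traj, 5)


class TestEnsembleSpread:
    def test_identical_models_give_zero(self, ring7):
        models = [ring7.coordinates.copy() for _ in range(20)]
        mean, sd = ensemble_spread(models)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_planted_displacements_recovered(self, ring7):
        m1 = make_basin(ring7, 1.0, 1.0, 0.0, seed=21).centroid
        m2 = make_basin(ring7, 2.0, 1.0, 0.0, seed=22).centroid
        mean, sd = ensemble_spread([ring7.coordinates, m1, m2])
        assert mean == pytest.approx(1.5, abs=1e-6)
        assert sd == pytest.approx(0.5, abs=1e-6)

    def test_single_model_rejected(self, ring7):
        with pytest.raises(ValueError):
            ensemble_spread([ring7.coordinates])


class TestTemperatureSelection:
    def test_all_at_target_all_kept(self, ring7):
        traj = Trajectory(np.tile(ring7.coordinates, (10, 1, 1)), ring7.atom_labels)
        out = select_temperature_frames(traj, np.full(10, 300.0))
        assert out.n_frames == 10

    def test_alternating_ladder_keeps_half(self, ring7):
        traj = Trajectory(np.tile(ring7.coordinates, (10, 1, 1)), ring7.atom_labels)
        temps = np.where(np.arange(10) % 2 == 0, 300.0, 318.0)
        out = select_temperature_frames(traj, temps, tol_K=0.5)
        assert out.n_frames == 5

    def test_empty_selection_warns(self, ring7):
        traj = Trajectory(np.tile(ring7.coordinates, (4, 1, 1)), ring7.atom_labels)
        with pytest.warns(UserWarning):
            out = select_temperature_frames(traj, np.full(4, 455.0))
        assert out.n_frames == 0
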