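"""Superposition and the four alignment-reference RMSDs."""

import math

import numpy as np
import pytest
from dataclasses import replace

from pfaseval import (aligned_rmsd, best_of, build_correspondence,
                      define_pocket, evaluate_pose, kabsch_superpose,
                      make_toy_complex, pocket_aligned_ligand_rmsd)
from pfaseval.pose_metrics import DegenerateGeometryError, PoseMetrics
from pfaseval.structure_io import Complex

from conftest import random_rigid


def quaternion_superpose_rmsd(moving: np.ndarray, reference: np.ndarray) -> float:
    """Independent oracle: optimal-rotation RMSD via the quaternion
    eigenvalue method (largest eigenvalue of the 4x4 key matrix)."""
    x = moving - moving.mean(axis=0)
    y = reference - reference.mean(axis=0)
    S = x.T @ y
    K = np.array([
        [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1], S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
        [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2], S[0, 1] + S[1, 0], S[0, 2] + S[2, 0]],
        [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0], -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
        [S[0, 1] - S[1, 0], S[0, 2] + S[2, 0], S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = ((x**2).sum() + (y**2).sum() - 2.0 * lam) / len(x)
    return math.sqrt(max(msd, 0.0))


class TestKabsch:
    def test_identical_points(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        transform, rmsd = kabsch_superpose(pts, pts)
        assert rmsd < 1e-12
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(transform.translation, 0, atol=1e-10)

    def test_exact_recovery_of_rigid_motion(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        rot, trans = random_rigid(rng)
        moved = pts @ rot.T + trans
        transform, rmsd = kabsch_superpose(pts, moved)
        assert rmsd < 1e-10
        assert np.allclose(transform.rotation, rot, atol=1e-8)

    def test_agrees_with_quaternion_oracle(self):
        """50 random noisy instances: SVD Kabsch == quaternion eigenvalue method."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = rng.normal(size=(8, 3))
            b = rng.normal(size=(8, 3))
            _, rmsd = kabsch_superpose(a, b)
            assert rmsd == pytest.approx(quaternion_superpose_rmsd(a, b), abs=1e-8)

    def test_reflection_excluded(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        transform, rmsd = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-10)
        assert rmsd > 0.1  # a chiral cloud cannot be superposed on its mirror

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)


class TestAlignedRmsd:
    def test_zero_under_global_transform(self, toy_native, toy_pocket, identity_corr):
        rng = np.random.default_rng(4)
        rot, trans = random_rigid(rng)
        moved = toy_native.transformed(rot, trans)
        keys = [a.key for a in toy_native.backbone_atoms()]
        assert aligned_rmsd(toy_native, moved, keys, identity_corr) < 1e-10
        assert aligned_rmsd(toy_native, moved, toy_pocket.atom_keys, identity_corr) < 1e-10

    def test_gaussian_noise_matches_sigma_sqrt3(self):
        """Fitted RMSD of sigma-noise on n=200 atoms ~ sigma*sqrt(3)."""
        native = make_toy_complex(seed=9, n_residues=50)
        keys = [a.key for a in native.backbone_atoms()]
        assert len(keys) == 200
        sigma = 0.05
        values = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = Complex(
                "N", native.ligand_id,
                [replace(a, position=a.position + rng.normal(scale=sigma, size=3))
                 for a in native.protein_atoms],
                list(native.ligand_atoms),
            )
            corr = build_correspondence(native, noisy)
            values.append(aligned_rmsd(native, noisy, keys, corr))
        mean = np.mean(values)
        assert abs(mean - sigma * math.sqrt(3)) < 0.1 * sigma * math.sqrt(3)

    def test_matches_mdtraj_superposition(self):
        """Backbone aligned RMSD agrees with mdtraj's least-squares fit."""
        import mdtraj as md

        rng = np.random.default_rng(11)
        native = make_toy_complex(seed=4)
        noisy = Complex(
            "N", native.ligand_id,
            [replace(a, position=a.position + rng.normal(scale=0.03, size=3))
             for a in native.protein_atoms],
            list(native.ligand_atoms),
        )
        keys = [a.key for a in native.backbone_atoms()]
        corr = build_correspondence(native, noisy)
        ours = aligned_rmsd(native, noisy, keys, corr)

        top = md.Topology()
        chain = top.add_chain()
        residue = top.add_residue("ALA", chain)
        for i in range(len(keys)):
            top.add_atom(f"A{i}", md.element.carbon, residue)
        ref = md.Trajectory(
            np.array([a.position for a in native.backbone_atoms()])[None], top
        )
        mov = md.Trajectory(
            np.array([a.position for a in noisy.backbone_atoms()])[None], top
        )
        theirs = float(md.rmsd(mov, ref)[0])
        assert ours == pytest.approx(theirs, abs=1e-5)

    def test_scaled_triangle_hand_value(self):
        """3-atom selection, predicted scaled x1.1: RMSD = 0.1 * rms centroid
        distance = 0.023570 nm for this triangle (hand computation)."""
        tri = np.array([[0.0, 0.0, 0.0], [0.3, 0.0, 0.0], [0.0, 0.4, 0.0]])
        _, rmsd = kabsch_superpose(tri * 1.1, tri)
        # centroid distances^2: 0.0277778, 0.0577778, 0.0811111; mean 0.0555556
        assert rmsd == pytest.approx(0.1 * math.sqrt(0.0555556), abs=1e-6)


class TestPocketAlignedLigand:
    def test_zero_under_global_transform(self, toy_native, toy_pocket, identity_corr):
        rng = np.random.default_rng(5)
        rot, trans = random_rigid(rng)
        moved = toy_native.transformed(rot, trans)
        assert pocket_aligned_ligand_rmsd(toy_native, moved, toy_pocket, identity_corr) < 1e-10

    def test_pure_ligand_translation_is_exact(self, toy_native, toy_pocket, identity_corr):
        """Protein untouched, ligand moved 0.3 nm: the placement score reads
        exactly 0.300 while the ligand-fit RMSD stays zero."""
        shift = np.array([0.3, 0.0, 0.0])
        pred = Complex(
            "T", toy_native.ligand_id, list(toy_native.protein_atoms),
            [replace(a, position=a.position + shift) for a in toy_native.ligand_atoms],
        )
        pal = pocket_aligned_ligand_rmsd(toy_native, pred, toy_pocket, identity_corr)
        assert pal == pytest.approx(0.300, abs=1e-9)
        m = evaluate_pose(toy_native, pred, toy_pocket, identity_corr)
        assert m.rmsd_ligand < 1e-9
        assert m.rmsd_backbone < 1e-12 and m.rmsd_pocket < 1e-12

    def test_inplace_rotation_matches_direct_enumeration(
        self, toy_native, toy_pocket, identity_corr
    ):
        """Ligand rotated 180 deg about its centroid: ligand-fit RMSD 0, and the
        placement score equals the directly enumerated mean-square displacement."""
        lig = np.array([a.position for a in toy_native.ligand_atoms])
        centroid = lig.mean(axis=0)
        axis = np.array([0.0, 0.0, 1.0])
        rot = np.diag([-1.0, -1.0, 1.0])  # 180 deg about z
        moved = (lig - centroid) @ rot.T + centroid
        pred = Complex(
            "R", toy_native.ligand_id, list(toy_native.protein_atoms),
            [replace(a, position=p) for a, p in zip(toy_native.ligand_atoms, moved)],
        )
        expected = math.sqrt(((moved - lig) ** 2).sum() / len(lig))
        m = evaluate_pose(toy_native, pred, toy_pocket, identity_corr)
        assert m.rmsd_ligand < 1e-9
        assert m.rmsd_pocket_aligned_ligand == pytest.approx(expected, abs=1e-9)

    def test_fitfree_dominates_fitted_for_rigid_perturbations(
        self, toy_native, toy_pocket
    ):
        """For rigid-ligand perturbations the direct (fit-free) score can never
        beat the fitted ligand RMSD on the same atom pairs."""
        from pfaseval.synthetic_data import PerturbationSpec, perturb

        for seed in range(10):
            pred = perturb(toy_native, PerturbationSpec("ligand_rigid", 0.25, seed=seed))
            corr = build_correspondence(toy_native, pred)
            m = evaluate_pose(toy_native, pred, toy_pocket, corr)
            assert m.rmsd_ligand <= m.rmsd_pocket_aligned_ligand + 1e-9


class TestEvaluatePose:
    def test_identity_prediction_all_zero(self, toy_native, toy_pocket, identity_corr):
        m = evaluate_pose(toy_native, toy_native, toy_pocket, identity_corr)
        for name in ("rmsd_backbone", "rmsd_pocket", "rmsd_ligand",
                     "rmsd_pocket_aligned_ligand"):
            assert getattr(m, name) < 1e-12
        assert m.pocket_coverage == 1.0

    def test_rigid_invariance_of_all_metrics(self, toy_native, toy_pocket):
        from pfaseval.synthetic_data import PerturbationSpec, perturb

        pred = perturb(toy_native, PerturbationSpec("ligand_rigid", 0.2, seed=0))
        corr = build_correspondence(toy_native, pred)
        base = evaluate_pose(toy_native, pred, toy_pocket, corr)
        rng = np.random.default_rng(6)
        for _ in range(5):
            rot, trans = random_rigid(rng)
            moved = pred.transformed(rot, trans)
            corr2 = build_correspondence(toy_native, moved)
            m = evaluate_pose(toy_native, moved, toy_pocket, corr2)
            for name in ("rmsd_backbone", "rmsd_pocket", "rmsd_ligand",
                         "rmsd_pocket_aligned_ligand"):
                assert getattr(m, name) == pytest.approx(getattr(base, name), abs=1e-9)

    def test_pocket_noise_leaves_ligand_metric_zero(self, toy_native, toy_pocket):
        from pfaseval.synthetic_data import PerturbationSpec, perturb

        pred = perturb(toy_native, PerturbationSpec("pocket_noise", 0.1, seed=1))
        corr = build_correspondence(toy_native, pred)
        m = evaluate_pose(toy_native, pred, toy_pocket, corr)
        assert m.rmsd_pocket > 0
        assert m.rmsd_ligand < 1e-12


class TestBestOf:
    def _poses(self, values, ranks=None):
        ranks = ranks or range(1, len(values) + 1)
        return [
            PoseMetrics(0.1, 0.1, 0.1, v, rank=r)
            for v, r in zip(values, ranks)
        ]

    def test_minimum_selected(self):
        poses = self._poses([0.3, 0.1, 0.5])
        assert best_of(poses, "pocket_aligned_ligand").rmsd_pocket_aligned_ligand == 0.1

    def test_single_pose(self):
        poses = self._poses([0.4])
        assert best_of(poses) is poses[0]

    def test_tie_goes_to_lower_rank(self):
        poses = self._poses([0.2, 0.2], ranks=[4, 2])
        assert best_of(poses).rank == 2

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            best_of([])

    def test_topn_minimum_is_monotone(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0.05, 0.6, size=10)
        poses = self._poses(values)
        minima = [
            best_of(poses[:k]).rmsd_pocket_aligned_ligand for k in range(1, 11)
        ]
        assert all(a >= b for a, b in zip(minima, minima[1:]))
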