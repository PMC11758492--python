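"""Gyration shape, RMSD, contact maps and dihedral helicity."""

import numpy as np
import pytest

from hdxcalib.descriptors import backbone_rmsd, contact_map, helicity, shape_series
from hdxcalib.synthetic import ToyTrajectorySpec, make_toy_trajectory
from hdxcalib.trajectory_states import read_trajectory

from conftest import manual_trajectory


def cloud_trajectory(frames):
    """Point-cloud pseudo-protein (equal-mass carbons) for shape tests."""
    frames = np.asarray(frames, float)
    n = frames.shape[-2]
    atoms = [(f"C{i}", 1, "DUM", "C") for i in range(n)]
    return manual_trajectory(frames, atoms)


def asphericity_oracle(xyz):
    xyz = xyz - xyz.mean(axis=0)
    s = xyz.T @ xyz / len(xyz)
    lam = np.sort(np.linalg.eigvalsh(s))[::-1]
    return 1 - 3 * (lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]) / lam.sum() ** 2


class TestShapeSeries:
    def test_tetrahedron_is_isotropic(self):
        verts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        ss = shape_series(cloud_trajectory(verts[None]), mass_weighting=False)
        assert ss.asphericity[0] == pytest.approx(0.0, abs=1e-12)

    def test_collinear_is_rod(self):
        pts = np.column_stack([np.linspace(0, 10, 6), np.zeros(6), np.zeros(6)])
        ss = shape_series(cloud_trajectory(pts[None]), mass_weighting=False)
        assert ss.asphericity[0] == pytest.approx(1.0)

    def test_random_cloud_matches_eigen_oracle(self):
        # coordinates pass through a float32 trajectory reader, hence the
        # micro-tolerance; the float64 formula identity is checked below
        rng = np.random.default_rng(44)
        frames = rng.normal(size=(5, 12, 3))
        ss = shape_series(cloud_trajectory(frames), mass_weighting=False)
        for f in range(5):
            xyz = frames[f] - frames[f].mean(axis=0)
            s = xyz.T @ xyz / 12
            assert ss.rg[f] == pytest.approx(np.sqrt(np.trace(s)), rel=1e-5)
            assert ss.asphericity[f] == pytest.approx(
                asphericity_oracle(frames[f]), abs=1e-5
            )

    def test_eigenvalue_and_trace_forms_agree(self):
        # delta from eigenvalues equals the invariant trace-form
        # 1 - 3 I2 / I1^2 with I1, I2 the tensor invariants, in float64
        rng = np.random.default_rng(48)
        for _ in range(50):
            xyz = rng.normal(size=(15, 3))
            xyz -= xyz.mean(axis=0)
            s = xyz.T @ xyz / 15
            lam = np.linalg.eigvalsh(s)
            i1 = np.trace(s)
            i2 = 0.5 * (i1**2 - np.trace(s @ s))
            from_eigs = 1 - 3 * (lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]) / lam.sum() ** 2
            from_trace = 1 - 3 * i2 / i1**2
            assert from_eigs == pytest.approx(from_trace, abs=1e-10)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(45)
        base = rng.normal(size=(10, 3))
        moved = Rotation.from_euler("zyx", [10, 40, 70], degrees=True).apply(base) + 3.0
        s1 = shape_series(cloud_trajectory(base[None]), mass_weighting=False)
        s2 = shape_series(cloud_trajectory(moved[None]), mass_weighting=False)
        assert s1.rg[0] == pytest.approx(s2.rg[0])
        assert s1.asphericity[0] == pytest.approx(s2.asphericity[0])


class TestBackboneRMSD:
    def test_identical_frames_zero(self, helix_toy):
        _, traj = helix_toy
        np.testing.assert_allclose(backbone_rmsd(traj), 0.0, atol=1e-6)

    def test_rotated_copy_zero_with_fit(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(46)
        base = rng.normal(size=(8, 3)) * 3
        rot = Rotation.from_euler("xyz", [15, 25, 35], degrees=True).apply(base) + 2.0
        atoms = [("N", 1, "ALA", "N"), ("CA", 1, "ALA", "C"), ("C", 1, "ALA", "C"),
                 ("O", 1, "ALA", "O")] * 2
        frames = np.stack([base, rot])
        traj = manual_trajectory(frames, atoms)
        out = backbone_rmsd(traj, reference_frame=0, fit=True)
        assert out[1] == pytest.approx(0.0, abs=1e-6)

    def test_uniform_translation_without_fit(self):
        rng = np.random.default_rng(47)
        base = rng.normal(size=(8, 3))
        shifted = base + np.array([1.0, 0.0, 0.0])
        atoms = [("N", 1, "ALA", "N"), ("CA", 1, "ALA", "C"), ("C", 1, "ALA", "C"),
                 ("O", 1, "ALA", "O")] * 2
        traj = manual_trajectory(np.stack([base, shifted]), atoms)
        out = backbone_rmsd(traj, reference_frame=0, fit=False)
        assert out[1] == pytest.approx(1.0)


class TestContactMap:
    def test_extended_chain_has_no_long_range_contacts(self, mixed_toy):
        _, traj = mixed_toy
        cm = contact_map(traj, cutoff=4.5, min_separation=2)
        assert cm.frequency.max() == 0.0

    def test_helix_i_i4_contacts(self, helix_toy):
        _, traj = helix_toy
        cm = contact_map(traj, cutoff=4.5, min_separation=2)
        idx = {r: k for k, r in enumerate(cm.residues)}
        for i in range(1, 7):
            assert cm.frequency[idx[i], idx[i + 4]] == pytest.approx(1.0)

    def test_symmetry_and_diagonal_band(self, helix_toy):
        _, traj = helix_toy
        cm = contact_map(traj, min_separation=2)
        np.testing.assert_allclose(cm.frequency, cm.frequency.T)
        n = cm.residues.size
        for i in range(n):
            for j in range(max(0, i - 1), min(n, i + 2)):
                assert cm.frequency[i, j] == 0.0

    def test_matches_brute_force_on_random_frames(self, coil_toy):
        _, traj = coil_toy
        cm = contact_map(traj, cutoff=4.5, min_separation=2)
        heavy = traj.protein_idx[traj.elements[traj.protein_idx] != "H"]
        resids = traj.universe.atoms.resids[heavy]
        counts = np.zeros_like(cm.frequency)
        for f in range(traj.n_frames):
            xyz = traj.frame_coords(f)[heavy]
            for a, ra in enumerate(cm.residues):
                for b, rb in enumerate(cm.residues):
                    if rb - ra < 2:
                        continue
                    da = xyz[resids == ra]
                    db = xyz[resids == rb]
                    dmin = np.min(
                        np.linalg.norm(da[:, None] - db[None, :], axis=2)
                    )
                    if dmin <= 4.5:
                        counts[a, b] += 1
                        counts[b, a] += 1
        np.testing.assert_allclose(cm.frequency, counts / traj.n_frames)


class TestHelicity:
    def test_ideal_helix_interior_fraction_one(self, helix_toy):
        _, traj = helix_toy
        h = helicity(traj)
        interior = h.iloc[1:-1]
        np.testing.assert_allclose(interior.to_numpy(), 1.0)
        assert np.isnan(h.iloc[0]) and np.isnan(h.iloc[-1])

    def test_extended_chain_zero(self, mixed_toy):
        _, traj = mixed_toy
        h = helicity(traj)
        np.testing.assert_allclose(h.iloc[1:-1].to_numpy(), 0.0)

    def test_mixed_trajectory_fraction(self, tmp_path):
        # 2 helix + 2 extended frames of the same sequence: interior
        # helix fraction is exactly 0.5
        import MDAnalysis as mda

        h = make_toy_trajectory(
            ToyTrajectorySpec("AAAAAAAA", n_frames=2, conformer="helix"), tmp_path / "h"
        )
        e = make_toy_trajectory(
            ToyTrajectorySpec("AAAAAAAA", n_frames=2, conformer="extended"), tmp_path / "e"
        )
        uh = mda.Universe(str(h.topology), str(h.coordinates))
        ue = mda.Universe(str(e.topology), str(e.coordinates))
        frames = np.concatenate(
            [
                np.stack([ts.positions.copy() for ts in uh.trajectory]),
                np.stack([ts.positions.copy() for ts in ue.trajectory]),
            ]
        )
        atoms = [
            (nm, int(r), rn, el)
            for nm, r, rn, el in zip(
                uh.atoms.names, uh.atoms.resids, uh.atoms.resnames,
                [n[0] for n in uh.atoms.names],
            )
        ]
        traj = manual_trajectory(frames, atoms)
        frac = helicity(traj)
        np.testing.assert_allclose(frac.iloc[1:-1].to_numpy(), 0.5)
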