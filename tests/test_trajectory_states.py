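"""SASA, hydrogen-bond geometry and open/closed state classification."""

import numpy as np
import pytest

from hdxcalib._geometry import build_backbone
from hdxcalib.synthetic import _ICOSA, ToyTrajectorySpec, make_toy_trajectory
from hdxcalib.trajectory_states import (
    StateParams,
    classify_states,
    intra_hbond_exists,
    read_trajectory,
    sasa_amide_h,
    shrake_rupley_atoms,
    water_hbond_count,
)

from conftest import manual_trajectory


def two_residue_with_water(dist, angle_deg):
    """Extended 2-residue backbone plus one water O at a set H-bond geometry."""
    bb = build_backbone(2, 180.0, 180.0)
    atoms, coords = [], []
    for i in range(2):
        for name in ("N", "H", "CA", "C", "O"):
            if name == "H" and i == 0:
                continue
            atoms.append((name, i + 1, "ALA", name[0]))
            coords.append(bb[name][i])
    n, h = bb["N"][1], bb["H"][1]
    u = (h - n) / np.linalg.norm(h - n)
    w = np.cross(u, [0.0, 0.0, 1.0])
    w /= np.linalg.norm(w)
    tilt = np.radians(180.0 - angle_deg)  # deviation from linear
    direction = np.cos(tilt) * u + np.sin(tilt) * w
    o = h + dist * direction
    atoms.append(("OW", 3, "HOH", "O"))
    coords.append(o)
    atoms.append(("HW1", 3, "HOH", "H"))
    coords.append(o + [0.76, 0.59, 0.0])
    return manual_trajectory(np.array(coords), atoms)


class TestReadTrajectory:
    def test_amide_resolution_excludes_first_residue(self, mixed_toy):
        _, traj = mixed_toy
        assert traj.amide_residues.tolist() == [2, 3, 4, 5, 6]

    def test_proline_excluded(self, tmp_path):
        built = make_toy_trajectory(
            ToyTrajectorySpec("APAA", n_frames=2, f_open=1.0), tmp_path
        )
        traj = read_trajectory(built.topology, built.coordinates)
        assert traj.amide_residues.tolist() == [3, 4]

    def test_write_read_roundtrip(self, tmp_path):
        spec = ToyTrajectorySpec("AAAA", n_frames=7, f_open=0.5, seed=9)
        built = make_toy_trajectory(spec, tmp_path)
        traj = read_trajectory(built.topology, built.coordinates)
        assert traj.n_frames == 7
        # frame 0 coordinates equal the emitted topology coordinates
        import MDAnalysis as mda

        ref = mda.Universe(str(built.topology)).atoms.positions
        np.testing.assert_allclose(traj.frame_coords(0), ref, atol=1e-3)


class TestSASA:
    def test_exposed_nh_pair_matches_monte_carlo(self):
        # isolated N-H: SASA of H is the fraction of its probe sphere
        # outside N's probe sphere; oracle by random-direction integration
        coords = np.array([[0.0, 0.0, 0.0], [1.01, 0.0, 0.0]])
        radii = np.array([1.55, 1.20])
        probe = 1.4
        got = shrake_rupley_atoms(coords, radii, np.array([1]), probe=probe)[0]
        rng = np.random.default_rng(123)
        pts = rng.normal(size=(100_000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        surf = coords[1] + (radii[1] + probe) * pts
        outside = np.linalg.norm(surf - coords[0], axis=1) > radii[0] + probe
        oracle = outside.mean() * 4 * np.pi * (radii[1] + probe) ** 2
        assert got == pytest.approx(oracle, abs=0.5)

    def test_fully_enclosed_hydrogen_is_zero(self):
        h = np.array([[0.0, 0.0, 0.0]])
        cage = 2.0 * _ICOSA
        coords = np.vstack([h, cage])
        radii = np.array([1.20] + [1.70] * 12)
        assert shrake_rupley_atoms(coords, radii, np.array([0]))[0] == 0.0

    def test_point_count_convergence(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(-3, 3, size=(8, 3))
        radii = np.full(8, 1.5)
        a = shrake_rupley_atoms(coords, radii, np.arange(8), n_points=960)
        b = shrake_rupley_atoms(coords, radii, np.arange(8), n_points=1920)
        assert np.all(np.abs(a - b) <= 0.01 * 4 * np.pi * 2.9**2)

    def test_against_independent_shrake_rupley(self, mixed_toy):
        biotite_struct = pytest.importorskip("biotite.structure")
        _, traj = mixed_toy
        got = sasa_amide_h(traj, 0)
        import biotite.structure as struc

        n = traj.protein_idx.size
        arr = struc.AtomArray(n)
        arr.coord = traj.frame_coords(0)[traj.protein_idx].astype(np.float32)
        arr.element = traj.elements[traj.protein_idx]
        from hdxcalib.trajectory_states import VDW_RADII

        radii = np.array(
            [VDW_RADII[traj.elements[i]] for i in traj.protein_idx], dtype=float
        )
        ref = struc.sasa(arr, probe_radius=1.4, vdw_radii=radii, point_number=960)
        pos_of = {int(i): k for k, i in enumerate(traj.protein_idx)}
        ref_amide = [ref[pos_of[int(i)]] for i in traj.amide_h_idx]
        np.testing.assert_allclose(got.to_numpy(), ref_amide, rtol=0.05, atol=0.3)

    def test_missing_radius_rejected(self, mixed_toy):
        _, traj = mixed_toy
        traj2 = traj.__class__(**{**traj.__dict__})
        traj2.elements = traj.elements.copy()
        traj2.elements[traj.protein_idx[0]] = "X"
        with pytest.raises(KeyError, match="X"):
            sasa_amide_h(traj2, 0)


class TestHydrogenBonds:
    def test_water_inside_both_cutoffs_counted(self):
        traj = two_residue_with_water(3.2, 172.0)
        assert water_hbond_count(traj, 0, residue=2) == 1

    def test_distance_fail_not_counted(self):
        traj = two_residue_with_water(3.4, 180.0)
        assert water_hbond_count(traj, 0, residue=2) == 0

    def test_angle_fail_not_counted(self):
        traj = two_residue_with_water(3.0, 140.0)
        assert water_hbond_count(traj, 0, residue=2) == 0

    def test_extended_chain_has_no_intra_hbonds(self, mixed_toy):
        _, traj = mixed_toy
        assert not intra_hbond_exists(traj, 0).any()

    def test_helix_has_canonical_i_minus_4_hbonds(self, helix_toy):
        _, traj = helix_toy
        flags = intra_hbond_exists(traj, 0)
        # residues 5+ have an i-4 carbonyl partner; 2-4 do not
        assert flags.loc[[2, 3, 4]].tolist() == [False, False, False]
        assert flags.loc[[5, 6, 7, 8, 9, 10]].all()

    def test_counts_match_brute_force_on_random_frames(self):
        rng = np.random.default_rng(21)
        params = StateParams()
        for _ in range(100):
            bb = build_backbone(3, 180.0, 180.0)
            atoms, coords = [], []
            for i in range(3):
                for name in ("N", "H", "CA", "C", "O"):
                    if name == "H" and i == 0:
                        continue
                    atoms.append((name, i + 1, "ALA", name[0]))
                    coords.append(bb[name][i])
            n_wat = 6
            for k in range(n_wat):
                atoms.append(("OW", 4 + k, "HOH", "O"))
                coords.append(rng.uniform(-2, 8, 3))
            traj = manual_trajectory(np.array(coords), atoms)
            got = water_hbond_count(traj, 0).to_dict()
            xyz = np.array(coords)
            for j, res in enumerate(traj.amide_residues):
                h = xyz[traj.amide_h_idx[j]]
                nn = xyz[traj.amide_n_idx[j]]
                count = 0
                for oi in traj.water_o_idx:
                    o = xyz[oi]
                    d = np.linalg.norm(o - h)
                    v1 = (nn - h) / np.linalg.norm(nn - h)
                    v2 = (o - h) / d
                    ang = np.degrees(np.arccos(np.clip(v1 @ v2, -1, 1)))
                    if d <= params.hbond_distance and ang >= params.hbond_angle:
                        count += 1
                assert got[res] == count


class TestClassifyStates:
    def test_exact_recovery_of_constructed_open_fractions(self, mixed_toy):
        built, traj = mixed_toy
        trace = classify_states(traj, "inter")
        np.testing.assert_array_equal(trace.open_matrix, built.open_matrix)
        np.testing.assert_allclose(trace.f_open, [0.4, 1.0, 0.0, 0.6, 0.25])

    def test_model_asymmetry_no_waters(self, mixed_toy):
        # exposed amide, no nearby waters, no intra H-bond: closed under
        # the inter model but open under the intra model
        built, traj = mixed_toy
        inter = classify_states(traj, "inter")
        intra = classify_states(traj, "intra")
        res4 = np.where(traj.amide_residues == 4)[0][0]
        assert not inter.open_matrix[res4].any()
        assert intra.open_matrix[res4].all()

    def test_intra_open_set_contains_inter_open_set(self, mixed_toy):
        built, traj = mixed_toy
        inter = classify_states(traj, "inter")
        intra = classify_states(traj, "intra")
        assert np.all(intra.open_matrix >= inter.open_matrix)

    def test_burial_closes_both_models(self, tmp_path):
        spec = ToyTrajectorySpec(
            "AAAAA", n_frames=40, f_open=0.5, closed_mode="burial", seed=4
        )
        built = make_toy_trajectory(spec, tmp_path)
        traj = read_trajectory(built.topology, built.coordinates)
        for model in ("inter", "intra"):
            trace = classify_states(traj, model)
            np.testing.assert_array_equal(trace.open_matrix, built.open_matrix)

    def test_rigid_rotation_invariance(self, mixed_toy):
        from scipy.spatial.transform import Rotation

        built, traj = mixed_toy
        rot = Rotation.from_euler("xyz", [31.0, -57.0, 112.0], degrees=True)
        xyz = traj.frame_coords(0)
        rotated = rot.apply(xyz) + np.array([5.0, -3.0, 11.0])
        atoms = [
            (nm, int(r), rn, el)
            for nm, r, rn, el in zip(
                traj.universe.atoms.names,
                traj.universe.atoms.resids,
                traj.universe.atoms.resnames,
                traj.elements,
            )
        ]
        traj_rot = manual_trajectory(rotated, atoms, water_resnames=("HOH",))
        np.testing.assert_allclose(
            sasa_amide_h(traj_rot, 0).to_numpy(),
            sasa_amide_h(traj, 0).to_numpy(),
            atol=0.2,
        )
        np.testing.assert_array_equal(
            water_hbond_count(traj_rot, 0).to_numpy(),
            water_hbond_count(traj, 0).to_numpy(),
        )

    def test_dwell_times_consistent_with_populations(self):
        # alternating open/closed trace: equal mean dwell lengths and
        # f_open = 0.5 (population and residence-time ratios agree)
        from hdxcalib.trajectory_states import StateTrace

        pattern = np.tile([True, False], 50)
        trace = StateTrace(
            model="inter",
            residues=np.array([2]),
            open_matrix=pattern[None, :],
            frame_indices=np.arange(100),
        )
        dw = trace.dwell_times().loc[2]
        assert dw["tau_open"] == dw["tau_closed"] == 1.0
        assert trace.f_open[0] == 0.5
        assert dw["n_open_frames"] + (100 - dw["n_open_frames"]) == dw["n_frames"]

    def test_subsampling_cap(self, mixed_toy):
        _, traj = mixed_toy
        trace = classify_states(traj, "inter", StateParams(n_max_frames=50))
        assert trace.n_frames == 50

    def test_unknown_model_rejected(self, mixed_toy):
        _, traj = mixed_toy
        with pytest.raises(ValueError):
            classify_states(traj, "both")
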