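import warnings

import MDAnalysis as mda
import numpy as np
import pytest

from hdxcalib.synthetic import ToyTrajectorySpec, make_toy_trajectory
from hdxcalib.trajectory_states import Trajectory, read_trajectory

warnings.filterwarnings("ignore", category=DeprecationWarning, module="MDAnalysis")


def manual_trajectory(frames, atoms, water_resnames=("HOH",)):
    """Build an in-memory Trajectory from explicit coordinates.

    ``frames``: array (n_frames, n_atoms, 3). ``atoms``: list of
    (name, resid, resname, element) tuples. Amide hydrogens are the
    atoms named H in residues >= 2 of non-water residues.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    names = [a[0] for a in atoms]
    resids = [a[1] for a in atoms]
    resnames_per_atom = [a[2] for a in atoms]
    elements = np.array([a[3] for a in atoms])

    unique = []
    for r, rn in zip(resids, resnames_per_atom):
        if not unique or unique[-1][0] != r:
            unique.append((r, rn))
    resindex = []
    lookup = {r: i for i, (r, _) in enumerate(unique)}
    resindex = [lookup[r] for r in resids]

    u = mda.Universe.empty(
        len(atoms), n_residues=len(unique),
        atom_resindex=np.array(resindex),
        residue_segindex=np.zeros(len(unique), dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resids", [r for r, _ in unique])
    u.add_TopologyAttr("resnames", [rn for _, rn in unique])
    u.add_TopologyAttr("elements", elements)
    u.load_new(frames, format=mda.coordinates.memory.MemoryReader)

    is_water = np.array([rn in water_resnames for rn in resnames_per_atom])
    protein_idx = np.nonzero(~is_water)[0]
    water_o_idx = np.nonzero(is_water & (elements == "O"))[0]
    amide_res, amide_h, amide_n = [], [], []
    for i in protein_idx:
        if names[i] == "H" and resids[i] >= 2 and resnames_per_atom[i] != "PRO":
            n_idx = [
                j for j in protein_idx if resids[j] == resids[i] and names[j] == "N"
            ][0]
            amide_res.append(resids[i])
            amide_h.append(i)
            amide_n.append(n_idx)
    acceptor_idx = protein_idx[np.isin(elements[protein_idx], ("N", "O"))]
    return Trajectory(
        universe=u,
        amide_residues=np.array(amide_res),
        amide_h_idx=np.array(amide_h),
        amide_n_idx=np.array(amide_n),
        water_o_idx=water_o_idx,
        protein_idx=protein_idx,
        acceptor_idx=acceptor_idx,
        elements=elements,
    )


@pytest.fixture(scope="session")
def mixed_toy(tmp_path_factory):
    """Extended hydrated toy with per-residue open fractions (inter model)."""
    spec = ToyTrajectorySpec(
        sequence="AAAAAA",
        n_frames=200,
        f_open={2: 0.4, 3: 1.0, 4: 0.0, 5: 0.6, 6: 0.25},
        seed=11,
    )
    built = make_toy_trajectory(spec, tmp_path_factory.mktemp("mixed_toy"))
    return built, read_trajectory(built.topology, built.coordinates)


@pytest.fixture(scope="session")
def helix_toy(tmp_path_factory):
    spec = ToyTrajectorySpec(
        sequence="AAAAAAAAAA", n_frames=4, f_open=1.0, conformer="helix", seed=7
    )
    built = make_toy_trajectory(spec, tmp_path_factory.mktemp("helix_toy"))
    return built, read_trajectory(built.topology, built.coordinates)


@pytest.fixture(scope="session")
def coil_toy(tmp_path_factory):
    spec = ToyTrajectorySpec(
        sequence="AAAAAAAA", n_frames=6, f_open=1.0, conformer="coil", seed=13
    )
    built = make_toy_trajectory(spec, tmp_path_factory.mktemp("coil_toy"))
    return built, read_trajectory(built.topology, built.coordinates)
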