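"""Open/closed state classification of backbone amides in MD trajectories.

Each backbone amide hydrogen is classified per frame as exchange-competent
("open") or exchange-incompetent ("closed") under one of two models:

* inter model — open iff the amide hydrogen's solvent-accessible surface
  area (SASA) is at least 8.3 A^2 AND at least two water molecules donate
  acceptable hydrogen-bond geometry (O within 3.3 A of the amide H, the
  N-H...O angle within 30 degrees of linear).
* intra model — closed iff SASA < 8.3 A^2 OR the amide hydrogen forms at
  least one intramolecular hydrogen bond (same geometry against protein
  N/O acceptors); open otherwise.

The intra model's open set therefore contains the inter model's open set
frame-by-frame, so intra-model open fractions are never smaller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import MDAnalysis as mda
import numpy as np
import pandas as pd

from ._geometry import sphere_points

__all__ = [
    "StateParams",
    "Trajectory",
    "StateTrace",
    "read_trajectory",
    "sasa_amide_h",
    "water_hbond_count",
    "intra_hbond_exists",
    "classify_states",
]

WATER_RESNAMES = ("TIP3", "HOH", "WAT", "SOL", "TIP3P")
AMIDE_H_NAMES = ("H", "HN", "HN1")

# Bondi-style van der Waals radii (angstrom), hydrogens included.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "NA": 2.27, "K": 2.75,
    "MG": 1.73, "CA": 2.31, "ZN": 1.39,
}


@dataclass(frozen=True)
class StateParams:
    """Thresholds and numerical settings for state classification."""

    sasa_threshold: float = 8.3      # A^2, open requires SASA >= threshold
    hbond_distance: float = 3.3      # A
    hbond_angle: float = 150.0       # deg, N-H...acceptor >= this (30 deg off linear)
    min_waters: int = 2
    probe_radius: float = 1.4        # A
    n_sphere_points: int = 960
    distance_mode: str = "H-O"       # or "N-O": which atom anchors the 3.3 A cutoff
    n_max_frames: int = 25000


@dataclass
class Trajectory:
    """An MD trajectory with resolved amide hydrogens and water oxygens."""

    universe: mda.Universe
    amide_residues: np.ndarray      # 1-based residue positions with an amide H
    amide_h_idx: np.ndarray         # atom indices of those amide hydrogens
    amide_n_idx: np.ndarray         # atom indices of the bonded backbone N
    water_o_idx: np.ndarray         # water oxygen atom indices
    protein_idx: np.ndarray         # all protein atom indices (SASA occluders)
    acceptor_idx: np.ndarray        # protein N/O heavy atoms (intra acceptors)
    elements: np.ndarray            # element symbol per atom
    replicate_id: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.universe.trajectory)

    def frame_coords(self, frame: int) -> np.ndarray:
        self.universe.trajectory[frame]
        return self.universe.atoms.positions.astype(float)

    def box(self, frame: int):
        self.universe.trajectory[frame]
        dims = self.universe.dimensions
        if dims is None or not np.all(dims[:3] > 0):
            return None
        return np.asarray(dims[:3], dtype=float)


def _guess_elements(universe: mda.Universe) -> np.ndarray:
    try:
        elems = [e.upper() if e else "" for e in universe.atoms.elements]
        if any(elems):
            return np.array(
                [e if e else _element_from_name(n) for e, n in
                 zip(elems, universe.atoms.names)]
            )
    except (mda.exceptions.NoDataError, AttributeError):
        pass
    return np.array([_element_from_name(n) for n in universe.atoms.names])


def _element_from_name(name: str) -> str:
    name = name.strip()
    for ch in name:
        if ch.isalpha():
            # two-letter elements seen in biomolecular systems
            two = name[:2].upper()
            if two in ("CL", "BR", "NA", "MG", "ZN") and ch == name[0]:
                return two
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


def read_trajectory(
    topology_path,
    coords_path=None,
    water_names=WATER_RESNAMES,
    amide_h_names=AMIDE_H_NAMES,
    replicate_id: str = "",
) -> Trajectory:
    """Load a topology (PDB/PSF) plus coordinates (DCD/XTC/multi-model PDB).

    Resolves one backbone amide hydrogen per non-proline residue after
    residue 1, by atom name alias; residues missing one are reported
    together in the error.
    """
    u = mda.Universe(str(topology_path)) if coords_path is None else mda.Universe(
        str(topology_path), str(coords_path)
    )
    resnames = u.atoms.resnames
    water_mask = np.isin(resnames, water_names)
    protein_idx = np.nonzero(~water_mask)[0]
    if protein_idx.size == 0:
        raise ValueError("no protein atoms found")
    elements = _guess_elements(u)

    water_o_idx = np.nonzero(water_mask & (elements == "O"))[0]

    prot = u.atoms[protein_idx]
    residues = prot.residues
    amide_res, amide_h, amide_n = [], [], []
    missing = []
    first_resid = residues.resids.min()
    for res in residues:
        res_names = set(res.atoms.names)
        if "N" not in res_names and "CA" not in res_names:
            continue  # het group / dummy occluder, not a peptide residue
        pos = int(res.resid - first_resid + 1)  # 1-based position in chain
        if pos == 1 or res.resname in ("PRO",):
            continue
        h_sel = [a for a in res.atoms if a.name in amide_h_names]
        n_sel = [a for a in res.atoms if a.name == "N"]
        if not h_sel or not n_sel:
            missing.append(pos)
            continue
        amide_res.append(pos)
        amide_h.append(h_sel[0].ix)
        amide_n.append(n_sel[0].ix)
    if missing:
        raise ValueError(f"missing backbone amide H (or N) for residues {missing}")

    acceptor_idx = protein_idx[
        np.isin(elements[protein_idx], ("N", "O"))
    ]
    return Trajectory(
        universe=u,
        amide_residues=np.array(amide_res, dtype=int),
        amide_h_idx=np.array(amide_h, dtype=int),
        amide_n_idx=np.array(amide_n, dtype=int),
        water_o_idx=water_o_idx,
        protein_idx=protein_idx,
        acceptor_idx=acceptor_idx,
        elements=elements,
        replicate_id=replicate_id,
    )


# ---------------------------------------------------------------------------
# Geometry kernels
# ---------------------------------------------------------------------------

def _radii_for(traj: Trajectory, idx: np.ndarray) -> np.ndarray:
    radii = np.empty(idx.size)
    for k, i in enumerate(idx):
        el = traj.elements[i]
        if el not in VDW_RADII:
            raise KeyError(f"no van der Waals radius for element {el!r}")
        radii[k] = VDW_RADII[el]
    return radii


def shrake_rupley_atoms(
    coords: np.ndarray,
    radii: np.ndarray,
    targets: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area by sphere-point sampling.

    Rolls a probe over each target atom's extended sphere and counts the
    fraction of quasi-uniform surface points not buried inside any other
    atom's extended sphere.
    """
    pts = sphere_points(n_points)
    ext = radii + probe
    out = np.empty(targets.size)
    for k, t in enumerate(targets):
        rt = ext[t]
        d = np.linalg.norm(coords - coords[t], axis=1)
        neigh = np.nonzero((d < rt + ext) & (d > 0))[0]
        surf = coords[t] + rt * pts
        if neigh.size:
            diff = surf[:, None, :] - coords[neigh][None, :, :]
            buried = np.any(
                np.einsum("pnk,pnk->pn", diff, diff) < (ext[neigh] ** 2)[None, :], axis=1
            )
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[k] = frac * 4.0 * np.pi * rt**2
    return out


def sasa_amide_h(
    traj: Trajectory, frame: int, params: StateParams = StateParams()
) -> pd.Series:
    """SASA (A^2) of each amide hydrogen in one frame, indexed by residue.

    Occluders are the protein atoms (waters are the solvent being
    probed, so they do not bury the surface).
    """
    coords = traj.frame_coords(frame)[traj.protein_idx]
    radii = _radii_for(traj, traj.protein_idx)
    pos_of = {int(i): k for k, i in enumerate(traj.protein_idx)}
    targets = np.array([pos_of[int(i)] for i in traj.amide_h_idx])
    areas = shrake_rupley_atoms(
        coords, radii, targets, probe=params.probe_radius,
        n_points=params.n_sphere_points,
    )
    return pd.Series(areas, index=traj.amide_residues, name="sasa")


def _min_image(diff: np.ndarray, box) -> np.ndarray:
    if box is None:
        return diff
    return diff - box * np.round(diff / box)


def _hbond_mask(
    h: np.ndarray, n: np.ndarray, acceptors: np.ndarray, params: StateParams, box=None
) -> np.ndarray:
    """Boolean (n_donors, n_acceptors): acceptable N-H...A geometry."""
    if acceptors.size == 0:
        return np.zeros((h.shape[0], 0), dtype=bool)
    ha = _min_image(acceptors[None, :, :] - h[:, None, :], box)
    dist_ha = np.linalg.norm(ha, axis=2)
    if params.distance_mode == "N-O":
        na = _min_image(acceptors[None, :, :] - n[:, None, :], box)
        dist = np.linalg.norm(na, axis=2)
    else:
        dist = dist_ha
    nh = h - n
    nh /= np.linalg.norm(nh, axis=1, keepdims=True)
    # angle at H between H->N and H->acceptor; 180 deg = linear N-H...A
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = -np.einsum("dk,dak->da", nh, ha) / dist_ha
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return (dist <= params.hbond_distance) & (angle >= params.hbond_angle)


def water_hbond_count(
    traj: Trajectory, frame: int, residue: int | None = None,
    params: StateParams = StateParams(),
):
    """Number of water oxygens in acceptable H-bond geometry per amide.

    Returns a Series indexed by residue, or an int for one ``residue``.
    """
    coords = traj.frame_coords(frame)
    mask = _hbond_mask(
        coords[traj.amide_h_idx], coords[traj.amide_n_idx],
        coords[traj.water_o_idx], params, box=traj.box(frame),
    )
    counts = pd.Series(mask.sum(axis=1), index=traj.amide_residues, name="waters")
    return int(counts.loc[residue]) if residue is not None else counts


def intra_hbond_exists(
    traj: Trajectory, frame: int, residue: int | None = None,
    params: StateParams = StateParams(),
):
    """Whether each amide H forms an intramolecular hydrogen bond.

    Acceptors are protein N/O heavy atoms; each amide's own backbone N
    (its donor) is excluded.
    """
    coords = traj.frame_coords(frame)
    acc = traj.acceptor_idx
    mask = _hbond_mask(
        coords[traj.amide_h_idx], coords[traj.amide_n_idx],
        coords[acc], params, box=traj.box(frame),
    )
    own = acc[None, :] == traj.amide_n_idx[:, None]
    mask &= ~own
    flags = pd.Series(mask.any(axis=1), index=traj.amide_residues, name="intra_hb")
    return bool(flags.loc[residue]) if residue is not None else flags


# ---------------------------------------------------------------------------
# State traces
# ---------------------------------------------------------------------------

@dataclass
class StateTrace:
    """Per-residue, per-frame open/closed assignments under one model."""

    model: str                      # "inter" | "intra"
    residues: np.ndarray            # 1-based positions
    open_matrix: np.ndarray         # bool, (n_residues, n_frames)
    frame_indices: np.ndarray       # trajectory frames used
    replicate_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.open_matrix.shape[1]

    @property
    def f_open(self) -> np.ndarray:
        return self.open_matrix.mean(axis=1)

    @property
    def f_closed(self) -> np.ndarray:
        return 1.0 - self.f_open

    def dwell_times(self) -> pd.DataFrame:
        """Mean dwell lengths (frames) in the open and closed states."""
        rows = []
        for r, row in zip(self.residues, self.open_matrix):
            lengths = {True: [], False: []}
            start = 0
            for k in range(1, len(row) + 1):
                if k == len(row) or row[k] != row[start]:
                    lengths[bool(row[start])].append(k - start)
                    start = k
            rows.append(
                {
                    "residue": int(r),
                    "tau_open": float(np.mean(lengths[True])) if lengths[True] else 0.0,
                    "tau_closed": float(np.mean(lengths[False])) if lengths[False] else 0.0,
                    "n_open_frames": int(row.sum()),
                    "n_frames": int(len(row)),
                }
            )
        return pd.DataFrame(rows).set_index("residue")

    def summary(self) -> pd.DataFrame:
        dw = self.dwell_times()
        dw.insert(0, "f_open", self.f_open)
        dw.insert(1, "f_closed", self.f_closed)
        return dw


def _subsample(n_frames: int, n_max: int) -> np.ndarray:
    if n_frames <= n_max:
        return np.arange(n_frames)
    return np.unique(np.round(np.linspace(0, n_frames - 1, n_max)).astype(int))


def classify_states(
    traj: Trajectory, model: str = "inter", params: StateParams = StateParams()
) -> StateTrace:
    """Classify every amide in every (subsampled) frame as open or closed.

    inter: open <=> SASA >= threshold AND >= ``min_waters`` waters in
    geometry. intra: closed <=> SASA < threshold OR any intramolecular
    H-bond. Frames beyond ``params.n_max_frames`` are evenly subsampled.
    """
    if model not in ("inter", "intra"):
        raise ValueError(f"unknown model {model!r}")
    frames = _subsample(traj.n_frames, params.n_max_frames)
    n_res = traj.amide_residues.size
    open_mat = np.zeros((n_res, frames.size), dtype=bool)
    for col, frame in enumerate(frames):
        sasa = sasa_amide_h(traj, int(frame), params).to_numpy()
        exposed = sasa >= params.sasa_threshold
        if model == "inter":
            waters = water_hbond_count(traj, int(frame), params=params).to_numpy()
            open_mat[:, col] = exposed & (waters >= params.min_waters)
        else:
            intra = intra_hbond_exists(traj, int(frame), params=params).to_numpy()
            open_mat[:, col] = exposed & ~intra
    return StateTrace(
        model=model,
        residues=traj.amide_residues.copy(),
        open_matrix=open_mat,
        frame_indices=frames,
        replicate_id=traj.replicate_id,
    )
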