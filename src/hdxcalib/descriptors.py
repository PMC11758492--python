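"""Ensemble structural descriptors: gyration shape, RMSD, contacts, helicity.

These summarize the conformational flexibility that underlies differences
in amide protection: per-frame radius of gyration and asphericity from the
gyration tensor, backbone RMSD to a reference frame, residue-residue
contact frequency maps, and a dihedral-window estimate of helical content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from MDAnalysis.analysis import rms

from ._geometry import dihedral
from .trajectory_states import Trajectory

__all__ = [
    "ShapeSeries",
    "ContactMap",
    "shape_series",
    "backbone_rmsd",
    "contact_map",
    "helicity",
]

_BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class ShapeSeries:
    """Per-frame gyration radius (A) and asphericity (0 sphere .. 1 rod)."""

    rg: np.ndarray
    asphericity: np.ndarray
    rmsd: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"rg": self.rg, "asphericity": self.asphericity}
        if self.rmsd is not None:
            data["rmsd"] = self.rmsd
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ContactMap:
    """Residue-residue contact frequencies over the trajectory."""

    residues: np.ndarray
    frequency: np.ndarray     # symmetric, zero diagonal band
    cutoff: float
    min_separation: int


def _protein_atoms(traj: Trajectory):
    return traj.universe.atoms[traj.protein_idx]


def shape_series(traj: Trajectory, mass_weighting: bool = True) -> ShapeSeries:
    """Radius of gyration and asphericity per frame.

    Both derive from the (optionally mass-weighted) gyration tensor S:
    Rg = sqrt(tr S) and delta = 1 - 3 (l1 l2 + l2 l3 + l3 l1) / (tr S)^2
    with eigenvalues l1 >= l2 >= l3. delta is 0 for an isotropic
    (spherical) distribution and 1 in the collinear (rod) limit.
    """
    atoms = _protein_atoms(traj)
    if len(atoms) < 4:
        raise ValueError("need at least 4 atoms")
    try:
        masses = atoms.masses if mass_weighting else np.ones(len(atoms))
        if not np.all(masses > 0):
            masses = np.ones(len(atoms))
    except Exception:
        masses = np.ones(len(atoms))
    w = masses / masses.sum()
    rg = np.empty(traj.n_frames)
    delta = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        xyz = traj.frame_coords(f)[traj.protein_idx]
        com = w @ xyz
        centered = xyz - com
        s = (w[:, None] * centered).T @ centered
        lam = np.sort(np.linalg.eigvalsh(s))[::-1]
        tr = lam.sum()
        rg[f] = np.sqrt(tr)
        if tr <= 0:
            delta[f] = np.nan
        else:
            delta[f] = 1.0 - 3.0 * (lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]) / tr**2
    return ShapeSeries(rg=rg, asphericity=delta)


def backbone_rmsd(traj: Trajectory, reference_frame: int = 0, fit: bool = True) -> np.ndarray:
    """Backbone (N, CA, C, O) RMSD of every frame to a reference frame.

    With ``fit=True`` each frame is optimally superposed (rotation +
    translation) before the deviation is computed.
    """
    atoms = _protein_atoms(traj)
    bb_idx = traj.protein_idx[np.isin(atoms.names, _BACKBONE_NAMES)]
    if bb_idx.size == 0:
        raise ValueError("no backbone atoms (N, CA, C, O) found")
    ref = traj.frame_coords(reference_frame)[bb_idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mobile = traj.frame_coords(f)[bb_idx]
        out[f] = rms.rmsd(mobile, ref, center=fit, superposition=fit)
    return out


def contact_map(traj: Trajectory, cutoff: float = 4.5, min_separation: int = 2) -> ContactMap:
    """Fraction of frames each residue pair is in heavy-atom contact.

    A pair (i, j), |i - j| >= ``min_separation``, is in contact in a
    frame when the minimum distance between their heavy (non-hydrogen)
    atoms is at most ``cutoff``.
    """
    atoms = _protein_atoms(traj)
    heavy_mask = traj.elements[traj.protein_idx] != "H"
    heavy_idx = traj.protein_idx[heavy_mask]
    resids = atoms.resids[heavy_mask]
    unique_res = np.unique(resids)
    groups = [np.nonzero(resids == r)[0] for r in unique_res]
    n_res = unique_res.size
    counts = np.zeros((n_res, n_res))
    for f in range(traj.n_frames):
        xyz = traj.frame_coords(f)[heavy_idx]
        d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=2)
        for a in range(n_res):
            for b in range(a + min_separation, n_res):
                if d2[np.ix_(groups[a], groups[b])].min() <= cutoff**2:
                    counts[a, b] += 1
    freq = (counts + counts.T) / traj.n_frames
    return ContactMap(
        residues=unique_res, frequency=freq, cutoff=cutoff, min_separation=min_separation
    )


def helicity(traj: Trajectory, window: float = 30.0) -> pd.Series:
    """Fraction of frames each interior residue is in the helical basin.

    A residue counts as helical in a frame when phi is within ``window``
    degrees of -57 and psi within ``window`` of -47 (a dihedral-window
    approximation of a secondary-structure assignment, not a DSSP/STRIDE
    equivalent). Terminal residues (no phi or no psi) are reported NaN.
    """
    atoms = _protein_atoms(traj)
    resids = np.unique(atoms.resids)
    n_res = resids.size
    idx = {}
    for r in resids:
        res_atoms = atoms[atoms.resids == r]
        named = {a.name: a.ix for a in res_atoms}
        idx[r] = named
    helical = np.zeros(n_res)
    defined = np.zeros(n_res, dtype=bool)
    for f in range(traj.n_frames):
        xyz = traj.frame_coords(f)
        for k in range(1, n_res - 1):
            r_prev, r, r_next = resids[k - 1], resids[k], resids[k + 1]
            try:
                phi = dihedral(
                    xyz[idx[r_prev]["C"]], xyz[idx[r]["N"]],
                    xyz[idx[r]["CA"]], xyz[idx[r]["C"]],
                )
                psi = dihedral(
                    xyz[idx[r]["N"]], xyz[idx[r]["CA"]],
                    xyz[idx[r]["C"]], xyz[idx[r_next]["N"]],
                )
            except KeyError:
                continue
            defined[k] = True
            if abs(_wrap(phi + 57.0)) <= window and abs(_wrap(psi + 47.0)) <= window:
                helical[k] += 1
    frac = np.full(n_res, np.nan)
    frac[defined] = helical[defined] / traj.n_frames
    return pd.Series(frac, index=resids, name="helix_fraction")


def _wrap(angle: float) -> float:
    return (angle + 180.0) % 360.0 - 180.0
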