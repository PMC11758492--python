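"""Shared geometry primitives: dihedrals, internal-coordinate chain
building (natural extension reference frame) and deterministic sphere
point sets for surface-area integration."""

from __future__ import annotations

import numpy as np

# Standard backbone internal coordinates (lengths in angstrom, angles in deg).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.5
ANGLE_C_N_H = 119.0


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given positions A, B, C and internal coordinates
    (|C-D|, angle B-C-D, dihedral A-B-C-D)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def build_backbone(n_residues: int, phi, psi, omega=180.0) -> dict[str, np.ndarray]:
    """Build an all-backbone peptide chain from dihedral angles.

    ``phi``/``psi``/``omega`` may be scalars or per-residue arrays (phi of
    residue 1 and psi/omega of the last residue are unused). Returns a
    mapping of atom name -> (n_residues, 3) coordinate arrays for
    N, H, CA, C, O. The amide H of residue 1 is placed too (callers
    decide whether to keep it); H is anti to the preceding carbonyl O.
    """
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (n_residues,))
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (n_residues,))
    omega = np.broadcast_to(np.asarray(omega, dtype=float), (n_residues,))

    coords = {k: np.zeros((n_residues, 3)) for k in ("N", "H", "CA", "C", "O")}
    # residue 1 seed triad
    coords["N"][0] = [0.0, 0.0, 0.0]
    coords["CA"][0] = [BOND_N_CA, 0.0, 0.0]
    theta = np.radians(ANGLE_N_CA_C)
    coords["C"][0] = coords["CA"][0] + BOND_CA_C * np.array(
        [-np.cos(theta), np.sin(theta), 0.0]
    )
    # arbitrary direction for residue-1 H (no preceding carbonyl)
    coords["H"][0] = coords["N"][0] + BOND_N_H * np.array([-0.3420, -0.9397, 0.0])

    for i in range(1, n_residues):
        n_prev, ca_prev, c_prev = coords["N"][i - 1], coords["CA"][i - 1], coords["C"][i - 1]
        n_i = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        ca_i = place_atom(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, omega[i - 1])
        c_i = place_atom(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi[i])
        # carbonyl O of residue i-1: anti to the new N across the C
        coords["O"][i - 1] = place_atom(
            n_prev, ca_prev, c_prev, BOND_C_O, ANGLE_CA_C_O, psi[i - 1] + 180.0
        )
        # amide H of residue i: in the peptide plane, anti to CA(i)
        coords["H"][i] = place_atom(
            ca_prev, c_prev, n_i, BOND_N_H, ANGLE_C_N_H, omega[i - 1] + 180.0
        )
        coords["N"][i], coords["CA"][i], coords["C"][i] = n_i, ca_i, c_i

    # terminal carbonyl O (no following N; use psi convention with a flat chain)
    coords["O"][-1] = place_atom(
        coords["N"][-1], coords["CA"][-1], coords["C"][-1],
        BOND_C_O, ANGLE_CA_C_O, psi[-1] + 180.0,
    )
    return coords


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )
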