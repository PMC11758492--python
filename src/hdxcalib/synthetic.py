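"""Synthetic fixtures: toy hydrated trajectories, isotopic envelopes and
amino-acid-standard series with construction-known ground truth.

Nothing here is physically simulated. Trajectories are built from ideal
internal coordinates with rigid waters placed analytically inside or
outside the hydrogen-bond acceptance cone of each amide, so the per-frame
open/closed state under the inter model is known exactly by construction
and recorded in a manifest. Envelopes are exact binomial convolutions of
a base isotope pattern, so the expected centroid shift is
``n_sites * p * (D-H mass difference)``. Standards are linear responses
of site-class counts to a known propensity table plus seeded noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import MDAnalysis as mda
import numpy as np

from ._geometry import build_backbone
from .decomposition import PropensityTable
from .peptides import DELTA_MD, Peptide, SiteInventory, enumerate_sites
from .spectra import PROTON_MASS, PeakList

__all__ = [
    "ToyTrajectorySpec",
    "ToyTrajectory",
    "EnvelopeSpec",
    "make_toy_trajectory",
    "make_envelope",
    "make_standards",
]

_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

_DIHEDRALS = {"extended": (180.0, 180.0), "helix": (-57.0, -47.0)}

# 12 icosahedron vertices for the burial cage.
_PHI_G = (1 + 5**0.5) / 2
_ICOSA = np.array(
    [(0, 1, _PHI_G), (0, -1, _PHI_G), (0, 1, -_PHI_G), (0, -1, -_PHI_G),
     (1, _PHI_G, 0), (-1, _PHI_G, 0), (1, -_PHI_G, 0), (-1, -_PHI_G, 0),
     (_PHI_G, 0, 1), (-_PHI_G, 0, 1), (_PHI_G, 0, -1), (-_PHI_G, 0, -1)],
    dtype=float,
)
_ICOSA /= np.linalg.norm(_ICOSA, axis=1, keepdims=True)


@dataclass(frozen=True)
class ToyTrajectorySpec:
    """Recipe for a hydrated toy trajectory with known open fractions.

    ``f_open`` is the per-residue target open fraction under the inter
    model (scalar, or mapping residue position -> fraction; residues
    without an amide are ignored). ``closed_mode`` selects how closed
    frames are realised: ``"water_removal"`` parks the residue's waters
    far away (closed for inter, still open for intra), ``"burial"``
    additionally wraps the amide H in an occluding cage (closed under
    both models). ``conformer`` is ``"extended"``, ``"helix"`` or
    ``"coil"`` (seeded random dihedrals with a clash check).
    """

    sequence: str = "AAAAAA"
    n_frames: int = 200
    f_open: float | dict[int, float] = 1.0
    conformer: str = "extended"
    closed_mode: str = "water_removal"
    seed: int = 0
    water_distance: float = 2.0
    cage_radius: float = 2.0


@dataclass
class ToyTrajectory:
    """Emitted files plus the construction ground truth."""

    topology: Path
    coordinates: Path
    manifest: Path
    amide_residues: np.ndarray
    open_matrix: np.ndarray          # bool (n_amides, n_frames), inter-model truth
    spec: ToyTrajectorySpec

    @property
    def f_open(self) -> np.ndarray:
        return self.open_matrix.mean(axis=1)


def _bresenham_schedule(n_frames: int, n_open: int, phase: int) -> np.ndarray:
    k = np.arange(n_frames)
    pattern = ((k + 1) * n_open) // n_frames - (k * n_open) // n_frames
    return np.roll(pattern.astype(bool), phase)


def _coil_dihedrals(n_res: int, rng: np.random.Generator, max_tries: int = 200):
    """Rejection-sample backbone dihedrals with a hard-sphere clash check."""
    labels = np.repeat(np.arange(n_res), 4)
    for _ in range(max_tries):
        phi = rng.uniform(-180, 180, n_res)
        psi = rng.uniform(-180, 180, n_res)
        bb = build_backbone(n_res, phi, psi)
        xyz = np.stack([bb[k] for k in ("N", "CA", "C", "O")], axis=1).reshape(-1, 3)
        d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
        nonlocal_pair = np.abs(labels[:, None] - labels[None, :]) >= 2
        if not np.any(d[nonlocal_pair] < 2.0):
            return phi, psi
    raise RuntimeError("could not sample a clash-free coil conformation")


def make_toy_trajectory(spec: ToyTrajectorySpec, outdir) -> ToyTrajectory:
    """Emit topology (PDB), coordinates (DCD) and a ground-truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seq = spec.sequence
    n_res = len(seq)
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.default_rng(spec.seed)

    amide_pos = [i for i in range(2, n_res + 1) if seq[i - 1] != "P"]
    targets = {}
    for pos in amide_pos:
        t = spec.f_open if np.isscalar(spec.f_open) else spec.f_open.get(pos, 1.0)
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"target f_open {t} for residue {pos} outside [0, 1]")
        targets[pos] = float(t)
    if spec.closed_mode not in ("water_removal", "burial"):
        raise ValueError(f"unknown closed_mode {spec.closed_mode!r}")

    # --- per-frame backbone coordinates -----------------------------------
    if spec.conformer in _DIHEDRALS:
        phi, psi = _DIHEDRALS[spec.conformer]
        frames_bb = [build_backbone(n_res, phi, psi)] * spec.n_frames
    elif spec.conformer == "coil":
        frames_bb = [
            build_backbone(n_res, *_coil_dihedrals(n_res, rng))
            for _ in range(spec.n_frames)
        ]
    else:
        raise ValueError(f"unknown conformer family {spec.conformer!r}")

    # --- topology ---------------------------------------------------------
    names, resnames, resids, elements, resindex = [], [], [], [], []
    res_counter = 0

    def new_residue(resname: str):
        nonlocal res_counter
        res_counter += 1
        resnames.append(resname)
        resids.append(res_counter)

    atom_of = {}  # (resid position, atom name) -> atom index for peptide atoms
    for i, aa in enumerate(seq, start=1):
        new_residue(_THREE[aa])
        for name in ("N", "H", "CA", "C", "O"):
            if name == "H" and (i == 1 or aa == "P"):
                continue
            atom_of[(i, name)] = len(names)
            names.append(name)
            elements.append(name[0])
            resindex.append(res_counter - 1)

    water_atoms = {}  # residue position -> list of (O, H1, H2) index triples
    for pos in amide_pos:
        triples = []
        for w in range(2):
            new_residue("HOH")
            base = len(names)
            names.extend(["OW", "HW1", "HW2"])
            elements.extend(["O", "H", "H"])
            resindex.extend([res_counter - 1] * 3)
            triples.append((base, base + 1, base + 2))
        water_atoms[pos] = triples

    cage_atoms = {}
    if spec.closed_mode == "burial":
        for pos in amide_pos:
            new_residue("CGE")
            base = len(names)
            names.extend([f"C{k}" for k in range(12)])
            elements.extend(["C"] * 12)
            resindex.extend([res_counter - 1] * 12)
            cage_atoms[pos] = np.arange(base, base + 12)

    n_atoms = len(names)

    # --- schedules --------------------------------------------------------
    open_rows = []
    for j, pos in enumerate(amide_pos):
        n_open = int(round(targets[pos] * spec.n_frames))
        open_rows.append(_bresenham_schedule(spec.n_frames, n_open, phase=j))
    open_matrix = np.array(open_rows, dtype=bool)

    # --- coordinates ------------------------------------------------------
    def water_sites(n_xyz, h_xyz):
        """Two water oxygen/hydrogen placements inside the acceptance cone."""
        u = h_xyz - n_xyz
        u /= np.linalg.norm(u)
        w = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(w) < 1e-6:
            w = np.cross(u, [0.0, 1.0, 0.0])
        w /= np.linalg.norm(w)
        tilt = np.radians(15.0)
        v = np.cos(tilt) * u + np.sin(tilt) * w
        placements = []
        for d, direction in ((spec.water_distance, u), (spec.water_distance + 0.2, v)):
            o = h_xyz + d * direction
            placements.append((o, o + np.array([0.76, 0.59, 0.0]),
                               o + np.array([-0.76, 0.59, 0.0])))
        return placements

    coords = np.zeros((spec.n_frames, n_atoms, 3), dtype=float)
    for f in range(spec.n_frames):
        bb = frames_bb[f]
        for i, aa in enumerate(seq, start=1):
            for name in ("N", "H", "CA", "C", "O"):
                if (i, name) in atom_of:
                    coords[f, atom_of[(i, name)]] = bb[name][i - 1]
        for j, pos in enumerate(amide_pos):
            n_xyz = bb["N"][pos - 1]
            h_xyz = bb["H"][pos - 1]
            is_open = open_matrix[j, f]
            park = np.array([400.0 + 20.0 * j, 0.0, 0.0])
            for w, (oi, h1, h2) in enumerate(water_atoms[pos]):
                if is_open:
                    o, a, b = water_sites(n_xyz, h_xyz)[w]
                else:
                    o = park + np.array([0.0, 5.0 * w, 0.0])
                    a, b = o + [0.76, 0.59, 0.0], o + [-0.76, 0.59, 0.0]
                coords[f, oi], coords[f, h1], coords[f, h2] = o, a, b
            if spec.closed_mode == "burial":
                cage = cage_atoms[pos]
                if is_open:
                    coords[f, cage] = park + np.array([0.0, 40.0, 0.0]) + \
                        spec.cage_radius * _ICOSA
                else:
                    coords[f, cage] = h_xyz + spec.cage_radius * _ICOSA

    # --- emit files -------------------------------------------------------
    u = mda.Universe.empty(
        n_atoms, n_residues=res_counter,
        atom_resindex=np.asarray(resindex),
        residue_segindex=np.zeros(res_counter, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("elements", elements)
    u.atoms.positions = coords[0]

    top_path = outdir / "toy_topology.pdb"
    dcd_path = outdir / "toy_trajectory.dcd"
    u.atoms.write(str(top_path))
    with mda.Writer(str(dcd_path), n_atoms) as writer:
        for f in range(spec.n_frames):
            u.atoms.positions = coords[f]
            writer.write(u.atoms)

    manifest_path = outdir / "toy_manifest.json"
    manifest = {
        "sequence": seq,
        "n_frames": spec.n_frames,
        "conformer": spec.conformer,
        "closed_mode": spec.closed_mode,
        "seed": spec.seed,
        "amide_residues": [int(p) for p in amide_pos],
        "target_f_open": {str(p): targets[p] for p in amide_pos},
        "realized_f_open": {
            str(p): float(open_matrix[j].mean()) for j, p in enumerate(amide_pos)
        },
        "open_frames": {
            str(p): [int(x) for x in np.nonzero(open_matrix[j])[0]]
            for j, p in enumerate(amide_pos)
        },
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))

    return ToyTrajectory(
        topology=top_path,
        coordinates=dcd_path,
        manifest=manifest_path,
        amide_residues=np.array(amide_pos, dtype=int),
        open_matrix=open_matrix,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Isotopic envelopes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvelopeSpec:
    """Binomially deuterated isotopic envelope on a fixed base pattern."""

    n_sites: int
    p: float
    charge: int = 1
    base_mass: float = 500.0                       # neutral monoisotopic, Da
    base_intensities: tuple = (100.0, 40.0, 10.0)  # natural isotope pattern
    isotope_spacing: float = 1.00336               # 13C-12C, Da
    noise: float = 0.0                             # relative intensity noise
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.n_sites < 0 or self.charge < 1:
            raise ValueError("invalid n_sites or charge")


def _binom_pmf(n: int, p: float) -> np.ndarray:
    from scipy.stats import binom

    return binom.pmf(np.arange(n + 1), n, p)


def make_envelope(spec: EnvelopeSpec) -> tuple[PeakList, PeakList]:
    """Before/after peak lists whose exact centroid shift is n*p*dm_D.

    The after envelope is the discrete convolution of the base isotope
    pattern with the binomial number-of-deuteriums distribution; with
    ``noise=0`` the centroid shift equals ``n_sites * p * 1.00628`` to
    machine precision.
    """
    rng = np.random.default_rng(spec.seed)
    z = spec.charge
    base = np.asarray(spec.base_intensities, dtype=float)
    masses = spec.base_mass + spec.isotope_spacing * np.arange(base.size)

    def to_peaks(mass_vals, intens, label):
        order = np.argsort(mass_vals)
        mz = (mass_vals[order] + z * PROTON_MASS) / z
        inten = intens[order]
        if spec.noise > 0:
            inten = np.clip(inten * (1 + spec.noise * rng.standard_normal(inten.size)),
                            1e-12, None)
        return PeakList(mz=mz, intensity=inten, charge=z, label=label)

    before = to_peaks(masses, base.copy(), "before")
    pmf = _binom_pmf(spec.n_sites, spec.p)
    shift_mass = masses[:, None] + DELTA_MD * np.arange(spec.n_sites + 1)[None, :]
    inten = base[:, None] * pmf[None, :]
    flat_mass = shift_mass.ravel()
    flat_int = inten.ravel()
    keep = flat_int > 1e-15
    # merge coincident masses so m/z stays strictly increasing
    uniq, inv = np.unique(np.round(flat_mass[keep], 9), return_inverse=True)
    merged = np.bincount(inv, weights=flat_int[keep])
    after = to_peaks(uniq, merged, "after")
    return before, after


# ---------------------------------------------------------------------------
# Amino-acid standards
# ---------------------------------------------------------------------------

_DEFAULT_STANDARD_PEPTIDES = (
    ("G", "free", "free_acid"),
    ("G", "acetyl", "free_acid"),
    ("G", "free", "amide"),
    ("K", "free", "free_acid"),
    ("R", "free", "free_acid"),
    ("S", "free", "free_acid"),
    ("T", "acetyl", "free_acid"),
    ("D", "free", "free_acid"),
    ("N", "free", "free_acid"),
    ("H", "free", "free_acid"),
    ("W", "free", "free_acid"),
    ("C", "free", "free_acid"),
    ("KK", "free", "free_acid"),
    ("RS", "acetyl", "amide"),
)


def default_standard_inventories() -> list[SiteInventory]:
    """Site inventories of a full-rank free-amino-acid/dipeptide panel."""
    return [
        enumerate_sites(Peptide(seq, n_term_mod=nt, c_term_mod=ct))
        for seq, nt, ct in _DEFAULT_STANDARD_PEPTIDES
    ]


def make_standards(
    table: PropensityTable,
    designs: list[SiteInventory] | None = None,
    noise: float = 0.0,
    seed: int = 0,
):
    """Standards dataset from a known propensity table.

    Returns ``(standards, truth)`` where ``standards`` is a list of
    ``(SiteInventory, observed_uptake)`` pairs ready for propensity
    fitting and ``truth`` records the noise-free observations. ``noise``
    is the absolute Gaussian sigma (hydrogen units) added per
    observation; classes present in the designs but absent from
    ``table`` contribute zero uptake.
    """
    rng = np.random.default_rng(seed)
    if designs is None:
        designs = default_standard_inventories()
    truth = []
    standards = []
    for inv in designs:
        clean = sum(
            count * table.values.get(cls, 0.0)
            for cls, count in inv.side_chain_counts.items()
        )
        obs = clean + (rng.normal(0.0, noise) if noise > 0 else 0.0)
        truth.append(clean)
        standards.append((inv, obs))
    return standards, np.asarray(truth)
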