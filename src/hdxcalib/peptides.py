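"""Peptide definitions, exchangeable-site inventories and intrinsic rates.

A peptide exposes two kinds of labile hydrogens to solvent: backbone amide
hydrogens (one per residue, except proline and a free N-terminal residue)
and side-chain/terminal heteroatom hydrogens (amines, hydroxyls, ...).
This module enumerates both classes for a peptide in its neutral form and
evaluates the sequence-dependent intrinsic exchange rate ``k_int`` of each
backbone amide from the packaged poly-DL-alanine reference model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "Peptide",
    "SiteInventory",
    "KintProfile",
    "enumerate_sites",
    "kint_profile",
    "peptide_from_fasta",
]

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

# Exchangeable side-chain hydrogens per residue, neutral form.
# (site class, hydrogen count)
_SIDE_CHAIN = {
    "K": ("amine", 2),
    "R": ("guanidino", 4),
    "S": ("hydroxyl", 1),
    "T": ("hydroxyl", 1),
    "Y": ("hydroxyl", 1),
    "D": ("carboxyl", 1),
    "E": ("carboxyl", 1),
    "N": ("amide_sidechain", 2),
    "Q": ("amide_sidechain", 2),
    "H": ("imidazole", 1),
    "W": ("indole", 1),
    "C": ("thiol", 1),
}

#: Gas-phase D-H mass difference used throughout (Da).
DELTA_MD = 1.00628


@dataclass(frozen=True)
class Peptide:
    """A standard-residue peptide with optional terminal modifications.

    Parameters
    ----------
    sequence:
        One-letter amino-acid string (20 standard residues).
    n_term_mod:
        ``"free"`` (protonatable alpha-amine) or ``"acetyl"``.
    c_term_mod:
        ``"free_acid"`` or ``"amide"``.
    charge:
        Number of extra protons for MS-ion site counting; 0 for the
        neutral form used in inventories.
    """

    sequence: str
    n_term_mod: str = "free"
    c_term_mod: str = "free_acid"
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in STANDARD_RESIDUES:
                raise ValueError(f"unknown residue {aa!r} at position {pos}")
        if self.n_term_mod not in ("free", "acetyl"):
            raise ValueError(f"illegal N-terminal modification {self.n_term_mod!r}")
        if self.c_term_mod not in ("free_acid", "amide"):
            raise ValueError(f"illegal C-terminal modification {self.c_term_mod!r}")
        if self.charge < 0:
            raise ValueError("charge must be >= 0")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteInventory:
    """Counts of exchangeable hydrogens by site class.

    ``total == backbone_count + sum(side_chain_counts.values()) + extra_protons``.
    ``side_total`` is the printed-style "side chain/terminal" count.
    """

    backbone_count: int
    side_chain_counts: dict[str, int]
    extra_protons: int = 0

    @property
    def side_total(self) -> int:
        return sum(self.side_chain_counts.values())

    @property
    def total(self) -> int:
        return self.backbone_count + self.side_total + self.extra_protons


def enumerate_sites(peptide: Peptide) -> SiteInventory:
    """Enumerate exchangeable hydrogens of a peptide.

    Backbone amides: every residue after the first, except prolines. The
    first residue carries a backbone amide hydrogen only when the
    N-terminus is acetylated (and the residue is not proline); a free
    N-terminus instead contributes two alpha-amine hydrogens counted as a
    terminal side-chain class. A free-acid C-terminus contributes one
    hydrogen; a C-terminal amide two (side-chain amide class). A
    protonated MS ion adds ``charge`` hydrogens to the total only.
    """
    seq = peptide.sequence
    side: dict[str, int] = {}

    def add(cls: str, n: int) -> None:
        if n:
            side[cls] = side.get(cls, 0) + n

    backbone = sum(1 for aa in seq[1:] if aa != "P")
    if peptide.n_term_mod == "acetyl":
        if seq[0] != "P":
            backbone += 1  # the acetylated alpha-amine becomes an amide N-H
    else:
        add("n_terminal_amine", 2)

    for aa in seq:
        if aa in _SIDE_CHAIN:
            cls, n = _SIDE_CHAIN[aa]
            add(cls, n)

    if peptide.c_term_mod == "free_acid":
        add("c_terminal_acid", 1)
    else:
        add("amide_sidechain", 2)

    return SiteInventory(backbone, side, extra_protons=peptide.charge)


# ---------------------------------------------------------------------------
# Intrinsic exchange rates
# ---------------------------------------------------------------------------

# Reference rate constants for poly-DL-alanine amide exchange into D2O at
# 293 K: acid- and base-catalysed (M^-1 min^-1, log10) and water (min^-1).
_LOG_KA_REF = 1.62
_LOG_KB_REF = 10.18
_LOG_KW_REF = -1.5
_T_REF = 293.0
# Activation energies, kcal/mol.
_EA_ACID = 14.0
_EA_BASE = 17.0
_EA_WATER = 19.0
_R_KCAL = 1.987e-3
#: Ion product of D2O (log10 scale) used to convert pD to [OD-].
PKD = 15.05


def _load_factors(reference_table_id: str = "kint_neighbor_factors") -> pd.DataFrame:
    path = resources.files("hdxcalib.data") / f"{reference_table_id}.csv"
    with path.open() as fh:
        return pd.read_csv(fh, comment="#", index_col="residue")


@dataclass(frozen=True)
class KintProfile:
    """Per-residue intrinsic backbone-amide exchange rates (s^-1).

    ``residues`` are 1-based sequence positions; prolines and a free
    N-terminal residue are absent. Rates are for an unprotected amide at
    the stated pD (pH meter reading + ``pd_offset``) and temperature.
    """

    residues: tuple[int, ...]
    rates: np.ndarray  # s^-1, aligned with residues
    pH: float
    temperature: float
    reference_table_id: str = "kint_neighbor_factors"

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.residues, self.rates))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.residues, "k_int": self.rates})


def kint_profile(
    peptide: Peptide,
    pH: float = 7.0,
    temperature: float = 300.0,
    pd_offset: float = 0.4,
    reference_table_id: str = "kint_neighbor_factors",
) -> KintProfile:
    """Evaluate sequence-dependent intrinsic amide exchange rates.

    Each amide's rate is the sum of acid-, base- and water-catalysed
    pathways.  Each pathway rate is the poly-DL-alanine reference rate
    scaled by the side-chain correction of the residue itself (lambda)
    and of its left neighbour (rho), an Arrhenius temperature factor, and
    catalyst concentration ([D+] or [OD-] from ``pD = pH + pd_offset``).
    Terminal groups apply additional corrections to the adjacent amides.
    """
    if not 0.0 < pH < 14.0:
        raise ValueError("pH out of range (0, 14)")
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")

    table = _load_factors(reference_table_id)
    seq = peptide.sequence
    pd_val = pH + pd_offset
    conc_d = 10.0 ** (-pd_val)
    conc_od = 10.0 ** (pd_val - PKD)

    def arrhenius(ea: float) -> float:
        return math.exp(-(ea / _R_KCAL) * (1.0 / temperature - 1.0 / _T_REF))

    ka = 10.0**_LOG_KA_REF / 60.0 * arrhenius(_EA_ACID)
    kb = 10.0**_LOG_KB_REF / 60.0 * arrhenius(_EA_BASE)
    kw = 10.0**_LOG_KW_REF / 60.0 * arrhenius(_EA_WATER)

    def fac(res: str, col: str) -> float:
        if res not in table.index:
            raise KeyError(f"missing rate-factor table entry for {res!r}")
        return 10.0 ** float(table.at[res, col])

    residues: list[int] = []
    rates: list[float] = []
    n = len(seq)
    for i, aa in enumerate(seq, start=1):  # 1-based
        if aa == "P":
            continue
        if i == 1 and peptide.n_term_mod != "acetyl":
            continue  # free alpha-amine, not an amide
        left = seq[i - 2] if i > 1 else ("ACETYL" if peptide.n_term_mod == "acetyl" else None)
        la, lb = fac(aa, "lambda_acid"), fac(aa, "lambda_base")
        ra = rb = 1.0
        if left is not None:
            ra, rb = fac(left, "rho_acid"), fac(left, "rho_base")
        if i == 2 and peptide.n_term_mod == "free":
            ra *= fac("N_TERM", "rho_acid")
            rb *= fac("N_TERM", "rho_base")
        if i == n and peptide.c_term_mod == "free_acid":
            la *= fac("C_TERM_ACID", "lambda_acid")
            lb *= fac("C_TERM_ACID", "lambda_base")
        rate = ka * la * ra * conc_d + kb * lb * rb * conc_od + kw * lb * rb
        residues.append(i)
        rates.append(rate)

    return KintProfile(
        residues=tuple(residues),
        rates=np.asarray(rates, dtype=float),
        pH=pH,
        temperature=temperature,
        reference_table_id=reference_table_id,
    )


def peptide_from_fasta(path) -> Peptide:
    """Read a single-record FASTA file into a :class:`Peptide` (free termini)."""
    seqs: list[str] = []
    with open(path) as fh:
        current: list[str] = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current:
                    seqs.append("".join(current))
                    current = []
            else:
                current.append(line)
        if current:
            seqs.append("".join(current))
    if len(seqs) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(seqs)}")
    return Peptide(seqs[0].upper())


# Peptides studied in the droplet HDX calibration set.  KDD's sequence is
# printed inconsistently in the source literature; both variants are kept.
STUDY_PEPTIDES = {
    "PA": Peptide("PAAAAKAAAAKAAAAKAAAAK", n_term_mod="acetyl"),
    "PS": Peptide("PSSSSKSSSSKSSSSKSSSSK", n_term_mod="acetyl"),
    "Nt17": Peptide("MATLEKLMKAFESLKSF"),
    "BK": Peptide("RPPGFSPFR"),
    "KDD_results": Peptide("KKDDDDDIIKIIK"),
    "KDD_reagents": Peptide("KDDDDDIIKIIK"),
}
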