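"""Protection factors and theoretical backbone exchange.

For amide i the protection factor is the closed/open population ratio,
PF_i = f_c,i / f_o,i, estimated from the classified state trace. Two
rules translate PF profiles into theoretical % backbone exchange:

* digital rule — a residue exchanges iff ln(PF_i) < 0 (open-dominated);
  the theoretical % BB is the fraction of such residues.
* combined kinetic rule — under the two-state pre-equilibrium limit the
  observed rate is k_obs = k_int/PF, so the exchanged fraction after
  reaction time t is 1 - exp(-k_int * t / PF_i), summed over residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peptides import KintProfile
from .trajectory_states import StateTrace

__all__ = [
    "PFProfile",
    "TheoreticalExchange",
    "protection_factors",
    "digital_exchange",
    "cmb_exchange",
    "aggregate_replicates",
]


@dataclass(frozen=True)
class PFProfile:
    """Per-residue open fractions and protection factors for one model."""

    residues: np.ndarray
    f_open: np.ndarray
    pf: np.ndarray
    ln_pf: np.ndarray
    model: str
    n_frames: int
    clamped: np.ndarray          # residues whose f_open hit the clamp bounds
    sem_ln_pf: np.ndarray | None = None
    sem_f_open: np.ndarray | None = None

    @property
    def f_closed(self) -> np.ndarray:
        return 1.0 - self.f_open

    @property
    def k_eq(self) -> np.ndarray:
        """Open/closed equilibrium constant, the reciprocal of PF."""
        return 1.0 / self.pf

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "residue": self.residues,
                "f_open": self.f_open,
                "pf": self.pf,
                "ln_pf": self.ln_pf,
                "clamped": self.clamped,
            }
        ).set_index("residue")
        if self.sem_ln_pf is not None:
            frame["sem_ln_pf"] = self.sem_ln_pf
        return frame


@dataclass(frozen=True)
class TheoreticalExchange:
    """Per-residue exchange contributions and their % BB summary."""

    residues: np.ndarray
    contributions: np.ndarray    # each in [0, 1]
    model: str                   # digital_inter, digital_intra, cmb_inter, cmb_intra
    time: float | None = None    # reaction time (s) for the kinetic rule

    @property
    def percent_bb_theory(self) -> float:
        return 100.0 * float(self.contributions.sum()) / self.contributions.size


def protection_factors(trace: StateTrace, clamp: float | None = None) -> PFProfile:
    """Protection factors from a state trace.

    f_open is clamped to ``[clamp, 1 - clamp]`` (default 1/n_frames) so
    that fully open or fully closed residues yield finite PF; clamped
    residues are flagged.
    """
    n = trace.n_frames
    if clamp is None:
        clamp = 1.0 / n
    if not 0 < clamp < 0.5:
        raise ValueError("clamp must lie in (0, 0.5)")
    f_open_raw = trace.f_open
    f_open = np.clip(f_open_raw, clamp, 1.0 - clamp)
    clamped = f_open != f_open_raw
    pf = (1.0 - f_open) / f_open
    return PFProfile(
        residues=trace.residues.copy(),
        f_open=f_open,
        pf=pf,
        ln_pf=np.log(pf),
        model=trace.model,
        n_frames=n,
        clamped=clamped,
    )


def digital_exchange(profile: PFProfile) -> TheoreticalExchange:
    """Binary exchange rule: residue i exchanges iff ln(PF_i) < 0.

    ln(PF) exactly 0 (balanced populations) counts as not exchanged.
    """
    contrib = (profile.ln_pf < 0.0).astype(float)
    return TheoreticalExchange(
        residues=profile.residues.copy(),
        contributions=contrib,
        model=f"digital_{profile.model}",
    )


def cmb_exchange(
    profile: PFProfile, kint: KintProfile | dict[int, float], t: float = 1.0
) -> TheoreticalExchange:
    """Combined kinetic rule: contribution_i = 1 - exp(-k_int,i * t / PF_i).

    ``kint`` must provide a rate for every residue in the profile (a
    :class:`KintProfile` or a residue -> rate mapping). ``t`` is the
    reaction time in seconds; for rank correlations its value is
    arbitrary (it rescales all contributions monotonically).
    """
    if t <= 0:
        raise ValueError("reaction time must be positive")
    rates_by_res = kint.as_dict() if isinstance(kint, KintProfile) else dict(kint)
    missing = [int(r) for r in profile.residues if int(r) not in rates_by_res]
    if missing:
        raise ValueError(f"no intrinsic rate for residues {missing}")
    k = np.array([rates_by_res[int(r)] for r in profile.residues], dtype=float)
    contrib = -np.expm1(-k * t / profile.pf)
    return TheoreticalExchange(
        residues=profile.residues.copy(),
        contributions=contrib,
        model=f"cmb_{profile.model}",
        time=t,
    )


def aggregate_replicates(profiles, method: str = "mean_fo") -> PFProfile:
    """Average replicate PF profiles residue-by-residue.

    ``method="mean_fo"`` (default) averages open fractions before
    recomputing PF; ``method="mean_pf"`` averages ln(PF) directly. SEM
    across replicates is attached for both ln(PF) and f_open.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles")
    first = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.residues, first.residues):
            raise ValueError("replicates cover different residues")
        if p.model != first.model:
            raise ValueError("replicates were classified under different models")
    f_mat = np.vstack([p.f_open for p in profiles])
    ln_mat = np.vstack([p.ln_pf for p in profiles])
    k = len(profiles)
    sem = lambda m: m.std(axis=0, ddof=1) / np.sqrt(k) if k > 1 else np.zeros(m.shape[1])

    if method == "mean_fo":
        f_open = f_mat.mean(axis=0)
        pf = (1.0 - f_open) / f_open
        ln_pf = np.log(pf)
    elif method == "mean_pf":
        ln_pf = ln_mat.mean(axis=0)
        pf = np.exp(ln_pf)
        f_open = 1.0 / (1.0 + pf)
    else:
        raise ValueError(f"unknown aggregation method {method!r}")

    return PFProfile(
        residues=first.residues.copy(),
        f_open=f_open,
        pf=pf,
        ln_pf=ln_pf,
        model=first.model,
        n_frames=first.n_frames,
        clamped=np.any([p.clamped for p in profiles], axis=0),
        sem_ln_pf=sem(ln_mat),
        sem_f_open=sem(f_mat),
    )
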