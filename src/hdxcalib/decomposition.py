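"""Side-chain exchange decomposition and experimental % backbone exchange.

Free-amino-acid standards measured alongside the internal standard
constrain how much each side-chain/terminal site class exchanges under
the reference condition (75% lysine incorporation). Solving the
resulting linear system under nonnegativity gives per-class exchange
propensities; subtracting the implied side-chain uptake from a peptide's
total uptake leaves the backbone amide contribution, expressed as a
percentage of backbone sites (% BB).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .peptides import SiteInventory

__all__ = [
    "PropensityTable",
    "BackboneExchange",
    "fit_propensities",
    "side_contribution",
    "percent_backbone",
]


@dataclass(frozen=True)
class PropensityTable:
    """Fraction of each site class's hydrogens exchanged at reference.

    Values lie in [0, 1]; ``uncertainties`` may be empty when the fit
    cannot support them (boundary-active classes).
    """

    values: dict[str, float]
    uncertainties: dict[str, float] = field(default_factory=dict)
    clipped: tuple[str, ...] = ()

    def __post_init__(self):
        for cls, v in self.values.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"propensity for {cls!r} outside [0, 1]: {v}")


@dataclass(frozen=True)
class BackboneExchange:
    """% backbone exchange after side-chain subtraction."""

    total_uptake: float
    side_contribution: float
    backbone_sites: int
    percent_bb: float
    uncertainty: float
    negative_flag: bool = False


def _design(inventories: list[SiteInventory], classes: list[str]) -> np.ndarray:
    return np.array(
        [[inv.side_chain_counts.get(c, 0) for c in classes] for inv in inventories],
        dtype=float,
    )


def fit_propensities(
    standards,
    uncertainties=None,
    weighted: bool = False,
) -> PropensityTable:
    """Solve per-class exchange propensities from standards by NNLS.

    Parameters
    ----------
    standards:
        Sequence of ``(SiteInventory, observed_uptake_Da)`` pairs, with
        uptake already referenced to the standard condition and expressed
        in exchanged-hydrogen (Da-equivalent) units. Backbone sites of
        the standards are assumed unexchanged on the standards' time
        scale (free amino acids / reference condition).
    uncertainties:
        Optional per-observation standard deviations; with
        ``weighted=True`` rows are scaled by 1/sigma.

    The nonnegative least-squares solution coincides with the analytic
    ordinary least-squares solution whenever the latter is elementwise
    nonnegative (cross-check asserted in the test suite). Rank-deficient
    designs are rejected naming the unresolvable classes. Propensities
    above 1 are clipped and flagged.
    """
    inventories = [s[0] for s in standards]
    y = np.array([s[1] for s in standards], dtype=float)
    classes = sorted({c for inv in inventories for c in inv.side_chain_counts})
    if not classes:
        raise ValueError("no side-chain classes present in standards")
    a = _design(inventories, classes)
    if weighted:
        if uncertainties is None:
            raise ValueError("weighted fit needs uncertainties")
        sig = np.asarray(uncertainties, dtype=float)
        if np.any(sig <= 0):
            raise ValueError("uncertainties must be positive")
        a = a / sig[:, None]
        y = y / sig
    rank = np.linalg.matrix_rank(a)
    if rank < len(classes):
        # name columns involved in the deficiency via near-zero singular directions
        _, s, vt = np.linalg.svd(a)
        tol = max(a.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
        bad = vt[rank:]
        culprits = sorted(
            {classes[j] for row in bad for j in np.nonzero(np.abs(row) > 1e-8)[0]}
        ) or classes
        raise ValueError(f"rank-deficient design; unresolvable classes: {culprits}")

    coef, _ = nnls(a, y)

    # Parameter uncertainties: OLS covariance restricted to the active
    # (interior) support; boundary-active classes get no uncertainty.
    free = coef > 0
    unc: dict[str, float] = {}
    if free.any() and len(standards) > int(free.sum()):
        af = a[:, free]
        resid = y - a @ coef
        dof = len(y) - int(free.sum())
        if dof > 0:
            s2 = float(resid @ resid) / dof
            cov = s2 * np.linalg.pinv(af.T @ af)
            ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
            for cls, se in zip(np.array(classes)[free], ses):
                unc[str(cls)] = float(se)

    clipped = tuple(c for c, v in zip(classes, coef) if v > 1.0)
    if clipped:
        warnings.warn(f"propensities clipped to 1 for classes: {clipped}")
    values = {c: float(min(v, 1.0)) for c, v in zip(classes, coef)}
    return PropensityTable(values=values, uncertainties=unc, clipped=clipped)


def side_contribution(inventory: SiteInventory, table: PropensityTable) -> float:
    """Expected side-chain/terminal uptake (exchanged-hydrogen units).

    Dot product of class counts with class propensities; every class
    present in the inventory must have a table entry.
    """
    total = 0.0
    for cls, count in inventory.side_chain_counts.items():
        if count and cls not in table.values:
            raise KeyError(f"no propensity for site class {cls!r}")
        total += count * table.values.get(cls, 0.0)
    return total


def percent_backbone(
    total_uptake: float,
    side: float,
    n_bb: int,
    total_uncertainty: float = 0.0,
    side_uncertainty: float = 0.0,
) -> BackboneExchange:
    """Experimental % backbone exchange.

    ``100 * (total - side) / n_bb``, with the uncertainty propagated
    from the total (and optionally the side contribution). Negative
    results are flagged, not rejected.
    """
    if n_bb <= 0:
        raise ValueError("n_bb must be positive")
    pct = 100.0 * (total_uptake - side) / n_bb
    unc = 100.0 * float(np.hypot(total_uncertainty, side_uncertainty)) / n_bb
    return BackboneExchange(
        total_uptake=total_uptake,
        side_contribution=side,
        backbone_sites=n_bb,
        percent_bb=pct,
        uncertainty=unc,
        negative_flag=pct < 0,
    )
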