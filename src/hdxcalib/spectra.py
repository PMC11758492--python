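"""Deuterium uptake from isotopic envelopes and internal-standard scaling.

Uptake is the shift in the intensity-weighted centroid mass of a species'
isotopic envelope between spectra acquired before and after D2O exposure.
Because droplet-fusion exposure varies between acquisitions, analyte
uptake is referenced to a co-sprayed internal standard (free lysine):
uptake is regressed against the standard's percent exchange across
acquisitions and evaluated at a fixed standard level (75%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import fit_line
from .peptides import DELTA_MD

__all__ = [
    "PeakList",
    "DeuteriumUptake",
    "ScaledUptake",
    "centroid",
    "centroid_mz",
    "uptake",
    "scale_to_standard",
    "combine_charge_states",
    "read_peaklist",
]

#: Proton mass (Da) for m/z -> neutral-mass conversion.
PROTON_MASS = 1.00728
#: Centroid shifts below this (Da) raise a back-exchange flag.
BACK_EXCHANGE_TOL = -0.05


@dataclass(frozen=True)
class PeakList:
    """Centroided isotopic peaks of one species at one charge state."""

    mz: np.ndarray
    intensity: np.ndarray
    charge: int
    label: str = ""
    replicate_id: str = ""

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.ndim != 1 or mz.shape != inten.shape or mz.size == 0:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("negative intensity")
        if not np.any(inten > 0):
            raise ValueError("all intensities are zero")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())


@dataclass(frozen=True)
class DeuteriumUptake:
    """Centroid mass shift on exposure, as Da and as percent of sites."""

    shift: float
    uncertainty: float
    percent_of_sites: float
    charge: int
    replicate_id: str = ""
    back_exchange_flag: bool = False


@dataclass(frozen=True)
class ScaledUptake:
    """Analyte uptake interpolated to a fixed internal-standard level."""

    value: float
    uncertainty: float
    level: float
    slope: float
    intercept: float


def centroid_mz(peaks: PeakList) -> float:
    """Intensity-weighted mean m/z of the envelope."""
    return float(np.average(peaks.mz, weights=peaks.intensity))


def centroid(peaks: PeakList) -> tuple[float, float]:
    """Neutral centroid mass (Da) and its uncertainty.

    The weighted mean m/z is converted to neutral mass with the charge
    and proton mass. The uncertainty is the weighted standard error of
    the mean over isotopic peaks (effective n from the intensity
    weights), a peak-statistics model that can be replaced upstream.
    """
    w = peaks.intensity / peaks.total_intensity
    mu = float(np.sum(w * peaks.mz))
    var = float(np.sum(w * (peaks.mz - mu) ** 2))
    n_eff = 1.0 / float(np.sum(w**2))
    sem_mz = np.sqrt(var / n_eff)
    z = peaks.charge
    return z * (mu - PROTON_MASS), z * sem_mz


def uptake(before: PeakList, after: PeakList, n_sites: int) -> DeuteriumUptake:
    """Deuterium uptake between paired envelopes.

    ``shift`` is the neutral centroid-mass difference (after - before);
    ``percent_of_sites`` expresses it as a percentage of ``n_sites``
    fully exchanged hydrogens (D-H mass difference per site). A shift
    below -0.05 Da is flagged as apparent back-exchange, not rejected.
    """
    if before.charge != after.charge:
        raise ValueError("before/after charge states differ")
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    m0, u0 = centroid(before)
    m1, u1 = centroid(after)
    shift = m1 - m0
    unc = float(np.hypot(u0, u1))
    pct = 100.0 * shift / (DELTA_MD * n_sites)
    return DeuteriumUptake(
        shift=shift,
        uncertainty=unc,
        percent_of_sites=pct,
        charge=before.charge,
        replicate_id=before.replicate_id or after.replicate_id,
        back_exchange_flag=shift < BACK_EXCHANGE_TOL,
    )


def scale_to_standard(series, level: float = 75.0) -> ScaledUptake:
    """Reference analyte uptake to a fixed internal-standard exchange level.

    ``series`` is a sequence of ``(standard_percent, analyte_uptake_Da)``
    pairs across acquisitions at varying D2O exposure. An unweighted OLS
    line of uptake against standard percent is evaluated at ``level``
    (default 75% lysine incorporation); the prediction uncertainty comes
    from the slope/intercept covariance,
    ``s * sqrt(1/n + (level - xbar)^2 / Sxx)``.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("series must be (standard %, uptake) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if x.size == 2:
        if x[0] == x[1]:
            raise ValueError("degenerate x: zero variance")
        m = (y[1] - y[0]) / (x[1] - x[0])
        b = y[0] - m * x[0]
        return ScaledUptake(m * level + b, 0.0, level, m, b)
    fit = fit_line(x, y)
    pred = fit.predict(x)
    dof = x.size - 2
    s2 = float(np.sum((y - pred) ** 2)) / dof if dof > 0 else 0.0
    sxx = float(np.sum((x - x.mean()) ** 2))
    var_pred = s2 * (1.0 / x.size + (level - x.mean()) ** 2 / sxx)
    return ScaledUptake(
        value=float(fit.predict(level)),
        uncertainty=float(np.sqrt(var_pred)),
        level=level,
        slope=fit.m,
        intercept=fit.b,
    )


def combine_charge_states(values, scheme: str = "intensity", weights=None) -> DeuteriumUptake:
    """Pool uptake measured on several charge states into one value.

    ``scheme="intensity"`` uses the supplied per-charge-state weights
    (e.g. total ion intensity; equal weights when none are given);
    ``scheme="inverse_variance"`` weights by 1/uncertainty^2. The pooled
    uncertainty follows standard propagation of the weighted mean.
    """
    values = list(values)
    if not values:
        raise ValueError("no uptake values to combine")
    shifts = np.array([v.shift for v in values])
    uncs = np.array([v.uncertainty for v in values])
    pcts = np.array([v.percent_of_sites for v in values])
    if scheme == "inverse_variance":
        if np.any(uncs <= 0):
            raise ValueError("inverse-variance weighting requires positive uncertainties")
        w = 1.0 / uncs**2
    elif scheme == "intensity":
        w = np.ones(len(values)) if weights is None else np.asarray(weights, dtype=float)
        if w.shape != shifts.shape or np.any(w < 0) or w.sum() == 0:
            raise ValueError("invalid weights")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    w = w / w.sum()
    pooled = float(np.sum(w * shifts))
    pooled_unc = float(np.sqrt(np.sum((w * uncs) ** 2)))
    return DeuteriumUptake(
        shift=pooled,
        uncertainty=pooled_unc,
        percent_of_sites=float(np.sum(w * pcts)),
        charge=0,
        replicate_id="pooled",
        back_exchange_flag=pooled < BACK_EXCHANGE_TOL,
    )


def read_peaklist(path, charge: int, label: str = "", replicate_id: str = "") -> PeakList:
    """Read an ``mz,intensity`` CSV/TSV peak list (header required)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep)
    cols = {c.lower().strip(): c for c in frame.columns}
    if "mz" not in cols or "intensity" not in cols:
        raise ValueError("peak list needs 'mz' and 'intensity' columns")
    frame = frame.sort_values(cols["mz"])
    return PeakList(
        mz=frame[cols["mz"]].to_numpy(float),
        intensity=frame[cols["intensity"]].to_numpy(float),
        charge=charge,
        label=label,
        replicate_id=replicate_id,
    )
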