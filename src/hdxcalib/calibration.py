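"""Linear calibration of experimental against theoretical backbone exchange.

Ordinary least-squares fits (slope, intercept, parameter standard errors,
R^2, residual sum of squares, average percent error) for the candidate
models relating experimental % backbone exchange to its predictors:
backbone-site count alone, digital open/closed state counts under the
inter- or intramolecular hydrogen-bond treatments, and the combined
kinetic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RegressionFit", "fit_line", "percent_error", "compare_models"]


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares line fit summary (LINEST-style statistics)."""

    m: float
    b: float
    se_m: float
    se_b: float
    r_squared: float
    ss_res: float
    n: int
    model_id: str = ""

    def predict(self, x) -> np.ndarray:
        return self.m * np.asarray(x, dtype=float) + self.b


def fit_line(x, y, model_id: str = "") -> RegressionFit:
    """Fit ``y = m*x + b`` by unweighted ordinary least squares.

    Requires at least 3 points and non-degenerate x. Standard errors are
    derived from the residual variance (n - 2 degrees of freedom).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("degenerate x: zero variance")

    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RegressionFit(
        m=float(res.slope),
        b=float(res.intercept),
        se_m=float(res.stderr),
        se_b=float(res.intercept_stderr),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        ss_res=ss_res,
        n=int(x.size),
        model_id=model_id,
    )


def percent_error(fit: RegressionFit, x, y, invert: bool = False) -> tuple[float, float]:
    """Average absolute percent error of the fitted line, with its SEM.

    Per point: ``100*|fit(x_i) - y_i| / y_i``. Points with ``y_i == 0``
    are excluded with a warning. With ``invert=True`` the roles are
    swapped (error of x against the inverse line), an alternative
    convention kept behind a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if invert:
        if fit.m == 0:
            raise ValueError("cannot invert a zero-slope fit")
        pred = (y - fit.b) / fit.m
        ref = x
    else:
        pred = fit.predict(x)
        ref = y
    keep = ref != 0
    if not keep.all():
        warnings.warn(f"excluded {int((~keep).sum())} point(s) with zero reference value")
    if keep.sum() == 0:
        raise ValueError("no points with nonzero reference value")
    err = 100.0 * np.abs(pred[keep] - ref[keep]) / np.abs(ref[keep])
    sem = float(err.std(ddof=1) / np.sqrt(err.size)) if err.size > 1 else 0.0
    return float(err.mean()), sem


def compare_models(
    experimental: dict[str, float],
    predictors: dict[str, dict[str, float]],
) -> pd.DataFrame:
    """Fit every predictor model against the experimental values.

    Parameters
    ----------
    experimental:
        Mapping peptide id -> experimental % backbone exchange.
    predictors:
        Mapping model id -> (peptide id -> predictor value). Models
        missing any experimental peptide are skipped with a warning.

    Returns
    -------
    DataFrame indexed by model id with columns ``m, b, se_m, se_b,
    r_squared, ss_res, pct_error, pct_error_sem``, sorted best-first by
    R^2 (ties by SS_res).
    """
    peptides = sorted(experimental)
    y = np.array([experimental[p] for p in peptides], dtype=float)
    rows = {}
    for model_id, values in predictors.items():
        missing = [p for p in peptides if p not in values]
        if missing:
            warnings.warn(f"model {model_id!r} skipped: missing peptides {missing}")
            continue
        x = np.array([values[p] for p in peptides], dtype=float)
        fit = fit_line(x, y, model_id=model_id)
        pe, pe_sem = percent_error(fit, x, y)
        rows[model_id] = {
            "m": fit.m,
            "b": fit.b,
            "se_m": fit.se_m,
            "se_b": fit.se_b,
            "r_squared": fit.r_squared,
            "ss_res": fit.ss_res,
            "pct_error": pe,
            "pct_error_sem": pe_sem,
        }
    columns = ["m", "b", "se_m", "se_b", "r_squared", "ss_res",
               "pct_error", "pct_error_sem"]
    frame = pd.DataFrame.from_dict(rows, orient="index")
    if frame.empty:
        return pd.DataFrame(columns=columns)
    return frame.sort_values(["r_squared", "ss_res"], ascending=[False, True])
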