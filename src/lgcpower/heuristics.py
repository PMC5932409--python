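"""Heuristics that turn reliability and stability coefficients into LGCM parameters.

When no prior growth-model estimates exist, two routinely published
psychometric quantities pin down plausible population parameters for design
planning:

* alternate-forms **reliability** at a single occasion,
  rho_rel = var_I / (var_I + var_e), which with an assumed total observed
  variance (e.g. 100 in T-score units) yields var_I and var_e; and
* a **stability coefficient** (test-retest correlation over an interval of
  T years),

      rho_stab = (var_I + T cov_IS) /
                 sqrt[(var_I + var_e) (var_I + var_e + T^2 var_S + 2 T cov_IS)],

  which, solved for var_S (typically assuming cov_IS = 0 as a starting
  point), gives the slope variance consistent with the observed erosion of
  the correlation over time. Stability equal to reliability implies zero
  slope variance — no individual differences in change to detect.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .params import GrowthParams

__all__ = [
    "params_from_reliability",
    "stability_coefficient",
    "slope_var_from_stability",
    "reliability_stability_table",
]

_NEG_TOL = 1e-9


def params_from_reliability(reliability: float, total_variance: float = 100.0
                            ) -> tuple[float, float]:
    """Split a total observed variance into (var_intercept, var_residual).

    Under no change and homogeneous measurement error, reliability is the
    proportion of observed variance that is stable between persons.
    """
    if not 0.0 < reliability <= 1.0:
        raise ValueError("reliability must lie in (0, 1]")
    if total_variance <= 0:
        raise ValueError("total_variance must be positive")
    return reliability * total_variance, (1.0 - reliability) * total_variance


def stability_coefficient(params: GrowthParams, elapsed_time: float) -> float:
    """Model-implied correlation of the outcome with itself T years apart."""
    if elapsed_time < 0:
        raise ValueError("elapsed_time must be non-negative")
    t = elapsed_time
    v0 = params.var_intercept + params.var_residual
    vt = v0 + t**2 * params.var_slope + 2.0 * t * params.cov_intercept_slope
    if v0 <= 0 or vt <= 0:
        raise ValueError("observed variance non-positive at one of the occasions")
    return (params.var_intercept + t * params.cov_intercept_slope) / np.sqrt(v0 * vt)


def slope_var_from_stability(
    var_intercept: float,
    var_residual: float,
    stability: float,
    elapsed_time: float,
    cov_intercept_slope: float = 0.0,
) -> float:
    """Solve the stability-coefficient equation for the slope variance.

    Exact inverse of :func:`stability_coefficient` in var_slope. Raises when
    the implied slope variance is negative, i.e. when the given stability is
    too high for the given reliability: a stability coefficient can only be
    *eroded* (relative to reliability) by true individual differences in
    change, never inflated, so stability > reliability has no valid solution
    (the degenerate diagonal of the reliability x stability grid is exactly
    zero).
    """
    if not 0.0 < stability <= 1.0:
        raise ValueError("stability must lie in (0, 1]")
    if elapsed_time <= 0:
        raise ValueError("elapsed_time must be positive")
    t = elapsed_time
    v0 = var_intercept + var_residual
    if v0 <= 0:
        raise ValueError("var_intercept + var_residual must be positive")
    num = var_intercept + t * cov_intercept_slope
    var_s = (num / stability) ** 2 / v0 - v0 - 2.0 * t * cov_intercept_slope
    var_s /= t**2
    if var_s < -_NEG_TOL * max(1.0, v0):
        raise ValueError(
            f"stability {stability} is too high for the implied reliability: "
            "the solved slope variance is negative (no individual differences "
            "in change can produce this pair)"
        )
    return float(max(var_s, 0.0))


def reliability_stability_table(
    reliabilities: Sequence[float],
    stabilities: Sequence[float],
    elapsed_time: float = 3.0,
    total_variance: float = 100.0,
) -> pd.DataFrame:
    """Grid of slope variances over reliability (rows) x stability (columns).

    Cells where the stability exceeds what the reliability permits (no
    non-negative solution) are reported as NaN. Values decrease along each
    row as stability rises and increase down each column as reliability
    rises.
    """
    table = pd.DataFrame(
        index=pd.Index([float(r) for r in reliabilities], name="reliability"),
        columns=pd.Index([float(s) for s in stabilities], name="stability"),
        dtype=float,
    )
    for r in table.index:
        var_i, var_e = params_from_reliability(r, total_variance)
        for s in table.columns:
            try:
                table.loc[r, s] = slope_var_from_stability(
                    var_i, var_e, s, elapsed_time
                )
            except ValueError:
                table.loc[r, s] = np.nan
    return table
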