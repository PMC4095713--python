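"""Perimeter-versus-area regression and the line-proximity procedure.

Each group's (A, P) cloud is summarised by an ordinary least-squares line
P = slope * A + intercept together with the Pearson correlation of A and P
(the "correlation factor").  Evaluating the three group lines at a common
area a* (default 30 um^2, a region dense with measurements) turns the
stage comparison into one number: the proximity ratio

    |P_II(a*) - P_I(a*)| / |P_III(a*) - P_II(a*)|,

which quantifies how many times closer the early-bell line is to the
late-bell line than to the cap line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["RegressionFit", "fit_linear", "evaluate_line", "line_proximity_ratio"]

DEFAULT_EVAL_AREA = 30.0  # um^2


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of perimeter (um) on area (um^2)."""

    slope: float
    intercept: float
    correlation: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("a regression fit needs at least 3 points")
        if not -1.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")


def fit_linear(areas, perimeters) -> RegressionFit:
    """Least-squares fit of P on A with the Pearson A-P correlation."""
    areas = np.asarray(areas, dtype=float)
    perimeters = np.asarray(perimeters, dtype=float)
    if areas.shape != perimeters.shape or areas.ndim != 1:
        raise ValueError("areas and perimeters must be equal-length vectors")
    if areas.size < 3:
        raise ValueError("a regression fit needs at least 3 points")
    if np.ptp(areas) == 0:
        raise ValueError("undefined fit: zero variance in areas")
    res = sps.linregress(areas, perimeters)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        correlation=float(res.rvalue),
        n=int(areas.size),
    )


def evaluate_line(fit: RegressionFit, area: float) -> float:
    """Predicted perimeter slope * area + intercept."""
    return fit.slope * area + fit.intercept


def line_proximity_ratio(
    fit_i: RegressionFit,
    fit_ii: RegressionFit,
    fit_iii: RegressionFit,
    area: float = DEFAULT_EVAL_AREA,
) -> float:
    """Ratio of line distances |P_II - P_I| / |P_III - P_II| at one area."""
    p1, p2, p3 = (evaluate_line(f, area) for f in (fit_i, fit_ii, fit_iii))
    denom = abs(p3 - p2)
    if denom == 0:
        raise ZeroDivisionError(
            f"lines II and III coincide at A = {area}: proximity ratio undefined"
        )
    return abs(p2 - p1) / denom
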