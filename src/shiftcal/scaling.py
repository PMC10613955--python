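"""Linear scaling of computed shieldings onto experimental shifts.

Computed isotropic shieldings carry a systematic, method-dependent error
that is to good approximation linear in the shift. It is removed by
ordinary least squares of the computed shielding against the
experimental shift,

    sigma_cal = a * delta_exp + b,

followed by inversion to predicted shifts

    delta_cal = (sigma_cal - b) / a.

The regression direction is deliberately shielding-on-shift (the two
directions differ whenever r^2 < 1); fits are made separately per
nucleus and per DFT method combination, since each combination has its
own systematic error. Typical slopes are near -1 (shielding decreases
as shift increases).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .errors import DegenerateRegressionError, UnderdeterminedError
from .study import Nucleus

__all__ = ["ScalingFit", "PredictedShift", "fit_scaling", "apply_scaling", "predict_shifts"]


@dataclass(frozen=True)
class ScalingFit:
    """One fitted scaling line: slope ``a``, intercept ``b`` (ppm), r² and n."""

    nucleus: Nucleus
    a: float
    b: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a scaling fit needs n_points >= 2")
        if self.a == 0:
            raise ValueError("degenerate regression: zero slope")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")


@dataclass(frozen=True)
class PredictedShift:
    group_id: str
    delta_cal: float


def fit_scaling(points: Iterable[tuple[float, float]] | np.ndarray,
                nucleus: Nucleus) -> ScalingFit:
    """Least-squares fit of sigma_cal (response) on delta_exp (predictor).

    Parameters
    ----------
    points : iterable of (delta_exp, sigma_cal)
        Experimental shift and computed shielding pairs, both in ppm.
    nucleus : Nucleus
        Tag recorded on the fit; fits are always per nucleus.

    Returns
    -------
    ScalingFit
        Slope, intercept, squared Pearson correlation of the point set,
        and the number of points.
    """
    arr = np.asarray(list(points) if not isinstance(points, np.ndarray) else points,
                     dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (delta_exp, sigma_cal) pairs")
    if arr.shape[0] < 2:
        raise UnderdeterminedError("underdetermined: need at least 2 points to fit")
    delta, sigma = arr[:, 0], arr[:, 1]
    if np.ptp(delta) == 0:
        raise DegenerateRegressionError(
            "degenerate regression: zero variance in delta_exp")

    res = stats.linregress(delta, sigma)
    if res.slope == 0:
        raise DegenerateRegressionError("degenerate regression: fitted slope is zero")
    # Exactly collinear input can give |r| marginally past 1 in floating point.
    r2 = min(float(res.rvalue) ** 2, 1.0)
    return ScalingFit(nucleus=nucleus, a=float(res.slope), b=float(res.intercept),
                      r_squared=r2, n_points=int(arr.shape[0]))


def apply_scaling(fit: ScalingFit, sigma_cal: float) -> float:
    """Invert the scaling line: delta_cal = (sigma_cal - b) / a."""
    if fit.a == 0:
        raise DegenerateRegressionError("degenerate regression: zero slope")
    return (float(sigma_cal) - fit.b) / fit.a


def predict_shifts(fit: ScalingFit,
                   sigma_by_group: Mapping[str, float]) -> list[PredictedShift]:
    """Apply a fit to a per-group shielding map, preserving group order."""
    out = []
    for gid, sigma in sigma_by_group.items():
        delta = apply_scaling(fit, sigma)
        if not math.isfinite(delta):
            raise ValueError(f"non-finite predicted shift for group {gid!r}")
        out.append(PredictedShift(group_id=gid, delta_cal=delta))
    return out
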