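"""Error statistics for predicted vs experimental chemical shifts.

Per-group absolute deviations |d_delta| = |delta_cal - delta_exp| are
summarized as MAE (mean absolute error), RMSE (root-mean-square error)
and |d_delta_max|, all in ppm, plus percentage-of-range forms
100 * metric / (max - min of the experimental shifts considered) so
that proton and carbon accuracies are comparable on one scale.
Cross-method per-atom averages identify individual nuclei that resist
accurate prediction (flag thresholds default to 1.50 ppm for 13C and
0.100 ppm for 1H).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import AssignmentInconsistencyError, EmptyMetricsError
from .study import MethodKey, Nucleus

__all__ = ["MetricsReport", "PerAtomSummary", "abs_deviations", "summarize",
           "per_atom_summary", "DEFAULT_FLAG_THRESHOLDS"]

#: Per-nucleus default thresholds (ppm) above which a per-atom
#: cross-method average deviation is flagged.
DEFAULT_FLAG_THRESHOLDS = {Nucleus.C13: 1.50, Nucleus.H1: 0.100}


@dataclass(frozen=True)
class MetricsReport:
    """Error statistics of one method combination on one nucleus set.

    ``range_ppm`` is max(delta_exp) - min(delta_exp) over the included
    groups; the ``*_pct`` fields express MAE/RMSE as a percentage of it.
    """

    nucleus: Nucleus
    per_group_abs_dev: Mapping[str, float]
    mae: float
    rmse: float
    max_abs_dev: float
    r_squared: float
    range_ppm: float
    mae_pct: float
    rmse_pct: float
    method: MethodKey | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.mae <= self.rmse + 1e-12
                and self.rmse <= self.max_abs_dev + 1e-12):
            raise ValueError("expected 0 <= MAE <= RMSE <= max |d_delta|")
        if self.range_ppm <= 0:
            raise ValueError("range_ppm must be positive")


@dataclass(frozen=True)
class PerAtomSummary:
    """Cross-method average |d_delta| per group, with over-threshold flags."""

    nucleus: Nucleus
    averages: Mapping[str, float]
    threshold_ppm: float
    flagged: frozenset[str] = field(default_factory=frozenset)


def abs_deviations(predictions: Mapping[str, float],
                   experimental: Mapping[str, float]) -> dict[str, float]:
    """|d_delta| per group: elementwise |delta_cal - delta_exp| in ppm.

    Both maps must cover exactly the same group ids.
    """
    if set(predictions) != set(experimental):
        missing = set(predictions) ^ set(experimental)
        raise AssignmentInconsistencyError(
            f"assignment inconsistency: mismatched group ids {sorted(missing)}")
    return {gid: abs(predictions[gid] - experimental[gid]) for gid in predictions}


def summarize(
    abs_devs: Mapping[str, float],
    experimental: Mapping[str, float],
    r_squared: float,
    nucleus: Nucleus,
    method: MethodKey | None = None,
) -> MetricsReport:
    """Aggregate per-group deviations into MAE / RMSE / max and % forms.

    MAE = mean |d_delta|; RMSE = sqrt(mean |d_delta|^2); percentages are
    100 * metric / range where range = max - min of the experimental
    shifts of the included groups.
    """
    if not abs_devs:
        raise EmptyMetricsError("empty metrics: no deviations supplied")
    if set(abs_devs) - set(experimental):
        raise AssignmentInconsistencyError(
            "assignment inconsistency: deviations reference unknown groups")
    d = np.asarray([abs_devs[g] for g in abs_devs], dtype=float)
    exp = np.asarray([experimental[g] for g in abs_devs], dtype=float)
    rng = float(exp.max() - exp.min())
    if rng <= 0:
        raise ValueError("experimental shifts span zero range")
    mae = float(d.mean())
    rmse = float(np.sqrt(np.mean(d ** 2)))
    return MetricsReport(
        nucleus=nucleus,
        per_group_abs_dev=dict(abs_devs),
        mae=mae,
        rmse=rmse,
        max_abs_dev=float(d.max()),
        r_squared=float(r_squared),
        range_ppm=rng,
        mae_pct=100.0 * mae / rng,
        rmse_pct=100.0 * rmse / rng,
        method=method,
    )


def pct_of_range(value_ppm: float, experimental_shifts: Sequence[float]) -> float:
    """Express an error in ppm as a percentage of the shift range.

    The denominator is max - min of ``experimental_shifts``; e.g. an
    RMSE of 0.84 ppm over shifts spanning 151.81 ppm is 0.55%.
    """
    shifts = np.asarray(experimental_shifts, dtype=float)
    rng = float(shifts.max() - shifts.min())
    if rng <= 0:
        raise ValueError("experimental shifts span zero range")
    return 100.0 * float(value_ppm) / rng


def per_atom_summary(
    reports: Sequence[MetricsReport],
    threshold_ppm: float | None = None,
) -> PerAtomSummary:
    """Average |d_delta| per group across a set of method combinations.

    Groups whose cross-method average exceeds the threshold (strictly)
    are flagged; thresholds default per nucleus to
    :data:`DEFAULT_FLAG_THRESHOLDS`.
    """
    if not reports:
        raise EmptyMetricsError("empty metrics: no reports supplied")
    nucleus = reports[0].nucleus
    gids = set(reports[0].per_group_abs_dev)
    for rep in reports[1:]:
        if set(rep.per_group_abs_dev) != gids or rep.nucleus is not nucleus:
            raise AssignmentInconsistencyError(
                "assignment inconsistency: reports cover different group sets "
                "or nuclei")
    if threshold_ppm is None:
        threshold_ppm = DEFAULT_FLAG_THRESHOLDS[nucleus]
    averages = {
        gid: float(np.mean([rep.per_group_abs_dev[gid] for rep in reports]))
        for gid in sorted(gids)
    }
    flagged = frozenset(g for g, v in averages.items() if v > threshold_ppm)
    if any(not math.isfinite(v) or v < 0 for v in averages.values()):
        raise ValueError("per-atom averages must be finite and nonnegative")
    return PerAtomSummary(nucleus=nucleus, averages=averages,
                          threshold_ppm=float(threshold_ppm), flagged=flagged)
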