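"""Screening of DFT method combinations against one assignment table.

A screen evaluates a grid of functional × basis-set cells, each cell
contributing a per-group computed shielding set for the same compound.
Every cell is independently calibrated (linear scaling fit), converted
to predicted shifts and scored; cells are then ranked by RMSE with a
deterministic tie-break and the best basis set per functional is
marked. Two ingestion modes exist:

* raw-shielding mode (:func:`run_screen`) — the full pipeline per cell;
* printed-metrics mode (:func:`screen_from_metrics`) — ranking of a
  table of already-computed (r², RMSE, ...) statistics, as published
  screening tables are usually all that survives of a benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import AssignmentInconsistencyError, EmptyMetricsError, InvalidSelectionError
from .metrics import MetricsReport, abs_deviations, summarize
from .scaling import apply_scaling, fit_scaling
from .study import EquivalenceGroup, MethodKey, Nucleus

__all__ = ["ScreenResult", "PrintedCell", "run_screen", "screen_from_metrics",
           "best_per_functional", "select_top_k", "format_grid"]


@dataclass(frozen=True)
class PrintedCell:
    """Pre-computed statistics for one grid cell (printed-table ingestion)."""

    r_squared: float
    rmse: float
    max_abs_dev: float = float("inf")
    mae: float = float("nan")


@dataclass(frozen=True)
class ScreenResult:
    """Ranked grid of method combinations for one nucleus.

    ``ranking`` is ascending in RMSE under the tie-break rule; ``cells``
    maps each :class:`MethodKey` to its :class:`MetricsReport` (raw mode)
    or :class:`PrintedCell` (ingestion mode).
    """

    nucleus: Nucleus
    cells: Mapping[MethodKey, MetricsReport | PrintedCell]
    ranking: tuple[MethodKey, ...]
    best_per_functional: Mapping[str, MethodKey]


def _rank_key(cells: Mapping[MethodKey, MetricsReport | PrintedCell]):
    # lower RMSE, then higher r^2, then lower |d_delta_max|, then
    # canonical (functional, basis) order: deterministic and auditable.
    def key(mk: MethodKey):
        c = cells[mk]
        return (c.rmse, -c.r_squared, c.max_abs_dev, mk.functional, mk.basis_set)
    return key


def _build_result(nucleus: Nucleus,
                  cells: Mapping[MethodKey, MetricsReport | PrintedCell]) -> ScreenResult:
    if not cells:
        raise EmptyMetricsError("empty metrics: no grid cells to rank")
    ranking = tuple(sorted(cells, key=_rank_key(cells)))
    best: dict[str, MethodKey] = {}
    for mk in ranking:
        best.setdefault(mk.functional, mk)  # first hit in ranking is best
    return ScreenResult(nucleus=nucleus, cells=dict(cells), ranking=ranking,
                        best_per_functional=best)


def run_screen(
    grid: Mapping[MethodKey, Mapping[str, float]],
    groups: Sequence[EquivalenceGroup],
    nucleus: Nucleus,
) -> ScreenResult:
    """Calibrate, predict and score every cell of a shielding grid.

    Parameters
    ----------
    grid : mapping of MethodKey -> (group_id -> sigma_cal)
        Per-cell group-averaged computed shieldings (already ensemble-
        and equivalence-averaged). Every cell must cover all groups.
    groups : the equivalence groups carrying delta_exp.
    nucleus : which nucleus this screen concerns.
    """
    wanted = {g.group_id for g in groups if g.nucleus is nucleus}
    if not wanted:
        raise EmptyMetricsError("empty metrics: no groups for this nucleus")
    exp = {g.group_id: g.delta_exp for g in groups if g.nucleus is nucleus}

    cells: dict[MethodKey, MetricsReport] = {}
    for mk, sigma in grid.items():
        if set(sigma) != wanted:
            raise AssignmentInconsistencyError(
                f"assignment inconsistency: cell {mk} does not cover the "
                f"group set")
        fit = fit_scaling([(exp[g], sigma[g]) for g in sorted(wanted)], nucleus)
        pred = {g: apply_scaling(fit, sigma[g]) for g in wanted}
        devs = abs_deviations(pred, exp)
        cells[mk] = summarize(devs, exp, fit.r_squared, nucleus, method=mk)
    return _build_result(nucleus, cells)


def screen_from_metrics(
    stats: Mapping[MethodKey, PrintedCell] | pd.DataFrame,
    nucleus: Nucleus,
) -> ScreenResult:
    """Rank a grid from already-computed statistics.

    ``stats`` is either a mapping of :class:`MethodKey` to
    :class:`PrintedCell` or a DataFrame with columns
    ``functional, basis_set, r2, rmse`` (optionally ``maxdev``).
    """
    if isinstance(stats, pd.DataFrame):
        cells = {}
        for _, row in stats.iterrows():
            mk = MethodKey(str(row["functional"]), str(row["basis_set"]))
            cells[mk] = PrintedCell(
                r_squared=float(row["r2"]), rmse=float(row["rmse"]),
                max_abs_dev=float(row["maxdev"]) if "maxdev" in stats.columns
                else float("inf"))
    else:
        cells = dict(stats)
    return _build_result(nucleus, cells)


def best_per_functional(result: ScreenResult) -> dict[str, MethodKey]:
    """Per functional, the basis set minimizing RMSE under the tie-break."""
    return dict(result.best_per_functional)


def select_top_k(result: ScreenResult, k: int) -> list[MethodKey]:
    """The k best-ranked method combinations."""
    if not 0 <= k <= len(result.ranking):
        raise InvalidSelectionError(
            f"invalid selection: k={k} with {len(result.ranking)} cells")
    return list(result.ranking[:k])


def format_grid(result: ScreenResult, statistic: str = "rmse") -> str:
    """Human-readable basis-row × functional-column table; best cells starred."""
    best = set(result.best_per_functional.values())
    rows = []
    for mk, cell in result.cells.items():
        val = getattr(cell, "rmse" if statistic == "rmse" else statistic)
        mark = "*" if mk in best else ""
        rows.append({"basis_set": mk.basis_set, "functional": mk.functional,
                     "value": f"{val:.4g}{mark}"})
    table = (pd.DataFrame(rows)
             .pivot(index="basis_set", columns="functional", values="value"))
    return table.to_string()


def ranking_table(result: ScreenResult) -> pd.DataFrame:
    """Ranked long-form table, one row per cell (for serialization)."""
    rows = []
    for rank, mk in enumerate(result.ranking, start=1):
        c = result.cells[mk]
        rows.append({
            "rank": rank, "functional": mk.functional, "basis_set": mk.basis_set,
            "nucleus": result.nucleus.value, "r2": c.r_squared,
            "mae_ppm": getattr(c, "mae", float("nan")),
            "rmse_ppm": c.rmse, "maxdev_ppm": c.max_abs_dev,
            "best_for_functional": result.best_per_functional[mk.functional] == mk,
        })
    return pd.DataFrame(rows)
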