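"""Functional x basis-set screening: ranking, ties, best-per-functional."""

import numpy as np
import pytest

from shiftcal import (EquivalenceGroup, MethodKey, Nucleus, PrintedCell,
                      best_per_functional, run_screen, screen_from_metrics,
                      select_top_k)
from shiftcal.datasets import OXIME1_C13_SCREEN, OXIME1_H1_SCREEN
from shiftcal.errors import AssignmentInconsistencyError, InvalidSelectionError
from shiftcal.screen import format_grid, ranking_table


def carbon_groups(n=20, lo=15.0, hi=170.0):
    shifts = np.linspace(lo, hi, n)
    return [EquivalenceGroup(group_id=f"C{i:02d}", nucleus=Nucleus.C13,
                             atom_indices=(i + 1,), delta_exp=float(s))
            for i, s in enumerate(shifts)]


def noisy_cell(groups, sd, rng, a=-1.05, b=186.0):
    return {g.group_id: a * g.delta_exp + b + rng.normal(0, sd)
            for g in groups}


class TestRunScreen:
    def test_exact_line_cell_ranks_first_with_zero_rmse(self):
        groups = carbon_groups()
        rng = np.random.default_rng(3)
        grid = {
            MethodKey("exact", "basis"): noisy_cell(groups, 0.0, rng),
            MethodKey("noisy", "basis"): noisy_cell(groups, 1.0, rng),
        }
        result = run_screen(grid, groups, Nucleus.C13)
        assert result.ranking[0] == MethodKey("exact", "basis")
        assert result.cells[result.ranking[0]].rmse == pytest.approx(0.0, abs=1e-9)

    def test_duplicated_cell_gets_adjacent_ranks_by_tiebreak(self):
        groups = carbon_groups()
        rng = np.random.default_rng(4)
        cell = noisy_cell(groups, 0.5, rng)
        grid = {
            MethodKey("zeta", "basis"): dict(cell),
            MethodKey("alpha", "basis"): dict(cell),
            MethodKey("mid", "basis"): noisy_cell(groups, 2.0, rng),
        }
        result = run_screen(grid, groups, Nucleus.C13)
        # identical cells tie; canonical (functional, basis) order breaks it
        assert result.ranking[:2] == (MethodKey("alpha", "basis"),
                                      MethodKey("zeta", "basis"))

    def test_ranking_follows_noise_level(self):
        """Cells with noise sd 0.2 / 0.5 / 1.0 ppm rank in that order,
        agreeing with independently computed per-cell RMSEs."""
        groups = carbon_groups(n=30)
        rng = np.random.default_rng(5)
        sds = {"low": 0.2, "mid": 0.5, "high": 1.0}
        grid = {MethodKey(name, "b"): noisy_cell(groups, sd, rng)
                for name, sd in sds.items()}
        result = run_screen(grid, groups, Nucleus.C13)
        assert [mk.functional for mk in result.ranking] == ["low", "mid", "high"]

        # independent oracle: residual RMSE of each cell after its own OLS
        def oracle_rmse(sigma):
            delta = np.array([g.delta_exp for g in groups])
            y = np.array([sigma[g.group_id] for g in groups])
            A = np.column_stack([delta, np.ones_like(delta)])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            pred = (y - coef[1]) / coef[0]
            return float(np.sqrt(np.mean((pred - delta) ** 2)))

        for mk in result.ranking:
            assert result.cells[mk].rmse == pytest.approx(
                oracle_rmse(grid[mk]), abs=1e-9)

    def test_ranking_invariant_under_insertion_order(self):
        groups = carbon_groups()
        rng = np.random.default_rng(6)
        grid = {MethodKey(f, "b"): noisy_cell(groups, sd, rng)
                for f, sd in [("x", 0.3), ("y", 0.6), ("z", 0.1)]}
        fwd = run_screen(grid, groups, Nucleus.C13)
        rev = run_screen(dict(reversed(list(grid.items()))), groups, Nucleus.C13)
        assert fwd.ranking == rev.ranking

    def test_ragged_grid_rejected(self):
        groups = carbon_groups(n=5)
        rng = np.random.default_rng(7)
        cell = noisy_cell(groups, 0.1, rng)
        short = dict(list(cell.items())[:-1])
        with pytest.raises(AssignmentInconsistencyError):
            run_screen({MethodKey("a", "b"): short}, groups, Nucleus.C13)


class TestPrintedIngestion:
    def test_b3lyp_row_best_basis_is_dgdzvp(self):
        """On the published oxime 13C screen, B3LYP's RMSE-minimizing
        basis set (1.19 ppm) is DGDZVP."""
        cells = {mk: PrintedCell(r_squared=r2, rmse=rmse)
                 for mk, (r2, rmse) in OXIME1_C13_SCREEN.items()
                 if mk.functional == "B3LYP"}
        result = screen_from_metrics(cells, Nucleus.C13)
        assert best_per_functional(result)["B3LYP"] == \
            MethodKey("B3LYP", "DGDZVP")

    def test_single_basis_grid_is_trivially_best(self):
        cells = {MethodKey("f", "only"): PrintedCell(0.99, 1.0)}
        result = screen_from_metrics(cells, Nucleus.C13)
        assert best_per_functional(result) == {"f": MethodKey("f", "only")}

    def test_exact_tie_resolved_canonically_and_deterministically(self):
        cells = {
            MethodKey("f", "zz"): PrintedCell(0.999, 1.0),
            MethodKey("f", "aa"): PrintedCell(0.999, 1.0),
        }
        for permuted in (cells, dict(reversed(list(cells.items())))):
            result = screen_from_metrics(permuted, Nucleus.C13)
            assert best_per_functional(result)["f"] == MethodKey("f", "aa")

    def test_higher_r2_breaks_equal_rmse(self):
        cells = {
            MethodKey("f", "lowr2"): PrintedCell(0.990, 1.0),
            MethodKey("f", "highr2"): PrintedCell(0.999, 1.0),
        }
        result = screen_from_metrics(cells, Nucleus.C13)
        assert result.ranking[0] == MethodKey("f", "highr2")

    def test_best_per_functional_dominates_its_column(self):
        for table, nucleus in [(OXIME1_C13_SCREEN, Nucleus.C13),
                               (OXIME1_H1_SCREEN, Nucleus.H1)]:
            cells = {mk: PrintedCell(r_squared=r2, rmse=rmse)
                     for mk, (r2, rmse) in table.items()}
            result = screen_from_metrics(cells, nucleus)
            for func, best in best_per_functional(result).items():
                best_rmse = result.cells[best].rmse
                same = [c.rmse for mk, c in result.cells.items()
                        if mk.functional == func]
                assert best_rmse <= min(same)


class TestTopK:
    @pytest.fixture()
    def result(self):
        cells = {mk: PrintedCell(r_squared=r2, rmse=rmse)
                 for mk, (r2, rmse) in OXIME1_C13_SCREEN.items()}
        return screen_from_metrics(cells, Nucleus.C13)

    def test_k_equals_cells_returns_whole_ranking(self, result):
        assert tuple(select_top_k(result, len(result.cells))) == result.ranking

    def test_k_one_is_global_minimizer(self, result):
        top = select_top_k(result, 1)[0]
        assert result.cells[top].rmse == min(c.rmse for c in result.cells.values())

    def test_k_beyond_cells_rejected(self, result):
        with pytest.raises(InvalidSelectionError, match="invalid selection"):
            select_top_k(result, len(result.cells) + 1)

    def test_six_lowest_noise_cells_selected_on_synthetic_grid(self):
        """Top-6 on a 13x11-style grid picks exactly the 6 least-noisy cells."""
        groups = carbon_groups(n=30)
        rng = np.random.default_rng(8)
        grid, sds = {}, {}
        for i in range(13):
            for j in range(11):
                mk = MethodKey(f"func{i:02d}", f"basis{j:02d}")
                sd = 0.1 if (i, j) in {(0, 0), (1, 3), (2, 5), (4, 7),
                                       (7, 2), (11, 9)} else rng.uniform(0.8, 2.0)
                sds[mk] = sd
                grid[mk] = noisy_cell(groups, sd, rng)
        result = run_screen(grid, groups, Nucleus.C13)
        expected = {mk for mk, sd in sds.items() if sd == 0.1}
        assert set(select_top_k(result, 6)) == expected

    def test_serialization_helpers(self, result):
        table = ranking_table(result)
        assert list(table["rank"]) == list(range(1, len(result.cells) + 1))
        text = format_grid(result)
        assert "DGDZVP" in text and "B3LYP" in text
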