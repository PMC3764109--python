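"""Stochastic grid analyses: confidence maps, the high-confidence census,
topology summaries and deterministic-stochastic divergence."""

import numpy as np
import pandas as pd
import pytest

from hourglass import (
    ConfidenceMap,
    ParameterGrid,
    census_vs_n0,
    confidence_map,
    det_stoch_divergence,
    deterministic_map,
    high_confidence_census,
    make_grid,
    topology_confidence_summary,
)


@pytest.fixture(scope="module")
def small_grid():
    return make_grid(0.1)


@pytest.fixture(scope="module")
def small_cmap(small_grid):
    return confidence_map(small_grid, n0=1000, reps=30, seed=17)


class TestConfidenceMap:
    def test_confidence_bounds_and_mode_floor(self, small_cmap):
        ok = ~small_cmap.missing
        assert np.all(small_cmap.confidence[ok] > 0)
        assert np.all(small_cmap.confidence[ok] <= 1)
        assert np.all(small_cmap.mode[ok] >= 2)

    def test_reproducible_from_seed(self, small_grid, small_cmap):
        again = confidence_map(small_grid, n0=1000, reps=30, seed=17)
        assert np.array_equal(again.mode, small_cmap.mode)
        assert np.array_equal(again.confidence, small_cmap.confidence)

    def test_high_threshold_point_pinned_to_two(self, small_cmap, small_grid):
        i = small_grid.p_values.index(0.5)
        j = len(small_grid.phi_values) - 1  # phi = 1.0
        assert small_cmap.mode[i, j] == 2
        assert small_cmap.confidence[i, j] == 1.0

    def test_non_terminating_points_recorded_missing(self):
        grid = ParameterGrid(p_values=(0.3,), phi_values=(0.0005, 0.5))
        cmap = confidence_map(grid, n0=1000, reps=5, seed=0)
        assert cmap.missing[0, 0]  # phi * n0 = 0.5 <= 1 molecule
        assert not cmap.missing[0, 1]
        assert (0, 0) in cmap.failures
        assert cmap.mode[0, 0] == -1

    def test_long_format_export(self, small_cmap, tmp_path):
        path = tmp_path / "cmap.csv"
        small_cmap.to_csv(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == [
            "p", "phi", "n0", "reps", "mode", "confidence", "topology", "missing",
        ]
        assert len(frame) == small_cmap.grid.size


class TestCensus:
    def test_census_counts_high_confidence_points(self, small_cmap):
        census, max_nf = high_confidence_census(small_cmap, threshold=0.9)
        ok = ~small_cmap.missing
        expected_total = int(
            ((small_cmap.confidence[ok] > 0.9)).sum()
        )
        assert census.sum() == expected_total
        if expected_total:
            assert max_nf == census.index.max()

    def test_census_non_increasing_in_threshold(self, small_cmap):
        totals = [
            high_confidence_census(small_cmap, threshold=t)[0].sum()
            for t in (0.5, 0.7, 0.9, 0.99)
        ]
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_census_vs_n0_long_format(self, small_grid):
        table = census_vs_n0(small_grid, [100, 1000], reps=20, seed=3)
        assert list(table.columns) == ["n0", "nf", "count"]
        assert set(table["n0"]).issubset({100, 1000})

    def test_census_vs_n0_requires_sorted_list(self, small_grid):
        with pytest.raises(ValueError, match="ascending"):
            census_vs_n0(small_grid, [1000, 100], reps=5, seed=0)


class TestTopologySummary:
    def test_fractions_are_fractions(self, small_cmap):
        summary = topology_confidence_summary(small_cmap)
        assert set(summary.index) == {"linear", "nonlinear"}
        present = summary.dropna()
        assert ((present["frac_above_90"] >= 0) & (present["frac_above_90"] <= 1)).all()
        assert ((present["frac_at_100"] <= present["frac_above_90"] + 1e-12)).all()

    def test_absent_class_reported_undefined_not_zero(self, small_cmap):
        all_nonlinear = ConfidenceMap(
            grid=small_cmap.grid,
            n0=small_cmap.n0,
            reps=small_cmap.reps,
            mode=small_cmap.mode,
            confidence=small_cmap.confidence,
            linear=np.zeros_like(small_cmap.linear),
            missing=small_cmap.missing,
        )
        summary = topology_confidence_summary(all_nonlinear)
        assert np.isnan(summary.loc["linear", "frac_above_90"])
        assert not np.isnan(summary.loc["nonlinear", "frac_above_90"])


class TestDivergence:
    def test_map_against_its_own_modes_is_zero(self, small_grid, small_cmap):
        dmap = deterministic_map(small_grid)
        mirrored = ConfidenceMap(
            grid=small_grid,
            n0=small_cmap.n0,
            reps=small_cmap.reps,
            mode=dmap.nf.copy(),
            confidence=np.ones_like(small_cmap.confidence),
            linear=dmap.linear.copy(),
            missing=np.zeros_like(small_cmap.missing),
        )
        res = det_stoch_divergence(dmap, mirrored)
        assert res.identity_fraction == 1.0
        assert np.nanmax(res.diff) == 0

    def test_grid_mismatch_rejected(self, small_grid, small_cmap):
        other = deterministic_map(make_grid(0.25))
        with pytest.raises(ValueError, match="grid"):
            det_stoch_divergence(other, small_cmap)
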