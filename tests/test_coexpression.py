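"""Per-cell marker-pair co-expression scores, their closed-form random
expectation (checked against a without-replacement Monte-Carlo oracle),
rank-sum comparisons and the spatial-spot utilities."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylmemory.coexpression import (
    MarkerPanel,
    compare_groups,
    detected_genes,
    expected_pair_proportion_mc,
    make_panel,
    pair_score,
    pseudobulk_profile,
    score_dataset,
    spot_purity_filter,
)
from methylmemory.simulate import CellSimConfig, simulate_cell_panel

SET_A = {f"a{i}" for i in range(10)}
SET_B = {f"b{i}" for i in range(10)}


def _cell(x, y, g):
    """Counts with x detected A-markers, y B-markers, g detected total."""
    counts = {}
    for i in range(x):
        counts[f"a{i}"] = 1
    for i in range(y):
        counts[f"b{i}"] = 1
    for i in range(g - x - y):
        counts[f"f{i}"] = 1
    return counts


class TestDetectedGenes:
    @pytest.mark.parametrize(
        "min_count,expected", [(1, ({"a", "c"}, 2)), (2, ({"a"}, 1))]
    )
    def test_thresholding(self, min_count, expected):
        assert detected_genes({"a": 3, "b": 0, "c": 1}, min_count) == expected

    def test_empty_cell(self):
        assert detected_genes({}) == (set(), 0)


class TestPairScore:
    def test_worked_example(self):
        ps = pair_score(_cell(3, 2, 100), SET_A, SET_B, 500)
        assert ps.observed_prop == pytest.approx(6 / 4950)
        assert ps.expected_prop == pytest.approx(100 / 124750)
        assert ps.log2fc == pytest.approx(0.5965, abs=5e-4)

    def test_zero_signal_is_undefined(self):
        ps = pair_score(_cell(0, 5, 50), SET_A, SET_B, 500)
        assert not ps.defined

    def test_swap_symmetry(self):
        a = pair_score(_cell(3, 2, 60), SET_A, SET_B, 500)
        b = pair_score(_cell(3, 2, 60), SET_B, SET_A, 500)
        assert a.log2fc == pytest.approx(b.log2fc)

    def test_too_few_detected_genes_flagged(self):
        ps = pair_score({"a0": 5}, SET_A, SET_B, 500)
        assert ps.g == 1 and not ps.defined

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            pair_score(_cell(1, 1, 10), {"a0"}, {"a0", "b0"}, 500)

    def test_invariant_to_nonmarker_identity_at_fixed_g(self):
        c1 = _cell(2, 3, 80)
        c2 = dict(c1)
        # swap which filler genes are detected; g unchanged
        del c2["f0"]
        c2["zz"] = 7
        s1 = pair_score(c1, SET_A, SET_B, 500)
        s2 = pair_score(c2, SET_A, SET_B, 500)
        assert s1.log2fc == pytest.approx(s2.log2fc)

    def test_continuity_mode_defines_zero_cells(self):
        ps = pair_score(_cell(0, 5, 50), SET_A, SET_B, 500, continuity=0.5)
        assert np.isfinite(ps.log2fc)

    @given(st.integers(2, 60), st.integers(0, 10), st.integers(0, 10))
    @settings(max_examples=40, deadline=None)
    def test_observed_proportion_formula(self, g, x, y):
        g = max(g, x + y, 2)
        ps = pair_score(_cell(x, y, g), SET_A, SET_B, 500)
        assert ps.observed_prop == pytest.approx(x * y / comb(g, 2))


class TestExpectedProportion:
    GRID = [
        (500, 10, 10, 100),
        (500, 10, 10, 10),
        (500, 10, 10, 200),
        (500, 5, 20, 50),
        (200, 8, 8, 40),
        (200, 20, 5, 100),
        (100, 10, 10, 30),
        (100, 4, 4, 10),
        (300, 15, 10, 150),
    ]

    @pytest.mark.parametrize("N,ma,mb,g", GRID)
    def test_closed_form_within_mc_error(self, N, ma, mb, g):
        # independent oracle: raw multivariate-hypergeometric sampling
        rng = np.random.default_rng(abs(hash((N, ma, mb, g))) % 2**31)
        draws = rng.multivariate_hypergeometric([ma, mb, N - ma - mb], g, size=30_000)
        obs = draws[:, 0] * draws[:, 1] / comb(g, 2)
        closed = ma * mb / comb(N, 2)
        se = obs.std(ddof=1) / np.sqrt(len(obs))
        assert abs(obs.mean() - closed) <= 3 * se

    def test_expectation_independent_of_g(self):
        # the closed form has no g; confirm via the package's resampling mode
        vals = [expected_pair_proportion_mc(500, 10, 10, g, 30_000, seed=g) for g in (10, 50, 200)]
        closed = 100 / comb(500, 2)
        for v in vals:
            assert v == pytest.approx(closed, rel=0.15)


class TestScoreDataset:
    def _tiny(self):
        counts = pd.DataFrame(
            [[1, 1, 0, 2], [0, 0, 0, 0]],
            columns=["a0", "b0", "c0", "f0"],
            index=["cell1", "cell2"],
        )
        meta = pd.DataFrame({"cell_id": ["cell1", "cell2"], "sample": ["s1", "s1"]})
        panel = MarkerPanel(
            genes=("a0", "b0", "c0", "f0"),
            marker_sets={"A": ("a0",), "B": ("b0",), "C": ("c0",)},
        )
        return counts, meta, panel

    def test_row_cardinality(self):
        counts, meta, panel = self._tiny()
        df = score_dataset(counts, meta, panel, [("A", "B"), ("A", "C")])
        assert len(df) == 4  # 2 cells x 2 pairs

    def test_all_zero_cell_undefined(self):
        counts, meta, panel = self._tiny()
        df = score_dataset(counts, meta, panel, [("A", "B")])
        assert not df.loc[df["cell_id"] == "cell2", "defined"].any()

    def test_unknown_pair_label_rejected(self):
        counts, meta, panel = self._tiny()
        with pytest.raises(ValueError, match="unknown"):
            score_dataset(counts, meta, panel, [("A", "X")])

    def test_transition_cells_score_higher(self):
        counts, meta, panel, truth = simulate_cell_panel(
            CellSimConfig(transition_fraction=0.15, seed=8)
        )
        df = score_dataset(counts, meta, panel, [("acinar", "duct")])
        trans = df["cell_id"].isin(set(truth.transition_cell_ids))
        defined = df["defined"]
        med_t = df.loc[trans & defined, "log2fc"].median()
        med_o = df.loc[~trans & defined, "log2fc"].median()
        assert med_t > med_o


class TestCompareGroups:
    def _scores(self, groups):
        rows = [(g, v) for g, vals in groups.items() for v in vals]
        return pd.DataFrame(rows, columns=["sample", "log2fc"])

    def test_exact_enumeration_example(self):
        res = compare_groups(self._scores({"a": [1, 2, 3], "b": [4, 5, 6]}))
        assert res["p"][0] == pytest.approx(0.1)  # 2/C(6,3)

    def test_single_observations(self):
        res = compare_groups(self._scores({"a": [1.0], "b": [2.0]}))
        assert res["p"][0] == pytest.approx(1.0)

    def test_identical_groups_all_ties(self):
        res = compare_groups(self._scores({"a": [1.0, 1.0], "b": [1.0, 1.0]}))
        assert res["p"][0] == pytest.approx(1.0)

    def test_group_without_defined_scores_skipped(self):
        df = self._scores({"a": [1, 2, 3], "b": [4, 5, 6]})
        df = pd.concat(
            [df, pd.DataFrame({"sample": ["c"], "log2fc": [np.nan]})], ignore_index=True
        )
        with pytest.warns(UserWarning, match="no defined scores"):
            res = compare_groups(df)
        assert set(res["group_a"]) | set(res["group_b"]) == {"a", "b"}


class TestSpotPurity:
    def _props(self, rows, cols=("acinar", "duct", "other")):
        return pd.DataFrame(rows, columns=list(cols), index=[f"spot{i}" for i in range(len(rows))])

    def test_pure_spot_kept(self):
        props = self._props([[0.95, 0.03, 0.02]] + [[0.30, 0.40, 0.30]] * 9)
        kept = spot_purity_filter(props, "acinar", pct=90)
        assert kept == ["spot0"]

    def test_greater_other_proportion_rejected(self):
        rows = [[0.45, 0.50, 0.05]] + [[0.10, 0.60, 0.30]] * 9
        props = self._props(rows)
        # spot0 is above the acinar 90th percentile but duct is greater
        assert "spot0" not in spot_purity_filter(props, "acinar", pct=90)

    def test_all_identical_spots_all_kept(self):
        props = self._props([[0.50, 0.30, 0.20]] * 5)
        assert len(spot_purity_filter(props, "acinar", pct=90)) == 5

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            spot_purity_filter(self._props([[0.5, 0.1, 0.1]]), "acinar")

    def test_missing_celltype(self):
        with pytest.raises(ValueError, match="islet"):
            spot_purity_filter(self._props([[0.5, 0.3, 0.2]]), "islet")


class TestPseudobulk:
    def test_sum_of_selected_cells(self):
        counts = pd.DataFrame({"G": np.ones(10, dtype=int)})
        assert pseudobulk_profile(counts, n=10, seed=0)["G"] == 10

    def test_all_cells_equals_column_total(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.integers(0, 5, (12, 4)), columns=list("abcd"))
        prof = pseudobulk_profile(counts, n=12, seed=1)
        pd.testing.assert_series_equal(prof, counts.sum(axis=0))

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.integers(0, 5, (30, 3)), columns=list("abc"))
        a = pseudobulk_profile(counts, n=10, seed=7)
        b = pseudobulk_profile(counts, n=10, seed=7)
        pd.testing.assert_series_equal(a, b)

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            pseudobulk_profile(pd.DataFrame({"G": [1, 2]}), n=10)


class TestMarkerPanel:
    def test_shared_genes_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="multiple marker sets"):
            panel = make_panel(["a", "b", "c"], {"A": ("a", "b"), "B": ("b", "c")})
        assert panel.marker_sets == {"A": ("a",), "B": ("c",)}

    def test_overlap_rejected_by_strict_constructor(self):
        with pytest.raises(ValueError):
            MarkerPanel(genes=("a", "b"), marker_sets={"A": ("a",), "B": ("a", "b")})
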