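"""Unit and property tests for the single-cell qPCR pipeline."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from muscletrace.panel import default_panel
from muscletrace.qpcr import (
    CellQualityFilter,
    ExpressionConverter,
    HousekeepingNormalizer,
    SpearmanCorrelogram,
    bulk_relative_expression,
    complete_linkage,
    compute_lod,
    ct_to_expression,
    filter_cells,
    heatmap_order,
    normalize_to_controls,
    primer_efficiency,
    spearman_correlogram,
)

from conftest import fixed_lod, make_ct


# ---------------------------------------------------------------------------
# LOD
# ---------------------------------------------------------------------------

class TestComputeLod:
    def test_rounds_mean_of_per_gene_maxima_up(self):
        ct = make_ct([[20.2, 18.0], [21.4, 19.0]], ["g1", "g2"], ["c1", "c2"])
        lod = compute_lod(ct)
        assert lod.value == 21  # mean(20.2, 21.4) = 20.8 -> ceil
        assert lod.per_gene_max.tolist() == [20.2, 21.4]

    def test_identity_when_all_maxima_integer(self):
        ct = make_ct([[21.0, 20.0], [21.0, 19.0]], ["g1", "g2"], ["c1", "c2"])
        assert compute_lod(ct).value == 21

    def test_failed_wells_excluded_from_maxima(self):
        ct = make_ct([[18.0, 999.0], [19.0, 20.0]], ["g1", "g2"], ["c1", "c2"])
        assert compute_lod(ct).per_gene_max.tolist() == [18.0, 20.0]

    def test_gene_with_only_failed_wells_is_an_error(self):
        ct = make_ct([[999.0, 999.0], [19.0, 20.0]], ["bad", "g2"], ["c1", "c2"])
        with pytest.raises(ValueError, match="bad"):
            compute_lod(ct)
        # but excluding it via gene_subset works
        assert compute_lod(ct, gene_subset=["g2"]).value == 20

    def test_empty_matrix_is_an_error(self):
        ct = make_ct([[18.0]], ["g1"], ["c1"])
        with pytest.raises(ValueError):
            compute_lod(ct, gene_subset=[])


# ---------------------------------------------------------------------------
# Ct -> Log2ex conversion
# ---------------------------------------------------------------------------

class TestCtToExpression:
    @pytest.mark.parametrize(
        "ct_value,expected,detected",
        [(21.0, 0.0, False), (15.0, 6.0, True), (25.0, 0.0, False)],
    )
    def test_log2ex_is_lod_minus_ct_floored_at_zero(self, ct_value, expected, detected):
        ct = make_ct([[ct_value]], ["g"], ["c"])
        expr = ct_to_expression(ct, fixed_lod(21))
        assert expr.values.iat[0, 0] == expected
        assert bool(expr.detected_mask.iat[0, 0]) is detected

    def test_failed_wells_become_zero_and_undetected(self):
        ct = make_ct([[999.0]], ["g"], ["c"])
        expr = ct_to_expression(ct, fixed_lod(21))
        assert expr.values.iat[0, 0] == 0.0
        assert not bool(expr.detected_mask.iat[0, 0])

    @given(
        cts=st.lists(st.floats(1.0, 40.0), min_size=2, max_size=12),
        lod=st.integers(5, 30),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_conversion_monotone_and_bounded(self, cts, lod):
        """Lower Ct never gives lower Log2ex; values bounded by LOD - min(Ct)."""
        ct = make_ct([[v] for v in cts], [f"g{i}" for i in range(len(cts))],
                     ["c"])
        expr = ct_to_expression(ct, fixed_lod(lod))
        vals = expr.values.to_numpy().ravel()
        order = np.argsort(cts)
        assert np.all(np.diff(vals[order]) <= 1e-12)
        assert np.all(vals >= 0)
        assert np.all(vals <= max(0.0, lod - min(cts)) + 1e-12)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _expr_from_values(values, genes, cells, panel=None, lod=21):
    arr = np.asarray(values, dtype=float)
    ct = make_ct(lod - arr, genes, cells, panel=panel)
    # entries equal to 0 in Log2ex come back as Ct == LOD (undetected)
    return ct_to_expression(ct, fixed_lod(lod))


class TestNormalization:
    def test_single_cell_identity(self):
        expr = _expr_from_values(
            [[2.0], [2.0], [2.0], [2.0], [5.0]],
            ["n1", "n2", "n3", "n4", "goi"], ["c1"],
        )
        out = normalize_to_controls(expr, normalizers=["n1", "n2", "n3", "n4"])
        assert out.offset == pytest.approx(2.0)
        assert out.values.loc["goi", "c1"] == pytest.approx(5.0)

    def test_two_cell_offset_arithmetic(self):
        # h1=2, h2=4 -> offset 3; cell1 gene value 6 -> 6 - 2 + 3 = 7
        expr = _expr_from_values(
            [[2.0, 4.0], [2.0, 4.0], [6.0, 5.0]],
            ["n1", "n2", "goi"], ["c1", "c2"],
        )
        out = normalize_to_controls(expr, normalizers=["n1", "n2"])
        assert out.offset == pytest.approx(3.0)
        assert out.values.loc["goi", "c1"] == pytest.approx(7.0)
        assert out.values.loc["goi", "c2"] == pytest.approx(4.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_normalizer_mean_equals_offset_for_every_cell(self, seed):
        rng = np.random.default_rng(seed)
        n_genes, n_cells = 6, 8
        vals = rng.uniform(0, 9, size=(n_genes, n_cells)).round(2)
        genes = [f"g{i}" for i in range(n_genes)]
        expr = _expr_from_values(vals, genes, [f"c{j}" for j in range(n_cells)])
        out = normalize_to_controls(expr, normalizers=genes[:3])
        norm_means = out.values.loc[genes[:3]].mean(axis=0)
        assert np.allclose(norm_means, out.offset, atol=1e-9)

    def test_double_normalization_rejected(self, toy_expression):
        out = normalize_to_controls(toy_expression)
        with pytest.raises(ValueError, match="already normalized"):
            normalize_to_controls(out)

    def test_missing_normalizer_gene_is_an_error(self, toy_expression):
        with pytest.raises(KeyError, match="NotAGene"):
            normalize_to_controls(toy_expression, normalizers=["NotAGene"])

    def test_estimator_records_offset(self, toy_expression):
        est = HousekeepingNormalizer()
        out = est.fit_transform(toy_expression)
        assert est.offset_ == out.offset


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

class TestFilterCells:
    def test_toy_matrix_verdicts_and_reasons(self, toy_expression):
        report = filter_cells(toy_expression)
        assert report.verdicts["c1"] == "retained"
        assert report.verdicts["c2"] == "discarded"
        assert any("controls" in r for r in report.reasons["c2"])
        assert report.verdicts["c3"] == "discarded"
        assert "exclusion_marker_detected" in report.reasons["c3"]
        assert report.n_input == 3 and report.n_retained == 1
        assert all(report.reasons[c] for c in report.reasons)

    def test_exclusion_detected_at_any_level_discards(self, panel):
        genes = list(panel.genes)
        vals = np.full((len(genes), 1), 12.0)
        vals[genes.index("Pax3"), 0] = 20.9  # barely detected
        expr = ct_to_expression(make_ct(vals, genes, ["c"], panel=panel), fixed_lod(21))
        report = filter_cells(expr)
        assert report.verdicts["c"] == "discarded"
        assert "exclusion_marker_detected" in report.reasons["c"]

    def test_min_controls_above_panel_size_is_an_error(self, toy_expression):
        with pytest.raises(ValueError, match="min_controls"):
            filter_cells(toy_expression, min_controls=6)

    def test_filtering_is_idempotent(self, toy_expression):
        first = filter_cells(toy_expression)
        kept = toy_expression.subset_cells(first.retained_cells)
        second = filter_cells(kept)
        assert second.retained_cells == first.retained_cells
        assert second.n_retained == second.n_input

    def test_filter_estimator_transform_drops_cells(self, toy_expression):
        est = CellQualityFilter().fit(toy_expression)
        assert est.report_.n_retained == 1
        assert list(est.transform(toy_expression).cell_ids) == ["c1"]


# ---------------------------------------------------------------------------
# Spearman correlogram
# ---------------------------------------------------------------------------

def brute_force_spearman(x, y):
    """Mid-ranks + Pearson by definition; the independent oracle."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        ranks = np.empty(len(v))
        order = np.argsort(v, kind="mergesort")
        sv = v[order]
        i = 0
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank, 1-based
            i = j
        return ranks

    rx, ry = midranks(x), midranks(y)
    mx, my = rx.mean(), ry.mean()
    num = ((rx - mx) * (ry - my)).sum()
    den = math.sqrt(((rx - mx) ** 2).sum() * ((ry - my) ** 2).sum())
    return num / den


class TestSpearmanCorrelogram:
    def _frame(self, rows, genes, cells):
        return pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=cells)

    def test_monotone_identity_and_reversal(self):
        df = self._frame([[1, 2, 3], [2, 4, 6], [6, 4, 2]], ["a", "b", "c"],
                         ["c1", "c2", "c3"])
        res = spearman_correlogram(df, zero_as_missing=False)
        assert res.rho.loc["a", "b"] == pytest.approx(1.0)
        assert res.rho.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(res.rho), 1.0)

    def test_tied_data_matches_brute_force_midranks(self):
        x, y = [1, 2, 2, 4], [3, 1, 4, 4]
        df = self._frame([x, y], ["x", "y"], list("abcd"))
        res = spearman_correlogram(df, zero_as_missing=False, min_pairs=3)
        assert res.rho.loc["x", "y"] == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_zero_as_missing_uses_pairwise_complete_cells(self):
        # gene b undetected (0) in cell c3: pair (a, b) must use only c1, c2, c4
        df = self._frame(
            [[1.0, 2.0, 3.0, 4.0], [5.0, 3.0, 0.0, 1.0]], ["a", "b"],
            ["c1", "c2", "c3", "c4"],
        )
        res = spearman_correlogram(df, zero_as_missing=True, min_pairs=3)
        assert res.n_pairs.loc["a", "b"] == 3
        expected = brute_force_spearman([1, 2, 4], [5, 3, 1])
        assert res.rho.loc["a", "b"] == pytest.approx(expected, abs=1e-12)

    def test_insufficient_pairs_gives_nan_not_zero(self):
        df = self._frame([[1.0, 2.0, 0.0], [0.0, 3.0, 4.0]], ["a", "b"],
                         ["c1", "c2", "c3"])
        res = spearman_correlogram(df, zero_as_missing=True, min_pairs=3)
        assert np.isnan(res.rho.loc["a", "b"])
        assert res.n_pairs.loc["a", "b"] == 1

    def test_constant_variable_gives_nan(self):
        df = self._frame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]], ["a", "b"],
                         ["c1", "c2", "c3"])
        res = spearman_correlogram(df, zero_as_missing=False)
        assert np.isnan(res.rho.loc["a", "b"])

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.integers(0, 6, size=(5, 12)).astype(float)
        df = self._frame(arr, [f"g{i}" for i in range(5)], [f"c{j}" for j in range(12)])
        res = spearman_correlogram(df, zero_as_missing=True, min_pairs=3)
        for i in range(5):
            for j in range(i + 1, 5):
                both = (arr[i] != 0) & (arr[j] != 0)
                if both.sum() < 3:
                    assert np.isnan(res.rho.iat[i, j])
                    continue
                x, y = arr[i, both], arr[j, both]
                if np.all(x == x[0]) or np.all(y == y[0]):
                    assert np.isnan(res.rho.iat[i, j])
                    continue
                assert res.rho.iat[i, j] == pytest.approx(
                    brute_force_spearman(x, y), abs=1e-12
                )

    def test_pvalue_matches_t_approximation(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=20), rng.normal(size=20)
        df = self._frame([x, y], ["a", "b"], [f"c{j}" for j in range(20)])
        res = spearman_correlogram(df, zero_as_missing=False)
        r = res.rho.loc["a", "b"]
        t = r * math.sqrt((20 - 2) / (1 - r**2))
        assert res.pval.loc["a", "b"] == pytest.approx(2 * stats.t.sf(abs(t), 18), rel=1e-9)

    def test_estimator_exposes_matrices(self, toy_expression):
        est = SpearmanCorrelogram(min_pairs=2).fit(toy_expression)
        assert est.rho_.shape == est.pval_.shape == est.n_pairs_.shape


# ---------------------------------------------------------------------------
# heatmap ordering / complete linkage
# ---------------------------------------------------------------------------

class TestHeatmapOrder:
    def test_identical_rows_merge_first(self):
        df = pd.DataFrame(
            [[1.0, 1.0], [5.0, 9.0], [1.0, 1.0]],
            index=["a", "b", "c"], columns=["x", "y"],
        )
        _, _, row_Z, _ = heatmap_order(df)
        assert row_Z[0, 2] == 0.0  # zero-distance merge happens first
        assert {int(row_Z[0, 0]), int(row_Z[0, 1])} == {0, 2}

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_linkage_heights_match_scipy_complete(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.normal(size=(6, 4))
        Z_ours = complete_linkage(squareform(pdist(mat)))
        Z_scipy = scipy_linkage(mat, method="complete")
        assert np.allclose(np.sort(Z_ours[:, 2]), np.sort(Z_scipy[:, 2]), atol=1e-9)

    def test_tiebreak_prefers_lowest_leaf_indices(self):
        # four equidistant-pair points: (0,1) and (2,3) both at distance 1
        d = np.array([
            [0, 1, 9, 9],
            [1, 0, 9, 9],
            [9, 9, 0, 1],
            [9, 9, 1, 0],
        ], dtype=float)
        Z = complete_linkage(d)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_singleton_axis_is_trivial(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["only"], columns=["a", "b", "c"])
        row_order, col_order, row_Z, col_Z = heatmap_order(df)
        assert row_order == ["only"] and row_Z is None
        assert sorted(col_order) == ["a", "b", "c"] and col_Z is not None

    def test_deterministic_given_input(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(5, 5)))
        assert heatmap_order(df)[:2] == heatmap_order(df.copy())[:2]


# ---------------------------------------------------------------------------
# bulk qPCR helpers
# ---------------------------------------------------------------------------

class TestBulkQpcr:
    @pytest.mark.parametrize(
        "slope,expected",
        [(-1.0 / math.log10(2.0), 2.0), (-1.0, 10.0), (-3.0, 10 ** (1 / 3))],
    )
    def test_primer_efficiency_closed_form(self, slope, expected):
        assert primer_efficiency(slope) == pytest.approx(expected, rel=1e-9)

    def test_zero_slope_is_an_error(self):
        with pytest.raises(ValueError):
            primer_efficiency(0.0)

    def test_negative_slope_gives_efficiency_above_one(self):
        assert primer_efficiency(-3.5) > 1.0

    @pytest.mark.parametrize(
        "target,ref,expected", [(20.0, 20.0, 1.0), (22.0, 25.0, 8.0), (23.5, 20.0, 2**-3.5)]
    )
    def test_bulk_relative_expression(self, target, ref, expected):
        assert bulk_relative_expression(target, ref) == pytest.approx(expected, rel=1e-12)

    def test_failed_well_sentinel_is_an_error(self):
        with pytest.raises(ValueError):
            bulk_relative_expression(999.0, 20.0)


class TestExpressionConverterEstimator:
    def test_fit_computes_lod_and_transform_converts(self):
        ct = make_ct([[20.2, 18.0], [21.4, 19.0]], ["g1", "g2"], ["c1", "c2"])
        est = ExpressionConverter().fit(ct)
        assert est.lod_.value == 21
        expr = est.transform(ct)
        assert expr.values.loc["g1", "c2"] == pytest.approx(3.0)

    def test_fixed_lod_overrides_computed(self):
        ct = make_ct([[20.2, 18.0], [21.4, 19.0]], ["g1", "g2"], ["c1", "c2"])
        est = ExpressionConverter(lod=25).fit(ct)
        assert est.lod_.value == 25
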