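"""Neutrality, ENC-plot, PR2, correspondence analysis and correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cubkit.selection import (
    correlation_suite,
    correspondence_analysis,
    enc_plot,
    neutrality_regression,
    pr2_plot,
    rscu_matrix,
)
from cubkit.sequence_io import CdsSet

from conftest import make_gene


class TestNeutrality:
    def test_identity_line(self):
        x = [0.2, 0.3, 0.4, 0.5]
        fit = neutrality_regression(x, x)
        assert fit.slope == pytest.approx(1.0) and fit.r == pytest.approx(1.0)

    def test_constant_gc12(self):
        fit = neutrality_regression([0.4] * 5, [0.1, 0.2, 0.3, 0.4, 0.5])
        assert fit.slope == pytest.approx(0.0)

    def test_zero_variance_gc3_flagged(self):
        with pytest.warns(UserWarning):
            fit = neutrality_regression([0.1, 0.2, 0.3], [0.4, 0.4, 0.4])
        assert np.isnan(fit.slope)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            neutrality_regression([0.1, 0.2], [0.3, 0.4])


class TestEncPlot:
    def _records(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "GC3s", "ENC", "ENC_expected"])
        df["ENC_ratio"] = (df["ENC_expected"] - df["ENC"]) / df["ENC_expected"]
        return df

    def test_gene_on_curve_has_zero_ratio(self):
        df = self._records([("g1", 0.5, 60.5, 60.5)])
        ep = enc_plot(df)
        assert ep.table["enc_ratio" if "enc_ratio" in ep.table else "ENC_ratio"].iloc[0] == 0

    def test_ratio_arithmetic(self):
        df = self._records([("g1", 0.5, 30.0, 60.5)])
        ep = enc_plot(df)
        assert ep.table["ENC_ratio"].iloc[0] == pytest.approx((60.5 - 30) / 60.5)
        assert ep.table["ENC_ratio"].iloc[0] == pytest.approx(0.50413, abs=1e-5)

    def test_histogram_covers_all_genes_and_band_fraction(self):
        rows = [(f"g{i}", 0.5, e, 60.5) for i, e in
                enumerate([60.5, 58.0, 50.0, 40.0, 75.0])]
        ep = enc_plot(self._records(rows))
        assert ep.bin_counts.sum() == 5
        # ratios: 0, 0.041, 0.174, 0.339, -0.240 -> 2 of 5 in [-0.05, 0.10]
        assert ep.frac_in_band == pytest.approx(2 / 5)
        assert np.allclose(ep.bin_edges * 20, np.round(ep.bin_edges * 20))

    def test_band_fraction_invariant_to_order(self):
        rows = [(f"g{i}", 0.5, e, 60.5) for i, e in enumerate([60.5, 50.0, 40.0])]
        a = enc_plot(self._records(rows))
        b = enc_plot(self._records(rows[::-1]))
        assert a.frac_in_band == b.frac_in_band


class TestPr2:
    def test_parity_point(self):
        gene = make_gene("ATAATTATGATC" * 30)  # thirds: A,T,G,C balanced
        points, quadrants = pr2_plot(CdsSet(species="toy", members=[gene]))
        assert (points[0].x, points[0].y) == (0.5, 0.5)

    def test_hand_arithmetic_bottom_right(self):
        # thirds: A3=10, T3=30, G3=30, C3=10
        seq = "AAA" * 10 + "AAT" * 30 + "AAG" * 30 + "ATC" * 10
        points, quadrants = pr2_plot(CdsSet(species="toy", members=[make_gene(seq)]))
        assert (points[0].x, points[0].y) == (0.75, 0.25)
        assert quadrants["bottom_right"] == 1

    def test_at_swap_reflects_y(self):
        seq_a = "AAA" * 10 + "AAT" * 30 + "AAG" * 20 + "ATC" * 20
        seq_b = "AAT" * 10 + "AAA" * 30 + "AAG" * 20 + "ATC" * 20
        pa, _ = pr2_plot(CdsSet(species="toy", members=[make_gene(seq_a)]))
        pb, _ = pr2_plot(CdsSet(species="toy", members=[make_gene(seq_b)]))
        assert pa[0].y == pytest.approx(1 - pb[0].y)
        assert pa[0].x == pytest.approx(pb[0].x)

    def test_zero_denominator_dropped(self):
        gene = make_gene("AAA" * 100)  # no G3 or C3
        with pytest.warns(UserWarning):
            points, _ = pr2_plot(CdsSet(species="toy", members=[gene]))
        assert points == []


def brute_force_ca_inertias(matrix: np.ndarray) -> np.ndarray:
    """Eigenvalues of the chi-square-residual cross-product (dense solver)."""
    grand = matrix.sum()
    p = matrix / grand
    r, c = p.sum(axis=1), p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    eigvals = np.linalg.eigvalsh(s.T @ s)
    return np.sort(eigvals[eigvals > 1e-12])[::-1]


class TestCorrespondenceAnalysis:
    def test_identical_rows_have_zero_inertia(self):
        m = pd.DataFrame([[1, 2, 3]] * 4, columns=list("abc"))
        res = correspondence_analysis(m)
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)
        assert res.n_axes == 0

    def test_toy_matrix_matches_eigendecomposition_oracle(self):
        m = pd.DataFrame(
            [[10, 2, 3], [1, 8, 2], [2, 1, 12]], columns=list("abc")
        )
        res = correspondence_analysis(m)
        oracle = brute_force_ca_inertias(m.to_numpy(float))
        sv2 = np.sort(res.inertia_pct / 100 * res.total_inertia)[::-1]
        assert np.allclose(sv2, oracle, atol=1e-8)

    def test_total_inertia_is_chi2_over_grand_total(self, rng):
        m = pd.DataFrame(rng.integers(1, 30, size=(5, 4)).astype(float))
        res = correspondence_analysis(m)
        chi2 = stats.chi2_contingency(m.to_numpy(), correction=False)[0]
        assert res.total_inertia == pytest.approx(chi2 / m.to_numpy().sum())

    def test_row_permutation_relabels_coords(self, rng):
        m = pd.DataFrame(
            rng.integers(1, 30, size=(6, 5)).astype(float),
            index=[f"g{i}" for i in range(6)],
        )
        perm = ["g3", "g0", "g5", "g1", "g4", "g2"]
        a = correspondence_analysis(m)
        b = correspondence_analysis(m.loc[perm])
        assert np.allclose(a.inertia_pct, b.inertia_pct)
        # coordinates agree up to per-axis sign
        for axis in a.row_coords.columns:
            col_a = a.row_coords.loc[perm, axis].to_numpy()
            col_b = b.row_coords[axis].to_numpy()
            assert np.allclose(col_a, col_b) or np.allclose(col_a, -col_b)

    def test_inertia_pct_sums_to_100(self, battery):
        cds_set, _ = battery["sel_s2"]
        res = correspondence_analysis(rscu_matrix(cds_set))
        assert res.inertia_pct.sum() == pytest.approx(100.0)
        assert np.all(np.diff(res.inertia_pct) <= 1e-9)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            correspondence_analysis(pd.DataFrame([[1, -1], [1, 1]]))


class TestCorrelationSuite:
    def test_monotone_relationships(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5]})
        df["y"] = df["x"] ** 2
        df["z"] = -df["x"]
        out = correlation_suite(df, [("x", "y"), ("x", "z")])
        assert out.loc[0, "rho"] == pytest.approx(1.0)
        assert out.loc[1, "rho"] == pytest.approx(-1.0)

    def test_missing_values_excluded_pairwise(self):
        df = pd.DataFrame(
            {"x": [1, 2, 3, 4, np.nan, 6], "y": [2, 4, 6, 8, 10, np.nan]}
        )
        out = correlation_suite(df, [("x", "y")])
        assert out.loc[0, "n"] == 4

    def test_constant_variable_flagged(self):
        df = pd.DataFrame({"x": [1, 1, 1, 1], "y": [1, 2, 3, 4]})
        with pytest.warns(UserWarning):
            out = correlation_suite(df, [("x", "y")])
        assert np.isnan(out.loc[0, "rho"])

    def test_pearson_flag(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [1.1, 1.9, 3.2, 3.9]})
        out = correlation_suite(df, [("x", "y")], method="pearson")
        expected = stats.pearsonr(df["x"], df["y"])
        assert out.loc[0, "rho"] == pytest.approx(expected[0])

    def test_too_few_observations(self):
        df = pd.DataFrame({"x": [1, 2, 3], "y": [1, 2, 3]})
        with pytest.raises(ValueError):
            correlation_suite(df, [("x", "y")])
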