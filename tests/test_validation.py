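"""Correlation suites, exact small-n p-values and OLS reductions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from benthirr.synth import GeneratorConfig, gen_measurements
from benthirr.validation import (
    corr_matrix,
    flux_association,
    linear_r2,
    spearman_exact_p,
    variance_explained,
)


class TestCorrMatrix:
    def test_monotone_pair_perfect_correlation(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 4, 8, 16, 32]})
        cm_s = corr_matrix(df, "spearman")
        cm_p = corr_matrix(pd.DataFrame({"x": df.x, "y": 2.0 * df.x}), "pearson")
        assert cm_s.coefficients.loc["x", "y"] == pytest.approx(1.0)
        assert cm_p.coefficients.loc["x", "y"] == pytest.approx(1.0)

    def test_decreasing_pair(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [9, 7, 4, 1]})
        assert corr_matrix(df, "spearman").coefficients.loc["x", "y"] == pytest.approx(-1.0)

    def test_symmetry_and_diagonal(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        cm = corr_matrix(df, "spearman")
        c = cm.coefficients
        assert np.allclose(c.values, c.values.T)
        assert np.allclose(np.diag(c.values), 1.0)
        assert ((cm.pvalues.fillna(0) >= 0) & (cm.pvalues.fillna(0) <= 1)).all().all()

    def test_pairwise_complete_handling(self):
        df = pd.DataFrame({
            "x": [1, 2, 3, 4, np.nan, 6],
            "y": [1, 2, 3, 4, 5, 6],
            "z": [6, 5, 4, 3, 2, np.nan],
        })
        cm = corr_matrix(df, "spearman")
        assert cm.n.loc["x", "y"] == 5
        assert cm.n.loc["x", "z"] == 4
        assert cm.n.loc["y", "z"] == 5

    def test_constant_variable_reported_missing(self):
        df = pd.DataFrame({"x": [1, 1, 1, 1], "y": [1, 2, 3, 4]})
        cm = corr_matrix(df, "spearman")
        assert np.isnan(cm.coefficients.loc["x", "y"])

    def test_spearman_is_pearson_of_ranks_with_ties(self, rng):
        x = rng.integers(0, 5, size=30).astype(float)
        y = rng.integers(0, 5, size=30).astype(float)
        rho = corr_matrix(pd.DataFrame({"x": x, "y": y}), "spearman").coefficients.loc["x", "y"]
        r_ranks = stats.pearsonr(stats.rankdata(x), stats.rankdata(y))[0]
        assert rho == pytest.approx(r_ranks, rel=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.lognormal(size=15)
        y = rng.lognormal(size=15)
        a = corr_matrix(pd.DataFrame({"x": x, "y": y}), "spearman")
        b = corr_matrix(pd.DataFrame({"x": np.log(x), "y": y**2}), "spearman")
        assert a.coefficients.loc["x", "y"] == pytest.approx(
            b.coefficients.loc["x", "y"], rel=1e-12)

    def test_matrix_layout_mixes_coefficients_and_p(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
        cm = corr_matrix(df, "spearman")
        lay = cm.matrix_layout()
        assert lay.loc["x", "y"] == cm.coefficients.loc["x", "y"]
        assert lay.loc["y", "x"] == cm.pvalues.loc["y", "x"]


class TestExactSpearmanP:
    def test_matches_independent_enumeration(self, rng):
        """Exact p equals a from-scratch enumeration over all rank permutations."""
        for n in (4, 5):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            p = spearman_exact_p(x, y)
            # independent oracle: scipy spearman rho on explicitly permuted y
            obs = abs(stats.spearmanr(x, y).statistic)
            count = total = 0
            for perm in itertools.permutations(y):
                rho = stats.spearmanr(x, perm).statistic
                count += abs(rho) >= obs - 1e-12
                total += 1
            assert p == pytest.approx(count / total)

    def test_perfect_monotone_n5_has_p_two_over_120(self):
        # only the identity and the reversal reach |rho| = 1
        p = spearman_exact_p([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert p == pytest.approx(2 / 120)

    def test_rejects_large_n(self, rng):
        with pytest.raises(ValueError):
            spearman_exact_p(rng.normal(size=10), rng.normal(size=10))

    def test_small_n_cells_carry_exact_p(self, rng):
        df = pd.DataFrame(rng.normal(size=(6, 2)), columns=["x", "y"])
        cm = corr_matrix(df, "spearman")
        assert cm.exact_pvalues is not None
        assert 0 <= cm.exact_pvalues.loc["x", "y"] <= 1


class TestLinearR2:
    def test_exact_line(self):
        fit = linear_r2([1, 2, 3, 4], [2, 4, 6, 8])
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_independent_data_near_zero(self):
        rng = np.random.default_rng(123)
        fit = linear_r2(rng.normal(size=1000), rng.normal(size=1000))
        assert fit.r2 < 0.02

    def test_matches_closed_form_on_hand_case(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        fit = linear_r2(x, y)
        # closed form: R² = 1 − SSE/SST for the least-squares line
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        inter = y.mean() - slope * x.mean()
        sse = np.sum((y - (inter + slope * x)) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        assert fit.r2 == pytest.approx(1 - sse / sst, rel=1e-12)
        assert fit.slope == pytest.approx(slope)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError):
            linear_r2([1, 1, 1], [1, 2, 3])


class TestVarianceExplained:
    def test_linear_response_is_100(self):
        assert variance_explained([1, 2, 3, 4], [3, 5, 7, 9]) == pytest.approx(100.0)

    def test_orthogonal_predictor_is_0(self):
        assert variance_explained([-1, 0, 1], [1, 0, 1]) == pytest.approx(0.0, abs=1e-9)

    def test_reduces_to_100_r2(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        assert variance_explained(x, y) == pytest.approx(100 * linear_r2(x, y).r2)


class TestFluxAssociation:
    def test_proportional_analyte_rho_one(self):
        idx = {"S1": 1.0, "S2": 2.0, "S3": 3.0, "S4": 4.0}
        fluxes = pd.DataFrame({
            "station": list(idx), "analyte": ["po4"] * 4,
            "value": [2.0, 4.0, 6.0, 8.0],
        })
        out = flux_association(idx, fluxes)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_station_mean_aggregation_equals_preaveraged(self):
        idx = {"S1": 1.0, "S2": 2.0, "S3": 3.0}
        dup = pd.DataFrame({
            "station": ["S1", "S1", "S2", "S2", "S3", "S3"],
            "analyte": ["si"] * 6,
            "value": [1.0, 3.0, 4.0, 6.0, 9.0, 11.0],
        })
        pre = pd.DataFrame({"station": ["S1", "S2", "S3"], "analyte": ["si"] * 3,
                            "value": [2.0, 5.0, 10.0]})
        a = flux_association(idx, dup, aggregate="mean")
        b = flux_association(idx, pre, aggregate=None)
        assert a.loc[0, "rho"] == pytest.approx(b.loc[0, "rho"])

    def test_under_three_stations_skipped_with_warning(self):
        out = flux_association({"S1": 1.0, "S2": 2.0},
                               pd.DataFrame({"station": ["S1", "S2"],
                                             "analyte": ["nh4"] * 2,
                                             "value": [1.0, 2.0]}))
        assert np.isnan(out.loc[0, "rho"]) and out.loc[0, "warning"]

    def test_generator_link_recovered_significant(self):
        """A declared monotone link at n=12 yields positive, significant rho."""
        cfg = GeneratorConfig(seed=0, measurement_sigma=0.3)
        truth = {f"C{i}": v for i, v in enumerate(np.linspace(20, 600, 12))}
        meas = gen_measurements(cfg, truth)
        irr = {m.core_id: m.value for m in meas if m.quantity == "irrigation_l_m2_d"}
        rho, p = stats.spearmanr(list(truth.values()),
                                 [irr[c] for c in truth])
        assert rho > 0 and p < 0.05
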