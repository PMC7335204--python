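import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from restgraph.stats import (
    ancova_interaction,
    bh_fdr,
    box_cox,
    descriptive_group_compare,
    fisher_exact_2x2,
    needs_transform,
    spearman_assoc,
    welch_t,
)

import oracles


class TestWelch:
    def test_identical_groups(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_raw == pytest.approx(1.0)

    def test_closed_form_example(self):
        res = welch_t([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3.6742, abs=1e-4)
        assert res.df == pytest.approx(4.0)

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 30))
            b = rng.normal(loc=0.5, scale=2.0, size=rng.integers(3, 30))
            res = welch_t(a, b)
            t, p = sps.ttest_ind(a, b, equal_var=False)
            assert res.statistic == pytest.approx(t, abs=1e-12)
            assert res.p_raw == pytest.approx(p, abs=1e-12)

    def test_zero_variance_equal_means(self):
        res = welch_t([2.0, 2.0], [2.0, 2.0])
        assert res.p_raw == 1.0


class TestKruskalAndDescriptives:
    def _manifest(self, hc, ibs, extra=None):
        rows = [{"group": "HC", "score": v} for v in hc]
        rows += [{"group": "IBS", "score": v} for v in ibs]
        frame = pd.DataFrame(rows)
        if extra is not None:
            frame["sex_m"] = extra
        return frame

    def test_identical_groups_accept(self):
        table = descriptive_group_compare(self._manifest([1, 2, 3], [1, 2, 3]))
        assert table.loc["score", "p_raw"] > 0.9

    def test_fully_separated_small_groups_match_rank_oracle(self):
        # ranks (1,2,3) vs (4,5,6): H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2
        table = descriptive_group_compare(self._manifest([1, 2, 3], [10, 11, 12]))
        n, rbar = 6, 3.5
        h = 12.0 / (n * (n + 1)) * (3 * (2 - rbar) ** 2 + 3 * (5 - rbar) ** 2)
        assert table.loc["score", "statistic"] == pytest.approx(h)
        assert table.loc["score", "p_raw"] == pytest.approx(sps.chi2.sf(h, 1))

    def test_constant_variable_warns_p_one(self):
        with pytest.warns(UserWarning, match="constant"):
            table = descriptive_group_compare(self._manifest([5, 5, 5], [5, 5, 5]))
        assert table.loc["score", "p_raw"] == 1.0

    def test_sex_uses_chi_square(self):
        frame = self._manifest([1, 2, 3, 4], [5, 6, 7, 8], extra=[1, 1, 0, 0, 1, 0, 0, 0])
        table = descriptive_group_compare(frame)
        assert table.loc["sex_m", "kind"] == "chi2"


class TestFisher:
    def test_balanced_table_is_null(self):
        assert fisher_exact_2x2(np.array([[5, 5], [5, 5]])) .p_raw == pytest.approx(1.0)

    def test_hub_contrast_table_is_extreme(self):
        # 2/29 versus 17/30 hub subjects
        res = fisher_exact_2x2(np.array([[2, 27], [17, 13]]))
        assert res.p_raw < 1e-4

    def test_zero_margin_gives_p_one(self):
        assert fisher_exact_2x2(np.array([[0, 0], [3, 4]])).p_raw == 1.0

    def test_matches_exact_enumeration_on_random_tables(self, rng):
        for _ in range(50):
            table = rng.integers(0, 10, size=(2, 2))
            res = fisher_exact_2x2(table)
            assert res.p_raw == pytest.approx(oracles.fisher_two_sided(table), abs=1e-9)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(np.array([[0.5, 1], [2, 3]]))


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert spearman_assoc(x, x**3).statistic == pytest.approx(1.0)
        assert spearman_assoc(x, -np.exp(x)).statistic == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 5, size=15).astype(float)  # heavy ties
            y = rng.integers(0, 4, size=15).astype(float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            res = spearman_assoc(x, y)
            assert res.statistic == pytest.approx(oracles.spearman_rho(x, y), abs=1e-12)

    def test_constant_input_reported_undefined(self):
        res = spearman_assoc([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(res.statistic)


class TestBoxCox:
    def test_forced_lambda_one_is_shift(self):
        res = box_cox([1.0, 2.0, 3.0], lam=1.0)
        np.testing.assert_allclose(res.transformed, [0.0, 1.0, 2.0])

    def test_forced_lambda_zero_is_log(self):
        res = box_cox([1.0, np.e, np.e**2], lam=0.0)
        np.testing.assert_allclose(res.transformed, [0.0, 1.0, 2.0], atol=1e-12)

    def test_lognormal_sample_recovers_lambda_near_zero(self, rng):
        x = np.exp(rng.normal(size=500))
        res = box_cox(x)
        assert abs(res.lam) < 0.2

    def test_nonpositive_without_shift_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            box_cox([-1.0, 2.0])
        res = box_cox([-1.0, 2.0], shift="auto")
        assert res.shift == 2.0

    def test_normality_gate(self, rng):
        assert needs_transform(np.exp(rng.normal(size=200)))
        assert not needs_transform(rng.normal(size=200))


class TestAncova:
    def test_matches_statsmodels_type3_on_random_data(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        for _ in range(5):
            n = 40
            frame = pd.DataFrame({
                "y": rng.normal(size=n),
                "g": np.where(rng.random(n) < 0.5, "HC", "IBS"),
                "z": rng.normal(size=n),
            })
            frame["z"] = (frame["z"] - frame["z"].mean()) / frame["z"].std()
            res = ancova_interaction(frame["y"], frame["g"], frame["z"], transform="none")
            fit = smf.ols("y ~ C(g, Sum) * z", data=frame).fit()
            table = anova_lm(fit, typ=3)
            assert res.terms.loc["group", "F"] == pytest.approx(
                table.loc["C(g, Sum)", "F"], rel=1e-6)
            assert res.terms.loc["covariate", "F"] == pytest.approx(
                table.loc["z", "F"], rel=1e-6)
            assert res.terms.loc["group:covariate", "F"] == pytest.approx(
                table.loc["C(g, Sum):z", "F"], rel=1e-6)

    def test_noiseless_null_data_gives_zero_f(self):
        g = np.array(["HC", "HC", "IBS", "IBS"] * 5)
        z = np.tile([-1.0, 1.0], 10)  # orthogonal to the group indicator
        y = np.ones(20)
        res = ancova_interaction(y, g, z, transform="none")
        assert (res.terms["F"] == 0).all()
        assert (res.terms["p_raw"] == 1).all()

    def test_planted_interaction_detected_and_slopes_reported(self, rng):
        n = 200
        g = np.array(["HC"] * n + ["IBS"] * n)
        z = rng.normal(size=2 * n)
        y = np.where(g == "HC", 0.6, 0.0) * z + 0.5 * rng.normal(size=2 * n)
        res = ancova_interaction(y, g, z, transform="none")
        assert res.terms.loc["group:covariate", "p_raw"] < 1e-6
        assert res.slopes.loc["HC", "slope"] == pytest.approx(0.6, abs=0.15)
        assert res.slopes.loc["IBS", "slope"] == pytest.approx(0.0, abs=0.15)
        assert res.slopes.loc["HC", "r"] > 0.5

    def test_singular_design_rejected(self):
        g = np.array(["HC", "HC", "IBS", "IBS"])
        with pytest.raises(ValueError, match="constant"):
            ancova_interaction([1.0, 2.0, 3.0, 4.0], g, [1.0, 1.0, 1.0, 1.0])


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.037]), [0.037])

    def test_stepup_example_all_collapse_to_largest(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_bounds_and_oracle_on_random_inputs(self, rng):
        for _ in range(20):
            p = rng.random(size=rng.integers(1, 40))
            adj = bh_fdr(p)
            assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
            np.testing.assert_allclose(adj, oracles.bh_stepup(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=40))
def test_bh_adjustment_properties_for_any_p_vector(p):
    """Property: BH-adjusted values are bounded by [p, 1] and preserve the
    order of the raw p-values."""
    p = np.asarray(p)
    adj = bh_fdr(p)
    assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0 + 1e-15)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)
    np.testing.assert_allclose(adj, oracles.bh_stepup(p), atol=1e-12)
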