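"""Rank tests and the zero-inflated Poisson count model."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from troopcall.stats import (
    CollinearDesignError,
    StatsError,
    VocalCountModel,
    fit_zip,
    mann_whitney,
    spearman,
)

from conftest import simulated_model_frame


def enumerate_mw_pvalue(x, y):
    """Independent oracle: two-sided exact p by full enumeration of all
    C(n1+n2, n1) group assignments of the pooled sample."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    n = len(pooled)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    observed = u_of(range(n1))
    us = [u_of(c) for c in itertools.combinations(range(n), n1)]
    total = len(us)
    p_le = sum(u <= observed for u in us) / total
    p_ge = sum(u >= observed for u in us) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestMannWhitney:
    def test_fully_separated_small_sample(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.u == 0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_samples_are_null(self):
        x = [1.5, 2.5, 3.5, 4.5]
        res = mann_whitney(x, x, mode="approx")
        assert res.u == len(x) ** 2 / 2
        assert res.p_value == 1.0

    def test_w_is_rank_sum_of_first_sample(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.w == 3.0  # ranks 1 + 2

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (5, 6), (6, 6)])
    def test_exact_mode_matches_full_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        x = rng.standard_normal(n1)
        y = rng.standard_normal(n2) + 0.5
        res = mann_whitney(x, y, mode="exact")
        assert res.p_value == pytest.approx(enumerate_mw_pvalue(x, y), abs=1e-12)

    def test_large_shift_is_highly_significant(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(40)
        y = rng.standard_normal(40) + 3.0
        assert mann_whitney(x, y).p_value < 0.001

    def test_ties_route_to_corrected_approximation(self):
        scipy_stats = pytest.importorskip("scipy.stats")
        rng = np.random.default_rng(5)
        x = rng.integers(0, 4, size=25).astype(float)
        y = rng.integers(1, 5, size=30).astype(float)
        res = mann_whitney(x, y)
        assert res.method == "normal_approx"
        assert res.tie_correction_applied
        ref = scipy_stats.mannwhitneyu(x, y, method="asymptotic", use_continuity=True)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_mode_rejects_ties(self):
        with pytest.raises(StatsError):
            mann_whitney([1, 1], [1, 2], mode="exact")

    def test_empty_sample_rejected(self):
        with pytest.raises(StatsError):
            mann_whitney([], [1.0])

    @given(st.integers(2, 6), st.integers(2, 6), st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40)
    def test_exact_p_matches_enumeration_property(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(np.arange(n1 + n2, dtype=float))[:n1]
        y = np.setdiff1d(np.arange(n1 + n2, dtype=float), x)
        res = mann_whitney(x, y, mode="exact")
        assert res.p_value == pytest.approx(enumerate_mw_pvalue(x, y), abs=1e-12)


class TestSpearman:
    def test_monotone_identity(self):
        res = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.rho == 1.0 and res.p_value == 0.0

    def test_reversal(self):
        res = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.rho == -1.0

    def test_matches_direct_midrank_formula(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(27)
        y = 0.5 * x + rng.standard_normal(27)
        res = spearman(x, y)
        # independent oracle: explicit midrank Pearson formula
        rx = np.argsort(np.argsort(x)) + 1.0
        ry = np.argsort(np.argsort(y)) + 1.0
        expected = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_with_ties(self):
        scipy_stats = pytest.importorskip("scipy.stats")
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(0, 5, 30).astype(float)
        res = spearman(x, y)
        ref = scipy_stats.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_sample_is_degenerate(self):
        res = spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(res.rho)


class TestCountModel:
    def test_poisson_family_matches_glm_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(0)
        n = 400
        x = rng.standard_normal((n, 2))
        exposure = rng.uniform(0.5, 2.0, n)
        lam = np.exp(0.3 + 0.5 * x[:, 0] - 0.4 * x[:, 1]) * exposure
        y = rng.poisson(lam)
        res = fit_zip(y, x, exposure=exposure, family="poisson")
        ref = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson(), exposure=exposure).fit()
        assert np.allclose(res.params, ref.params, atol=1e-6)
        assert np.allclose(res.bse, ref.bse, atol=1e-5)

    def test_zip_matches_statsmodels_oracle(self):
        zip_mod = pytest.importorskip("statsmodels.discrete.count_model")
        rng = np.random.default_rng(1)
        n = 600
        x = rng.standard_normal((n, 2))
        lam = np.exp(0.2 + 0.6 * x[:, 0] - 0.3 * x[:, 1])
        y = np.where(rng.random(n) < 0.3, 0, rng.poisson(lam))
        res = fit_zip(y, x, family="zip")
        import numpy as _np

        ref = zip_mod.ZeroInflatedPoisson(
            y, _np.column_stack([_np.ones(n), x]), exog_infl=_np.ones((n, 1))
        ).fit(disp=0, maxiter=500)
        # statsmodels orders [inflate, count...]; ours is [count..., inflate]
        assert np.allclose(res.params[:3], ref.params[1:], atol=1e-4)
        assert res.params[-1] == pytest.approx(ref.params[0], abs=1e-4)
        assert res.llf == pytest.approx(ref.llf, abs=1e-6)

    def test_parameter_recovery_within_three_se(self):
        obs, truth = simulated_model_frame(seed=11, n_events=500)
        model = VocalCountModel.from_dataframe(
            obs, predictors=["female", "centrality", "rank", "relatives", "order_index"]
        )
        res = model.fit()
        assert res.converged
        for name in ("female", "centrality", "order_index"):
            assert abs(res.coef(name) - truth[name]) < 3 * res.se(name)
        assert res.zero_inflation == pytest.approx(truth["zero_inflation"], abs=0.1)

    def test_loglike_path_monotone_and_gradient_tiny(self):
        obs, _ = simulated_model_frame(seed=4)
        model = VocalCountModel.from_dataframe(
            obs, predictors=["female", "centrality", "order_index"]
        )
        res = model.fit()
        path = np.array(res.loglike_path)
        assert np.all(np.diff(path) >= -1e-8)
        assert np.max(np.abs(res.gradient)) < 1e-6

    def test_all_zero_counts_flag_boundary(self):
        x = np.linspace(-1, 1, 50).reshape(-1, 1)
        with pytest.warns(RuntimeWarning, match="boundary"):
            res = fit_zip(np.zeros(50, dtype=int), x, family="zip")
        assert res.inflation_boundary
        assert not res.converged

    def test_collinear_design_names_columns(self):
        x = np.ones((30, 2))
        x[:, 1] = 2 * x[:, 0]
        y = np.zeros(30, dtype=int)
        y[0] = 1
        with pytest.raises(CollinearDesignError, match="x"):
            fit_zip(y, x, family="poisson")

    def test_nonpositive_exposure_rejected(self):
        with pytest.raises(StatsError, match="exposure"):
            fit_zip([1, 2], [[1.0], [2.0]], exposure=[1.0, 0.0])

    def test_missing_values_rejected(self):
        with pytest.raises(StatsError):
            fit_zip([1, 2], [[1.0], [np.nan]])

    def test_summary_table_shape(self):
        obs, _ = simulated_model_frame(seed=6)
        res = VocalCountModel.from_dataframe(
            obs, predictors=["female", "centrality", "rank", "relatives", "order_index"]
        ).fit()
        table = res.summary()
        assert list(table.columns) == ["factor", "estimate", "se", "z", "p"]
        assert set(["female", "centrality", "rank", "relatives"]).issubset(table.factor.tolist())
        z = table.set_index("factor")
        assert np.allclose(z["z"], z["estimate"] / z["se"], equal_nan=True)
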