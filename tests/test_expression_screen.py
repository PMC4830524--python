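"""Normalisation, the log-intensity-variation filter, and the per-gene
association screens (univariate Cox, Spearman)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pdhs.screen import (
    DegenerateCovariateError,
    InsufficientEventsError,
    ScreenConfig,
    cox_univariate,
    log_intensity_variation_filter,
    normalize_to_median_array,
    screen_genes,
    spearman_test,
)
from conftest import make_expr, make_pheno


class TestNormalization:
    def test_equal_median_matrix_unchanged(self, rng):
        v = rng.normal(size=(20, 5))
        v -= np.median(v, axis=0, keepdims=True)  # all per-sample medians 0
        expr = make_expr(v)
        out = normalize_to_median_array(expr)
        np.testing.assert_allclose(out.data.to_numpy(), v, atol=1e-12)

    def test_additive_shift_removed(self, rng):
        v = rng.normal(size=(31, 5))
        shifted = v.copy()
        shifted[:, 2] += 2.0
        out = normalize_to_median_array(make_expr(shifted))
        ref = normalize_to_median_array(make_expr(v))
        np.testing.assert_allclose(out.data.to_numpy(), ref.data.to_numpy(), atol=1e-12)

    def test_all_medians_equal_after(self, rng):
        out = normalize_to_median_array(make_expr(rng.normal(size=(50, 20))))
        med = out.data.median(axis=0).to_numpy()
        np.testing.assert_allclose(med, med[0], atol=1e-12)

    def test_idempotent(self, rng):
        expr = make_expr(rng.normal(size=(15, 7)))
        once = normalize_to_median_array(expr)
        twice = normalize_to_median_array(once)
        np.testing.assert_allclose(once.data.to_numpy(), twice.data.to_numpy(), atol=1e-12)


class TestVarianceFilter:
    def test_constant_gene_excluded_with_p_one(self, rng):
        v = rng.normal(size=(9, 30))
        v[0] = 5.0
        kept, p = log_intensity_variation_filter(make_expr(v))
        assert p.iloc[0] == 1.0 and "g0" not in kept

    def test_statistic_matches_chi2_survival(self, rng):
        """A gene whose variance equals the median variance has
        T = n - 1 and p = P(chi2_{n-1} >= n-1)."""
        n = 30
        v = rng.normal(size=(11, n))
        # force gene 0's sample variance to the median of all gene variances
        variances = v.var(axis=1, ddof=1)
        med = np.median(variances)
        v[0] = (v[0] - v[0].mean()) / v[0].std(ddof=1) * math.sqrt(med)
        kept, p = log_intensity_variation_filter(make_expr(v))
        # medians of an odd count are attained, so gene 0 now sits at the median
        expected = stats.chi2.sf(n - 1, df=n - 1)
        assert p.iloc[0] == pytest.approx(expected, rel=1e-6)
        assert "g0" not in kept  # p ~= 0.47 at n=30

    def test_all_constant_is_error(self):
        with pytest.raises(ValueError):
            log_intensity_variation_filter(make_expr(np.ones((4, 5))))


class TestCox:
    def grid_oracle(self, x, times, events, lo=-5, hi=5, step=1e-4):
        """Grid search maximiser of the Breslow partial likelihood."""
        x = np.asarray(x, float)
        t = np.asarray(times, float)
        e = np.asarray(events, int)
        order = np.argsort(t)
        x, t, e = x[order], t[order], e[order]
        grid = np.arange(lo, hi + step, step)
        best, best_ll = None, -np.inf
        for b in grid:
            theta = np.exp(b * x)
            ll = 0.0
            for i in range(len(t)):
                if e[i]:
                    ll += b * x[i] - math.log(theta[t >= t[i]].sum())
            if ll > best_ll:
                best, best_ll = b, ll
        return best

    @pytest.mark.parametrize(
        "x,events",
        [
            ([1, 0, 1, 0, 0, 1], [1, 1, 1, 1, 1, 1]),
            ([2.0, 1.0, 0.5, 1.5, 0.0, 1.0], [1, 0, 1, 1, 1, 0]),
            ([0, 1, 0, 1, 1, 0], [1, 1, 0, 1, 1, 1]),
        ],
    )
    def test_matches_grid_search(self, x, events):
        times = [1, 2, 3, 4, 5, 6]
        a = cox_univariate(x, times, events, tie_method="breslow")
        b_grid = self.grid_oracle(x, times, events)
        assert a.beta == pytest.approx(b_grid, abs=1e-4)

    def test_separated_case_capped_with_hr_above_one(self):
        # high expression in all early events: the partial likelihood is
        # monotone and the estimate runs to the cap
        a = cox_univariate([1, 1, 1, 0, 0, 0], [1, 2, 3, 4, 5, 6], [1] * 6)
        assert a.hr > 1 and a.monotone_likelihood

    def test_matches_lifelines(self, rng):
        """Efron fit agrees with an independent implementation."""
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(0.7 * x))
        # duplicate some times to exercise the tie correction
        t = np.round(t, 1) + 0.1
        e = (rng.random(n) < 0.8).astype(int)
        if e.sum() < 2:
            e[:2] = 1
        a = cox_univariate(x, t, e, tie_method="efron")
        cph = lifelines.CoxPHFitter()
        cph.fit(
            pd.DataFrame({"T": t, "E": e, "x": x}), duration_col="T", event_col="E"
        )
        # lifelines stops at its own looser default precision; the in-package
        # Newton solution has gradient ~1e-15 at convergence
        assert a.beta == pytest.approx(float(cph.params_["x"]), abs=1e-4)
        assert a.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-4)

    def test_sign_convention(self):
        # larger covariate, earlier event times => beta > 0
        times = [1, 2, 3, 10, 11, 12]
        x = [3.0, 2.5, 2.0, 1.0, 0.5, 0.0]
        a = cox_univariate(x, times, [1] * 6)
        assert a.beta > 0 and a.hr > 1

    def test_null_p_uniform(self):
        """Wald p-values approximately uniform under a permutation null."""
        rng = np.random.default_rng(42)
        n = 100
        t = rng.exponential(1.0, n)
        e = (rng.random(n) < 0.7).astype(int)
        x = rng.normal(size=n)
        ps = []
        for _ in range(400):
            ps.append(cox_univariate(rng.permutation(x), t, e).p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateCovariateError):
            cox_univariate([1.0] * 5, [1, 2, 3, 4, 5], [1] * 5)
        with pytest.raises(InsufficientEventsError):
            cox_univariate([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], [1, 0, 0, 0, 0])

    def test_monotone_likelihood_flagged(self):
        # perfect separation: all early events in the high-x group
        times = [1, 2, 3, 10, 11, 12]
        events = [1, 1, 1, 0, 0, 0]
        x = [1, 1, 1, 0, 0, 0]
        a = cox_univariate(x, times, events)
        assert a.monotone_likelihood


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        up = spearman_test(x, x**3 + 1)
        down = spearman_test(x, -x - 2)
        assert up.rho == pytest.approx(1.0)
        assert down.rho == pytest.approx(-1.0)

    def test_midrank_ties_match_oracle(self):
        x = np.array([1, 2, 2, 3], float)
        y = np.array([10, 20, 20, 40], float)
        a = spearman_test(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        assert a.rho == pytest.approx(float(np.corrcoef(rx, ry)[0, 1]), abs=1e-12)

    def test_exact_permutation_matches_scipy_small_n(self):
        rng = np.random.default_rng(5)
        x = rng.permutation(7).astype(float)
        y = rng.normal(size=7)
        a = spearman_test(x, y)
        ref = stats.spearmanr(x, y)
        assert a.rho == pytest.approx(ref.statistic, abs=1e-12)

    def test_t_approximation_matches_scipy(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40) + 0.4 * x
        a = spearman_test(x, y)
        ref = stats.spearmanr(x, y)
        assert a.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert a.p == pytest.approx(ref.pvalue, rel=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.sampled_from(["exp", "cube", "affine"]),
    )
    def test_invariant_under_monotone_transforms(self, seed, kind):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        f = {"exp": np.exp, "cube": lambda v: v**3, "affine": lambda v: 3 * v + 1}[kind]
        base = spearman_test(x, y)
        trans = spearman_test(f(x), y)
        assert trans.rho == pytest.approx(base.rho, abs=1e-12)
        assert trans.p == pytest.approx(base.p, abs=1e-12)

    def test_degenerate(self):
        with pytest.raises(DegenerateCovariateError):
            spearman_test([1, 2, 3, 4], [5, 5, 5, 5])


class TestScreenGenes:
    def test_alpha_strictly_honored(self, rng):
        """A gene with p just above alpha is excluded at that alpha."""
        n = 60
        v = rng.normal(size=(30, n))
        t = rng.exponential(1.0, n)
        e = np.ones(n, dtype=int)
        expr = make_expr(v)
        pheno = make_pheno(t, e)
        res = screen_genes(expr, pheno, expr.gene_ids, "dmfs")
        for a in res.passing:
            assert a.p < res.alpha
        all_p = dict(zip(res.all_p["gene_id"], res.all_p["p"]))
        excluded = set(all_p) - set(res.gene_ids())
        assert all(all_p[g] >= res.alpha for g in excluded)

    def test_planted_gene_detected(self, rng):
        n = 150
        v = rng.normal(size=(20, n))
        L = 1.0 * v[0]
        t = rng.exponential(1 / (0.1 * np.exp(L)))
        e = np.ones(n, dtype=int)
        res = screen_genes(make_expr(v), make_pheno(t, e), [f"g{i}" for i in range(20)], "dmfs")
        assert "g0" in res.gene_ids()

    def test_metcount_endpoint(self, rng):
        n = 100
        v = rng.normal(size=(10, n))
        counts = rng.poisson(np.exp(1.5 + 0.8 * v[0]))
        res = screen_genes(
            make_expr(v), make_pheno(np.ones(n), np.ones(n, int), counts),
            [f"g{i}" for i in range(10)], "met_count",
        )
        assert "g0" in res.gene_ids()
        assert all(a.rho is not None for a in res.passing)

    def test_empty_candidates_error(self, rng):
        expr = make_expr(rng.normal(size=(3, 5)))
        pheno = make_pheno(np.ones(5), np.ones(5, int))
        with pytest.raises(ValueError):
            screen_genes(expr, pheno, [], "dmfs")

    def test_sorted_by_p(self, rng):
        n = 80
        v = rng.normal(size=(25, n))
        t = rng.exponential(1.0, n)
        res = screen_genes(
            make_expr(v), make_pheno(t, np.ones(n, int)), [f"g{i}" for i in range(25)],
            "dmfs", ScreenConfig(association_alpha=0.9),
        )
        ps = [a.p for a in res.passing]
        assert ps == sorted(ps)


def test_collapse_probes_keeps_max_variance_row(rng):
    import pandas as pd
    from pdhs.screen import collapse_probes_max_variance

    df = pd.DataFrame(
        [[1.0, 1.1, 0.9, 1.0], [0.0, 5.0, -5.0, 2.0], [3.0, 3.0, 3.1, 2.9]],
        index=["gA", "gA", "gB"],
        columns=list("wxyz"),
    )
    out = collapse_probes_max_variance(df)
    assert list(out.data.index) == ["gA", "gB"]
    assert out.data.loc["gA", "x"] == 5.0  # the high-variance probe won
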