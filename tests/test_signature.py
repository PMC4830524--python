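"""Weighted signatures: construction, scoring, stratification, Kaplan-Meier,
log-rank, end-to-end evaluation and discovery/test reweighting."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from pdhs.screen import GeneAssociation
from pdhs.signature import (
    WeightedSignature,
    build_foldchange_signature,
    build_weighted_signature,
    evaluate_signature,
    km_estimate,
    logrank_test,
    score_samples,
    split_and_reweight,
    stratify_samples,
)
from conftest import make_expr, make_pheno


def dmfs_assoc(gene, hr, p=0.01):
    return GeneAssociation(
        gene_id=gene, endpoint="dmfs", beta=math.log(hr), hr=hr, p=p, n=100
    )


def rho_assoc(gene, rho, p=0.01):
    return GeneAssociation(gene_id=gene, endpoint="met_count", rho=rho, p=p, n=100)


class TestBuildSignature:
    def test_log2_hazard_ratio_weights(self):
        sig = build_weighted_signature([dmfs_assoc("a", 2.0), dmfs_assoc("b", 0.5)], "dmfs")
        assert sig.entries == pytest.approx({"a": 1.0, "b": -1.0})

    def test_unit_hazard_ratio_retained_with_zero_weight(self):
        sig = build_weighted_signature([dmfs_assoc("a", 1.0)], "dmfs")
        assert sig.entries["a"] == 0.0

    def test_correlation_weights(self):
        sig = build_weighted_signature([rho_assoc("a", 0.3)], "correlation")
        assert sig.entries["a"] == pytest.approx(0.3)

    def test_mixed_endpoint_is_error(self):
        with pytest.raises(ValueError):
            build_weighted_signature([dmfs_assoc("a", 2.0), rho_assoc("b", 0.1)], "dmfs")

    def test_foldchange_filter_and_weights(self):
        sig = build_foldchange_signature({"a": 12.0, "b": -15.0, "c": 5.0})
        assert sig.entries == {"a": 12.0, "b": -15.0}
        with pytest.raises(ValueError):
            build_foldchange_signature({"a": 2.0, "b": -3.0})
        allg = build_foldchange_signature({"a": 2.0, "b": -3.0}, min_fold=0)
        assert set(allg.entries) == {"a", "b"}

    def test_signature_tsv_round_trip(self, tmp_path):
        sig = WeightedSignature("dmfs", {"a": 1.25, "b": -0.5})
        p = tmp_path / "sig.tsv"
        sig.to_tsv(p)
        back = WeightedSignature.from_tsv(p)
        assert back.mode == sig.mode and back.entries == pytest.approx(sig.entries)


class TestScoring:
    def test_zero_weights_zero_scores(self, rng):
        expr = make_expr(rng.normal(size=(3, 8)))
        sc = score_samples(WeightedSignature("dmfs", {"g0": 0.0, "g1": 0.0}), expr)
        assert all(v == 0 for v in sc.scores.values())

    def test_single_gene_score_is_zscore(self, rng):
        expr = make_expr(rng.normal(size=(4, 10)))
        sc = score_samples(WeightedSignature("dmfs", {"g2": 1.0}), expr)
        v = expr.data.loc["g2"].to_numpy()
        z = (v - v.mean()) / v.std(ddof=1)
        np.testing.assert_allclose(list(sc.scores.values()), z, atol=1e-12)

    def test_hand_computed_weighted_mean(self):
        vals = np.array([[1.0, 2.0, 3.0], [4.0, 2.0, 0.0]])
        expr = make_expr(vals)
        sc = score_samples(WeightedSignature("dmfs", {"g0": 1.0, "g1": -1.0}), expr,
                           standardize=False)
        expected = (1.0 * vals[0] + (-1.0) * vals[1]) / 2
        np.testing.assert_allclose(list(sc.scores.values()), expected, atol=1e-12)

    def test_coverage_and_missing_genes(self, rng):
        expr = make_expr(rng.normal(size=(2, 6)))
        sc = score_samples(WeightedSignature("dmfs", {"g0": 1.0, "nope": 2.0}), expr)
        assert sc.coverage == pytest.approx(0.5)
        with pytest.raises(ValueError):
            score_samples(WeightedSignature("dmfs", {"absent": 1.0}), expr)

    def test_affine_rescaling_invariance(self, rng):
        v = rng.normal(size=(5, 12))
        sig = WeightedSignature("dmfs", {f"g{i}": w for i, w in enumerate([1, -2, 0.5, 3, -1])})
        base = score_samples(sig, make_expr(v))
        resc = score_samples(sig, make_expr(v * 7.0 + 3.0))
        np.testing.assert_allclose(
            list(base.scores.values()), list(resc.scores.values()), atol=1e-9
        )


class TestStratify:
    def test_nine_distinct_tertiles(self, rng):
        labels = stratify_samples(rng.permutation(9).astype(float), 3)
        assert sorted(np.bincount(labels)) == [3, 3, 3]

    def test_median_split(self):
        labels = stratify_samples(np.array([4.0, 1.0, 3.0, 2.0]), 2)
        assert np.bincount(labels).tolist() == [2, 2]
        assert labels[np.argsort([4.0, 1.0, 3.0, 2.0])].tolist() == [0, 0, 1, 1]

    def test_boundary_ties_go_low_exhaustive(self):
        """All orderings of six values with one tied pair: tied samples land
        in the same (lower) group whenever the tie sits on a cut point."""
        base = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        for ordering in set(itertools.permutations(base)):
            vals = np.array(ordering)
            labels = stratify_samples(vals, 2)
            cut = float(np.quantile(vals, 0.5, method="lower"))
            expected = (vals > cut).astype(int)
            assert labels.tolist() == expected.tolist()
            # the tied pair always shares a group
            tied = np.flatnonzero(vals == 2.0)
            assert labels[tied[0]] == labels[tied[1]]

    def test_identical_scores_error(self):
        with pytest.raises(ValueError):
            stratify_samples(np.ones(10), 3)


class TestKaplanMeier:
    def test_no_events_flat(self):
        c = km_estimate([1, 2, 3], [0, 0, 0])
        assert len(c.times) == 0 and c.survival_at(99) == 1.0

    def test_two_events(self):
        c = km_estimate([1, 2], [1, 1])
        assert c.survival_at(1) == pytest.approx(0.5)
        assert c.survival_at(2) == pytest.approx(0.0)

    def test_censoring_hand_computation(self):
        # data 1+ (censored), 2, 3: S = 1, then 1*(1-1/2)=0.5 after t=2,
        # then 0.5*(1-1/1)=0 after t=3
        c = km_estimate([1, 2, 3], [0, 1, 1])
        assert c.survival_at(1.5) == 1.0
        assert c.survival_at(2.5) == pytest.approx(0.5)
        assert c.survival_at(3.5) == pytest.approx(0.0)

    def test_equals_one_minus_ecdf_without_censoring(self, rng):
        t = rng.exponential(1.0, 50)
        c = km_estimate(t, np.ones(50, int))
        for q in rng.uniform(0, 3, 20):
            ecdf = np.mean(t <= q)
            assert c.survival_at(q) == pytest.approx(1 - ecdf, abs=1e-12)

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.exponential(1.0, 80)
        e = (rng.random(80) < 0.6).astype(int)
        c = km_estimate(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        for q in (0.2, 0.5, 1.0, 2.0):
            assert c.survival_at(q) == pytest.approx(
                float(kmf.predict(q)), abs=1e-10
            )


def hand_logrank_two_groups(times, events, groups):
    """Independent O-E/V computation for two groups."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups, int)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        stat, df, p = logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_three_groups_df_two(self, rng):
        t = rng.exponential(1, 30)
        e = np.ones(30, int)
        g = np.repeat([0, 1, 2], 10)
        _stat, df, _p = logrank_test(t, e, g)
        assert df == 2

    def test_two_group_matches_hand_oracle(self, rng):
        t = np.concatenate([rng.exponential(1.0, 25), rng.exponential(0.5, 25)])
        e = (rng.random(50) < 0.8).astype(int)
        g = np.repeat([0, 1], 25)
        stat, df, p = logrank_test(t, e, g)
        expected = hand_logrank_two_groups(t, e, g)
        assert df == 1
        assert stat == pytest.approx(expected, abs=1e-10)

    def test_matches_lifelines_multigroup(self, rng):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import multivariate_logrank_test

        t = rng.exponential(1.0, 90)
        e = (rng.random(90) < 0.7).astype(int)
        g = rng.integers(0, 3, 90)
        stat, df, p = logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert stat == pytest.approx(float(ref.test_statistic), abs=1e-8)
        assert p == pytest.approx(float(ref.p_value), abs=1e-10)

    def test_no_events_error(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], [0, 1])


class TestEvaluate:
    def make_cohort(self, rng, n=300, effect=1.5):
        v = rng.normal(size=(10, n))
        L = effect * v[0] - effect * v[1]
        t = rng.exponential(1 / (0.1 * np.exp(L)))
        e = np.ones(n, int)
        return make_expr(v), make_pheno(t, e)

    def test_planted_signal_low_p(self, rng):
        expr, pheno = self.make_cohort(rng)
        sig = WeightedSignature("dmfs", {"g0": 1.0, "g1": -1.0})
        res = evaluate_signature(sig, expr, pheno)
        assert res.p < 1e-3
        assert sum(res.group_sizes) == 300

    def test_sign_flip_leaves_statistic_unchanged(self, rng):
        expr, pheno = self.make_cohort(rng)
        sig = WeightedSignature("dmfs", {"g0": 1.0, "g1": -1.0})
        flipped = WeightedSignature("dmfs", {"g0": -1.0, "g1": 1.0})
        a = evaluate_signature(sig, expr, pheno)
        b = evaluate_signature(flipped, expr, pheno)
        assert a.logrank_stat == pytest.approx(b.logrank_stat, abs=1e-9)

    def test_null_p_roughly_uniform(self):
        ps = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            v = rng.normal(size=(6, 60))
            t = rng.exponential(1.0, 60)
            expr, pheno = make_expr(v), make_pheno(t, np.ones(60, int))
            sig = WeightedSignature("dmfs", {f"g{i}": w for i, w in enumerate([1, -1, 0.5])})
            ps.append(evaluate_signature(sig, expr, pheno).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSplitReweight:
    def make_cohort(self, seed=7, n=500, n_causal=20):
        rng = np.random.default_rng(seed)
        betas = rng.uniform(0.3, 0.8, n_causal) * rng.choice([-1, 1], n_causal)
        v = rng.normal(size=(n_causal + 10, n))
        L = betas @ v[:n_causal]
        t = rng.exponential(1 / (0.1 * np.exp(L)))
        e = (rng.random(n) < 0.8).astype(int)
        return make_expr(v), make_pheno(t, e), betas

    def test_same_seed_same_split(self):
        expr, pheno, _ = self.make_cohort()
        genes = [f"g{i}" for i in range(20)]
        _, d1, t1 = split_and_reweight(genes, expr, pheno, seed=3)
        _, d2, t2 = split_and_reweight(genes, expr, pheno, seed=3)
        assert d1 == d2 and t1 == t2
        assert set(d1).isdisjoint(t1)

    def test_weights_rank_correlate_with_planted_betas(self):
        expr, pheno, betas = self.make_cohort()
        genes = [f"g{i}" for i in range(20)]
        sig, disc, test = split_and_reweight(genes, expr, pheno, seed=1)
        w = np.array([sig.entries[g] for g in genes])
        rho = stats.spearmanr(w, betas).statistic
        assert rho > 0.5

    def test_fraction_default_half(self):
        expr, pheno, _ = self.make_cohort()
        _, disc, test = split_and_reweight([f"g{i}" for i in range(5)], expr, pheno)
        assert abs(len(disc) - len(test)) <= 2
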