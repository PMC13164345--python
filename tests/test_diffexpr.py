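"""NB Wald engine: size factors, dispersion recovery, GLM calibration, BH."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as smapi
from hypothesis import given, settings, strategies as st
from scipy import stats

import stratmeta as sm
from stratmeta.diffexpr import DEError, LN2, nb_loglik


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5], "c": [10, 20, 5]},
                          index=["g1", "g2", "g3"])
        sf = sm.estimate_size_factors(sm.CountMatrix(df))
        assert np.allclose(sf, 1.0)

    def test_doubled_column_hand_values(self):
        # col2 = 2*col1: geometric mean per gene = sqrt(2)*col1, so ratios are
        # 1/sqrt(2) and sqrt(2) for every gene
        df = pd.DataFrame({"a": [4, 10, 7], "b": [8, 20, 14]}, index=["g1", "g2", "g3"])
        sf = sm.estimate_size_factors(sm.CountMatrix(df))
        assert sf["a"] == pytest.approx(1 / np.sqrt(2), rel=1e-12)
        assert sf["b"] == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.integers(1, 100, size=(30, 4)),
                          index=[f"g{i}" for i in range(30)],
                          columns=list("abcd"))
        sf = sm.estimate_size_factors(sm.CountMatrix(df))
        perm = df[["c", "a", "d", "b"]]
        sf_perm = sm.estimate_size_factors(sm.CountMatrix(perm))
        assert np.allclose(sf_perm[list("abcd")], sf[list("abcd")])

    def test_no_allpositive_gene_rejected(self):
        df = pd.DataFrame({"a": [0, 5], "b": [3, 0]}, index=["g1", "g2"])
        with pytest.raises(DEError, match="filter"):
            sm.estimate_size_factors(sm.CountMatrix(df))


def _two_group_design(n_ctrl, n_trt):
    X = np.column_stack([np.ones(n_ctrl + n_trt),
                         np.r_[np.zeros(n_ctrl), np.ones(n_trt)]])
    return X


class TestNBGLM:
    def test_matches_statsmodels_negative_binomial(self):
        """Independent cross-check: same fixed-alpha NB GLM via statsmodels."""
        rng = np.random.default_rng(2)
        n = 60
        X = _two_group_design(40, 20)
        sf = np.exp(rng.normal(0, 0.2, size=n))
        mu = sf * 50 * np.exp(0.7 * X[:, 1])
        alpha = 0.15
        y = rng.negative_binomial(1 / alpha, (1 / alpha) / (1 / alpha + mu))
        beta, cov, _, ok = sm.fit_nb_glm(y, X, sf, alpha)
        ref = smapi.GLM(y, X, family=smapi.families.NegativeBinomial(alpha=alpha),
                        offset=np.log(sf)).fit()
        assert ok
        assert np.allclose(beta, ref.params, atol=1e-5)
        # expected-information SE agrees with statsmodels' within a few percent
        assert np.allclose(np.sqrt(np.diag(cov)), ref.bse, rtol=0.05)

    def test_offset_invariance(self):
        rng = np.random.default_rng(3)
        X = _two_group_design(15, 15)
        sf = np.ones(30)
        y = rng.poisson(20, size=30)
        b1, c1, _, _ = sm.fit_nb_glm(y, X, sf, 0.1)
        y2, sf2 = y.copy(), sf.copy()
        y2[4] *= 2
        sf2[4] *= 2
        b2, c2, _, _ = sm.fit_nb_glm(y2, X, sf2, 0.1)
        # doubling a sample's count and size factor leaves the rate unchanged
        assert np.allclose(b1[1], b2[1], atol=5e-3)

    def test_null_wald_p_uniform(self):
        rng = np.random.default_rng(4)
        X = _two_group_design(30, 30)
        sf = np.ones(60)
        alpha = 0.1
        pvals = []
        for _ in range(400):
            mu = 40.0
            y = rng.negative_binomial(1 / alpha, (1 / alpha) / (1 / alpha + mu), size=60)
            beta, cov, _, ok = sm.fit_nb_glm(y, X, sf, alpha)
            if ok:
                z = beta[1] / np.sqrt(cov[1, 1])
                pvals.append(2 * stats.norm.sf(abs(z)))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_recovers_planted_log2fc(self):
        rng = np.random.default_rng(5)
        X = _two_group_design(50, 50)
        sf = np.ones(100)
        alpha = 0.1
        estimates = []
        for _ in range(200):
            mu = 30 * 2.0 ** (1.0 * X[:, 1])
            y = rng.negative_binomial(1 / alpha, (1 / alpha) / (1 / alpha + mu))
            beta, _, _, ok = sm.fit_nb_glm(y, X, sf, alpha)
            if ok:
                estimates.append(beta[1] / LN2)
        assert abs(np.median(estimates) - 1.0) < 0.1


class TestDispersionEstimation:
    def _simulate(self, alpha, n=100, G=150, seed=0):
        rng = np.random.default_rng(seed)
        X = _two_group_design(n // 2, n // 2)
        sf = np.ones(n)
        mu = rng.uniform(20, 200, size=G)
        counts = np.empty((G, n), dtype=np.int64)
        for i in range(G):
            if alpha < 1e-8:
                counts[i] = rng.poisson(mu[i], size=n)
            else:
                r = 1 / alpha
                counts[i] = rng.negative_binomial(r, r / (r + mu[i]), size=n)
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(G)],
                          columns=[f"s{i}" for i in range(n)])
        return df, pd.Series(sf, index=df.columns), X

    def test_poisson_counts_give_tiny_alpha(self):
        df, sf, X = self._simulate(alpha=0.0, seed=6)
        alpha_hat, diag = sm.estimate_dispersions(df, sf, X, shrink_weight=0.0)
        assert alpha_hat.median() < 0.01

    def test_nb_dispersion_recovered(self):
        df, sf, X = self._simulate(alpha=0.2, seed=7)
        alpha_hat, _ = sm.estimate_dispersions(df, sf, X, shrink_weight=0.0)
        assert 0.1 < alpha_hat.median() < 0.3

    def test_shrinkage_pulls_toward_trend(self):
        df, sf, X = self._simulate(alpha=0.2, seed=8)
        raw, _ = sm.estimate_dispersions(df, sf, X, shrink_weight=0.0)
        shrunk, _ = sm.estimate_dispersions(df, sf, X, shrink_weight=0.5)
        assert np.log(shrunk).std() < np.log(raw).std()


class TestBH:
    def test_hand_applied_step_up(self):
        p = pd.Series([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(sm.bh_adjust(p), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert sm.bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_nan_passthrough(self):
        out = sm.bh_adjust(pd.Series([0.01, np.nan, 0.5]))
        assert np.isnan(out.iloc[1])
        assert not np.isnan(out.iloc[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sm.bh_adjust(np.array([0.5, 1.2]))

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=6, max_size=6))
    def test_matches_brute_force_on_permutations(self, pvals):
        def brute_force_bh(p):
            m = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.empty(m)
            running_min = 1.0
            for rank_from_top in range(m - 1, -1, -1):
                i = order[rank_from_top]
                running_min = min(running_min, p[i] * m / (rank_from_top + 1))
                adj[i] = running_min
            return adj

        arr = np.array(pvals)
        for perm in itertools.islice(itertools.permutations(range(6)), 0, 24, 7):
            q = arr[list(perm)]
            assert np.allclose(sm.bh_adjust(q), brute_force_bh(q), atol=1e-12)


class TestRunContrast:
    def test_planted_effects_recovered(self):
        cfg = sm.SimConfig(n_genes=500, n_subgroups=1, controls_per_subgroup=[60],
                           n_treated=20, frac_de=0.1, effect_mean_log2=2.0,
                           effect_heterogeneity_tau=0.0, subgroup_shift_sd=0.0,
                           dispersion_lognormal=(-2.302585, 0.0),
                           baseline_log2_range=(3.0, 10.0), seed=17)
        counts, samples, truth = sm.simulate(cfg)
        design = sm.DesignSpec(treatment="ponatinib", vehicle="DMSO")
        tab = sm.run_contrast(counts, samples, design)
        sig = sm.diffexpr.significant_genes(tab)
        de = set(truth.de_gene_ids())
        recall = len(sig & de) / len(de)
        assert recall > 0.8

    def test_too_few_treated_rejected(self, small_sim):
        _, counts, samples, _ = small_sim
        meta = samples.table.copy()
        # keep a single treated sample
        treated = meta.index[meta["treatment"] == "ponatinib"]
        meta = meta.drop(treated[1:])
        sub = counts.subset_samples(list(meta.index))
        with pytest.raises(DEError, match="treated"):
            sm.run_contrast(sub, sm.SampleTable(meta),
                            sm.DesignSpec(treatment="ponatinib"))

    def test_deterministic(self, small_sim):
        _, counts, samples, _ = small_sim
        design = sm.DesignSpec(treatment="ponatinib")
        t1 = sm.run_contrast(counts, samples, design)
        t2 = sm.run_contrast(counts, samples, design)
        pd.testing.assert_frame_equal(t1, t2)

    def test_scale_equivariance(self, small_sim):
        """Doubling every count roughly doubles size factors and leaves
        log2fc unchanged."""
        _, counts, samples, _ = small_sim
        design = sm.DesignSpec(treatment="ponatinib")
        t1 = sm.run_contrast(counts, samples, design)
        doubled = sm.CountMatrix(counts.counts * 2)
        t2 = sm.run_contrast(doubled, samples, design)
        both = t1["converged"] & t2["converged"]
        diff = (t1.loc[both, "log2fc"] - t2.loc[both, "log2fc"]).abs()
        assert diff.median() < 0.05


def test_nb_loglik_poisson_limit():
    y = np.array([3.0, 0.0, 7.0])
    mu = np.array([2.5, 1.0, 6.0])
    assert nb_loglik(y, mu, 1e-12) == pytest.approx(
        float(np.sum(stats.poisson.logpmf(y, mu))), rel=1e-9)
    assert nb_loglik(y, mu, 0.3) == pytest.approx(
        float(np.sum(stats.nbinom.logpmf(y, 1 / 0.3, (1 / 0.3) / (1 / 0.3 + mu)))),
        rel=1e-9)
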