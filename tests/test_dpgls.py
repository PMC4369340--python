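"""Distance-based PGLS: design coding, fitting, and permutation inference."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import craniopgls as cp
from craniopgls.dpgls import build_design


def identity_covariance(n):
    return cp.PhyloCovariance([f"t{i}" for i in range(n)], np.eye(n))


class TestDesign:
    taxa = [f"t{i}" for i in range(16)]

    def test_three_level_factor(self):
        loc = pd.Series(["b"] * 6 + ["a"] * 5 + ["c"] * 5, index=self.taxa)
        d = build_design(loc, self.taxa)
        assert d.X.shape == (16, 3)
        assert d.df_model == 2
        assert d.term_labels[0] == "Intercept"
        assert np.allclose(d.X[:, 0], 1.0)

    def test_boolean_factor(self):
        b = pd.Series([True] * 9 + [False] * 7, index=self.taxa)
        d = build_design(b, self.taxa)
        assert d.X.shape == (16, 2)
        assert d.df_model == 1

    def test_covariate_enters_raw(self):
        x = pd.Series(np.arange(16.0), index=self.taxa, name="FT")
        d = build_design(x, self.taxa)
        assert d.X.shape == (16, 2)
        assert np.allclose(d.X[:, 1], np.arange(16.0))

    def test_single_level_factor_rejected(self):
        f = pd.Series(["a"] * 16, index=self.taxa)
        with pytest.raises(ValueError, match="single level"):
            build_design(f, self.taxa)

    def test_missing_taxa_named(self):
        f = pd.Series(["a", "b"], index=self.taxa[:2])
        with pytest.raises(ValueError, match="t2"):
            build_design(f, self.taxa)


class TestFit:
    def test_identity_covariance_reduces_to_classical_anova(self, rng):
        # star phylogeny: the phylogenetic transform is a scaled identity,
        # which cancels in F -> textbook one-way ANOVA
        for scale in (1.0, 2.0):
            n = 12
            C = cp.PhyloCovariance([f"t{i}" for i in range(n)],
                                   scale * np.eye(n))
            groups = pd.Series(["a"] * 4 + ["b"] * 4 + ["c"] * 4, index=C.taxa)
            y = rng.normal(size=n)
            res = cp.DPGLS(y[:, None], groups, C).fit()
            ref = scipy.stats.f_oneway(y[:4], y[4:8], y[8:])
            assert res.F == pytest.approx(ref.statistic, rel=1e-10)

    def test_identity_covariance_manova_matches_naive_trace_oracle(self, rng):
        # trace-based SS from explicit group-mean arithmetic
        n, p = 10, 4
        C = identity_covariance(n)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=C.taxa)
        Y = rng.normal(size=(n, p))
        res = cp.DPGLS(Y, groups, C).fit()
        grand = Y.mean(axis=0)
        ss_total = np.sum((Y - grand) ** 2)
        ss_resid = sum(np.sum((Y[i0:i1] - Y[i0:i1].mean(axis=0)) ** 2)
                       for i0, i1 in ((0, 5), (5, 10)))
        assert res.ss_total == pytest.approx(ss_total, rel=1e-10)
        assert res.ss_resid == pytest.approx(ss_resid, rel=1e-10)
        assert res.ss_model == pytest.approx(ss_total - ss_resid, rel=1e-8)

    def test_univariate_coefficients_equal_explicit_gls(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        for seed in (1, 2):
            t = cp.simulate_tree(10, seed=seed)
            C = t.vcv()
            x = rng.normal(size=10)
            y = 2.0 + 0.5 * x + rng.normal(size=10)
            res = cp.DPGLS(y[:, None], x, C).fit()
            ref = sm.GLS(y, np.column_stack([np.ones(10), x]),
                         sigma=C.matrix).fit()
            assert np.abs(res.coefficients.to_numpy().ravel()
                          - ref.params).max() < 1e-8

    def test_ss_decomposition_and_r2(self, tree16, rng):
        C = tree16.vcv()
        Y = rng.normal(size=(16, 10))
        groups = pd.Series(["a"] * 5 + ["b"] * 6 + ["c"] * 5, index=C.taxa)
        res = cp.DPGLS(Y, groups, C).fit()
        assert res.ss_model + res.ss_resid == pytest.approx(
            res.ss_total, rel=1e-8)
        assert res.R2 == pytest.approx(res.ss_model / res.ss_total)
        assert res.df_model + res.df_resid == 15

    def test_f_invariant_to_response_scaling(self, tree16, rng):
        C = tree16.vcv()
        Y = rng.normal(size=(16, 3))
        x = rng.normal(size=16)
        f0 = cp.DPGLS(Y, x, C).fit().F
        f1 = cp.DPGLS(-41.0 * Y, x, C).fit().F
        assert f1 == pytest.approx(f0, rel=1e-10)

    def test_perfect_linear_relation_gives_r2_one(self):
        C = identity_covariance(8)
        x = np.arange(8.0)
        Y = np.outer(x, [1.0, -2.0, 0.5]) + 3.0
        res = cp.DPGLS(Y, x, C).fit()
        assert res.R2 == pytest.approx(1.0, abs=1e-10)

    def test_rank_deficient_design_rejected(self, tree16):
        C = tree16.vcv()
        X = np.column_stack([np.ones(16), np.ones(16)])
        with pytest.raises(ValueError, match="rank"):
            cp.DPGLS(np.random.default_rng(0).normal(size=(16, 2)),
                     cp.DesignMatrix(X, ["Intercept", "dup"], 1), C)


class TestPermutation:
    def test_p_matches_exhaustive_enumeration(self, rng):
        # small case where all n! relabelings can be enumerated exactly
        n = 6
        t = cp.simulate_tree(n, seed=17)
        C = t.vcv()
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=C.taxa)
        y = rng.normal(size=(n, 1))
        model = cp.DPGLS(y, groups, C)
        obs = model.fit().F
        exact_fs = [model._f(y[list(perm)])
                    for perm in itertools.permutations(range(n))]
        p_exact = np.mean([f >= obs - 1e-12 for f in exact_fs])
        res = model.fit(n_perm=4999, seed=3)
        assert res.p_value == pytest.approx(p_exact, abs=0.02)

    def test_p_invariant_to_factor_relabeling(self, tree16, rng):
        C = tree16.vcv()
        y = rng.normal(size=(16, 1))
        g1 = pd.Series(["a"] * 8 + ["b"] * 8, index=C.taxa)
        g2 = g1.map({"a": "zz", "b": "aa"})
        r1 = cp.DPGLS(y, g1, C).fit(n_perm=99, seed=5)
        r2 = cp.DPGLS(y, g2, C).fit(n_perm=99, seed=5)
        assert r1.F == pytest.approx(r2.F, rel=1e-12)
        assert r1.p_value == r2.p_value

    def test_determinism_and_bounds(self, tree16, rng):
        C = tree16.vcv()
        Y = rng.normal(size=(16, 10))
        x = rng.normal(size=16)
        r1 = cp.dpgls_permutation_test(Y, x, C, n_perm=99, seed=11)
        r2 = cp.dpgls_permutation_test(Y, x, C, n_perm=99, seed=11)
        assert r1.p_value == r2.p_value
        assert 0.01 <= r1.p_value <= 1.0

    def test_null_p_values_roughly_uniform(self, tree16):
        # desk-scale KS sanity check under a true null (RRPP scheme, which
        # is calibrated for phylogenetically correlated responses)
        C = tree16.vcv()
        groups = pd.Series(["a"] * 8 + ["b"] * 8, index=C.taxa)
        ps = []
        for s in range(60):
            y = cp.simulate_bm(tree16, 1.0, 0.0, seed=1000 + s)
            ps.append(cp.DPGLS(y, groups, C)
                      .fit(n_perm=99, seed=s, permutation="rrpp").p_value)
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.005

    def test_tip_shuffling_is_liberal_when_groups_align_with_clades(self, tree16):
        # documented pathology of shuffling raw correlated species means:
        # with groups painted on clades the test over-rejects markedly,
        # while RRPP stays near nominal on the same data
        C = tree16.vcv()
        groups = pd.Series(np.repeat(["g", "s", "c"], [3, 10, 3]), index=C.taxa)
        traits = cp.simulate_bm(tree16, 1.0, np.zeros(200), seed=99).to_numpy()
        rej_tips = rej_rrpp = 0
        for i in range(200):
            m = cp.DPGLS(traits[:, i:i + 1], groups, C)
            rej_tips += m.fit(n_perm=99, seed=i).p_value <= 0.05
            rej_rrpp += m.fit(n_perm=99, seed=i,
                              permutation="rrpp").p_value <= 0.05
        assert rej_tips / 200 > 0.15
        assert rej_rrpp / 200 < 0.12

    def test_regression_convenience_reports_r2(self, tree16, rng):
        C = tree16.vcv()
        Y = rng.normal(size=(16, 10))
        cov = pd.Series(rng.normal(size=16), index=C.taxa, name="FT")
        res = cp.dpgls_regression(Y, cov, C, n_perm=49, seed=2)
        assert 0.0 <= res.R2 <= 1.0
        assert res.n_perm == 49
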