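"""Univariate screen, FDR, PCA, PLS-DA and variance-partition tests, with
independent oracles (brute-force BH, eigen-decomposition PCA, sklearn PLS)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vinomix import diffstats
from vinomix.diffstats import (
    FeatureMatrix,
    anova_per_feature,
    bh_fdr,
    match_feature_ids,
    overlap_counts,
    pca_fit,
    permutation_test,
    plsda_fit,
    preprocess,
    top_k_table,
    variance_partition,
)
from vinomix.synthio import SampleMeta


def make_matrix(values: np.ndarray, rootstocks, irrigations=None, state="autoscaled") -> FeatureMatrix:
    n = values.shape[0]
    irrigations = irrigations or ["Full"] * n
    sids = [f"s{i}" for i in range(n)]
    meta = {
        sid: SampleMeta(sid, rs, irr, 2018, i, 1)
        for i, (sid, rs, irr) in enumerate(zip(sids, rootstocks, irrigations))
    }
    df = pd.DataFrame(values, index=sids, columns=[f"f{j}" for j in range(values.shape[1])])
    return FeatureMatrix(values=df, meta=meta, state=state)


class TestPreprocess:
    def _raw(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(5, 1, size=(6, 4))
        vals[:, 0] = 1000.0  # the IS feature: constant response
        return make_matrix(vals, ["Own"] * 3 + ["1103P"] * 3, state="raw")

    def test_global_response_scaling_cancels(self):
        m = self._raw()
        doubled = m.values.copy()
        doubled.iloc[0] *= 2.0  # sample 0 measured at double response, IS included
        m2 = FeatureMatrix(values=doubled, meta=m.meta, state="raw")
        out1 = preprocess(m, "f0")
        out2 = preprocess(m2, "f0")
        np.testing.assert_allclose(out1.values.values, out2.values.values, atol=1e-10)

    def test_autoscaled_columns(self):
        out = preprocess(self._raw(), "f0")
        np.testing.assert_allclose(out.values.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(out.values.var(axis=0, ddof=1), 1, atol=1e-8)
        assert out.state == "autoscaled"

    def test_double_preprocess_guarded(self):
        out = preprocess(self._raw(), "f0")
        with pytest.raises(ValueError, match="state"):
            preprocess(out, "f1")

    def test_missing_is_names_sample(self):
        m = self._raw()
        m.values.loc["s2", "f0"] = 0.0
        with pytest.raises(ValueError, match="s2"):
            preprocess(m, "f0")


class TestAnova:
    def test_identical_groups_give_p_one(self):
        vals = np.array([[1.0], [2.0], [1.0], [2.0]])
        m = make_matrix(vals, ["Own", "Own", "1103P", "1103P"])
        res = anova_per_feature(m, "rootstock")
        assert res.loc[0, "F"] == 0.0
        assert res.loc[0, "p"] == 1.0

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(0, 1, (3, 1)), rng.normal(10, 1, (3, 1))])
        m = make_matrix(vals, ["Own"] * 3 + ["1103P"] * 3)
        res = anova_per_feature(m, "rootstock")
        assert res.loc[0, "p"] < 1e-3

    def test_matches_scipy_f_oneway(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(2)
        vals = rng.normal(size=(12, 20))
        rs = ["Own"] * 4 + ["1103P"] * 4 + ["SO4"] * 4
        m = make_matrix(vals, rs)
        res = anova_per_feature(m, "rootstock")
        for j in range(20):
            ref = f_oneway(vals[:4, j], vals[4:8, j], vals[8:, j])
            assert res.loc[j, "F"] == pytest.approx(ref.statistic, rel=1e-10)
            assert res.loc[j, "p"] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_feature_p_one_not_nan(self):
        vals = np.ones((6, 1))
        m = make_matrix(vals, ["Own"] * 3 + ["1103P"] * 3)
        res = anova_per_feature(m, "rootstock")
        assert res.loc[0, "p"] == 1.0

    def test_discovery_count_monotone_in_effect_size(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(24, 60))
        rs = (["Own"] * 12 + ["1103P"] * 12)
        counts = []
        for effect in (0.0, 0.8, 2.0):
            vals = base.copy()
            vals[:12, :15] += effect  # plant effect on 15 features
            res = anova_per_feature(make_matrix(vals, rs), "rootstock")
            counts.append(int((res["q"] <= 0.05).sum()))
        assert counts == sorted(counts)


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Brute-force BH: q_i = min over j with p_j >= p_i of p_j * n / rank_j."""
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    q = np.empty(n)
    for i in range(n):
        cand = [p[j] * n / ranks[j] for j in range(n) if p[j] >= p[i]]
        q[i] = min(min(cand), 1.0)
    return q


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_single(self):
        np.testing.assert_allclose(bh_fdr([0.123]), [0.123])

    def test_matches_brute_force_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        for _ in range(25):
            n = int(rng.integers(1, 200))
            p = rng.uniform(size=n)
            q = bh_fdr(p)
            np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
            np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_order_preserving(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestPca:
    def test_single_varying_feature(self):
        vals = np.zeros((6, 3))
        vals[:, 1] = np.arange(6.0)
        m = make_matrix(vals, ["Own"] * 6)
        model = pca_fit(m, 1)
        assert model.var_fraction[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition(self, rng):
        X = rng.normal(size=(10, 50))
        m = make_matrix(X, ["Own"] * 10)
        k = 5
        model = pca_fit(m, k)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc @ Xc.T)
        evals = evals[::-1]
        frac = evals / evals.sum()
        np.testing.assert_allclose(model.var_fraction, frac[:k], atol=1e-8)

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(12, 30))
        model = pca_fit(make_matrix(X, ["Own"] * 12), 4)
        G = model.scores.values.T @ model.scores.values
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_k_too_large(self, rng):
        X = rng.normal(size=(5, 10))
        with pytest.raises(ValueError):
            pca_fit(make_matrix(X, ["Own"] * 5), 5)


def _two_class_data(rng, n=20, p=30, d=6.0):
    X = rng.normal(size=(n, p))
    X[: n // 2, :5] += d / np.sqrt(5)
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    labels = ["Own"] * (n // 2) + ["1103P"] * (n - n // 2)
    return make_matrix(X, labels)


class TestPlsda:
    def test_well_separated_classes_high_q2(self, rng):
        m = _two_class_data(rng)
        model = plsda_fit(m, "rootstock")
        assert model.Q2 > 0.8
        assert model.R2Y >= model.Q2 - 1e-9

    def test_null_labels_low_q2(self):
        neg = 0
        for seed in range(10):
            g = np.random.default_rng(seed)
            X = g.normal(size=(16, 40))
            labels = ["Own"] * 8 + ["1103P"] * 8
            model = plsda_fit(make_matrix((X - X.mean(0)) / X.std(0, ddof=1), labels), "rootstock")
            neg += model.Q2 <= 0
        assert neg >= 8  # Q2 <= 0 in >= 80 % of null seeds

    def test_mean_vip_squared_is_one(self, rng):
        for _ in range(3):
            X = rng.normal(size=(14, 25))
            labels = list(rng.choice(["Own", "1103P", "SO4"], size=14))
            if len(set(labels)) < 2:
                continue
            model = plsda_fit(make_matrix(X, labels), "rootstock")
            assert float((model.vip**2).mean()) == pytest.approx(1.0, abs=1e-6)

    def test_r2y_matches_sklearn_pls(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        m = _two_class_data(rng, n=16, p=20, d=3.0)
        model = plsda_fit(m, "rootstock", n_components=2)
        X = m.values.values
        Y = np.zeros((16, 2))
        labels = m.factor_levels("rootstock")
        for i, lab in enumerate(labels):
            Y[i, sorted(set(labels)).index(lab)] = 1.0
        sk = PLSRegression(n_components=2, scale=False).fit(X, Y)
        Yc = Y - Y.mean(axis=0)
        rss = float(np.sum((Yc - (sk.predict(X) - Y.mean(axis=0))) ** 2))
        r2y_sk = 1.0 - rss / float(np.sum(Yc**2))
        assert model.R2Y == pytest.approx(r2y_sk, abs=1e-6)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(6, 5))
        with pytest.raises(ValueError):
            plsda_fit(make_matrix(X, ["Own"] * 6), "rootstock")


class TestPermutation:
    def test_b_too_small_rejected(self, rng):
        m = _two_class_data(rng)
        with pytest.raises(ValueError):
            permutation_test(m, "rootstock", B=10)

    def test_perfectly_separating_data_minimal_p(self, rng):
        m = _two_class_data(rng, d=20.0)
        B = 39
        perm_p, obs, null = permutation_test(m, "rootstock", B=B, rng=0)
        assert perm_p == pytest.approx(1.0 / (B + 1))

    def test_p_in_valid_range(self, rng):
        m = _two_class_data(rng, d=0.0)
        B = 24
        perm_p, _, null = permutation_test(m, "rootstock", B=B, rng=0)
        assert 1.0 / (B + 1) <= perm_p <= 1.0
        assert null.size == B


class TestVariancePartition:
    def test_pure_rootstock_scores(self):
        rs = ["Own", "Own", "1103P", "1103P", "SO4", "SO4"] * 2
        irr = ["Full", "RDI"] * 6
        coding = {"Own": -1.0, "1103P": 0.0, "SO4": 1.0}
        scores = pd.DataFrame({"PC1": [coding[r] for r in rs]}, index=[f"s{i}" for i in range(12)])
        meta = {
            f"s{i}": SampleMeta(f"s{i}", rs[i], irr[i], 2018, i, 1) for i in range(12)
        }
        pca = diffstats.PCAModel(loadings=pd.DataFrame(), scores=scores, var_fraction=np.array([1.0]))
        out = variance_partition(pca, meta)
        rs_row = out[(out.term == "rootstock") & (out.pc == 1)].iloc[0]
        assert rs_row.frac_variance == pytest.approx(1.0, abs=1e-9)

    def test_fractions_sum_to_one(self, rng):
        rs = np.repeat(["Own", "1103P", "3309C", "SO4"], 6)
        irr = np.tile(np.repeat(["Full", "RDI", "None"], 2), 4)
        scores = pd.DataFrame({"PC1": rng.normal(size=24), "PC2": rng.normal(size=24)}, index=[f"s{i}" for i in range(24)])
        meta = {f"s{i}": SampleMeta(f"s{i}", rs[i], irr[i], 2018, i, 1) for i in range(24)}
        pca = diffstats.PCAModel(loadings=pd.DataFrame(), scores=scores, var_fraction=np.array([0.5, 0.5]))
        out = variance_partition(pca, meta)
        for pc in (1, 2):
            total = out[out.pc == pc]["frac_variance"].sum()
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_planted_irrigation_effect_found(self, rng):
        rs = np.repeat(["Own", "1103P", "3309C", "SO4"], 6)
        irr = np.tile(np.repeat(["Full", "RDI", "None"], 2), 4)
        effect = {"Full": 0.0, "RDI": 3.0, "None": -3.0}
        scores = pd.DataFrame(
            {"PC1": rng.normal(size=24), "PC2": [effect[i] for i in irr] + rng.normal(0, 0.5, 24)},
            index=[f"s{i}" for i in range(24)],
        )
        meta = {f"s{i}": SampleMeta(f"s{i}", rs[i], irr[i], 2018, i, 1) for i in range(24)}
        pca = diffstats.PCAModel(loadings=pd.DataFrame(), scores=scores, var_fraction=np.array([0.5, 0.5]))
        out = variance_partition(pca, meta)
        row = out[(out.pc == 2) & (out.term == "irrigation")].iloc[0]
        assert row.p < 0.01
        row1 = out[(out.pc == 1) & (out.term == "irrigation")].iloc[0]
        assert row1.p > 0.01


class TestOverlapAndTopK:
    def test_overlap_counts(self):
        out = overlap_counts({"y2017": ["a", "b", "c"], "y2018": ["b", "c", "d"]})
        common = out[(out.kind == "common")]["count"].iloc[0]
        assert common == 2
        uniques = out[out.kind == "unique"].set_index("sets")["count"]
        assert uniques["y2017"] == 1 and uniques["y2018"] == 1

    def test_identical_and_disjoint(self):
        same = overlap_counts({"a": ["x", "y"], "b": ["x", "y"]})
        assert same[same.kind == "common"]["count"].iloc[0] == 2
        disj = overlap_counts({"a": ["x"], "b": ["y"]})
        assert disj[disj.kind == "common"]["count"].iloc[0] == 0

    def test_match_feature_ids_with_rt_tolerance(self):
        a = ["M55T5.00", "M55T8.00", "M99T5.00"]
        b = ["M55T5.03", "M99T5.10", "M55T9.00"]
        assert match_feature_ids(a, b) == []
        pairs = match_feature_ids(a, b, rt_tol_s=5.0)
        assert ("M55T5.00", "M55T5.03") in pairs
        assert len(pairs) == 1

    def test_top_k_returns_min_p_feature(self, rng):
        X = rng.normal(size=(8, 10))
        X[:4, 3] += 5.0
        m = make_matrix((X - X.mean(0)) / X.std(0, ddof=1), ["Own"] * 4 + ["1103P"] * 4)
        res = anova_per_feature(m, "rootstock")
        table = top_k_table(m, res, k=1)
        assert list(table.index) == ["f3"]
        assert set(table.columns) == {"Own", "1103P"}

    def test_top_k_shape(self, rng):
        X = rng.normal(size=(9, 12))
        m = make_matrix(X, ["Own"] * 3 + ["1103P"] * 3 + ["SO4"] * 3)
        res = anova_per_feature(m, "rootstock")
        table = top_k_table(m, res, k=5)
        assert table.shape == (5, 3)
        # k larger than n_features uses all
        assert top_k_table(m, res, k=99).shape == (12, 3)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_property_bounds_and_oracle(pvals):
    """q lies in [p, 1] and matches the brute-force oracle for any input."""
    p = np.array(pvals)
    q = bh_fdr(p)
    assert (q >= p - 1e-15).all() and (q <= 1.0 + 1e-15).all()
    np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
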