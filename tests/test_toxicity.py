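"""Toxicity stratification: clustering, exact tests, permutation null, screening."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rtproteomics import toxicity as tox
from rtproteomics.errors import ConfigError


def fisher_two_sided_enumeration(table):
    """Independent oracle: enumerate all 2x2 tables with the observed margins
    and sum hypergeometric probabilities <= that of the observed table."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestClusterPatients:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        z = np.vstack([rng.normal(-5, 0.3, (8, 2)), rng.normal(5, 0.3, (8, 2))])
        labels = tox.cluster_patients(pd.DataFrame(z, index=[f"P{i}" for i in range(16)]))
        assert labels.iloc[:8].nunique() == 1
        assert labels.iloc[8:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_duplicate_patients_cocluster(self):
        rng = np.random.default_rng(1)
        z = rng.normal(0, 1, (5, 3))
        z = np.vstack([z, z[0]])
        labels = tox.cluster_patients(pd.DataFrame(z, index=list("ABCDEF")))
        assert labels["A"] == labels["F"]

    def test_too_few_patients_rejected(self):
        with pytest.raises(ConfigError):
            tox.cluster_patients(pd.DataFrame(np.zeros((3, 2))))

    def test_planted_factor_with_weights(self):
        """d=2 separation on a dominant factor -> >=80% label agreement
        (median over replicates; d=2 puts the Bayes limit near 84%)."""
        n = 26
        y = (np.arange(n) < 17).astype(int)
        weights = np.array([5.0, 1.0, 1.0, 1.0])  # variance-explained-like
        agree = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            z = rng.normal(0, 1, (n, 4))
            z[:, 1:] *= 0.6
            z[:, 0] += 2.0 * y
            labels = tox.cluster_patients(
                pd.DataFrame(z, index=[f"P{i}" for i in range(n)]), weights=weights)
            agree.append(max(((labels.to_numpy() == c).astype(int) == y).mean()
                             for c in (1, 2)))
        assert np.median(agree) >= 0.8


class TestFisherAssociation:
    def _series(self, table):
        clusters, toxic = [], []
        (a, b), (c, d) = table
        clusters = [1] * (a + b) + [2] * (c + d)
        toxic = [0] * a + [1] * b + [0] * c + [1] * d
        idx = [f"P{i}" for i in range(len(clusters))]
        return pd.Series(clusters, index=idx), pd.Series(toxic, index=idx)

    def test_perfect_split(self):
        clus, toxv = self._series([[5, 0], [0, 5]])
        p, table = tox.fisher_association(clus, toxv)
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_perfect_independence(self):
        clus, toxv = self._series([[2, 2], [2, 2]])
        p, _ = tox.fisher_association(clus, toxv)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 8, size=(2, 2))
        table += 1  # non-degenerate margins
        clus, toxv = self._series(table.tolist())
        p, _ = tox.fisher_association(clus, toxv)
        assert p == pytest.approx(fisher_two_sided_enumeration(table), rel=1e-9)

    def test_invariance_transpose_and_swap(self):
        clus, toxv = self._series([[6, 2], [3, 7]])
        p1, _ = tox.fisher_association(clus, toxv)
        swapped = clus.map({1: 2, 2: 1})
        p2, _ = tox.fisher_association(swapped, toxv)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_degenerate_margin_warns_p_one(self):
        clus = pd.Series([1, 1, 2, 2], index=list("ABCD"))
        toxv = pd.Series([1, 1, 1, 1], index=list("ABCD"))
        with pytest.warns(UserWarning, match="degenerate"):
            p, _ = tox.fisher_association(clus, toxv)
        assert p == 1.0


class TestFactorClusterDifference:
    def test_identical_clusters_null(self):
        rng = np.random.default_rng(0)
        z = pd.DataFrame(np.repeat(rng.normal(0, 1, (1, 3)), 8, axis=0),
                         index=[f"P{i}" for i in range(8)])
        clusters = pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=z.index)
        res = tox.factor_cluster_difference(z, clusters)
        assert (res["p_bonferroni"] == 1.0).all()

    def test_bonferroni_arithmetic(self):
        # adjusted p = min(1, p * K); spot value 0.003 * 9 = 0.027
        assert min(1.0, 0.003 * 9) == pytest.approx(0.027)
        rng = np.random.default_rng(1)
        z = pd.DataFrame(rng.normal(0, 1, (10, 9)))
        clusters = pd.Series([1] * 5 + [2] * 5, index=z.index)
        res = tox.factor_cluster_difference(z, clusters)
        np.testing.assert_allclose(res["p_bonferroni"],
                                   np.minimum(1.0, res["p"] * 9))

    def test_planted_separating_factor_ranks_first(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            z = pd.DataFrame(rng.normal(0, 1, (20, 5)),
                             columns=[f"F{k}" for k in range(5)])
            clusters = pd.Series([1] * 10 + [2] * 10, index=z.index)
            z.loc[clusters == 2, "F2"] += 3.0
            res = tox.factor_cluster_difference(z, clusters)
            hits += res["p_bonferroni"].idxmin() == "F2"
        assert hits >= 19

    def test_small_cluster_rejected(self):
        z = pd.DataFrame(np.zeros((5, 2)))
        clusters = pd.Series([1, 2, 2, 2, 2], index=z.index)
        with pytest.raises(ConfigError):
            tox.factor_cluster_difference(z, clusters)


class TestTopWeightProteins:
    def _w(self, loadings):
        return pd.DataFrame({"F1": loadings},
                            index=[f"G{i:03d}" for i in range(len(loadings))])

    def test_five_percent_of_600(self):
        rng = np.random.default_rng(0)
        W = self._w(rng.normal(0, 1, 600))
        top = tox.top_weight_proteins(W, "F1", 0.05)
        assert len(top) == 30
        assert (np.diff(np.abs(top["loading"].to_numpy())) <= 1e-12).all()

    def test_all_equal_ties_lexicographic(self):
        W = self._w(np.ones(40))
        with pytest.warns(UserWarning, match="tie"):
            top = tox.top_weight_proteins(W, "F1", 0.05)
        assert list(top.index) == ["G000", "G001"]

    def test_bad_fraction_rejected(self):
        W = self._w(np.ones(10))
        with pytest.raises(ConfigError):
            tox.top_weight_proteins(W, "F1", 0.0)

    def test_sign_retained(self):
        W = self._w([-5.0, 4.0, 0.1, 0.2])
        top = tox.top_weight_proteins(W, "F1", 0.5)
        assert list(top["sign"]) == ["down", "up"]


class TestPermutationLoadingTest:
    def test_max_loading_floor(self):
        rng = np.random.default_rng(0)
        w = rng.normal(0, 1, 50)
        w[7] = 10.0
        W = pd.DataFrame({"F1": w}, index=[f"G{i}" for i in range(50)])
        p = tox.permutation_loading_test(W, "F1", B=1000, seed=1)
        assert p["G7"] == pytest.approx(1 / 1001)

    def test_median_loading_p_half(self):
        rng = np.random.default_rng(3)
        w = rng.normal(0, 1, 201)
        W = pd.DataFrame({"F1": w}, index=[f"G{i}" for i in range(201)])
        p = tox.permutation_loading_test(W, "F1", B=1000, seed=1)
        med = np.argsort(np.abs(w))[100]
        assert abs(p.iloc[med] - 0.5) < 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        W = pd.DataFrame({"F1": rng.normal(0, 1, 30)})
        p1 = tox.permutation_loading_test(W, "F1", B=200, seed=9)
        p2 = tox.permutation_loading_test(W, "F1", B=200, seed=9)
        pd.testing.assert_series_equal(p1, p2)


class TestFoldChangeValidation:
    def _mat(self, toxic_vals, non_vals):
        cols = [f"s{i}" for i in range(len(toxic_vals) + len(non_vals))]
        vals = pd.DataFrame([list(toxic_vals) + list(non_vals)],
                            index=["G1"], columns=cols)
        toxv = pd.Series([1] * len(toxic_vals) + [0] * len(non_vals), index=cols)
        return vals, toxv

    def test_identical_groups(self):
        vals, toxv = self._mat([1.0, 2.0], [1.0, 2.0])
        out = tox.fold_change_validation(vals, toxv)
        assert out.loc["G1", "log2_fc"] == 0.0
        assert out.loc["G1", "two_fold"] == ""

    def test_exact_twofold_boundary_not_flagged(self):
        vals, toxv = self._mat([2.0, 3.0], [1.0, 2.0])
        out = tox.fold_change_validation(vals, toxv)
        assert out.loc["G1", "log2_fc"] == pytest.approx(1.0)
        assert out.loc["G1", "two_fold"] == ""  # strict inequality

    def test_flagged_up_and_down(self):
        vals, toxv = self._mat([2.5, 3.5], [1.0, 2.0])
        assert tox.fold_change_validation(vals, toxv).loc["G1", "two_fold"] == "up"
        vals, toxv = self._mat([1.0, 2.0], [2.5, 3.5])
        assert tox.fold_change_validation(vals, toxv).loc["G1", "two_fold"] == "down"

    def test_empty_group_rejected(self):
        vals, toxv = self._mat([1.0, 2.0], [])
        with pytest.raises(ConfigError):
            tox.fold_change_validation(vals, toxv)


class TestUnivariableScreen:
    def test_perfect_separation(self):
        row = tox.univariable_screen([4, 5, 6, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert row.auc == pytest.approx(1.0)

    def test_identical_groups(self):
        row = tox.univariable_screen([1, 2, 3, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert row.cohens_d == pytest.approx(0.0)
        assert row.auc == pytest.approx(0.5)

    def test_unit_effect_is_large_separation(self):
        # means 1 vs 0, pooled SD 1 -> d = 1 ("large")
        x = np.array([0.0, 1.0, 2.0])
        row = tox.univariable_screen(np.concatenate([x + 1, x]),
                                     [1, 1, 1, 0, 0, 0])
        assert row.cohens_d == pytest.approx(1.0)
        assert row.d_category == "large"

    def test_auc_equals_pairwise_probability(self):
        """AUC = U/(n1 n0) = P(random toxic > random non-toxic), ties half."""
        rng = np.random.default_rng(6)
        for _ in range(10):
            vals = rng.integers(0, 6, size=12).astype(float)  # ties likely
            y = np.array([1] * 5 + [0] * 7)
            row = tox.univariable_screen(vals, y)
            pos, neg = vals[y == 1], vals[y == 0]
            brute = np.mean([(p > q) + 0.5 * (p == q)
                             for p, q in itertools.product(pos, neg)])
            assert row.auc == pytest.approx(brute, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ConfigError):
            tox.univariable_screen([1, 2, 3], [1, 1, 1])


class TestBootstrapAucCi:
    def test_perfect_separation_ci(self):
        vals = np.array([5.0, 6, 7, 1, 2, 3])
        y = np.array([1, 1, 1, 0, 0, 0])
        lo, hi = tox.bootstrap_auc_ci(vals, y, B=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_metadata_default_B(self):
        rng = np.random.default_rng(1)
        screen = tox.toxicity_screen(
            {"t0": pd.DataFrame({"F1": rng.normal(0, 1, 12)},
                                index=[f"P{i}" for i in range(12)])},
            pd.Series([1] * 6 + [0] * 6, index=[f"P{i}" for i in range(12)]),
            bootstrap_B=2000, seed=0,
        )
        assert (screen["bootstrap_B"] == 2000).all()
        assert (screen["auc_ci_low"] <= screen["auc_ci_high"]).all()


class TestLogisticOr:
    def test_binary_predictor_matches_cross_product(self):
        # counts [[6,2],[2,6]]: x=0 -> 6 non/2 toxic, x=1 -> 2 non/6 toxic
        x = np.array([0] * 8 + [1] * 8, dtype=float)
        y = np.array([0] * 6 + [1] * 2 + [0] * 2 + [1] * 6)
        res = tox.logistic_or(x, y)
        assert res.or_per_log2 == pytest.approx(9.0, rel=1e-6)

    def test_halving_by_rescaling(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 40)
        y = (x + rng.normal(0, 1, 40) > 0).astype(int)
        r1 = tox.logistic_or(x, y)
        r2 = tox.logistic_or(2 * x, y)
        assert r2.slope == pytest.approx(r1.slope / 2, rel=1e-6)

    def test_perfect_separation_flagged(self):
        x = np.array([1.0, 2, 3, 10, 11, 12])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(UserWarning, match="separation"):
            res = tox.logistic_or(x, y)
        assert res.separable


def test_biomarker_table_assembly():
    rng = np.random.default_rng(5)
    n_prot, n_samp = 40, 20
    W = pd.DataFrame({"F1": rng.normal(0, 1, n_prot)},
                     index=[f"G{i:02d}" for i in range(n_prot)])
    vals = pd.DataFrame(rng.normal(0, 1, (n_prot, n_samp)), index=W.index,
                        columns=[f"s{i}" for i in range(n_samp)])
    toxv = pd.Series([1] * 11 + [0] * 9, index=vals.columns)
    table = tox.biomarker_table(W, "F1", vals, toxv, fraction=0.1, perm_B=200,
                                seed=0)
    assert len(table) == 4  # ceil(0.1 * 40)
    assert {"loading", "perm_p", "log2_fc", "or_per_log2", "auc"} <= set(table.columns)
    assert ((table["perm_p"] > 0) & (table["perm_p"] <= 1)).all()
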