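import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_zscaled
from matreotype import (InputError, RiskSignature, elastic_net_select,
                        firth_log_odds, matrix_risk_score, partition_cohort,
                        refine_minimal_signature, roc_auc)
from matreotype.risk import _enet_logistic_path, _firth_fit


def _meta(n_tumor, n_non):
    ids = [f"t{i}" for i in range(n_tumor)] + [f"n{i}" for i in range(n_non)]
    return pd.DataFrame({
        "sample_id": ids,
        "tissue_class": ["tumor"] * n_tumor + ["non_tumor"] * n_non,
    }).set_index("sample_id", drop=False)


def _labels(n_tumor, n_non, samples):
    return pd.Series(["tumor"] * n_tumor + ["non_tumor"] * n_non,
                     index=samples)


class TestPartition:
    def test_stratification_arithmetic(self):
        train, test = partition_cohort(_meta(100, 20), 0.8, seed=0)
        assert len(train) == 96 and len(test) == 24
        assert sum(s.startswith("t") for s in train) == 80
        assert sum(s.startswith("n") for s in train) == 16

    def test_deterministic_and_disjoint(self):
        a = partition_cohort(_meta(30, 10), 0.8, seed=3)
        b = partition_cohort(_meta(30, 10), 0.8, seed=3)
        assert a == b
        assert not set(a[0]) & set(a[1])
        assert sorted(a[0] + a[1]) == sorted(_meta(30, 10)["sample_id"])

    def test_proportions_exact_across_many_seeds(self):
        meta = _meta(37, 13)
        for seed in range(200):
            train, _ = partition_cohort(meta, 0.8, seed=seed)
            assert sum(s.startswith("t") for s in train) == 30  # round(29.6)
            assert sum(s.startswith("n") for s in train) == 10  # round(10.4)

    def test_invalid_fraction(self):
        with pytest.raises(InputError):
            partition_cohort(_meta(10, 10), 1.2, seed=0)


class TestElasticNet:
    def test_lambda_max_zeroes_all_coefficients(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((40, 30))
        y = np.r_[np.ones(20), np.zeros(20)]
        lam_max = np.max(np.abs(x.T @ (y - y.mean()))) / (len(y) * 0.5)
        betas, _ = _enet_logistic_path(
            np.ascontiguousarray(x.T), y, np.array([lam_max]), 0.5)
        assert np.all(betas[0] == 0.0)

    def test_single_separating_gene_selected(self):
        rng = np.random.default_rng(1)
        n = 60
        noise = rng.standard_normal((29, n))
        informative = np.r_[np.full(n // 2, 2.0), np.full(n // 2, -2.0)]
        informative += 0.05 * rng.standard_normal(n)
        z = make_zscaled(np.vstack([informative, noise]),
                         genes=["HIT"] + [f"g{i}" for i in range(29)])
        classes = _labels(n // 2, n // 2, z.sample_ids)
        sel = elastic_net_select(z, classes, folds=5, seed=1, n_lambda=50)
        assert "HIT" in sel["selected_genes"]
        assert len(sel["selected_genes"]) <= 3

    def test_lambda_1se_not_smaller_than_lambda_min(self):
        rng = np.random.default_rng(2)
        z = make_zscaled(rng.standard_normal((50, 60)))
        y = _labels(30, 30, z.sample_ids)
        sel = elastic_net_select(z, y, folds=5, seed=2, n_lambda=40)
        assert sel["lambda_1se"] >= sel["lambda_min"]


class TestFirth:
    def test_separable_fixture_matches_grid_search(self):
        """Complete separation: the Firth estimate stays finite and matches a
        brute-force maximization of the penalized likelihood to 1e-4."""
        x = np.column_stack([np.ones(4), [-1.0, -1.0, 1.0, 1.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        beta = _firth_fit(x, y)

        def penalized(b1):
            eta = x[:, 1] * b1
            ll = np.sum(y * eta - np.logaddexp(0.0, eta))
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            info = x.T @ (x * w[:, None])
            return ll + 0.5 * np.linalg.slogdet(info)[1]

        grid = np.linspace(0.01, 5.0, 50001)
        best = grid[np.argmax([penalized(b) for b in grid])]
        assert np.isfinite(beta).all()
        assert beta[1] == pytest.approx(best, abs=1e-4)

    def test_null_gene_has_small_coefficient(self):
        rng = np.random.default_rng(3)
        z = make_zscaled(rng.standard_normal((1, 4000)))
        y = _labels(2000, 2000, z.sample_ids)
        sig = firth_log_odds(z, y)
        assert abs(sig.beta[0]) < 0.05

    def test_recovers_generative_log_odds(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.standard_normal(n)
        p = 1.0 / (1.0 + np.exp(-x))  # true log-odds coefficient 1.0
        y_raw = (rng.random(n) < p)
        z = make_zscaled(x[None, :])
        y = pd.Series(np.where(y_raw, "tumor", "non_tumor"),
                      index=z.sample_ids)
        sig = firth_log_odds(z, y)
        assert 0.8 <= sig.beta[0] <= 1.2

    def test_per_gene_mode_matches_univariate_fits(self):
        rng = np.random.default_rng(5)
        z = make_zscaled(rng.standard_normal((3, 200)))
        y = _labels(100, 100, z.sample_ids)
        joint = firth_log_odds(z, y, mode="per_gene")
        for i, g in enumerate(z.gene_ids):
            single = firth_log_odds(z.subset_genes([g]), y, mode="per_gene")
            assert joint.beta[i] == pytest.approx(single.beta[0], abs=1e-8)


class TestRiskScore:
    def test_hand_computed_toys(self):
        z = make_zscaled(np.array([[1.0], [-1.0], [2.0]]),
                         genes=["A", "B", "C"])
        sig = RiskSignature(["A", "B", "C"], [0.5, -0.25, 1.0])
        assert matrix_risk_score(z, sig).iloc[0] == pytest.approx(2.75)
        z1 = make_zscaled(np.array([[1.0]]), genes=["A"])
        sig1 = RiskSignature(["A"], [np.log(2.0)])
        assert matrix_risk_score(z1, sig1).iloc[0] == pytest.approx(0.6931, abs=1e-4)

    def test_zero_z_gives_zero_score(self):
        z = make_zscaled(np.zeros((4, 3)))
        sig = RiskSignature(z.gene_ids, [1.0, -2.0, 0.5, 3.0])
        assert (matrix_risk_score(z, sig) == 0.0).all()

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(6)
        z = make_zscaled(rng.standard_normal((5, 8)))
        beta = rng.standard_normal(5)
        s1 = matrix_risk_score(z, RiskSignature(z.gene_ids, beta))
        s3 = matrix_risk_score(z, RiskSignature(z.gene_ids, 3.0 * beta))
        np.testing.assert_allclose(3.0 * s1, s3, atol=1e-12)

    def test_missing_gene_listed(self):
        z = make_zscaled(np.zeros((2, 2)), genes=["A", "B"])
        with pytest.raises(InputError, match="MISSING"):
            matrix_risk_score(z, RiskSignature(["A", "MISSING"], [1.0, 1.0]))


class TestRoc:
    def test_brute_force_pair_counting(self):
        rng = np.random.default_rng(7)
        scores = pd.Series(rng.choice(np.linspace(0, 1, 10), size=40),
                           index=[f"s{i}" for i in range(40)])
        classes = pd.Series(rng.choice(["tumor", "non_tumor"], size=40,
                                       p=[0.4, 0.6]), index=scores.index)
        pos = scores[classes == "tumor"].to_numpy()
        neg = scores[classes == "non_tumor"].to_numpy()
        wins = sum((p > n) + 0.5 * (p == n)
                   for p, n in itertools.product(pos, neg))
        expected = wins / (len(pos) * len(neg))
        assert roc_auc(scores, classes).auc == pytest.approx(expected, abs=1e-12)

    def test_known_small_example(self):
        scores = pd.Series([0.1, 0.4, 0.35, 0.8], index=list("abcd"))
        classes = pd.Series(["non_tumor", "non_tumor", "tumor", "tumor"],
                            index=list("abcd"))
        roc = roc_auc(scores, classes)
        assert roc.auc == pytest.approx(0.75)
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.trapezoid(roc.tpr, roc.fpr) == pytest.approx(roc.auc)

    def test_extremes(self):
        idx = list("abcdef")
        classes = pd.Series(["tumor"] * 3 + ["non_tumor"] * 3, index=idx)
        perfect = pd.Series([3.0, 2.5, 2.0, 1.0, 0.5, 0.1], index=idx)
        assert roc_auc(perfect, classes).auc == 1.0
        ties = pd.Series([1.0] * 6, index=idx)
        assert roc_auc(ties, classes).auc == 0.5

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        scores = pd.Series(rng.standard_normal(60),
                           index=[f"s{i}" for i in range(60)])
        classes = pd.Series(["tumor"] * 30 + ["non_tumor"] * 30,
                            index=scores.index)
        a = roc_auc(scores, classes).auc
        b = roc_auc(np.exp(scores / 3.0), classes).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestRefinement:
    def test_planted_pair_found(self):
        # P1 and P2 share a large common nuisance component that cancels in
        # the joint fit, so only the pair (not either gene alone, nor a pair
        # with a noise gene) separates the classes well.
        rng = np.random.default_rng(9)
        n = 80
        y_num = np.r_[np.ones(40), np.zeros(40)]
        h = (y_num - 0.5) * 2.0
        nuisance = rng.normal(0.0, 2.0, n)
        signal = np.vstack([h + nuisance, h - nuisance])
        signal += 0.1 * rng.standard_normal((2, n))
        noise = rng.standard_normal((4, n))
        z = make_zscaled(np.vstack([signal, noise]),
                         genes=["P1", "P2", "n1", "n2", "n3", "n4"])
        classes = _labels(40, 40, z.sample_ids)
        sig = firth_log_odds(z, classes)
        table = refine_minimal_signature(z, sig, classes, max_size=2, seed=0)
        top_pairs = table[table["size"] == 2].iloc[0]["genes"]
        assert set(top_pairs) == {"P1", "P2"}

    def test_max_size_one_ranks_informative_gene_first(self):
        rng = np.random.default_rng(10)
        n = 60
        y_num = np.r_[np.ones(30), np.zeros(30)]
        x = np.vstack([(y_num - 0.5) * 4 + 0.2 * rng.standard_normal(n),
                       rng.standard_normal((3, n))])
        z = make_zscaled(x, genes=["GOOD", "a", "b", "c"])
        classes = _labels(30, 30, z.sample_ids)
        sig = firth_log_odds(z, classes)
        table = refine_minimal_signature(z, sig, classes, max_size=1, seed=0)
        assert table.iloc[0]["genes"] == ("GOOD",)

    def test_invalid_max_size(self):
        z = make_zscaled(np.zeros((2, 10)) + np.random.default_rng(0).standard_normal((2, 10)))
        sig = RiskSignature(z.gene_ids, [1.0, 1.0])
        classes = _labels(5, 5, z.sample_ids)
        with pytest.raises(InputError):
            refine_minimal_signature(z, sig, classes, max_size=0)
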