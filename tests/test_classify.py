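"""Split plans, elastic-net limits and recovery, metrics, stability path."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ubcsig import classify as cls


class TestSplit:
    def test_balanced_70_30(self):
        ids = np.array([f"s{i}" for i in range(200)], dtype=object)
        labels = np.array(["basal"] * 100 + ["luminal"] * 100)
        plan = cls.split_train_test(ids, labels, 0.7, seed=0)
        assert plan.stratum_counts["basal"] == {"train": 70, "test": 30}
        assert plan.stratum_counts["luminal"] == {"train": 70, "test": 30}
        assert set(plan.train_ids) | set(plan.test_ids) == set(ids)
        assert not set(plan.train_ids) & set(plan.test_ids)

    def test_seed_reproducibility(self):
        ids = np.array([f"s{i}" for i in range(40)], dtype=object)
        labels = np.array(["a", "b"] * 20)
        p1 = cls.split_train_test(ids, labels, seed=5)
        p2 = cls.split_train_test(ids, labels, seed=5)
        assert list(p1.train_ids) == list(p2.train_ids)

    def test_odd_class_size_rounding(self):
        ids = np.array([f"s{i}" for i in range(42)], dtype=object)
        labels = np.array(["a"] * 21 + ["b"] * 21)
        plan = cls.split_train_test(ids, labels, 0.7, seed=1)
        # 21 * 0.7 = 14.7 -> round half up gives 15
        assert plan.stratum_counts["a"]["train"] in (14, 15)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            cls.split_train_test(
                np.array(["a", "b", "c"], dtype=object),
                np.array(["x", "x", "y"]),
            )


class TestElasticNet:
    def test_lambda_zero_matches_unpenalized(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 2))
        eta = X @ np.array([1.5, -1.0])
        y = np.where(rng.uniform(size=80) < 1 / (1 + np.exp(-eta)),
                     "basal", "luminal")
        model = cls.fit_elastic_net_at(X, y, alpha=0.0, lam=1e-7)
        ref = sm.Logit((y == "basal").astype(float), sm.add_constant(X)).fit(
            disp=0
        )
        assert model.intercept == pytest.approx(ref.params[0], abs=1e-4)
        assert np.allclose(model.coefficients, ref.params[1:], atol=1e-4)

    def test_full_shrinkage_above_lambda_max(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 3))
        y = np.where(rng.uniform(size=80) < 0.4, "basal", "luminal")
        model = cls.fit_elastic_net_at(X, y, alpha=1.0, lam=100.0)
        assert np.all(model.coefficients == 0.0)
        p = np.mean(y == "basal")
        assert model.intercept == pytest.approx(np.log(p / (1 - p)), abs=1e-8)

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            cls.fit_elastic_net_logistic(X, np.array(["a"] * 10))

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            cls.fit_elastic_net_logistic(
                np.zeros((10, 0)), np.array(["a", "b"] * 5)
            )

    def test_recovery_on_signal_cohort(self, expr_and_labels):
        """CV-tuned model on a Delta=2 signature separates the test set."""
        X, y = expr_and_labels
        plan = cls.split_train_test(X.index.to_numpy(), y.to_numpy(), seed=3)
        model = cls.fit_elastic_net_logistic(
            X.loc[plan.train_ids], y.loc[plan.train_ids],
            n_folds=10, seed=3, n_lambda=40,
        )
        assert np.sum(model.coefficients != 0) >= 1
        metrics = cls.evaluate_classifier(
            model, X.loc[plan.test_ids], y.loc[plan.test_ids]
        )
        assert metrics.accuracy >= 0.9

    def test_ridge_coefficients_shrink_monotonically(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 4))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=60) > 0, "basal",
                     "luminal")
        norms = []
        for lam in (0.01, 0.1, 1.0, 10.0):
            m = cls.fit_elastic_net_at(X, y, alpha=0.0, lam=lam)
            norms.append(np.linalg.norm(m.coefficients))
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 0.05 * norms[0]


class TestMetrics:
    def _model_for_predictions(self):
        # score gene passes straight through: prediction = sign of the value
        return cls.ElasticNetModel(
            intercept=0.0, coefficients=np.array([1.0]),
            gene_ids=np.array(["score"], dtype=object),
            alpha=1.0, lam=0.0, positive_class="basal",
            classes=("basal", "luminal"),
        )

    def test_perfect_confusion_and_ci(self):
        model = self._model_for_predictions()
        X = np.r_[np.ones(30), -np.ones(30)][:, None]
        y = np.array(["basal"] * 30 + ["luminal"] * 30)
        m = cls.evaluate_classifier(model, X, y)
        assert m.accuracy == 1.0
        assert m.confusion.tolist() == [[30, 0], [0, 30]]
        assert m.accuracy_ci[0] == pytest.approx(0.940, abs=5e-4)
        assert m.accuracy_ci[1] == 1.0

    def test_printed_interval_for_110_of_117(self):
        """Clopper-Pearson CI for 110/117 matches the published-style 0.88-0.98."""
        model = self._model_for_predictions()
        correct = np.r_[np.ones(55), -np.ones(55)]
        wrong = np.r_[-np.ones(4), np.ones(3)]
        X = np.r_[correct, wrong][:, None]
        y = np.array(["basal"] * 55 + ["luminal"] * 55
                     + ["basal"] * 4 + ["luminal"] * 3)
        m = cls.evaluate_classifier(model, X, y)
        assert m.accuracy == pytest.approx(110 / 117, abs=1e-12)
        assert m.accuracy_ci[0] == pytest.approx(0.8806, abs=5e-4)
        assert m.accuracy_ci[1] == pytest.approx(0.9756, abs=5e-4)

    def test_one_sided_predictions_zero_sensitivity(self):
        model = self._model_for_predictions()
        X = -np.ones((20, 1))
        y = np.array(["basal"] * 10 + ["luminal"] * 10)
        m = cls.evaluate_classifier(model, X, y)
        assert m.sensitivity == 0.0 and m.specificity == 1.0

    def test_metrics_recompute_from_confusion(self, expr_and_labels):
        X, y = expr_and_labels
        model = cls.fit_elastic_net_at(X, y, alpha=0.5, lam=0.01)
        m = cls.evaluate_classifier(model, X, y)
        tp, fn = m.confusion[0]
        fp, tn = m.confusion[1]
        assert m.accuracy == pytest.approx((tp + tn) / m.n, abs=1e-12)
        assert m.sensitivity == pytest.approx(tp / (tp + fn), abs=1e-12)
        assert m.specificity == pytest.approx(tn / (tn + fp), abs=1e-12)

    def test_missing_gene_rejected(self):
        model = self._model_for_predictions()
        X = pd.DataFrame({"other": [1.0, 2.0]})
        with pytest.raises(KeyError):
            cls.evaluate_classifier(model, X, np.array(["basal", "luminal"]))


class TestStabilityPath:
    def test_q_bound_worked_example(self):
        # q^2 <= 0.1 * 0.6 * 625 = 37.5 -> q = 6
        assert cls.stability_q(25, 0.8, 0.1) == 6

    def test_q_zero_raises(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 2))
        y = np.array(["a", "b"] * 10)
        with pytest.raises(ValueError, match="q = 0"):
            cls.stability_path_select(X, y, pcer=0.001)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 30))
        X[:, 5] += np.repeat([1.5, 0.0], 30)
        y = np.array(["basal"] * 30 + ["luminal"] * 30)
        r1 = cls.stability_path_select(X, y, n_subsamples=30, seed=9)
        perm = rng.permutation(30)
        r2 = cls.stability_path_select(X[:, perm], y, n_subsamples=30, seed=9,
                                       gene_ids=np.array(
                                           [f"g{i}" for i in perm],
                                           dtype=object))
        f2 = r2.selection_frequency.reindex(r1.selection_frequency.index)
        assert np.allclose(r1.selection_frequency.to_numpy(),
                           f2.to_numpy(), atol=1e-12)

    def test_stable_set_subset_of_selected(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 20))
        y = np.array(["basal", "luminal"] * 30)
        res = cls.stability_path_select(X, y, n_subsamples=25, seed=1)
        freq = res.selection_frequency
        assert set(res.stable_set) <= set(freq.index[freq > 0])
        assert all(freq[g] >= res.pi_threshold for g in res.stable_set)

    def test_signal_genes_dominate_frequencies(self):
        rng = np.random.default_rng(12)
        n, p = 120, 60
        X = rng.normal(size=(n, p))
        y01 = np.repeat([1.0, 0.0], n // 2)
        X[:, :3] += 2.0 * y01[:, None]
        y = np.where(y01 == 1, "basal", "luminal")
        res = cls.stability_path_select(X, y, n_subsamples=50, seed=2)
        freq = res.selection_frequency
        assert freq.iloc[:3].min() > freq.iloc[3:].max()


def test_external_validation_batch_contrast():
    """Training on one pseudo-dataset and scoring on the other: ComBat
    restores the accuracy lost to heterogeneous per-gene batch effects."""
    from ubcsig.combat import combat_adjust
    from ubcsig.normalization import log2_rpkm, tmm_factors
    from ubcsig.synthetic import SyntheticConfig, generate_cohort

    def run(seed, shift, scale):
        c = generate_cohort(
            SyntheticConfig(n_samples=240, n_genes=120, n_signature_genes=13,
                            log2_effect=1.0, n_batches=2, batch_shift=shift,
                            batch_scale=scale, seed=seed)
        )
        expr = log2_rpkm(c.counts, tmm_factors(c.counts))
        ann = c.annotation.set_index("sample_id")
        batch = ann.loc[expr.sample_ids, "batch"].to_numpy()
        y = ann.loc[expr.sample_ids, "subtype"].to_numpy()
        idx = [list(expr.gene_ids).index(g)
               for g in c.truth["signature_genes"]]

        def acc(values):
            X = np.asarray(values).T[:, idx]
            _, m = cls.external_validation(
                X[batch == 0], y[batch == 0], X[batch == 1], y[batch == 1],
                alpha=0.5, lam=0.01,
            )
            return m.accuracy

        adj, _ = combat_adjust(expr, batch)
        return acc(expr.values), acc(adj.values)

    gains, gaps = [], []
    for seed in (31, 32, 33):
        raw, adjusted = run(seed, shift=4.0, scale=2.0)
        nobatch, _ = run(seed, shift=0.0, scale=1.0)
        gains.append(adjusted - raw)
        gaps.append(abs(adjusted - nobatch))
    assert sum(g > 0 for g in gains) >= 2
    assert np.median(gaps) <= 0.05


def test_external_validation_self_consistency(expr_and_labels):
    """Validating a frozen model on its own training set equals resubstitution."""
    X, y = expr_and_labels
    model, metrics = cls.external_validation(
        X, y, X, y, alpha=0.5, lam=0.05
    )
    direct = cls.evaluate_classifier(model, X, y)
    assert metrics.accuracy == direct.accuracy
    assert metrics.confusion.tolist() == direct.confusion.tolist()
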