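import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comosub import (
    ExpressionDataset,
    covariate_anova,
    cross_validated_auc,
    fit_logistic_gd,
    random_gene_baseline,
    roc_auc,
)
from comosub.validate import predict_proba

from _oracles import auc_brute


class TestLogisticGd:
    def test_zero_epochs_means_zero_weights_and_half_probabilities(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = np.r_[np.zeros(10), np.ones(10)]
        w = fit_logistic_gd(X, y, epochs=0)
        np.testing.assert_array_equal(w, np.zeros(4))
        np.testing.assert_array_equal(predict_proba(X, w), np.full(20, 0.5))

    def test_separable_1d_reaches_perfect_training_auc(self):
        X = np.r_[np.linspace(-2, -1, 10), np.linspace(1, 2, 10)].reshape(-1, 1)
        y = np.r_[np.zeros(10), np.ones(10)]
        w = fit_logistic_gd(X, y, learning_rate=0.05, epochs=500)
        assert roc_auc(predict_proba(X, w), y) == 1.0

    def test_class_swapped_mirror_keeps_intercept_zero(self):
        rng = np.random.default_rng(1)
        Xp = rng.normal(1, 1, size=(15, 2))
        X = np.vstack([Xp, -Xp])
        y = np.r_[np.ones(15), np.zeros(15)]
        w = fit_logistic_gd(X, y, epochs=200)
        assert abs(w[0]) < 1e-10

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic_gd(np.ones((4, 1)), np.ones(4))

    def test_non_finite_features_rejected(self):
        X = np.ones((4, 1))
        X[0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            fit_logistic_gd(X, np.r_[0.0, 0, 1, 1])


class TestRocAuc:
    def test_worked_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_all_tied_scores_give_half(self):
        assert roc_auc([0.3] * 6, [0, 1, 0, 1, 0, 1]) == pytest.approx(0.5)

    def test_perfect_ordering_gives_one(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice(np.linspace(0, 1, 7), size=30)  # force ties
        labels = rng.integers(0, 2, size=30)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) == pytest.approx(auc_brute(scores, labels), abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=6, max_size=20))
    def test_invariant_to_monotone_transform(self, raw):
        scores = np.asarray(raw)
        labels = (np.arange(scores.size) % 2).astype(int)
        transformed = 8.0 * scores  # strictly monotone and exact in floats
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc(transformed, labels), abs=1e-12
        )


def _panel_dataset(seed=3, n_per=20, n_ctrl=20, separation=2.0):
    # mostly uninformative genes, so random baseline panels stay weak
    from comosub import SimulationDesign, generate_disease_dataset

    design = SimulationDesign(
        n_genes=600, patients_per_cluster=[n_per] * 3, n_controls=n_ctrl,
        effect_size=separation, module_size=10, shared_candidate_size=10, seed=seed,
    )
    return generate_disease_dataset(design, "A")


class TestCrossValidatedAuc:
    def test_separating_panel_is_nearly_perfect(self):
        ds, truth = _panel_dataset()
        cv = cross_validated_auc(ds, sorted(truth.module_genes()), n_folds=10, seed=0)
        assert cv.mean_auc >= 0.99
        assert cv.mean_auc == pytest.approx(np.mean(cv.per_fold_auc))

    def test_folds_partition_every_sample(self):
        from sklearn.model_selection import StratifiedKFold

        ds, _ = _panel_dataset()
        y = ds.patient_mask.astype(int)
        seen = np.zeros(ds.n_samples, dtype=int)
        for _, test in StratifiedKFold(5, shuffle=True, random_state=0).split(ds.values.T, y):
            seen[test] += 1
        assert (seen == 1).all()

    def test_panel_missing_from_data_rejected(self):
        ds, _ = _panel_dataset()
        with pytest.raises(ValueError, match="panel gene"):
            cross_validated_auc(ds, ["not_a_gene"])

    def test_missing_panel_genes_dropped_with_count(self):
        ds, truth = _panel_dataset()
        panel = sorted(truth.module_genes()) + ["missing1", "missing2"]
        cv = cross_validated_auc(ds, panel, n_folds=5, seed=0)
        assert len(cv.gene_panel) == len(panel) - 2

    def test_seeded_determinism(self):
        ds, truth = _panel_dataset()
        panel = sorted(truth.module_genes())
        a = cross_validated_auc(ds, panel, n_folds=5, seed=9)
        b = cross_validated_auc(ds, panel, n_folds=5, seed=9)
        assert a.per_fold_auc == b.per_fold_auc


class TestRandomGeneBaseline:
    def test_seeded_repetition_identical(self):
        ds, truth = _panel_dataset()
        m1, _ = random_gene_baseline(ds, 10, 3, 0.6, n_folds=3, epochs=50, seed=4)
        m2, _ = random_gene_baseline(ds, 10, 3, 0.6, n_folds=3, epochs=50, seed=4)
        np.testing.assert_array_equal(m1, m2)

    def test_candidate_at_baseline_mean_gives_large_p(self):
        ds, _ = _panel_dataset()
        means, _ = random_gene_baseline(ds, 8, 5, 0.5, n_folds=3, epochs=50, seed=5)
        _, p = random_gene_baseline(ds, 8, 5, float(np.mean(means)), n_folds=3, epochs=50, seed=5)
        assert p > 0.95

    def test_planted_panel_beats_baselines(self):
        ds, truth = _panel_dataset()
        panel = sorted(truth.module_genes())
        cv = cross_validated_auc(ds, panel, n_folds=5, seed=1)
        means, p = random_gene_baseline(
            ds, len(panel), 20, cv.mean_auc, n_folds=5, epochs=200, seed=2
        )
        assert cv.mean_auc > means.max()
        assert p < 0.01

    def test_oversized_panel_rejected(self):
        ds, _ = _panel_dataset()
        with pytest.raises(ValueError, match="panel_size"):
            random_gene_baseline(ds, ds.n_genes + 1, 3, 0.5)


class TestCovariateAnova:
    def test_copied_groups_are_null(self):
        g = [1.0, 2.0, 3.0]
        F, p = covariate_anova(np.r_[g, g], np.r_[[1] * 3, [2] * 3])
        assert F == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_worked_example(self):
        # groups (1,2,3) and (11,12,13): SSB = 150 with 1 df, MSW = 1,
        # so F = 150 and p = P(F_{1,4} >= 150) ~ 2.55e-4
        F, p = covariate_anova(
            np.r_[1.0, 2, 3, 11, 12, 13], np.r_[[1] * 3, [2] * 3]
        )
        assert F == pytest.approx(150.0, abs=1e-9)
        assert p == pytest.approx(2.552e-4, abs=5e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reference_implementation(self, seed):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(seed)
        cov = rng.normal(60, 10, size=40)
        clusters = rng.integers(1, 4, size=40)
        while min(np.bincount(clusters)[1:]) < 2:
            clusters = rng.integers(1, 4, size=40)
        F, p = covariate_anova(cov, clusters)
        Fr, pr = f_oneway(*[cov[clusters == c] for c in np.unique(clusters)])
        assert F == pytest.approx(float(Fr), abs=1e-10)
        assert p == pytest.approx(float(pr), abs=1e-10)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError, match="ANOVA"):
            covariate_anova([1.0, 2.0, 3.0], [1, 1, 2])
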