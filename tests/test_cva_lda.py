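"""Discriminant core: F-values, the canonical axis, accuracy, LOOCV."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from respanel import (
    DomainError,
    SimulationConfig,
    canonical_scores,
    f_value,
    fit_cva,
    loocv,
    predict,
    resubstitution_accuracy,
    simulate_expression_cohort,
)
from respanel.datamodel_io import NONRESPONDER, RESPONDER, ExpressionMatrix

from conftest import matrix_from_rows, two_group_labels


class TestFValue:
    def test_matches_direct_anova_arithmetic(self):
        m = matrix_from_rows({"g": [1, 2, 3, 4, 5, 6]})
        fv = f_value(m, two_group_labels(3, 3), "g")
        assert fv.f_value == pytest.approx(13.5)  # SSB 13.5 / (SSW 4 / 4)

    def test_agrees_with_scipy_f_oneway(self, rng):
        values = rng.normal(loc=10.0, size=9)
        m = matrix_from_rows({"g": list(values)})
        fv = f_value(m, two_group_labels(4, 5), "g")
        ref = stats.f_oneway(values[:4], values[4:])
        assert fv.f_value == pytest.approx(ref.statistic)

    def test_equal_group_means_give_zero(self):
        m = matrix_from_rows({"g": [1.0, 3.0, 2.0, 1.0, 3.0, 2.0]})
        assert f_value(m, two_group_labels(3, 3), "g").f_value == pytest.approx(0.0)

    def test_zero_within_variance_gives_infinity(self):
        m = matrix_from_rows({"g": [5.0, 5.0, 9.0, 9.0]})
        assert math.isinf(f_value(m, two_group_labels(2, 2), "g").f_value)

    def test_single_sample_group_rejected(self):
        m = matrix_from_rows({"g": [1.0, 2.0, 3.0]})
        with pytest.raises(DomainError):
            f_value(m, two_group_labels(1, 2), "g")


class TestFitCva:
    def test_separable_1d_groups_classified_perfectly(self):
        m = matrix_from_rows({"g": [0.0, 0.1, 10.0, 10.1]})
        labels = two_group_labels(2, 2)
        assert resubstitution_accuracy(m, labels) == 100.0

    def test_label_swap_flips_axis_and_predictions(self, separable_matrix):
        labels = two_group_labels(3, 3)
        swapped = [NONRESPONDER if lab == RESPONDER else RESPONDER for lab in labels]
        model = fit_cva(separable_matrix, labels)
        model_sw = fit_cva(separable_matrix, swapped)
        np.testing.assert_allclose(model.canonical_axis, -model_sw.canonical_axis,
                                   rtol=1e-9)
        preds = predict(model, separable_matrix)
        preds_sw = predict(model_sw, separable_matrix)
        assert all(a != b for a, b in zip(preds, preds_sw))

    def test_axis_matches_two_gene_eigen_oracle(self):
        """Fisher direction vs explicit eigenanalysis of W^-1 B on a 2-gene toy."""
        m = matrix_from_rows({
            "g1": [1.0, 2.0, 3.0, 4.0, 6.0, 5.0],
            "g2": [2.0, 1.5, 2.5, 5.0, 4.0, 6.0],
        })
        labels = two_group_labels(3, 3)
        model = fit_cva(m, labels, ridge=0.0)
        X = m.data.to_numpy().T
        mu1, mu0 = X[:3].mean(0), X[3:].mean(0)
        within = (np.cov(X[:3].T, bias=False) * 2 + np.cov(X[3:].T, bias=False) * 2) / 4
        between = np.outer(mu1 - mu0, mu1 - mu0) * (3 * 3) / 6
        eigvals, eigvecs = np.linalg.eig(np.linalg.solve(within, between))
        lead = eigvecs[:, np.argmax(eigvals.real)].real
        cos = abs(lead @ model.canonical_axis) / (
            np.linalg.norm(lead) * np.linalg.norm(model.canonical_axis))
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_fisher_direction_oracle_random_toys(self, rng):
        """Axis is proportional to S_W^-1 (mu_R - mu_N) on non-singular data."""
        for _ in range(10):
            X = rng.normal(size=(12, 3))
            X[:6] += [2.0, -1.0, 0.5]
            m = ExpressionMatrix(pd.DataFrame(
                X.T + 10.0, index=["a", "b", "c"],
                columns=[f"s{i}" for i in range(12)]))
            labels = two_group_labels(6, 6)
            model = fit_cva(m, labels, ridge=0.0)
            Y = m.data.to_numpy().T
            mu1, mu0 = Y[:6].mean(0), Y[6:].mean(0)
            centered = np.vstack([Y[:6] - mu1, Y[6:] - mu0])
            s_w = centered.T @ centered / 10
            oracle = np.linalg.solve(s_w, mu1 - mu0)
            np.testing.assert_allclose(model.canonical_axis, oracle, rtol=1e-8)

    def test_single_class_rejected(self, separable_matrix):
        with pytest.raises(DomainError):
            fit_cva(separable_matrix, [RESPONDER] * 6)


class TestCanonicalScores:
    def test_centroid_scores_zero(self, separable_matrix, separable_labels):
        model = fit_cva(separable_matrix, separable_labels)
        centroid = separable_matrix.data.mean(axis=1)
        m = ExpressionMatrix(centroid.to_frame("c"))
        assert canonical_scores(model, m)["c"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_shift_leaves_scores_unchanged(self, separable_matrix,
                                                    separable_labels):
        shifted = ExpressionMatrix(separable_matrix.data + 100.0)
        s1 = canonical_scores(fit_cva(separable_matrix, separable_labels),
                              separable_matrix)
        s2 = canonical_scores(fit_cva(shifted, separable_labels), shifted)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), rtol=1e-6, atol=1e-8)

    def test_scores_match_dot_product_oracle(self, separable_matrix, separable_labels):
        model = fit_cva(separable_matrix, separable_labels)
        X = separable_matrix.data.to_numpy().T
        expected = (X - X.mean(0)) @ model.canonical_axis
        np.testing.assert_allclose(canonical_scores(model, separable_matrix).to_numpy(),
                                   expected)

    def test_gene_order_invariance(self, separable_matrix, separable_labels):
        model = fit_cva(separable_matrix, separable_labels)
        reordered = separable_matrix.subset_genes(["gB", "gA"])
        np.testing.assert_allclose(canonical_scores(model, separable_matrix).to_numpy(),
                                   canonical_scores(model, reordered).to_numpy())

    def test_missing_model_gene_rejected(self, separable_matrix, separable_labels):
        model = fit_cva(separable_matrix, separable_labels)
        with pytest.raises(DomainError):
            canonical_scores(model, separable_matrix.subset_genes(["gA"]))


class TestAccuracy:
    def test_permuted_labels_give_near_majority_accuracy(self, rng):
        """With labels shuffled, resubstitution accuracy on few genes and
        many samples hovers near the majority-class rate."""
        cohort = simulate_expression_cohort(SimulationConfig(
            n_genes=4, n_informative=2, n_responders=150, n_nonresponders=100, seed=17))
        labels = list(cohort.labels)
        accs = []
        for _ in range(20):
            rng.shuffle(labels)
            accs.append(resubstitution_accuracy(cohort.expression, labels))
        assert abs(np.mean(accs) - 60.0) < 8.0  # majority rate 150/250

    def test_one_mislabeled_point_costs_one_of_twenty(self):
        values = list(np.linspace(0, 1, 10)) + list(np.linspace(10, 11, 10))
        values[0] = 10.5  # a 'responder' deep inside the other class
        m = matrix_from_rows({"g": values})
        assert resubstitution_accuracy(m, two_group_labels(10, 10)) == 95.0

    def test_scale_equivariance(self, separable_matrix, separable_labels):
        scaled = separable_matrix.data.copy()
        scaled.loc["gA"] *= 1000.0
        preds = predict(fit_cva(separable_matrix, separable_labels), separable_matrix)
        preds_scaled = predict(fit_cva(ExpressionMatrix(scaled), separable_labels),
                               ExpressionMatrix(scaled))
        assert preds == preds_scaled

    def test_deterministic_bit_for_bit(self, separable_matrix, separable_labels):
        m1 = fit_cva(separable_matrix, separable_labels)
        m2 = fit_cva(separable_matrix, separable_labels)
        assert m1.threshold == m2.threshold
        assert np.array_equal(m1.canonical_axis, m2.canonical_axis)
        assert np.array_equal(m1.pooled_within_scatter, m2.pooled_within_scatter)


class TestLoocv:
    def test_separated_1d_groups_fully_cross_validate(self):
        m = matrix_from_rows({"g": [0, 1, 2, 1.5, 0.5, 100, 101, 102, 100.5, 101.5]})
        acc, scores = loocv(m, two_group_labels(5, 5))
        assert acc == 100.0
        assert len(scores) == 10
        # responders (low values, axis oriented responder-high) score above others
        assert scores.iloc[:5].min() > scores.iloc[5:].max() or \
               scores.iloc[:5].max() < scores.iloc[5:].min()

    def test_null_data_accuracy_near_majority_rate(self):
        """Two identical distributions: LOOCV accuracy is chance-like.

        Leave-one-out slightly depletes the held-out sample's own class in
        training, which biases null accuracy below the majority rate; the
        band is wide accordingly but excludes genuine signal.
        """
        accs = []
        for i in range(30):
            cohort = simulate_expression_cohort(SimulationConfig(
                n_genes=5, n_informative=0, effect_size=0.0,
                n_responders=13, n_nonresponders=7, seed=7000 + i))
            accs.append(loocv(cohort.expression, cohort.labels)[0])
        assert abs(np.mean(accs) - 65.0) < 20.0
        assert np.mean(accs) < 85.0

    def test_loocv_never_beats_resubstitution_on_typical_cohorts(self):
        wins = 0
        for i in range(100):
            cohort = simulate_expression_cohort(SimulationConfig(
                n_genes=8, n_informative=4, effect_size=1.0,
                n_responders=13, n_nonresponders=7, seed=3000 + i))
            resub = resubstitution_accuracy(cohort.expression, cohort.labels)
            cv = loocv(cohort.expression, cohort.labels)[0]
            wins += cv <= resub
        assert wins >= 95

    def test_too_few_samples_rejected(self):
        m = matrix_from_rows({"g": [1.0, 2.0]})
        with pytest.raises(DomainError):
            loocv(m, two_group_labels(1, 1))
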