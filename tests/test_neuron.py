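"""The sigmoid neuron: initialization, forward, loss, gradients, training."""

import numpy as np
import pandas as pd
import pytest

from ieaan import (
    ContractError,
    DegenerateInputError,
    FeatureTable,
    LabelSet,
    NeuronModel,
    auc_init,
    enrichment_score,
    forward,
    gradient,
    loss,
    rank_genes,
    train,
)


def make_features(matrix, genes=None, names=None) -> FeatureTable:
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    names = names or [f"f{i}" for i in range(matrix.shape[1])]
    return FeatureTable(pd.DataFrame(matrix, index=genes, columns=names))


def make_labels(values, genes=None) -> LabelSet:
    genes = genes or [f"g{i}" for i in range(len(values))]
    return LabelSet(pd.Series(values, index=genes, dtype=int))


def numeric_gradient(model, features, labels, h=1e-6):
    """Central finite differences on the loss, parameter by parameter."""
    dW = np.zeros_like(model.weights)
    for i in range(len(model.weights)):
        up, down = model.copy(), model.copy()
        up.weights[i] += h
        down.weights[i] -= h
        dW[i] = (loss(up, features, labels) - loss(down, features, labels)) / (2 * h)
    up, down = model.copy(), model.copy()
    up.bias += h
    down.bias -= h
    db = (loss(up, features, labels) - loss(down, features, labels)) / (2 * h)
    return dW, db


class TestAucInit:
    def test_rule_on_constructed_aucs(self):
        # f0 separates 3/4 pairs (AUC .75), f1 is anti-correlated (AUC 0),
        # f2 is constant (AUC .5): only f0 gets its AUC as weight
        X = np.array([
            [0.9, 0.1, 1.0],
            [0.8, 0.9, 1.0],
            [0.7, 0.2, 1.0],
            [0.1, 0.8, 1.0],
        ])
        labels = make_labels([1, -1, 1, -1])
        model = auc_init(make_features(X), labels)
        assert model.weights == pytest.approx([0.75, 0.0, 0.0])
        assert model.bias == 0.0

    def test_perfect_and_anticorrelated_features(self):
        X = np.array([[2.0, 1.0], [3.0, 2.0], [1.0, 3.0], [0.5, 4.0]])
        labels = make_labels([1, 1, -1, -1])
        model = auc_init(make_features(X), labels)
        assert model.weights[0] == 1.0   # perfectly separating feature
        assert model.weights[1] == 0.0   # AUC 0 -> else branch

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            auc_init(make_features([[1.0], [2.0]]), make_labels([1, 1]))


class TestForward:
    def test_zero_model_outputs_half(self):
        m = NeuronModel(np.zeros(3), 0.0, ("a", "b", "c"))
        assert forward(m, np.array([5.0, -2.0, 7.0])) == 0.5

    def test_sigma_of_two(self):
        m = NeuronModel(np.ones(2), 0.0, ("a", "b"))
        assert forward(m, np.array([1.0, 1.0])) == pytest.approx(0.880797, abs=1e-6)

    def test_saturation_without_overflow(self):
        m = NeuronModel(np.zeros(1), 1000.0, ("a",))
        assert forward(m, np.array([0.0])) == pytest.approx(1.0, abs=1e-15)
        m.bias = -1000.0
        out = forward(m, np.array([0.0]))
        assert 0.0 <= out < 1e-300 or out == 0.0

    def test_dimension_mismatch_rejected(self):
        m = NeuronModel(np.zeros(2), 0.0, ("a", "b"))
        with pytest.raises(ContractError):
            forward(m, np.array([1.0, 2.0, 3.0]))


class TestLoss:
    def test_worked_contributions(self):
        # y=-1 vs yhat=0.5 contributes 0.5*(1.5)^2 = 1.125; zero-weight model
        # predicts 0.5 everywhere
        m = NeuronModel(np.zeros(1), 0.0, ("f0",))
        ft = make_features([[1.0]])
        assert loss(m, ft, make_labels([-1])) == pytest.approx(1.125)
        # two genes: 0.5*(1-0.5)^2 + 0.5*(-1-0.5)^2 = 0.125 + 1.125
        ft2 = make_features([[1.0], [1.0]])
        assert loss(m, ft2, make_labels([1, -1])) == pytest.approx(1.25)


class TestGradient:
    def test_single_gene_hand_example(self):
        # y=1, W=0, b=0, x=(1): yhat=0.5, sigma'=0.25 -> dw = db = -0.125
        m = NeuronModel(np.zeros(1), 0.0, ("f0",))
        dW, db = gradient(m, make_features([[1.0]]), make_labels([1]))
        assert dW == pytest.approx([-0.125])
        assert db == pytest.approx(-0.125)

    def test_zero_feature_column_gives_zero_weight_gradient(self):
        m = NeuronModel(np.array([0.3, 0.1]), 0.2, ("f0", "f1"))
        ft = make_features([[1.0, 0.0], [2.0, 0.0], [0.5, 0.0]])
        dW, _ = gradient(m, ft, make_labels([1, -1, 1]))
        assert dW[1] == 0.0

    def test_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n, d = 6, 3
            ft = make_features(rng.uniform(1, 4, size=(n, d)))
            labels = make_labels([1, 1, 1, -1, -1, -1])
            m = NeuronModel(rng.normal(0, 0.5, d), float(rng.normal()), tuple(ft.contrast_names))
            dW, db = gradient(m, ft, labels)
            ndW, ndb = numeric_gradient(m, ft, labels)
            assert dW == pytest.approx(ndW, abs=1e-6)
            assert db == pytest.approx(ndb, abs=1e-6)


class TestTrain:
    def test_one_step_hand_example(self):
        m = NeuronModel(np.zeros(1), 0.0, ("f0",))
        trained, state = train(m, make_features([[1.0]]), make_labels([1]),
                               eta=1.0, max_iter=1, tol=0.0)
        assert trained.weights == pytest.approx([0.125])
        assert trained.bias == pytest.approx(0.125)
        assert m.weights[0] == 0.0  # input model untouched

    def test_tol_infinity_stops_after_one_iteration(self):
        m = NeuronModel(np.zeros(2), 0.0, ("f0", "f1"))
        ft = make_features([[1.0, 2.0], [2.0, 1.0]])
        _, state = train(m, ft, make_labels([1, -1]), eta=0.01, max_iter=100, tol=np.inf)
        assert state.n_iter == 1
        assert state.stop_reason == "tol_reached"
        assert len(state.loss_history) == state.n_iter + 1

    def test_loss_non_increasing_with_small_eta_on_unit_features(self):
        rng = np.random.default_rng(9)
        ft = make_features(rng.uniform(0, 1, size=(20, 4)))
        labels = make_labels([1] * 10 + [-1] * 10)
        m = NeuronModel(rng.normal(0, 0.3, 4), 0.0, tuple(ft.contrast_names))
        _, state = train(m, ft, labels, eta=1e-4, max_iter=100, tol=0.0)
        diffs = np.diff(state.loss_history)
        assert (diffs <= 1e-15).all()


class TestEnrichment:
    def test_worked_examples(self):
        ft = make_features([[2.0, 100.0], [3.0, 1.0]])
        m = NeuronModel(np.array([0.6, 0.0]), 0.0, tuple(ft.contrast_names))
        assert enrichment_score(m, ft).tolist() == pytest.approx([1.2, 1.8])
        m2 = NeuronModel(np.array([0.5, 0.5]), 0.0, tuple(ft.contrast_names))
        assert enrichment_score(m2, ft)["g1"] == pytest.approx(2.0)

    def test_zero_weights_score_zero_for_all(self):
        ft = make_features([[5.0], [7.0]])
        m = NeuronModel(np.zeros(1), 3.0, ("f0",))
        assert (enrichment_score(m, ft) == 0.0).all()

    def test_ranking_invariant_to_bias(self):
        rng = np.random.default_rng(1)
        ft = make_features(rng.uniform(1, 5, size=(10, 3)))
        m = NeuronModel(rng.uniform(0, 1, 3), 0.0, tuple(ft.contrast_names))
        shifted = m.copy()
        shifted.bias += 123.4
        assert rank_genes(m, ft).gene_ids == rank_genes(shifted, ft).gene_ids

    def test_scores_all_genes_even_unlabeled(self):
        # g2 carries no label yet still receives an enrichment score
        ft = make_features([[1.0], [2.0], [3.0]])
        m = auc_init(ft, make_labels([1, -1], genes=["g0", "g1"]))
        scores = enrichment_score(m, ft)
        assert list(scores.index) == ["g0", "g1", "g2"]
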