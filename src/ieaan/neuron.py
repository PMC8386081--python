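"""The integrative artificial neuron.

A single sigmoid unit integrates a gene's differential-expression
scores.  For gene g with feature vector x_g = (p_g1, ..., p_gn):

    z_g    = Σ_i w_i p_gi + b
    ŷ_g    = σ(z_g) = 1 / (1 + exp(-z_g))
    loss   = Σ_g ½ (y_g - ŷ_g)²          over labeled genes, y_g ∈ {+1, -1}
    Δw_i   = -Σ_g (y_g - ŷ_g) σ'(z_g) p_gi
    Δb     = -Σ_g (y_g - ŷ_g) σ'(z_g)
    update = θ ← θ - η Δθ               (full-batch gradient descent)

After training, every gene — labeled or not — receives the integrative
enrichment score E_g = Σ_i w_i p_gi (bias excluded), and genes are
ranked by E_g descending.

Weights are initialized from each feature's discriminative power: w_i is
preset to the feature's AUC against the labels when that AUC exceeds
0.5, otherwise to 0; the bias starts at 0.

The ±1 targets sit outside the sigmoid's (0,1) range, so the
negative-class loss is bounded below; this is the model's stated design
and the gradient formulas hold for any target coding.  A ``targets="01"``
option remaps -1 → 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_io import LabelSet, RankedList
from .errors import ContractError, DegenerateInputError, DivergenceError
from .evaluation import auc_score
from .scoring import FeatureTable

logger = logging.getLogger(__name__)

TARGET_MODES = ("pm1", "01")


@dataclass
class NeuronModel:
    """Weights, bias and learning rate of the single neuron."""

    weights: np.ndarray
    bias: float
    feature_names: tuple[str, ...]
    eta: float = 1e-3

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or len(self.weights) != len(self.feature_names):
            raise ContractError("weights must be one value per feature name")
        if self.eta <= 0:
            raise ContractError("learning rate eta must be > 0")

    def copy(self) -> "NeuronModel":
        return NeuronModel(self.weights.copy(), self.bias, self.feature_names, self.eta)


@dataclass
class TrainingState:
    n_iter: int
    loss_history: list[float]
    converged: bool
    stop_reason: str  # "tol_reached" | "max_iter"


def _design(features: FeatureTable, labels: LabelSet, targets: str = "pm1"):
    """Aligned (X, y, gene order) over the labeled genes."""
    if targets not in TARGET_MODES:
        raise ContractError(f"targets must be one of {TARGET_MODES}")
    if len(labels) == 0:
        raise DegenerateInputError("at least one labeled gene required")
    genes = labels.gene_ids
    X = features.matrix_for(genes)
    y = labels.labels.loc[genes].to_numpy(dtype=float)
    if targets == "01":
        y = (y + 1.0) / 2.0
    return X, y, genes


def _check_alignment(model: NeuronModel, features: FeatureTable) -> None:
    if tuple(features.contrast_names) != model.feature_names:
        raise ContractError(
            f"feature columns {features.contrast_names} do not match model features "
            f"{list(model.feature_names)}"
        )


def auc_init(features: FeatureTable, labels: LabelSet, eta: float = 1e-3) -> NeuronModel:
    """AUC-based weight preset: w_i = AUC_i if AUC_i > 0.5 else 0; b = 0."""
    labels.require_both_classes()
    sub = labels.restrict_to(features.gene_ids)
    if len(sub) != len(labels):
        missing = sorted(set(labels.gene_ids) - set(features.gene_ids))
        raise ContractError(f"labeled genes absent from feature table: {missing[:5]}")
    weights = []
    for name in features.contrast_names:
        a = auc_score(features.table[name], labels)
        weights.append(a if a > 0.5 else 0.0)
    return NeuronModel(np.array(weights), 0.0, tuple(features.contrast_names), eta)


def forward(model: NeuronModel, x: np.ndarray) -> np.ndarray | float:
    """ŷ = σ(Σ w_i p_i + b), overflow-safe for any pre-activation."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != len(model.weights):
        raise ContractError(
            f"feature vector of length {x.shape[-1]} fed to a {len(model.weights)}-weight model"
        )
    z = x @ model.weights + model.bias
    out = expit(z)
    return float(out) if np.ndim(out) == 0 else out


def loss(model: NeuronModel, features: FeatureTable, labels: LabelSet, targets: str = "pm1") -> float:
    """Summed squared-error loss L = Σ_g ½ (y_g − ŷ_g)² over labeled genes."""
    X, y, _ = _design(features, labels, targets)
    _check_alignment(model, features)
    yhat = expit(X @ model.weights + model.bias)
    return float(0.5 * np.square(y - yhat).sum())


def gradient(
    model: NeuronModel, features: FeatureTable, labels: LabelSet, targets: str = "pm1"
) -> tuple[np.ndarray, float]:
    """Analytic (ΔW, Δb); σ'(z) computed as ŷ(1−ŷ)."""
    X, y, _ = _design(features, labels, targets)
    _check_alignment(model, features)
    yhat = expit(X @ model.weights + model.bias)
    resid = (y - yhat) * yhat * (1.0 - yhat)
    dW = -(X.T @ resid)
    db = -float(resid.sum())
    return dW, db


def train(
    model: NeuronModel,
    features: FeatureTable,
    labels: LabelSet,
    eta: float | None = None,
    max_iter: int = 10000,
    tol: float = 1e-8,
    targets: str = "pm1",
) -> tuple[NeuronModel, TrainingState]:
    """Full-batch gradient descent until the loss change falls below tol.

    Iterates θ ← θ − η Δθ; stops when |L(k) − L(k−1)| < tol
    (``tol_reached``) or after ``max_iter`` updates (``max_iter``).
    Returns a new model; the input model is untouched.
    """
    if max_iter < 1:
        raise ContractError("max_iter must be >= 1")
    if tol < 0:
        raise ContractError("tol must be >= 0")
    eta = model.eta if eta is None else eta
    if eta <= 0:
        raise ContractError("eta must be > 0")
    m = model.copy()
    m.eta = eta
    history = [loss(m, features, labels, targets)]
    converged = False
    reason = "max_iter"
    for _ in range(max_iter):
        dW, db = gradient(m, features, labels, targets)
        m.weights = m.weights - eta * dW
        m.bias = m.bias - eta * db
        current = loss(m, features, labels, targets)
        if not math.isfinite(current):
            raise DivergenceError(
                f"non-finite loss after {len(history)} update(s); "
                f"learning rate eta={eta:g} is likely too large"
            )
        history.append(current)
        if abs(history[-1] - history[-2]) < tol:
            converged = True
            reason = "tol_reached"
            break
    state = TrainingState(
        n_iter=len(history) - 1, loss_history=history, converged=converged, stop_reason=reason
    )
    logger.info(
        "training stopped after %d iteration(s) (%s); loss %.6g -> %.6g",
        state.n_iter, reason, history[0], history[-1],
    )
    return m, state


def cross_fit_scores(
    features: FeatureTable,
    labels: LabelSet,
    n_folds: int = 5,
    eta: float = 1e-3,
    max_iter: int = 10000,
    tol: float = 1e-8,
    targets: str = "pm1",
    seed: int = 0,
) -> pd.Series:
    """Out-of-fold enrichment scores for the labeled genes.

    Stratified k-fold: within each class, genes are shuffled (seeded)
    and dealt into folds; for each fold the neuron is AUC-initialized
    and trained on the other folds only, and the held-out genes receive
    that model's enrichment score.  Because no gene's score depends on
    its own label, metrics computed on these scores are free of the
    in-sample selection bias that AUC-thresholded initialization
    introduces (on label-free data, in-sample AUC sits above 0.5; the
    out-of-fold AUC does not).
    """
    labels.require_both_classes()
    if n_folds < 2:
        raise ContractError("n_folds must be >= 2")
    if min(labels.n_pos, labels.n_neg) < n_folds:
        raise DegenerateInputError(
            f"need >= {n_folds} genes per class for {n_folds}-fold stratification"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    folds: dict[str, int] = {}
    for cls in (1, -1):
        genes = sorted(g for g in labels.gene_ids if labels.labels[g] == cls)
        order = rng.permutation(len(genes))
        for pos, idx in enumerate(order):
            folds[genes[idx]] = pos % n_folds
    out: dict[str, float] = {}
    for f in range(n_folds):
        train_genes = [g for g in labels.gene_ids if folds[g] != f]
        test_genes = [g for g in labels.gene_ids if folds[g] == f]
        sub = LabelSet(labels.labels.loc[train_genes].copy())
        model0 = auc_init(features, sub, eta=eta)
        model, _ = train(model0, features, sub, eta=eta, max_iter=max_iter, tol=tol, targets=targets)
        fold_scores = enrichment_score(model, features)
        for g in test_genes:
            out[g] = float(fold_scores[g])
    return pd.Series(out, name="oof_enrichment_score").loc[labels.gene_ids]


def enrichment_score(model: NeuronModel, features: FeatureTable) -> pd.Series:
    """Integrative enrichment score E_g = Σ_i w_i p_gi for every gene.

    The bias is deliberately excluded: it shifts every gene equally and
    would not change the ranking.
    """
    _check_alignment(model, features)
    scores = features.table.to_numpy(dtype=float) @ model.weights
    return pd.Series(scores, index=features.table.index, name="enrichment_score")


def rank_genes(model: NeuronModel, features: FeatureTable) -> RankedList:
    """Genes ranked by descending enrichment score."""
    return RankedList.from_scores(enrichment_score(model, features))


def serialize_model(model: NeuronModel, path) -> None:
    df = pd.DataFrame({"feature_name": model.feature_names, "weight": model.weights})
    df.loc[len(df)] = ["__bias__", model.bias]
    df.to_csv(path, sep="\t", index=False)


def deserialize_model(path, eta: float = 1e-3) -> NeuronModel:
    df = pd.read_csv(path, sep="\t")
    bias_rows = df["feature_name"] == "__bias__"
    bias = float(df.loc[bias_rows, "weight"].iloc[0]) if bias_rows.any() else 0.0
    df = df[~bias_rows]
    return NeuronModel(
        df["weight"].to_numpy(dtype=float), bias, tuple(df["feature_name"].astype(str)), eta
    )
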