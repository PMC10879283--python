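"""Scikit-learn estimator wrapping the parallel embedding network.

:class:`ParallelEmbeddingClassifier` follows the sklearn fit/predict
contract (``get_params``/``set_params``, ``classes_``, trailing
underscore for fitted state) so it composes with sklearn model-selection
utilities. Inputs are harmonized w-score matrices in canonical block
order (thickness 360, cortical volume 360, subcortical volume 15).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_X_y, check_array

from .metrics import confusion, overall_balanced_accuracy
from .network import (
    ParallelNet,
    ParallelNetConfig,
    compute_class_weights,
    concat_config,
    parallel_config,
    single_type_config,
    softmax,
    weighted_cross_entropy,
    weighted_cross_entropy_grad,
)
from .tables import DIAGNOSES

ARCHITECTURES = ("parallel", "concat", "single")


class ParallelEmbeddingClassifier(ClassifierMixin, BaseEstimator):
    """Three-way FTD subtype classifier with multi-type feature fusion.

    Parameters
    ----------
    architecture : {"parallel", "concat", "single"}
        "parallel": two first-level arms (thickness 360 -> 128 -> 32,
        volume 375 -> 128 -> 32) fused through 64 -> 32 -> 3.
        "concat": single stack 735 -> 256 -> 64 -> 32 -> 3 (naive
        concatenation baseline). "single": one arm sized to whatever
        width ``fit`` receives (thickness-only or volume-only ablation).
    lr, weight_decay
        Plain SGD learning rate and L2 weight-decay rate.
    batch_size, max_epochs, patience
        Minibatch size; epoch cap; early-stopping patience on validation
        overall balanced accuracy (only when a validation set is given —
        the checkpoint of the best validation epoch is restored).
    class_weighting : bool
        Use inverse-frequency class weights (mean 1) in the loss.
    dropout : float
        Dropout probability after every hidden layer during training.
    random_state : int
        Seeds parameter initialization, shuffling and dropout masks.

    Attributes
    ----------
    net_ : ParallelNet
        The trained network.
    classes_ : ndarray
        Class labels in encoding order.
    history_ : dict
        Per-epoch training loss and (if applicable) validation balanced
        accuracy.
    best_epoch_ : int
        Epoch whose checkpoint was kept.
    """

    def __init__(
        self,
        architecture: str = "parallel",
        dropout: float = 0.2,
        lr: float = 1e-3,
        weight_decay: float = 1e-5,
        batch_size: int = 32,
        max_epochs: int = 300,
        patience: int = 30,
        class_weighting: bool = True,
        random_state: int = 0,
    ):
        self.architecture = architecture
        self.dropout = dropout
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.class_weighting = class_weighting
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _make_config(self, n_features: int) -> ParallelNetConfig:
        if self.architecture == "parallel":
            if n_features != 735:
                raise ValueError(
                    f"parallel architecture expects 735 inputs, got {n_features}"
                )
            return parallel_config(seed=self.random_state, dropout=self.dropout)
        if self.architecture == "concat":
            if n_features != 735:
                raise ValueError(
                    f"concat architecture expects 735 inputs, got {n_features}"
                )
            return concat_config(seed=self.random_state, dropout=self.dropout)
        if self.architecture == "single":
            return single_type_config(
                n_features, seed=self.random_state, dropout=self.dropout
            )
        raise ValueError(f"unknown architecture {self.architecture!r}")

    def _encode(self, y) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.classes_)}
        return np.array([idx[v] for v in y], dtype=int)

    def fit(self, X, y, X_val=None, y_val=None) -> "ParallelEmbeddingClassifier":
        """Train with SGD on weighted cross entropy.

        When ``X_val``/``y_val`` are given, the per-epoch validation
        overall balanced accuracy drives checkpoint selection and early
        stopping; otherwise the model trains for ``max_epochs`` and
        keeps the final parameters.
        """
        X, y = check_X_y(X, np.asarray(y))
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        yi = self._encode(y)
        self.n_features_in_ = X.shape[1]

        config = self._make_config(X.shape[1])
        net = ParallelNet(config)
        if self.class_weighting and list(self.classes_) == list(DIAGNOSES):
            counts = {c: int((y == c).sum()) for c in self.classes_}
            weights = compute_class_weights(counts)
        elif self.class_weighting:
            counts = np.bincount(yi, minlength=len(self.classes_)).astype(float)
            weights = counts.sum() / counts
            weights = weights / weights.mean()
        else:
            weights = np.ones(len(self.classes_))
        self.class_weights_ = weights

        has_val = X_val is not None and y_val is not None
        if has_val:
            X_val = check_array(X_val)
            yv = self._encode(np.asarray(y_val))

        rng = np.random.default_rng(self.random_state)
        n = len(yi)
        history = {"train_loss": [], "val_balanced_accuracy": []}
        best_ba, best_epoch, best_params = -np.inf, 0, net.get_flat_params()
        since_best = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                b = order[start : start + self.batch_size]
                logits, cache = net.forward(X[b], training=True, rng=rng)
                losses.append(weighted_cross_entropy(logits, yi[b], weights))
                dlogits = weighted_cross_entropy_grad(logits, yi[b], weights)
                grads, _ = net.backward(cache, dlogits)
                net.sgd_step(grads, self.lr, self.weight_decay)
            history["train_loss"].append(float(np.mean(losses)))
            if has_val:
                pred = np.argmax(net.predict_logits(X_val), axis=1)
                ba = overall_balanced_accuracy(
                    confusion(yv, pred, n_classes=len(self.classes_)),
                    skip_empty=True,
                )
                history["val_balanced_accuracy"].append(ba)
                if ba > best_ba:
                    best_ba, best_epoch = ba, epoch
                    best_params = net.get_flat_params()
                    since_best = 0
                else:
                    since_best += 1
                    if since_best >= self.patience:
                        break
        if has_val:
            net.set_flat_params(best_params)
            self.best_epoch_ = best_epoch
            self.best_val_balanced_accuracy_ = float(best_ba)
        else:
            self.best_epoch_ = len(history["train_loss"]) - 1
        self.net_ = net
        self.history_ = history
        return self

    # ------------------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        X = check_array(X)
        return self.net_.predict_logits(X)

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        # np.argmax breaks ties toward the lowest class index
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
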