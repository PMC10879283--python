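"""Two-level multi-type parallel feature-embedding classifier network.

The architecture embeds each morphometric feature type through its own
first-level MLP arm (thickness: 360 inputs; volume: 375 = 360 cortical +
15 subcortical inputs), concatenates the arm embeddings into a fused
latent vector, and passes it through a second-level fusion MLP ending in
three logits (bvFTD, nfvPPA, svPPA). Default widths: thickness arm
360->128->32, volume arm 375->128->32, fusion 64->32->3, ReLU
activations, dropout 0.2 after every hidden layer.

Implemented directly on numpy with hand-derived backpropagation: the
model is a few small dense layers, so explicit gradients keep the
package dependency-light, fully deterministic under a seed, and fast on
a single CPU. The same backward pass also yields gradients with respect
to the *inputs*, which the attribution module reuses for Integrated
Gradients.

Training uses plain stochastic gradient descent (learning rate 1e-3, L2
weight decay 1e-5) on a class-weighted cross-entropy loss, with weights
proportional to inverse class frequency to counter the 173/63/41
imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tables import DIAGNOSES


@dataclass(frozen=True)
class ParallelNetConfig:
    """Architecture hyperparameters.

    ``arm_input_sizes[i]`` consumes a contiguous block of the input
    vector; ``arm_hidden[i]`` are that arm's layer widths. Arm outputs
    are concatenated and passed through ``fusion_hidden`` layers, then a
    final linear map to ``n_classes`` logits.
    """

    arm_input_sizes: tuple[int, ...] = (360, 375)
    arm_hidden: tuple[tuple[int, ...], ...] = ((128, 32), (128, 32))
    fusion_hidden: tuple[int, ...] = (32,)
    n_classes: int = 3
    activation: str = "relu"
    dropout: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.arm_hidden) != len(self.arm_input_sizes):
            raise ValueError("one hidden spec required per input arm")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if any(len(h) == 0 for h in self.arm_hidden):
            raise ValueError("each arm needs at least one layer")

    @property
    def n_inputs(self) -> int:
        return sum(self.arm_input_sizes)


def parallel_config(seed: int = 0, dropout: float = 0.2) -> ParallelNetConfig:
    """The proposed multi-level parallel fusion architecture (735 inputs)."""
    return ParallelNetConfig(seed=seed, dropout=dropout)


def concat_config(seed: int = 0, dropout: float = 0.2) -> ParallelNetConfig:
    """Naive-concatenation baseline: one stack 735->256->64->32->3."""
    return ParallelNetConfig(
        arm_input_sizes=(735,),
        arm_hidden=((256, 64, 32),),
        fusion_hidden=(),
        seed=seed,
        dropout=dropout,
    )


def single_type_config(
    n_inputs: int, seed: int = 0, dropout: float = 0.2
) -> ParallelNetConfig:
    """Single-feature-type ablation: one arm with the standard funnel."""
    return ParallelNetConfig(
        arm_input_sizes=(n_inputs,),
        arm_hidden=((128, 32),),
        fusion_hidden=(32,),
        seed=seed,
        dropout=dropout,
    )


# ---------------------------------------------------------------------
# class weighting and loss


def compute_class_weights(class_counts: dict[str, int]) -> np.ndarray:
    """Inverse-frequency class weights, rescaled to mean 1.

    ``w_c`` is proportional to ``N_total / n_c``; rescaling to mean 1
    keeps the loss magnitude comparable across imbalance levels.
    Returned in :data:`~ftdx.tables.DIAGNOSES` order.
    """
    counts = np.array([class_counts[d] for d in DIAGNOSES], dtype=float)
    if (counts < 1).any():
        raise ValueError(f"all class counts must be >= 1, got {class_counts}")
    w = counts.sum() / counts
    return w / w.mean()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, weights: np.ndarray
) -> float:
    """Weighted-mean cross entropy: sum_i w_{y_i} nll_i / sum_i w_{y_i}."""
    if not np.isfinite(logits).all():
        raise FloatingPointError("non-finite logits")
    p = softmax(logits)
    n = len(labels)
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None))
    w = weights[labels]
    return float((w * nll).sum() / w.sum())


def weighted_cross_entropy_grad(
    logits: np.ndarray, labels: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """d loss / d logits for the weighted-mean cross entropy."""
    p = softmax(logits)
    n = len(labels)
    one_hot = np.zeros_like(p)
    one_hot[np.arange(n), labels] = 1.0
    w = weights[labels][:, None]
    return w * (p - one_hot) / w.sum()


# ---------------------------------------------------------------------
# the network


@dataclass
class _Layer:
    W: np.ndarray
    b: np.ndarray


class ParallelNet:
    """Numpy implementation of the parallel embedding network.

    Parameters are initialized deterministically from ``config.seed``
    (He-style normal for ReLU, Glorot-style for tanh).
    """

    def __init__(self, config: ParallelNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.arms: list[list[_Layer]] = []
        for n_in, widths in zip(config.arm_input_sizes, config.arm_hidden):
            layers, prev = [], n_in
            for w in widths:
                layers.append(self._init_layer(rng, prev, w))
                prev = w
            self.arms.append(layers)
        fused = sum(h[-1] for h in config.arm_hidden)
        self.fusion: list[_Layer] = []
        prev = fused
        for w in config.fusion_hidden:
            self.fusion.append(self._init_layer(rng, prev, w))
            prev = w
        self.out = self._init_layer(rng, prev, config.n_classes)

    def _init_layer(self, rng, n_in: int, n_out: int) -> _Layer:
        if self.config.activation == "relu":
            scale = np.sqrt(2.0 / n_in)
        else:
            scale = np.sqrt(1.0 / n_in)
        return _Layer(
            W=rng.normal(0.0, scale, (n_in, n_out)), b=np.zeros(n_out)
        )

    # ---- forward / backward -----------------------------------------
    def _act(self, z):
        return np.maximum(z, 0.0) if self.config.activation == "relu" else np.tanh(z)

    def _act_grad(self, z, a):
        return (z > 0).astype(float) if self.config.activation == "relu" else 1 - a**2

    def _split(self, X: np.ndarray) -> list[np.ndarray]:
        bounds = np.cumsum(self.config.arm_input_sizes)[:-1]
        return np.split(X, bounds, axis=1)

    def forward(
        self, X: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ):
        """Return (logits, cache). Dropout is active only when training."""
        if X.shape[1] != self.config.n_inputs:
            raise ValueError(
                f"expected {self.config.n_inputs} inputs, got {X.shape[1]}"
            )
        drop = self.config.dropout if training else 0.0
        if drop > 0 and rng is None:
            raise ValueError("training forward with dropout needs an rng")

        cache = {"X": X, "arms": [], "fusion": [], "drop": drop}
        outs = []
        for arm, Xa in zip(self.arms, self._split(X)):
            h = Xa
            arm_cache = []
            for layer in arm:
                z = h @ layer.W + layer.b
                a = self._act(z)  # pre-dropout activation, cached for backward
                mask = None
                if drop > 0:
                    mask = (rng.random(a.shape) >= drop) / (1.0 - drop)
                arm_cache.append((h, z, a, mask))
                h = a if mask is None else a * mask
            cache["arms"].append(arm_cache)
            outs.append(h)
        h = np.concatenate(outs, axis=1)
        cache["fused_width"] = [o.shape[1] for o in outs]
        for layer in self.fusion:
            z = h @ layer.W + layer.b
            a = self._act(z)
            mask = None
            if drop > 0:
                mask = (rng.random(a.shape) >= drop) / (1.0 - drop)
            cache["fusion"].append((h, z, a, mask))
            h = a if mask is None else a * mask
        cache["out_in"] = h
        logits = h @ self.out.W + self.out.b
        return logits, cache

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, training=False)[0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.predict_logits(X))

    def backward(self, cache, dlogits: np.ndarray):
        """Gradients of a scalar loss wrt parameters and inputs.

        Returns (grads, dX) where grads mirrors the parameter structure.
        """
        grads = {
            "arms": [[_Layer(np.zeros_like(l.W), np.zeros_like(l.b)) for l in arm]
                     for arm in self.arms],
            "fusion": [_Layer(np.zeros_like(l.W), np.zeros_like(l.b))
                       for l in self.fusion],
        }
        h = cache["out_in"]
        grads["out"] = _Layer(h.T @ dlogits, dlogits.sum(axis=0))
        dh = dlogits @ self.out.W.T
        for layer, (h_in, z, a, mask), g in zip(
            reversed(self.fusion), reversed(cache["fusion"]),
            reversed(grads["fusion"]),
        ):
            if mask is not None:
                dh = dh * mask
            dz = dh * self._act_grad(z, a)
            g.W[...] = h_in.T @ dz
            g.b[...] = dz.sum(axis=0)
            dh = dz @ layer.W.T
        # split fused gradient back into arm outputs
        bounds = np.cumsum(cache["fused_width"])[:-1]
        darm_outs = np.split(dh, bounds, axis=1)
        dX_parts = []
        for arm, arm_cache, garm, da in zip(
            self.arms, cache["arms"], grads["arms"], darm_outs
        ):
            dh = da
            for layer, (h_in, z, a, mask), g in zip(
                reversed(arm), reversed(arm_cache), reversed(garm)
            ):
                if mask is not None:
                    dh = dh * mask
                dz = dh * self._act_grad(z, a)
                g.W[...] = h_in.T @ dz
                g.b[...] = dz.sum(axis=0)
                dh = dz @ layer.W.T
            dX_parts.append(dh)
        dX = np.concatenate(dX_parts, axis=1)
        return grads, dX

    def input_gradients(self, X: np.ndarray, target_class: int) -> np.ndarray:
        """d logit[target] / d input for each row (dropout off)."""
        logits, cache = self.forward(X, training=False)
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0
        _, dX = self.backward(cache, dlogits)
        return dX

    # ---- optimizer / checkpointing ----------------------------------
    def _layers(self):
        for arm in self.arms:
            yield from arm
        yield from self.fusion
        yield self.out

    def _grad_layers(self, grads):
        for garm in grads["arms"]:
            yield from garm
        yield from grads["fusion"]
        yield grads["out"]

    def sgd_step(self, grads, lr: float, weight_decay: float = 0.0) -> None:
        for layer, g in zip(self._layers(), self._grad_layers(grads)):
            layer.W -= lr * (g.W + weight_decay * layer.W)
            layer.b -= lr * g.b

    def get_flat_params(self) -> np.ndarray:
        return np.concatenate(
            [np.concatenate([l.W.ravel(), l.b]) for l in self._layers()]
        )

    def set_flat_params(self, flat: np.ndarray) -> None:
        k = 0
        for layer in self._layers():
            n = layer.W.size
            layer.W[...] = flat[k : k + n].reshape(layer.W.shape)
            k += n
            layer.b[...] = flat[k : k + layer.b.size]
            k += layer.b.size
        if k != flat.size:
            raise ValueError("flat parameter vector has wrong length")


    # ---- checkpointing ----------------------------------------------
    def save_checkpoint(self, path) -> None:
        """Serialize config + parameters (JSON, lossless float repr)."""
        import dataclasses
        import json

        payload = {
            "config": dataclasses.asdict(self.config),
            "params": self.get_flat_params().tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load_checkpoint(cls, path) -> "ParallelNet":
        import json

        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        cfg = d["config"]
        cfg["arm_input_sizes"] = tuple(cfg["arm_input_sizes"])
        cfg["arm_hidden"] = tuple(tuple(h) for h in cfg["arm_hidden"])
        cfg["fusion_hidden"] = tuple(cfg["fusion_hidden"])
        net = cls(ParallelNetConfig(**cfg))
        net.set_flat_params(np.asarray(d["params"], dtype=float))
        return net


def build_model(config: ParallelNetConfig) -> ParallelNet:
    """Construct a :class:`ParallelNet` with seeded initialization."""
    return ParallelNet(config)
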