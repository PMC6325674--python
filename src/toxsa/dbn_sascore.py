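"""Synthetic-accessibility regression with a Deep Belief Network.

The model maps a 1024-bit molecular fingerprint to an SAscore in [1, 10]
(1 = easy to synthesize, 10 = very hard).  Architecture: a stack of
Restricted Boltzmann Machines with hidden layers of 512, 128 and 32 units,
pretrained greedily by contrastive divergence (CD-k, Gibbs sampling), then a
linear regression head on the top hidden layer fine-tuned jointly with all
layers by mini-batch gradient descent on the mean-squared error with an L2
weight penalty and an inverse-time learning-rate decay
``lr_t = lr0 / (1 + decay * t)``.

Defaults follow the published training recipe: initial learning rate 0.01,
decay 0.0001, mini-batch 100, 20 pretraining epochs, 1000 fine-tuning
epochs.  All randomness (weight init, Gibbs sampling, batch order) derives
from the config seed, so training is bit-for-bit reproducible.  Prediction
is a deterministic mean-field forward pass (sigmoid probabilities, no
sampling) with the output clamped to [1, 10].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .chem_io import FINGERPRINT_SCHEME
from .dataset import SA_MAX, SA_MIN, LabeledDataset

DEFAULT_LAYER_SIZES = (1024, 512, 128, 32)


@dataclass(frozen=True)
class DbnTrainConfig:
    lr0: float = 0.01
    decay: float = 0.0001
    batch: int = 100
    pretrain_epochs: int = 20
    finetune_epochs: int = 1000
    l2: float = 1e-4
    cd_steps: int = 1
    seed: int = 0
    head_only: bool = False  # freeze pretrained layers during fine-tuning

    def __post_init__(self):
        if self.lr0 <= 0 or self.decay < 0 or self.batch < 1:
            raise ValueError("invalid learning-rate/batch configuration")
        if min(self.pretrain_epochs, self.finetune_epochs) < 0 or self.cd_steps < 1:
            raise ValueError("epoch and CD-step counts must be non-negative/positive")


@dataclass
class RbmLayer:
    """One RBM: weights (visible x hidden) and the two bias vectors."""

    W: np.ndarray
    b_vis: np.ndarray
    b_hid: np.ndarray

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def hidden_probs(self, v: np.ndarray) -> np.ndarray:
        return expit(v @ self.W + self.b_hid)

    def visible_probs(self, h: np.ndarray) -> np.ndarray:
        return expit(h @ self.W.T + self.b_vis)


@dataclass
class DbnModel:
    layer_sizes: tuple[int, ...]
    layers: list[RbmLayer]
    head_w: np.ndarray
    head_b: float
    config: DbnTrainConfig
    metadata: dict = field(default_factory=dict)

    def forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Mean-field activations per hidden layer (input excluded)."""
        acts = []
        a = np.asarray(X, dtype=float)
        for layer in self.layers:
            a = layer.hidden_probs(a)
            acts.append(a)
        return acts


def _init_rbm(n_visible: int, n_hidden: int, rng: np.random.Generator) -> RbmLayer:
    # N(0, 0.01) weights, zero biases
    return RbmLayer(
        W=rng.normal(0.0, 0.01, size=(n_visible, n_hidden)),
        b_vis=np.zeros(n_visible),
        b_hid=np.zeros(n_hidden),
    )


def pretrain_rbm(data: np.ndarray, n_hidden: int, config: DbnTrainConfig,
                 rng: np.random.Generator | None = None,
                 layer: RbmLayer | None = None) -> tuple[RbmLayer, list[float]]:
    """Train one RBM by CD-k and report per-epoch mean reconstruction error.

    ``data`` rows must lie in [0, 1]: binary fingerprints at the bottom of a
    stack, activation probabilities for upper layers.  The positive phase
    uses hidden probabilities, the Gibbs chain samples hidden states and
    reconstructs visible probabilities (mean-field visibles, CD-1 default).
    With 0 epochs the freshly initialized layer is returned unchanged.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a matrix")
    if data.size and (data.min() < 0.0 or data.max() > 1.0):
        raise ValueError("RBM input must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if layer is None:
        layer = _init_rbm(data.shape[1], n_hidden, rng)
    n = data.shape[0]
    batch = min(config.batch, n)
    errors: list[float] = []
    step = 0
    for _ in range(config.pretrain_epochs):
        order = rng.permutation(n)
        epoch_err = []
        for start in range(0, n, batch):
            v0 = data[order[start:start + batch]]
            h_prob = layer.hidden_probs(v0)
            pos = v0.T @ h_prob
            h = (rng.random(h_prob.shape) < h_prob).astype(float)
            for _k in range(config.cd_steps):
                v_prob = layer.visible_probs(h)
                h_prob_k = layer.hidden_probs(v_prob)
                if _k < config.cd_steps - 1:
                    h = (rng.random(h_prob_k.shape) < h_prob_k).astype(float)
            neg = v_prob.T @ h_prob_k
            m = v0.shape[0]
            lr = config.lr0 / (1.0 + config.decay * step)
            layer.W += lr * ((pos - neg) / m - config.l2 * 2.0 * layer.W)
            layer.b_vis += lr * (v0 - v_prob).mean(axis=0)
            layer.b_hid += lr * (h_prob - h_prob_k).mean(axis=0)
            epoch_err.append(float(np.mean((v0 - v_prob) ** 2)))
            step += 1
        errors.append(float(np.mean(epoch_err)))
    return layer, errors


def pretrain_dbn(data: np.ndarray, config: DbnTrainConfig,
                 layer_sizes: tuple[int, ...] = DEFAULT_LAYER_SIZES) -> DbnModel:
    """Greedy layer-wise pretraining of the full stack.

    Layer i is trained on the mean-field hidden probabilities of layer i-1;
    the bottom layer requires strictly binary input.  The regression head is
    initialized to zero — fine-tuning gives it its values.
    """
    data = np.asarray(data, dtype=float)
    layer_sizes = tuple(int(s) for s in layer_sizes)
    if len(layer_sizes) < 2:
        raise ValueError("layer_sizes needs a visible and at least one hidden layer")
    if layer_sizes[0] != data.shape[1]:
        raise ValueError(
            f"visible size {layer_sizes[0]} does not match data width {data.shape[1]}"
        )
    if not np.isin(data, (0.0, 1.0)).all():
        raise ValueError("bottom-layer input must be binary")
    rng = np.random.default_rng(config.seed)
    layers: list[RbmLayer] = []
    recon_errors: list[list[float]] = []
    a = data
    for n_vis, n_hid in zip(layer_sizes, layer_sizes[1:]):
        assert a.shape[1] == n_vis
        layer, errs = pretrain_rbm(a, n_hid, config, rng=rng)
        layers.append(layer)
        recon_errors.append(errs)
        a = layer.hidden_probs(a)
    return DbnModel(
        layer_sizes=layer_sizes,
        layers=layers,
        head_w=np.zeros(layer_sizes[-1]),
        head_b=0.0,
        config=config,
        metadata={
            "fingerprint_scheme": FINGERPRINT_SCHEME,
            "pretrain_reconstruction_errors": recon_errors,
        },
    )


def _forward_raw(model: DbnModel, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    acts = model.forward(X)
    pred = acts[-1] @ model.head_w + model.head_b
    return acts, pred


def supervised_loss(model: DbnModel, X: np.ndarray, y: np.ndarray,
                    l2: float) -> float:
    """Fine-tuning objective: MSE plus L2 on all weight matrices (not biases)."""
    _, pred = _forward_raw(model, X)
    penalty = sum(float(np.sum(l.W ** 2)) for l in model.layers)
    penalty += float(np.sum(model.head_w ** 2))
    return float(np.mean((pred - y) ** 2)) + l2 * penalty


def supervised_gradients(model: DbnModel, X: np.ndarray, y: np.ndarray,
                         l2: float, head_only: bool = False):
    """Exact gradients of :func:`supervised_loss` by backpropagation.

    Returns ``(grad_head_w, grad_head_b, layer_grads)`` where ``layer_grads``
    is a list of ``(dW, db_hid)`` per layer (empty when ``head_only``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    acts, pred = _forward_raw(model, X)
    m = X.shape[0]
    dpred = 2.0 * (pred - y) / m
    grad_w = acts[-1].T @ dpred + 2.0 * l2 * model.head_w
    grad_b = float(dpred.sum())
    layer_grads: list[tuple[np.ndarray, np.ndarray]] = []
    if not head_only:
        da = np.outer(dpred, model.head_w)
        rev = []
        for li in range(len(model.layers) - 1, -1, -1):
            a = acts[li]
            dz = da * a * (1.0 - a)
            prev = X if li == 0 else acts[li - 1]
            gW = prev.T @ dz + 2.0 * l2 * model.layers[li].W
            gb = dz.sum(axis=0)
            if li > 0:
                da = dz @ model.layers[li].W.T
            rev.append((gW, gb))
        layer_grads = rev[::-1]
    return grad_w, grad_b, layer_grads


def finetune_regression(model: DbnModel, ds: LabeledDataset,
                        config: DbnTrainConfig | None = None) -> DbnModel:
    """Supervised fine-tuning by mini-batch SGD on MSE + L2.

    Backpropagates through the head and (unless ``head_only``) every
    pretrained layer; the L2 penalty applies to weights only, never biases.
    The learning rate decays as ``lr0 / (1 + decay * t)`` with t counting
    update steps.  Deterministic given the config seed.
    """
    if config is None:
        config = model.config
    if len(ds) == 0:
        raise ValueError("empty training set")
    y = np.asarray(ds.y, dtype=float)
    if y.min() < SA_MIN or y.max() > SA_MAX:
        raise ValueError("SAscore labels must lie in [1, 10]")
    X = np.asarray(ds.X, dtype=float)
    if X.shape[1] != model.layer_sizes[0]:
        raise ValueError("fingerprint width does not match model visible size")

    out = DbnModel(
        layer_sizes=model.layer_sizes,
        layers=[RbmLayer(l.W.copy(), l.b_vis.copy(), l.b_hid.copy())
                for l in model.layers],
        head_w=model.head_w.copy(),
        head_b=float(model.head_b),
        config=replace(config),
        metadata=dict(model.metadata),
    )
    rng = np.random.default_rng(config.seed + 1)  # distinct from pretraining stream
    n = X.shape[0]
    batch = min(config.batch, n)
    step = 0
    for _ in range(config.finetune_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            xb, yb = X[idx], y[idx]
            lr = config.lr0 / (1.0 + config.decay * step)
            grad_w, grad_b, layer_grads = supervised_gradients(
                out, xb, yb, config.l2, head_only=config.head_only
            )
            for layer, (gW, gb) in zip(out.layers, layer_grads):
                layer.W -= lr * gW
                layer.b_hid -= lr * gb
            out.head_w -= lr * grad_w
            out.head_b -= lr * grad_b
            step += 1
    out.metadata["finetuned"] = True
    return out


def predict_sascore(model: DbnModel, fps: np.ndarray) -> np.ndarray:
    """Deterministic forward pass; output clamped to the SAscore domain."""
    X = np.atleast_2d(np.asarray(fps, dtype=float))
    if X.shape[1] != model.layer_sizes[0]:
        raise ValueError(
            f"fingerprint width {X.shape[1]} != model visible size {model.layer_sizes[0]}"
        )
    _, pred = _forward_raw(model, X)
    return np.clip(pred, SA_MIN, SA_MAX)
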