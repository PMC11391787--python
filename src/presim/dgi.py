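"""GCN encoder trained with the Deep Graph Infomax objective.

The encoder is a stack of graph-convolution layers

    H^(l+1) = sigma( D̃^{-1/2} (A+I) D̃^{-1/2} H^(l) W^(l) )

trained self-supervised: a corruption function shuffles node-feature rows
to make negatives, a readout compresses the true embeddings into a global
summary ``s = sigmoid(mean_i h_i)``, and a bilinear discriminator
``D(h, s) = sigmoid(h' W s)`` is pushed (via binary cross-entropy) to score
true patch–summary pairs high and corrupted ones low, maximizing mutual
information between node and graph representations.  Forward and backward
passes are written directly in numpy/scipy; weights are updated with Adam.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .kg import KnowledgeGraph, init_features, normalize_adjacency

logger = logging.getLogger("presim.dgi")

ACTIVATIONS = ("prelu", "relu", "tanh", "identity")


@dataclass
class TrainConfig:
    """Hyperparameters of the encoder and its training loop.

    Defaults follow the stability-based selection: 128 hidden units and 26
    epochs minimize output dispersion while retaining expressiveness.
    """

    hidden_units: int = 128
    epochs: int = 26
    learning_rate: float = 1e-3
    n_layers: int = 1
    seed: int = 0
    activation: str = "prelu"

    def __post_init__(self):
        if self.hidden_units < 1 or self.n_layers < 1 or self.epochs < 0:
            raise ValueError("hidden_units/n_layers must be >= 1 and epochs >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")


@dataclass
class EncoderParams:
    layer_weights: list[np.ndarray]
    discriminator_weight: np.ndarray
    prelu_slopes: list[float]
    activation: str = "prelu"

    def flat(self) -> list[np.ndarray]:
        return self.layer_weights + [self.discriminator_weight]


@dataclass
class CorruptedGraph:
    X_hat: sp.spmatrix | np.ndarray
    A_hat: sp.spmatrix | np.ndarray
    permutation: np.ndarray | None = None


@dataclass
class EmbeddingSet:
    """Per-node embeddings H aligned with graph node order, plus summary s."""

    H: np.ndarray
    summary: np.ndarray
    node_ids: list[str]
    _index: dict[str, int] = field(default=None, repr=False)

    def __post_init__(self):
        if self.H.shape[0] != len(self.node_ids):
            raise ValueError("embedding row count must match node_ids")
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}

    def vector(self, node_id: str) -> np.ndarray:
        return self.H[self._index[node_id]]

    def subset(self, node_ids) -> np.ndarray:
        return self.H[[self._index[i] for i in node_ids]]


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=np.float64)))


def _activate(pre: np.ndarray, name: str, slope: float) -> np.ndarray:
    if name == "prelu":
        return np.where(pre > 0, pre, slope * pre)
    if name == "relu":
        return np.maximum(pre, 0.0)
    if name == "tanh":
        return np.tanh(pre)
    return pre


def _activate_grad(pre: np.ndarray, post: np.ndarray, name: str, slope: float):
    if name == "prelu":
        return np.where(pre > 0, 1.0, slope)
    if name == "relu":
        return (pre > 0).astype(np.float64)
    if name == "tanh":
        return 1.0 - post ** 2
    return np.ones_like(pre)


def gcn_layer(H_l, A_norm, W_l, activation: str = "identity", slope: float = 0.25):
    """One graph-convolution layer: sigma(A_norm @ H_l @ W_l)."""
    pre = A_norm @ (H_l @ W_l)
    pre = np.asarray(pre)
    return _activate(pre, activation, slope)


def corrupt(X, A, rng: np.random.Generator) -> CorruptedGraph:
    """Negative-sample corruption: permute feature rows, keep the topology.

    The corrupted graph has the same node count (M = N) and the identical
    multiset of feature rows, so positives and negatives differ only in
    which structure each feature row sits on.
    """
    n = X.shape[0]
    perm = rng.permutation(n)
    X_hat = X[perm]
    return CorruptedGraph(X_hat=X_hat, A_hat=A, permutation=perm)


def readout(H: np.ndarray) -> np.ndarray:
    """Graph-level summary s = sigmoid of the mean node embedding."""
    H = np.asarray(H, dtype=np.float64)
    if H.size == 0:
        raise ValueError("cannot read out an empty embedding matrix")
    return _sigmoid(H.mean(axis=0))


def discriminate(h: np.ndarray, s: np.ndarray, W: np.ndarray) -> float:
    """Bilinear patch–summary score sigmoid(h' W s), in (0, 1)."""
    h = np.asarray(h, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if W.shape != (h.shape[-1], s.shape[-1]):
        raise ValueError(f"discriminator weight shape {W.shape} does not match ({h.shape[-1]}, {s.shape[-1]})")
    return float(_sigmoid(h @ W @ s))

_CLAMP = 1e-12


def dgi_objective(pos_scores, neg_scores) -> float:
    """Mutual-information objective L (binary cross-entropy form).

    L = 1/(N+M) [ sum_i log D(h_i, s) + sum_j log(1 - D(ĥ_j, s)) ].
    L is maximized during training (the loop minimizes -L); its supremum is
    0 for perfectly separated scores, and uniform scores of 0.5 give ln 0.5.
    """
    pos = np.clip(np.asarray(pos_scores, dtype=np.float64), _CLAMP, 1 - _CLAMP)
    neg = np.clip(np.asarray(neg_scores, dtype=np.float64), _CLAMP, 1 - _CLAMP)
    total = np.log(pos).sum() + np.log1p(-neg).sum()
    return float(total / (pos.size + neg.size))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(n_features: int, config: TrainConfig, rng: np.random.Generator) -> EncoderParams:
    dims = [n_features] + [config.hidden_units] * config.n_layers
    weights = [_glorot(rng, dims[i], dims[i + 1]) for i in range(config.n_layers)]
    disc = _glorot(rng, config.hidden_units, config.hidden_units)
    slopes = [0.25] * config.n_layers
    return EncoderParams(
        layer_weights=weights,
        discriminator_weight=disc,
        prelu_slopes=slopes,
        activation=config.activation,
    )


def _encode(X, A_norm, params: EncoderParams):
    """Forward pass through all layers; returns (H, per-layer caches)."""
    caches = []
    Z = X
    for W, a in zip(params.layer_weights, params.prelu_slopes):
        pre = np.asarray(A_norm @ (Z @ W))
        post = _activate(pre, params.activation, a)
        caches.append((Z, pre, post))
        Z = post
    return Z, caches


def _backprop_encoder(dH, caches, params: EncoderParams, A_norm, grads_W, grads_a):
    """Accumulate dL/dW_l and dL/da_l for one encoder branch (A_norm symmetric)."""
    dZ = dH
    for l in range(len(params.layer_weights) - 1, -1, -1):
        Z_in, pre, post = caches[l]
        act_grad = _activate_grad(pre, post, params.activation, params.prelu_slopes[l])
        dPre = dZ * act_grad
        if params.activation == "prelu":
            grads_a[l] += float((dZ * np.where(pre > 0, 0.0, pre)).sum())
        back = np.asarray(A_norm @ dPre)          # A_norm is symmetric
        grads_W[l] += np.asarray((Z_in.T @ back))
        if l > 0:
            dZ = back @ params.layer_weights[l].T
    return grads_W, grads_a


class _Adam:
    def __init__(self, shapes, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def loss_and_grads(X, A_norm, params: EncoderParams, permutation: np.ndarray):
    """One full-batch DGI evaluation for a given corruption permutation.

    Returns ``(-L, dW_layers, dW_discriminator, da_slopes)`` where L is the
    mutual-information objective; the corrupted branch shares weights with
    the positive branch, and the summary s is read out from the positive
    embeddings only.
    """
    n = X.shape[0]
    H, caches = _encode(X, A_norm, params)
    H_hat, caches_hat = _encode(X[permutation], A_norm, params)

    m = H.mean(axis=0)
    s = _sigmoid(m)
    q = params.discriminator_weight @ s
    u = H @ q                                  # positive logits
    u_hat = H_hat @ q                          # negative logits
    # -L = mean of softplus(-u) over positives plus softplus(u_hat) over negatives
    neg_L = (np.logaddexp(0.0, -u).sum() + np.logaddexp(0.0, u_hat).sum()) / (2 * n)

    dU = (_sigmoid(u) - 1.0) / (2 * n)
    dU_hat = _sigmoid(u_hat) / (2 * n)

    hTd = H.T @ dU + H_hat.T @ dU_hat
    dWd = np.outer(hTd, s)
    ds = params.discriminator_weight.T @ hTd
    dm = ds * s * (1.0 - s)
    dH = np.outer(dU, q) + dm / n
    dH_hat = np.outer(dU_hat, q)

    grads_W = [np.zeros_like(w) for w in params.layer_weights]
    grads_a = [0.0] * len(params.layer_weights)
    _backprop_encoder(dH, caches, params, A_norm, grads_W, grads_a)
    _backprop_encoder(dH_hat, caches_hat, params, A_norm, grads_W, grads_a)
    return float(neg_L), grads_W, dWd, grads_a


def train(
    graph: KnowledgeGraph,
    config: TrainConfig,
    features=None,
    return_history: bool = False,
):
    """Train the DGI encoder full-batch and return final node embeddings.

    Each epoch: encode the true graph, encode a freshly corrupted graph with
    the *same* weights, read out the summary from the true embeddings, score
    every node against the summary with the discriminator, and take one Adam
    step on the negated objective.  Fully reproducible given ``config.seed``.
    """
    X = init_features(graph) if features is None else features
    A_norm = normalize_adjacency(graph.A)
    n = graph.n_nodes
    rng = np.random.default_rng(config.seed)
    params = init_params(X.shape[1], config, rng)

    flat = params.layer_weights + [params.discriminator_weight]
    adam = _Adam([w.shape for w in flat] + [(config.n_layers,)], config.learning_rate)
    history: list[float] = []

    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        neg_L, grads_W, dWd, grads_a = loss_and_grads(X, A_norm, params, perm)
        if not np.isfinite(neg_L):
            raise RuntimeError(
                f"non-finite objective at epoch {epoch} "
                f"(hidden_units={config.hidden_units}, lr={config.learning_rate})"
            )
        history.append(-neg_L)
        logger.debug("epoch=%d objective=%.6f", epoch, -neg_L)

        slopes = np.asarray(params.prelu_slopes)
        adam.step(
            params.layer_weights + [params.discriminator_weight, slopes],
            grads_W + [dWd, np.asarray(grads_a)],
        )
        params.prelu_slopes = list(slopes)

    H, _ = _encode(X, A_norm, params)
    emb = EmbeddingSet(H=np.asarray(H), summary=readout(H), node_ids=graph.node_ids)
    if return_history:
        return emb, history
    return emb
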