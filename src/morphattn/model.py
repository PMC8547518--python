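"""Self-attention classifier over morphological-network region features.

Each subject is an M x M KLS matrix X whose row X_p is region p's feature
vector. A stack of dot-product self-attention layers maps the M region
vectors to d-dimensional embeddings:

    Q_p = W_Q X_p,  K_p = W_K X_p,  V_p = W_V X_p
    alpha_pq = softmax_q(Q_p . K_q / sqrt(d_K))
    X1_p = sum_q alpha_pq V_q

followed by Leaky ReLU and layer normalisation after every attention layer.
The region embeddings are mean-pooled to one vector per subject and passed
through linear -> ReLU -> batch-norm -> linear -> sigmoid to produce the
probability of the positive (ASD) class. Training minimises binary
cross-entropy with Adam. The attention coefficients alpha of every layer are
recorded at inference time; they are the raw material for biomarker mapping.

With more than one head the embedding is split evenly across heads, per-head
attention maps are averaged into one M x M map (preserving row-stochasticity)
and the per-head outputs are concatenated, so the learned parameter count is
independent of the head count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from ._autograd import Adam, Tensor, bce_with_logits, concat, softmax
from .network import MorphNetwork

__all__ = [
    "ModelConfig",
    "AttentionLayerParams",
    "AttentionRecord",
    "TrainedModel",
    "attention_layer_forward",
    "model_forward",
    "train_model",
    "predict",
    "save_model",
    "load_model",
]

_LN_EPS = 1e-5
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyper-parameters.

    The defaults are the published recipe for the full-scale study (two
    single-head attention layers, 32-dim embeddings, Leaky ReLU slope 1e-2,
    Adam at learning rate 6e-6 with batch size 32 and weight decay 0.01);
    desk-scale synthetic cohorts typically need a larger learning rate.
    """

    n_attention_layers: int = 2
    n_heads: int = 1
    d_embed: int = 32
    leaky_slope: float = 1e-2
    learning_rate: float = 6e-6
    batch_size: int = 32
    weight_decay: float = 0.01
    max_epochs: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_heads not in (1, 2, 4, 8):
            raise ValueError(f"n_heads must be one of 1, 2, 4, 8; got {self.n_heads}")
        if not 1 <= self.n_attention_layers <= 5:
            raise ValueError("n_attention_layers must be in 1..5")
        if self.d_embed % self.n_heads:
            raise ValueError("d_embed must be divisible by n_heads")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")


@dataclass
class AttentionLayerParams:
    """Per-head query/key/value projections of one attention layer."""

    W_Q: list[Tensor]
    W_K: list[Tensor]
    W_V: list[Tensor]

    @property
    def n_heads(self) -> int:
        return len(self.W_Q)

    @property
    def d_k(self) -> int:
        return self.W_K[0].shape[0]

    def tensors(self) -> list[Tensor]:
        return [*self.W_Q, *self.W_K, *self.W_V]


@dataclass
class AttentionRecord:
    """Inference trace of one subject: probability, alpha maps, embeddings."""

    probability: float
    alpha: list[np.ndarray]
    layer_outputs: list[np.ndarray]


def _attention_core(X: Tensor, params: AttentionLayerParams) -> tuple[Tensor, Tensor]:
    """Multi-head dot-product attention; returns (output, head-averaged alpha)."""
    outputs: list[Tensor] = []
    alpha_sum: Tensor | None = None
    scale = 1.0 / np.sqrt(params.d_k)
    for wq, wk, wv in zip(params.W_Q, params.W_K, params.W_V):
        Q = X @ wq.swap_last()
        K = X @ wk.swap_last()
        V = X @ wv.swap_last()
        scores = (Q @ K.swap_last()) * scale
        alpha_h = softmax(scores, axis=-1)
        outputs.append(alpha_h @ V)
        alpha_sum = alpha_h if alpha_sum is None else alpha_sum + alpha_h
    Y = outputs[0] if len(outputs) == 1 else concat(outputs, axis=-1)
    return Y, alpha_sum * (1.0 / params.n_heads)


def attention_layer_forward(
    X: np.ndarray, params: AttentionLayerParams
) -> tuple[np.ndarray, np.ndarray]:
    """One attention layer on raw arrays (no gradient tracking).

    Returns the M x d_out output and the M x M coefficient map (averaged over
    heads when multi-headed).
    """
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("attention input must be finite")
    Y, alpha = _attention_core(Tensor(X), params)
    return Y.data, alpha.data


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / ((var + _LN_EPS) ** 0.5) * gamma + beta


@dataclass
class TrainedModel:
    """All learned parameters plus batch-norm running statistics."""

    config: ModelConfig
    M: int
    attn_layers: list[AttentionLayerParams]
    ln_gamma: list[Tensor]
    ln_beta: list[Tensor]
    W1: Tensor
    b1: Tensor
    bn_gamma: Tensor
    bn_beta: Tensor
    W2: Tensor
    b2: Tensor
    running_mean: np.ndarray
    running_var: np.ndarray
    region_labels: list[int] | None = None
    train_log: dict = field(default_factory=dict)

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer in self.attn_layers:
            params.extend(layer.tensors())
        params.extend(self.ln_gamma)
        params.extend(self.ln_beta)
        params.extend([self.W1, self.b1, self.bn_gamma, self.bn_beta,
                       self.W2, self.b2])
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def forward(
        self, X: np.ndarray, training: bool = False
    ) -> tuple[Tensor, list[Tensor], list[Tensor]]:
        """Full forward pass on a (B, M, M) batch.

        Returns the (B,) logits plus per-layer alpha maps and embeddings.
        In training mode batch-norm uses batch statistics and updates the
        running estimates; in evaluation mode it is a fixed affine map, so
        inference is deterministic.
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1] != self.M or X.shape[2] != self.M:
            raise ValueError(f"expected (B, {self.M}, {self.M}) input, got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("model input must be finite")
        cfg = self.config
        h = Tensor(X)
        alphas: list[Tensor] = []
        embeddings: list[Tensor] = []
        for layer, gamma, beta in zip(self.attn_layers, self.ln_gamma, self.ln_beta):
            h, alpha = _attention_core(h, layer)
            h = h.leaky_relu(cfg.leaky_slope)
            h = _layer_norm(h, gamma, beta)
            alphas.append(alpha)
            embeddings.append(h)
        pooled = h.mean(axis=1)                       # (B, d)
        z = pooled @ self.W1.swap_last() + self.b1
        z = z.relu()
        if training:
            B = z.shape[0]
            mu = z.mean(axis=0, keepdims=True)
            var = ((z - mu) ** 2).mean(axis=0, keepdims=True)
            z = (z - mu) / ((var + _BN_EPS) ** 0.5)
            unbiased = var.data[0] * (B / max(B - 1, 1))
            self.running_mean = ((1 - _BN_MOMENTUM) * self.running_mean
                                 + _BN_MOMENTUM * mu.data[0])
            self.running_var = ((1 - _BN_MOMENTUM) * self.running_var
                                + _BN_MOMENTUM * unbiased)
        else:
            z = (z - Tensor(self.running_mean)) / (
                Tensor(self.running_var + _BN_EPS) ** 0.5)
        z = z * self.bn_gamma + self.bn_beta
        logits = z @ self.W2.swap_last() + self.b2    # (B, 1)
        return logits.reshape(-1), alphas, embeddings


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> Tensor:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def init_model(config: ModelConfig, M: int,
               region_labels: list[int] | None = None) -> TrainedModel:
    """Seeded Glorot-uniform initialisation of all weights."""
    rng = np.random.default_rng(config.seed)
    d = config.d_embed
    d_k = d // config.n_heads
    layers: list[AttentionLayerParams] = []
    ln_gamma: list[Tensor] = []
    ln_beta: list[Tensor] = []
    d_in = M
    for _ in range(config.n_attention_layers):
        layers.append(AttentionLayerParams(
            W_Q=[_glorot(rng, (d_k, d_in)) for _ in range(config.n_heads)],
            W_K=[_glorot(rng, (d_k, d_in)) for _ in range(config.n_heads)],
            W_V=[_glorot(rng, (d_k, d_in)) for _ in range(config.n_heads)],
        ))
        ln_gamma.append(Tensor(np.ones(d), requires_grad=True))
        ln_beta.append(Tensor(np.zeros(d), requires_grad=True))
        d_in = d
    return TrainedModel(
        config=config, M=M, attn_layers=layers,
        ln_gamma=ln_gamma, ln_beta=ln_beta,
        W1=_glorot(rng, (d, d)), b1=Tensor(np.zeros(d), requires_grad=True),
        bn_gamma=Tensor(np.ones(d), requires_grad=True),
        bn_beta=Tensor(np.zeros(d), requires_grad=True),
        W2=_glorot(rng, (1, d)), b2=Tensor(np.zeros(1), requires_grad=True),
        running_mean=np.zeros(d), running_var=np.ones(d),
        region_labels=region_labels,
    )


def _stack_networks(networks: Sequence[MorphNetwork]) -> np.ndarray:
    M = networks[0].M
    if any(net.M != M for net in networks):
        raise ValueError("all networks must have the same number of regions")
    return np.stack([net.X for net in networks])


def train_model(
    networks: Sequence[MorphNetwork],
    labels: Sequence[int],
    config: ModelConfig,
) -> TrainedModel:
    """Mini-batch Adam training of the attention classifier.

    Labels are binary with ASD = 1. Weight decay is applied as an L2 term
    folded into the Adam gradient. Raises on single-class input or if the
    loss becomes non-finite.
    """
    y = np.asarray(labels, dtype=np.float64)
    if len(networks) != len(y):
        raise ValueError("networks and labels length mismatch")
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 subjects per class")
    X = _stack_networks(networks)
    model = init_model(config, M=X.shape[1],
                       region_labels=list(networks[0].region_labels))
    opt = Adam(model.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 1]))
    n = len(y)
    losses: list[float] = []
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits, _, _ = model.forward(X[idx], training=True)
            loss = bce_with_logits(logits, y[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {_epoch}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        losses.append(epoch_loss / n)
    model.train_log = {"loss": losses, "seed": config.seed,
                       "config": config.__dict__.copy()}
    return model


def model_forward(network: MorphNetwork, model: TrainedModel) -> AttentionRecord:
    """Evaluation-mode forward pass of one subject, recording all alpha maps."""
    if network.M != model.M:
        raise ValueError(f"network has {network.M} regions, model expects {model.M}")
    logits, alphas, embeddings = model.forward(network.X[None], training=False)
    prob = float(1.0 / (1.0 + np.exp(-logits.data[0])))
    return AttentionRecord(
        probability=prob,
        alpha=[a.data[0] for a in alphas],
        layer_outputs=[e.data[0] for e in embeddings],
    )


def predict(
    model: TrainedModel, network: MorphNetwork, threshold: float = 0.5
) -> tuple[int, float]:
    """Binary prediction; probability exactly at threshold counts positive."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    record = model_forward(network, model)
    return int(record.probability >= threshold), record.probability


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialise config, weights and batch-norm statistics to a JSON file."""
    payload = {
        "config": model.config.__dict__.copy(),
        "M": model.M,
        "region_labels": model.region_labels,
        "train_log": model.train_log,
        "running_mean": model.running_mean.tolist(),
        "running_var": model.running_var.tolist(),
        "layers": [
            {
                "W_Q": [w.data.tolist() for w in layer.W_Q],
                "W_K": [w.data.tolist() for w in layer.W_K],
                "W_V": [w.data.tolist() for w in layer.W_V],
            }
            for layer in model.attn_layers
        ],
        "ln_gamma": [t.data.tolist() for t in model.ln_gamma],
        "ln_beta": [t.data.tolist() for t in model.ln_beta],
        "W1": model.W1.data.tolist(), "b1": model.b1.data.tolist(),
        "bn_gamma": model.bn_gamma.data.tolist(),
        "bn_beta": model.bn_beta.data.tolist(),
        "W2": model.W2.data.tolist(), "b2": model.b2.data.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    config = ModelConfig(**payload["config"])

    def t(x) -> Tensor:
        return Tensor(np.asarray(x, dtype=np.float64), requires_grad=True)

    layers = [
        AttentionLayerParams(
            W_Q=[t(w) for w in layer["W_Q"]],
            W_K=[t(w) for w in layer["W_K"]],
            W_V=[t(w) for w in layer["W_V"]],
        )
        for layer in payload["layers"]
    ]
    return TrainedModel(
        config=config, M=int(payload["M"]), attn_layers=layers,
        ln_gamma=[t(x) for x in payload["ln_gamma"]],
        ln_beta=[t(x) for x in payload["ln_beta"]],
        W1=t(payload["W1"]), b1=t(payload["b1"]),
        bn_gamma=t(payload["bn_gamma"]), bn_beta=t(payload["bn_beta"]),
        W2=t(payload["W2"]), b2=t(payload["b2"]),
        running_mean=np.asarray(payload["running_mean"]),
        running_var=np.asarray(payload["running_var"]),
        region_labels=payload["region_labels"],
        train_log=payload["train_log"],
    )


def fast_config(config: ModelConfig, max_epochs: int = 30) -> ModelConfig:
    """A reduced-epoch copy of a config for permutation-scale reruns."""
    return replace(config, max_epochs=min(config.max_epochs, max_epochs))
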