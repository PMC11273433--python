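"""Six-layer Chebyshev graph-convolutional classifier.

Each layer filters node features with a truncated Chebyshev expansion in the
rescaled Laplacian L_tilde = 2L/lambda_max - I:

    Y = sum_{k<P} T_k(L_tilde) X Theta_k + b,
    T_0 = I,  T_1 = L_tilde,  T_k = 2 L_tilde T_{k-1} - T_{k-2},

which equals exact spectral filtering U g(Lambda) U^T X with a degree-P-1
polynomial filter g. The default architecture follows the reference design:
a learned per-node affine embedding lifts the scalar mean-intensity feature
to 32 channels, then six conv blocks (conv -> ReLU -> batch norm ->
dropout, the last conv mapping to 2 channels), and a dense softmax readout
over the flattened, padding-masked node features.

With P = 1 the expansion stops at T_0 = I and each conv reduces to a
node-wise linear map; P = 2 (an order-1 polynomial) is the smallest setting
that propagates information along graph edges.

Everything is numpy with hand-written backprop; batch norm statistics are
computed over real (non-padding) node entries only.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .graphs import RegionGraph, scale_laplacian
from .nn import cross_entropy, glorot_uniform, make_optimizer, relu, softmax
from .preprocess import CLASS_LABELS

_BN_EPS = 1e-5


@dataclass
class ChebConvLayer:
    """Weights (P terms x in-channels x out-channels) and bias of one layer."""

    weights: np.ndarray
    bias: np.ndarray

    @property
    def n_terms(self) -> int:
        return self.weights.shape[0]

    def parameter_count(self, include_bias: bool = True) -> int:
        n = int(np.prod(self.weights.shape))
        return n + (self.bias.size if include_bias else 0)


def conv_layer_param_count(P: int, f_in: int, f_out: int) -> int:
    """Closed-form parameter count of one conv layer: P*F_in*F_out + F_out."""
    return P * f_in * f_out + f_out


@dataclass
class ModelConfig:
    """Classifier architecture and training hyperparameters."""

    n_layers: int = 6
    hidden_channels: int = 32
    cheb_terms: list[int] = field(default_factory=lambda: [1] * 6)
    dropout_rate: float = 0.2
    learning_rate: float = 0.0001
    optimizer: str = "sgd"
    #: classical momentum; sized so lr/(1-momentum) gives a usable effective
    #: step at the small reference learning rate within the epoch budget
    momentum: float = 0.99
    batch_size: int = 32
    weight_decay: float = 4e-4
    loss: str = "cross_entropy"
    epochs: int = 150
    node_budget: int = 150
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if len(self.cheb_terms) != self.n_layers:
            raise ValueError("cheb_terms must list one P per layer")
        if any(p < 1 for p in self.cheb_terms):
            raise ValueError("every Chebyshev term count must be >= 1")


@dataclass
class TrainReport:
    """Per-epoch training curves and the best-validation epoch index."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1


# ---------------------------------------------------------------------------
# Chebyshev basis and convolution


def cheb_basis(L_tilde: np.ndarray, X: np.ndarray, K: int) -> list[np.ndarray]:
    """[T_0(L~)X, ..., T_{K-1}(L~)X] by the three-term recurrence.

    Accepts a single graph ((N,N), (N,F)) or a batch ((B,N,N), (B,N,F)).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    L_tilde = np.asarray(L_tilde, dtype=float)
    X = np.asarray(X, dtype=float)
    if L_tilde.shape[-1] != X.shape[-2]:
        raise ValueError("L_tilde and X node counts differ")
    out = [X]
    if K > 1:
        out.append(L_tilde @ X)
    for _ in range(2, K):
        out.append(2.0 * (L_tilde @ out[-1]) - out[-2])
    return out


def cheb_conv_forward(
    layer: ChebConvLayer, L_tilde: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """Y = sum_k T_k(L~) X Theta_k + bias."""
    P, f_in, f_out = layer.weights.shape
    if X.shape[-1] != f_in:
        raise ValueError(f"X has {X.shape[-1]} channels, layer expects {f_in}")
    T = cheb_basis(L_tilde, X, P)
    Y = sum(T[k] @ layer.weights[k] for k in range(P))
    return Y + layer.bias


def input_embedding(X_raw: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-node affine lift from the scalar feature to hidden channels."""
    X_raw = np.asarray(X_raw, dtype=float)
    if X_raw.shape[-1] != W.shape[0]:
        raise ValueError("input width does not match embedding weights")
    return X_raw @ W + b


# ---------------------------------------------------------------------------
# the model


class ChebNet:
    """The full classifier: embedding, conv blocks, masked dense readout."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        self.config = config
        if rng is None:
            rng = np.random.default_rng(config.seed)
        c = config.hidden_channels
        self.params: dict[str, np.ndarray] = {
            "embed_W": glorot_uniform(rng, 1, c),
            "embed_b": np.zeros(c),
        }
        channels = [c] * config.n_layers + [2]
        for l in range(config.n_layers):
            P = config.cheb_terms[l]
            f_in, f_out = channels[l], channels[l + 1]
            limit = np.sqrt(6.0 / (P * f_in + f_out))
            self.params[f"conv{l}_W"] = rng.uniform(
                -limit, limit, size=(P, f_in, f_out)
            )
            self.params[f"conv{l}_b"] = np.zeros(f_out)
            self.params[f"bn{l}_gamma"] = np.ones(f_out)
            self.params[f"bn{l}_beta"] = np.zeros(f_out)
        flat = config.node_budget * 2
        self.params["out_W"] = glorot_uniform(rng, flat, 2)
        self.params["out_b"] = np.zeros(2)
        # batch-norm running statistics (inference mode), not trained by SGD
        self.running: dict[str, np.ndarray] = {}
        for l in range(config.n_layers):
            f_out = channels[l + 1]
            self.running[f"bn{l}_mean"] = np.zeros(f_out)
            self.running[f"bn{l}_var"] = np.ones(f_out)
        self.trained = False

    # -- conv layers as ChebConvLayer views
    def conv_layer(self, l: int) -> ChebConvLayer:
        return ChebConvLayer(self.params[f"conv{l}_W"], self.params[f"conv{l}_b"])

    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward -----------------------------------------------------------
    def forward(
        self,
        L_tilde: np.ndarray,
        X: np.ndarray,
        mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        cache: dict | None = None,
    ) -> np.ndarray:
        """Class probabilities (B, 2) for a batch of padded graphs."""
        cfg = self.config
        m = np.asarray(mask, dtype=float)[:, :, None]  # (B, N, 1)
        if X.shape[1] != cfg.node_budget:
            raise ValueError(
                f"graphs must be padded to node_budget={cfg.node_budget}"
            )
        drop_keep = 1.0 - cfg.dropout_rate

        def dropout(H, tag):
            if not training or cfg.dropout_rate == 0.0:
                return H
            dmask = (
                rng.uniform(size=H.shape) < drop_keep
            ).astype(float) / drop_keep
            if cache is not None:
                cache[f"drop_{tag}"] = dmask
            return H * dmask

        H = input_embedding(X, self.params["embed_W"], self.params["embed_b"]) * m
        if cache is not None:
            cache["X"] = X
            cache["m"] = m
        H = dropout(H, "in")
        for l in range(cfg.n_layers):
            P = cfg.cheb_terms[l]
            T = cheb_basis(L_tilde, H, P)
            Z = sum(T[k] @ self.params[f"conv{l}_W"][k] for k in range(P))
            Z = Z + self.params[f"conv{l}_b"]
            A = relu(Z)
            # masked batch norm over (batch, node) per channel
            cnt = m.sum()
            if training:
                mu = (A * m).sum(axis=(0, 1)) / cnt
                var = (((A - mu) ** 2) * m).sum(axis=(0, 1)) / cnt
                mom = 0.9
                self.running[f"bn{l}_mean"] = (
                    mom * self.running[f"bn{l}_mean"] + (1 - mom) * mu
                )
                self.running[f"bn{l}_var"] = (
                    mom * self.running[f"bn{l}_var"] + (1 - mom) * var
                )
            else:
                mu = self.running[f"bn{l}_mean"]
                var = self.running[f"bn{l}_var"]
            std = np.sqrt(var + _BN_EPS)
            An = (A - mu) / std
            B_ = (self.params[f"bn{l}_gamma"] * An + self.params[f"bn{l}_beta"]) * m
            if cache is not None:
                cache[f"T{l}"] = T
                cache[f"Z{l}"] = Z
                cache[f"An{l}"] = An
                cache[f"std{l}"] = std
            H = dropout(B_, f"l{l}")
        flat = (H * m).reshape(H.shape[0], -1)
        logits = flat @ self.params["out_W"] + self.params["out_b"]
        if cache is not None:
            cache["flat"] = flat
        return softmax(logits)

    # -- backward ----------------------------------------------------------
    def _backward(
        self,
        L_tilde: np.ndarray,
        probs: np.ndarray,
        y: np.ndarray,
        cache: dict,
    ) -> dict[str, np.ndarray]:
        """Gradients of mean cross-entropy w.r.t. every parameter."""
        cfg = self.config
        B = probs.shape[0]
        m = cache["m"]
        grads: dict[str, np.ndarray] = {}

        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads["out_W"] = cache["flat"].T @ dlogits
        grads["out_b"] = dlogits.sum(axis=0)
        dH = (dlogits @ self.params["out_W"].T).reshape(B, cfg.node_budget, -1)
        dH = dH * m

        for l in reversed(range(cfg.n_layers)):
            if f"drop_l{l}" in cache:
                dH = dH * cache[f"drop_l{l}"]
            An = cache[f"An{l}"]
            std = cache[f"std{l}"]
            cnt = m.sum()
            dB = dH * m
            grads[f"bn{l}_gamma"] = (dB * An).sum(axis=(0, 1))
            grads[f"bn{l}_beta"] = dB.sum(axis=(0, 1))
            dAn = dB * self.params[f"bn{l}_gamma"]
            mean_dAn = (dAn * m).sum(axis=(0, 1)) / cnt
            mean_dAn_An = (dAn * An * m).sum(axis=(0, 1)) / cnt
            dA = (dAn - mean_dAn - An * mean_dAn_An) / std * m
            dZ = dA * (cache[f"Z{l}"] > 0)
            W = self.params[f"conv{l}_W"]
            P = W.shape[0]
            T = cache[f"T{l}"]
            grads[f"conv{l}_W"] = np.stack(
                [np.einsum("bnf,bng->fg", T[k], dZ) for k in range(P)]
            )
            grads[f"conv{l}_b"] = dZ.sum(axis=(0, 1))
            # adjoint w.r.t. the input: T_k(L~) is symmetric, so
            # dH = sum_k T_k(L~) (dZ Theta_k^T); one recurrence over the
            # channel-concatenated right-hand sides covers every k
            f_in = W.shape[1]
            cat = np.concatenate([dZ @ W[k].T for k in range(P)], axis=-1)
            T_cat = cheb_basis(L_tilde, cat, P)
            dH = np.zeros_like(T[0])
            for k in range(P):
                dH = dH + T_cat[k][..., k * f_in : (k + 1) * f_in]
        if "drop_in" in cache:
            dH = dH * cache["drop_in"]
        dH = dH * m
        grads["embed_W"] = np.einsum("bnf,bng->fg", cache["X"], dH)
        grads["embed_b"] = dH.sum(axis=(0, 1))
        return grads

    def predict_proba(self, graphs: list[RegionGraph]) -> np.ndarray:
        L_t, X, mask, _ = batch_graphs(graphs, self.config.node_budget)
        return self.forward(L_t, X, mask, training=False)

    def predict(self, graphs: list[RegionGraph]) -> list[str]:
        probs = self.predict_proba(graphs)
        # ties break toward class index 0 (ALL)
        idx = np.where(probs[:, 0] >= probs[:, 1], 0, 1)
        return [CLASS_LABELS[i] for i in idx]


def batch_graphs(
    graphs: list[RegionGraph], node_budget: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack padded graphs into (L_tilde, X, mask, y) batch arrays.

    Graphs must already be padded to ``node_budget`` nodes; labels absent
    from any graph yield -1 in y.
    """
    B = len(graphs)
    L_t = np.empty((B, node_budget, node_budget))
    X = np.empty((B, node_budget, 1))
    mask = np.zeros((B, node_budget), dtype=bool)
    y = np.full(B, -1)
    for i, g in enumerate(graphs):
        if g.n_nodes != node_budget:
            raise ValueError(
                f"graph {g.source_id!r} has {g.n_nodes} nodes; pad to "
                f"{node_budget} first"
            )
        L_t[i] = scale_laplacian(g.L, g.lambda_max)
        X[i] = g.X[:, :1]
        mask[i] = g.mask
        if g.label is not None:
            y[i] = CLASS_LABELS.index(g.label)
    return L_t, X, mask, y


def train_model(
    train_set: list[RegionGraph],
    val_set: list[RegionGraph],
    config: ModelConfig,
) -> tuple[ChebNet, TrainReport]:
    """Mini-batch SGD training on cross-entropy with weight decay.

    Per-epoch train/validation loss and accuracy are recorded; with a fixed
    seed the entire history is reproducible.
    """
    if not train_set:
        raise ValueError("training set is empty")
    labels = {g.label for g in train_set}
    if len(labels) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(config.seed)
    model = ChebNet(config, rng)
    opt = make_optimizer(
        config.optimizer,
        config.learning_rate,
        weight_decay=config.weight_decay,
        momentum=config.momentum,
    )
    L_tr, X_tr, m_tr, y_tr = batch_graphs(train_set, config.node_budget)
    if val_set:
        L_va, X_va, m_va, y_va = batch_graphs(val_set, config.node_budget)
    report = TrainReport()
    n = len(train_set)
    bs = min(config.batch_size, n)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            cache: dict = {}
            probs = model.forward(
                L_tr[idx], X_tr[idx], m_tr[idx], training=True, rng=rng, cache=cache
            )
            grads = model._backward(L_tr[idx], probs, y_tr[idx], cache)
            opt.step(model.params, grads)
        tl, ta = _evaluate(model, L_tr, X_tr, m_tr, y_tr)
        report.train_loss.append(tl)
        report.train_acc.append(ta)
        if val_set:
            vl, va = _evaluate(model, L_va, X_va, m_va, y_va)
            report.val_loss.append(vl)
            report.val_acc.append(va)
    if report.val_acc:
        report.best_epoch = int(np.argmax(report.val_acc))
    elif report.train_acc:
        report.best_epoch = int(np.argmax(report.train_acc))
    model.trained = config.epochs > 0
    return model, report


def _evaluate(model, L_t, X, mask, y) -> tuple[float, float]:
    probs = model.forward(L_t, X, mask, training=False)
    loss = cross_entropy(probs, y)
    pred = np.where(probs[:, 0] >= probs[:, 1], 0, 1)
    return loss, float(np.mean(pred == y))


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: ChebNet, report: TrainReport | None, out_dir: str | Path):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = dict(model.params)
    arrays.update({f"run_{k}": v for k, v in model.running.items()})
    np.savez(out_dir / "model.npz", **arrays)
    with open(out_dir / "model.json", "w") as fh:
        json.dump({"config": asdict(model.config), "trained": model.trained}, fh,
                  indent=2)
    if report is not None:
        with open(out_dir / "history.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "train_acc", "val_loss", "val_acc"])
            for i in range(len(report.train_loss)):
                writer.writerow(
                    [
                        i,
                        report.train_loss[i],
                        report.train_acc[i],
                        report.val_loss[i] if report.val_loss else "",
                        report.val_acc[i] if report.val_acc else "",
                    ]
                )


def load_model(out_dir: str | Path) -> ChebNet:
    out_dir = Path(out_dir)
    with open(out_dir / "model.json") as fh:
        meta = json.load(fh)
    config = ModelConfig(**meta["config"])
    model = ChebNet(config)
    with np.load(out_dir / "model.npz") as z:
        for k in z.files:
            if k.startswith("run_"):
                model.running[k[4:]] = z[k]
            else:
                model.params[k] = z[k]
    model.trained = meta["trained"]
    return model
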