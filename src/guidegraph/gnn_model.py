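"""Graph regression model: NodeMLP -> graph attention -> graph convolution
-> pooled regression head.

The model is implemented directly on NumPy arrays with hand-written
backpropagation (verified against numerical gradients in the test suite) so
that training is fully deterministic and dependency-light. Graphs are
mini-batched by concatenating node sets and offsetting arc indices, exactly
as molecular-graph libraries do.

Attention uses softmax normalization over each node's incoming arcs; every
node carries an implicit self-loop so single-node/no-arc graphs are handled.
Edge types are not distinguished during message passing; ablations are done
by editing the graph (see :func:`guidegraph.graph_builder.strip_structural_arcs`).
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .graph_builder import GuideGraph

__all__ = [
    "ModelConfig",
    "TrainingHistory",
    "TrainedModel",
    "CheckpointError",
    "init_model",
    "forward",
    "predict",
    "train",
    "fine_tune",
    "random_search",
    "save_checkpoint",
    "load_checkpoint",
]

_VERSION = "0.1.0"


class CheckpointError(RuntimeError):
    """Raised when a checkpoint file is missing, corrupted, or inconsistent."""


@dataclass(frozen=True)
class ModelConfig:
    node_mlp_layers: int = 2
    hidden_dim: int = 128
    attention_heads: int = 4
    attention_layers: int = 1
    conv_layers: int = 1
    dropout: float = 0.0
    pooling: str = "mean"  # mean | sum | max
    head_layers: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "node_mlp_layers",
            "hidden_dim",
            "attention_heads",
            "attention_layers",
            "conv_layers",
            "head_layers",
            "batch_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.max_epochs < 0 or self.patience < 0:
            raise ValueError("max_epochs and patience must be >= 0")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.pooling not in ("mean", "sum", "max"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.hidden_dim % self.attention_heads != 0:
            raise ValueError("hidden_dim must be divisible by attention_heads")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


@dataclass
class TrainedModel:
    config: ModelConfig
    params: dict[str, np.ndarray]
    feature_dim: int
    history: TrainingHistory = field(default_factory=TrainingHistory)


# ---------------------------------------------------------------------------
# initialization


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_model(cfg: ModelConfig, feature_dim: int) -> TrainedModel:
    """Deterministically initialize a model for ``feature_dim`` node features."""
    if feature_dim < 1:
        raise ValueError("feature_dim must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    H = cfg.hidden_dim
    K = cfg.attention_heads
    Dh = H // K
    params: dict[str, np.ndarray] = {}
    d_in = feature_dim
    for i in range(cfg.node_mlp_layers):
        params[f"mlp{i}_W"] = _glorot(rng, (d_in, H))
        params[f"mlp{i}_b"] = np.zeros(H)
        d_in = H
    for l in range(cfg.attention_layers):
        params[f"att{l}_W"] = _glorot(rng, (H, H))
        params[f"att{l}_asrc"] = _glorot(rng, (K, Dh))
        params[f"att{l}_adst"] = _glorot(rng, (K, Dh))
        params[f"att{l}_b"] = np.zeros(H)
    for l in range(cfg.conv_layers):
        params[f"conv{l}_Wself"] = _glorot(rng, (H, H))
        params[f"conv{l}_Wnb"] = _glorot(rng, (H, H))
        params[f"conv{l}_b"] = np.zeros(H)
    for i in range(cfg.head_layers):
        d_out = 1 if i == cfg.head_layers - 1 else H
        params[f"head{i}_W"] = _glorot(rng, (H, d_out))
        params[f"head{i}_b"] = np.zeros(d_out)
    return TrainedModel(config=cfg, params=params, feature_dim=feature_dim)


# ---------------------------------------------------------------------------
# batching


def _segments(seg_sorted: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Start offsets and lengths of the contiguous runs of ``seg_sorted``
    (non-decreasing segment ids) for segments ``0..n-1``."""
    starts = np.searchsorted(seg_sorted, np.arange(n), side="left")
    counts = np.diff(np.append(starts, len(seg_sorted)))
    return starts, counts


def _scatter_matrix(seg: np.ndarray, n_seg: int) -> sp.csr_matrix:
    """CSR matrix ``S`` with ``S[seg[a], a] = 1`` so that ``S @ V`` sums the
    rows of ``V`` into their segments (fast C scatter-add)."""
    a = len(seg)
    return sp.csr_matrix(
        (np.ones(a), (seg, np.arange(a, dtype=np.int64))), shape=(n_seg, a)
    )


def _seg_max(values: np.ndarray, starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    n = len(starts)
    if values.shape[0] == 0:
        return np.full((n,) + values.shape[1:], -np.inf)
    safe = np.minimum(starts, values.shape[0] - 1)
    out = np.maximum.reduceat(values, safe, axis=0)
    if np.any(counts == 0):
        out[counts == 0] = -np.inf
    return out


def _make_batch(graphs: Sequence[GuideGraph], require_labels: bool = False) -> dict:
    """Concatenate graphs into one node set with offset arc indices.

    Arcs are stored sorted by destination (then source) so that incoming-arc
    aggregations are contiguous segment reductions; a source-sorted
    permutation is kept for the backward scatter.
    """
    if not graphs:
        raise ValueError("empty graph list")
    xs, srcs, dsts, gids, labels = [], [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        xs.append(g.node_features)
        srcs.append(g.arc_src + offset)
        dsts.append(g.arc_dst + offset)
        gids.append(np.full(g.n_nodes, gi, dtype=np.int64))
        if require_labels:
            if g.label is None:
                raise ValueError(
                    f"graph {g.meta.get('id', gi)!r} has no efficiency label"
                )
            labels.append(g.label)
        offset += g.n_nodes
    X = np.vstack(xs)
    N = X.shape[0]
    src = np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.int64)
    dst = np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.int64)

    # real arcs (convolution): sorted by (dst, src) for a stable layout
    order = np.lexsort((src, dst))
    src, dst = src[order], dst[order]
    dst_starts, dst_counts = _segments(dst, N)

    # attention arcs: real arcs plus one self-loop per node
    loops = np.arange(N, dtype=np.int64)
    asrc = np.concatenate([src, loops])
    adst = np.concatenate([dst, loops])
    aorder = np.lexsort((asrc, adst))
    asrc, adst = asrc[aorder], adst[aorder]
    adst_starts, adst_counts = _segments(adst, N)

    gid = np.concatenate(gids)
    gid_starts, gid_counts = _segments(gid, len(graphs))
    return {
        "X": X,
        "src": src,
        "dst": dst,
        "dst_counts": dst_counts,
        "scat_src": _scatter_matrix(src, N),
        "scat_dst": _scatter_matrix(dst, N),
        "asrc": asrc,
        "adst": adst,
        "adst_starts": adst_starts,
        "adst_counts": adst_counts,
        "scat_asrc": _scatter_matrix(asrc, N),
        "scat_adst": _scatter_matrix(adst, N),
        "gid": gid,
        "gid_starts": gid_starts,
        "scat_gid": _scatter_matrix(gid, len(graphs)),
        "counts": gid_counts.astype(np.float64),
        "n_graphs": len(graphs),
        "y": np.array(labels, dtype=np.float64) if require_labels else None,
        "n_real_arcs": int(src.shape[0]),
    }


# ---------------------------------------------------------------------------
# forward / backward


def _forward_pass(
    params: Mapping[str, np.ndarray],
    batch: dict,
    cfg: ModelConfig,
    *,
    training: bool = False,
    dropout_rng: np.random.Generator | None = None,
    collect_attention: bool = False,
):
    """Run the network; returns (preds, cache, attention)."""
    N = batch["X"].shape[0]
    K = cfg.attention_heads
    Dh = cfg.hidden_dim // K
    asrc, adst = batch["asrc"], batch["adst"]
    src, dst = batch["src"], batch["dst"]
    gid, counts, G = batch["gid"], batch["counts"], batch["n_graphs"]
    cache: list[tuple] = []
    attention: list[dict] = []
    h = batch["X"]

    def maybe_dropout(h: np.ndarray) -> np.ndarray:
        if training and cfg.dropout > 0.0:
            if dropout_rng is None:
                raise ValueError("dropout requires a dropout_rng during training")
            mask = (dropout_rng.random(h.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            cache.append(("dropout", mask))
            return h * mask
        cache.append(("dropout", None))
        return h

    for i in range(cfg.node_mlp_layers):
        W, b = params[f"mlp{i}_W"], params[f"mlp{i}_b"]
        pre = h @ W + b
        out = np.maximum(pre, 0.0)
        cache.append(("linear_relu", f"mlp{i}", h, pre))
        h = maybe_dropout(out)

    for l in range(cfg.attention_layers):
        W = params[f"att{l}_W"]
        a_src, a_dst = params[f"att{l}_asrc"], params[f"att{l}_adst"]
        b = params[f"att{l}_b"]
        z = (h @ W).reshape(N, K, Dh)
        ssrc = np.einsum("nkd,kd->nk", z, a_src)
        sdst = np.einsum("nkd,kd->nk", z, a_dst)
        logits = ssrc[asrc] + sdst[adst]
        el = np.where(logits > 0, logits, 0.2 * logits)  # LeakyReLU(0.2)
        m = _seg_max(el, batch["adst_starts"], batch["adst_counts"])
        ex = np.exp(el - m[adst])
        total = batch["scat_adst"] @ ex
        alpha = ex / total[adst]
        msgs = (alpha[:, :, None] * z[asrc]).reshape(-1, K * Dh)
        pre = batch["scat_adst"] @ msgs + b
        out = np.maximum(pre, 0.0)
        cache.append(("attention", f"att{l}", h, z, logits, alpha, pre))
        if collect_attention:
            attention.append(
                {"layer": l, "src": asrc.copy(), "dst": adst.copy(), "weights": alpha.copy()}
            )
        h = maybe_dropout(out)

    for l in range(cfg.conv_layers):
        Wself, Wnb = params[f"conv{l}_Wself"], params[f"conv{l}_Wnb"]
        b = params[f"conv{l}_b"]
        # sum aggregation over incoming neighbours (degree-sensitive)
        agg = batch["scat_dst"] @ h[src]
        pre = h @ Wself + agg @ Wnb + b
        out = np.maximum(pre, 0.0)
        cache.append(("conv", f"conv{l}", h, agg, pre))
        h = maybe_dropout(out)

    # pooling over nodes per graph
    if cfg.pooling == "max":
        pooled = _seg_max(h, batch["gid_starts"], batch["counts"])
        cache.append(("pool_max", h, pooled))
    else:
        pooled = batch["scat_gid"] @ h
        if cfg.pooling == "mean":
            pooled = pooled / counts[:, None]
        cache.append(("pool_add", None, None))
    p = pooled

    for i in range(cfg.head_layers):
        W, b = params[f"head{i}_W"], params[f"head{i}_b"]
        pre = p @ W + b
        if i < cfg.head_layers - 1:
            out = np.maximum(pre, 0.0)
            cache.append(("linear_relu", f"head{i}", p, pre))
            p = maybe_dropout(out)
        else:
            cache.append(("linear", f"head{i}", p, pre))
            p = pre

    preds = p[:, 0]
    return preds, cache, attention


def _backward_pass(
    params: Mapping[str, np.ndarray],
    batch: dict,
    cfg: ModelConfig,
    cache: list[tuple],
    dpreds: np.ndarray,
) -> dict[str, np.ndarray]:
    N = batch["X"].shape[0]
    K = cfg.attention_heads
    Dh = cfg.hidden_dim // K
    asrc, adst = batch["asrc"], batch["adst"]
    src, dst = batch["src"], batch["dst"]
    gid, counts = batch["gid"], batch["counts"]
    grads: dict[str, np.ndarray] = {k: np.zeros_like(v) for k, v in params.items()}
    d = dpreds[:, None]

    for entry in reversed(cache):
        kind = entry[0]
        if kind == "dropout":
            mask = entry[1]
            if mask is not None:
                d = d * mask
        elif kind == "linear":
            _, name, x, pre = entry
            grads[f"{name}_W"] += x.T @ d
            grads[f"{name}_b"] += d.sum(axis=0)
            d = d @ params[f"{name}_W"].T
        elif kind == "linear_relu":
            _, name, x, pre = entry
            dpre = d * (pre > 0)
            grads[f"{name}_W"] += x.T @ dpre
            grads[f"{name}_b"] += dpre.sum(axis=0)
            d = dpre @ params[f"{name}_W"].T
        elif kind == "pool_add":
            if cfg.pooling == "mean":
                d = d[gid] / counts[gid][:, None]
            else:
                d = d[gid]
        elif kind == "pool_max":
            _, h, pooled = entry
            mask = h == pooled[gid]
            share = np.zeros_like(pooled)
            np.add.at(share, gid, mask.astype(np.float64))
            d = mask * d[gid] / np.maximum(share, 1.0)[gid]
        elif kind == "conv":
            _, name, x, agg, pre = entry
            dpre = d * (pre > 0)
            grads[f"{name}_Wself"] += x.T @ dpre
            grads[f"{name}_Wnb"] += agg.T @ dpre
            grads[f"{name}_b"] += dpre.sum(axis=0)
            dx = dpre @ params[f"{name}_Wself"].T
            dagg = dpre @ params[f"{name}_Wnb"].T
            dx += batch["scat_src"] @ dagg[dst]
            d = dx
        elif kind == "attention":
            _, name, x, z, logits, alpha, pre = entry
            W = params[f"{name}_W"]
            a_src, a_dst = params[f"{name}_asrc"], params[f"{name}_adst"]
            dpre = d * (pre > 0)
            grads[f"{name}_b"] += dpre.sum(axis=0)
            dout3 = dpre.reshape(N, K, Dh)
            dalpha = np.einsum("akd,akd->ak", dout3[adst], z[asrc])
            dz = (
                batch["scat_asrc"]
                @ (alpha[:, :, None] * dout3[adst]).reshape(-1, K * Dh)
            ).reshape(N, K, Dh)
            t = alpha * dalpha
            tsum = batch["scat_adst"] @ t
            del_ = alpha * (dalpha - tsum[adst])
            dlogits = del_ * np.where(logits > 0, 1.0, 0.2)
            dssrc = batch["scat_asrc"] @ dlogits
            dsdst = batch["scat_adst"] @ dlogits
            grads[f"{name}_asrc"] += np.einsum("nkd,nk->kd", z, dssrc)
            grads[f"{name}_adst"] += np.einsum("nkd,nk->kd", z, dsdst)
            dz += dssrc[:, :, None] * a_src[None] + dsdst[:, :, None] * a_dst[None]
            dz2 = dz.reshape(N, K * Dh)
            grads[f"{name}_W"] += x.T @ dz2
            d = dz2 @ W.T
        else:  # pragma: no cover
            raise RuntimeError(f"unknown cache entry {kind!r}")
    return grads


def _loss_and_grads(
    params: Mapping[str, np.ndarray],
    batch: dict,
    cfg: ModelConfig,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    preds, cache, _ = _forward_pass(
        params, batch, cfg, training=True, dropout_rng=dropout_rng
    )
    y = batch["y"]
    resid = preds - y
    loss = float(np.mean(resid**2))
    dpreds = 2.0 * resid / len(y)
    grads = _backward_pass(params, batch, cfg, cache, dpreds)
    return loss, grads, preds


# ---------------------------------------------------------------------------
# public inference API


def _check_compat(model: TrainedModel, g: GuideGraph, index: int | None = None) -> None:
    if g.feature_dim != model.feature_dim:
        where = f" (graph index {index})" if index is not None else ""
        raise ValueError(
            f"feature dimension mismatch{where}: graph has {g.feature_dim}, "
            f"model expects {model.feature_dim}"
        )


def forward(
    model: TrainedModel, g: GuideGraph, return_attention: bool = False
) -> float | tuple[float, list[dict]]:
    """Predict efficiency for a single graph (evaluation mode, deterministic).

    With ``return_attention=True`` also returns, per attention layer, the arc
    list (including self-loops) and per-head softmax weights; each node's
    incoming weights sum to 1.
    """
    _check_compat(model, g)
    batch = _make_batch([g])
    preds, _, attention = _forward_pass(
        model.params, batch, model.config, collect_attention=return_attention
    )
    value = float(preds[0])
    if not np.isfinite(value):
        raise FloatingPointError("non-finite prediction")
    if return_attention:
        return value, attention
    return value


def predict(
    model: TrainedModel, graphs: Sequence[GuideGraph], batch_size: int = 256
) -> np.ndarray:
    """Order-preserving predictions for a list of graphs."""
    if len(graphs) == 0:
        return np.zeros(0)
    for i, g in enumerate(graphs):
        _check_compat(model, g, index=i)
    out = []
    for start in range(0, len(graphs), batch_size):
        batch = _make_batch(graphs[start : start + batch_size])
        preds, _, _ = _forward_pass(model.params, batch, model.config)
        out.append(preds)
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: Mapping[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: Mapping[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            params[k] = params[k] - self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def _eval_mse(params, graphs, cfg, batch_size: int = 512) -> float:
    total, n = 0.0, 0
    for start in range(0, len(graphs), batch_size):
        batch = _make_batch(graphs[start : start + batch_size], require_labels=True)
        preds, _, _ = _forward_pass(params, batch, cfg)
        total += float(np.sum((preds - batch["y"]) ** 2))
        n += len(batch["y"])
    return total / n


def train(
    model: TrainedModel,
    train_graphs: Sequence[GuideGraph],
    val_graphs: Sequence[GuideGraph],
    cfg: ModelConfig | None = None,
) -> TrainedModel:
    """Train by minibatch Adam on MSE with early stopping on validation MSE.

    Returns a new :class:`TrainedModel` holding the parameters of the best
    validation epoch and the full loss history. Fully deterministic given
    ``cfg.seed``.
    """
    cfg = cfg or model.config
    if not train_graphs or not val_graphs:
        raise ValueError("train and validation splits must be non-empty")
    train_ids = {g.meta.get("id") for g in train_graphs} - {None}
    val_ids = {g.meta.get("id") for g in val_graphs} - {None}
    overlap = train_ids & val_ids
    if overlap:
        raise ValueError(f"train/validation overlap: {sorted(overlap)[:5]}")
    for g in list(train_graphs) + list(val_graphs):
        if g.label is None:
            raise ValueError(f"unlabelled graph {g.meta.get('id')!r} in training data")
        _check_compat(model, g)

    params = {k: v.copy() for k, v in model.params.items()}
    opt = _Adam(params, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    dropout_rng = np.random.default_rng(cfg.seed + 2)
    history = TrainingHistory()
    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    bad_epochs = 0

    n = len(train_graphs)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = _make_batch([train_graphs[i] for i in idx], require_labels=True)
            loss, grads, _ = _loss_and_grads(params, batch, cfg, dropout_rng)
            opt.step(params, grads)
            epoch_loss += loss * len(idx)
            seen += len(idx)
        val_mse = _eval_mse(params, val_graphs, cfg)
        history.train_loss.append(epoch_loss / seen)
        history.val_loss.append(val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best_params = {k: v.copy() for k, v in params.items()}
            history.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.patience:
                break
    return TrainedModel(
        config=cfg,
        params=best_params,
        feature_dim=model.feature_dim,
        history=history,
    )


def fine_tune(
    model: TrainedModel,
    graphs: Sequence[GuideGraph],
    cfg: ModelConfig | None = None,
) -> TrainedModel:
    """Continue optimization from a trained model's parameters.

    Runs ``cfg.max_epochs`` epochs of minibatch Adam at ``cfg.learning_rate``
    (default: a tenth of the original rate) with no early stopping; zero
    epochs returns the model unchanged.
    """
    if not graphs:
        raise ValueError("empty fine-tuning dataset")
    if cfg is None:
        cfg = replace(
            model.config,
            learning_rate=model.config.learning_rate * 0.1,
            max_epochs=10,
        )
    for g in graphs:
        if g.label is None:
            raise ValueError(f"unlabelled graph {g.meta.get('id')!r}")
        _check_compat(model, g)
    params = {k: v.copy() for k, v in model.params.items()}
    history = copy.deepcopy(model.history)
    if cfg.max_epochs == 0:
        return TrainedModel(
            config=cfg, params=params, feature_dim=model.feature_dim, history=history
        )
    opt = _Adam(params, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    dropout_rng = np.random.default_rng(cfg.seed + 2)
    n = len(graphs)
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = _make_batch([graphs[i] for i in idx], require_labels=True)
            loss, grads, _ = _loss_and_grads(params, batch, cfg, dropout_rng)
            opt.step(params, grads)
            epoch_loss += loss * len(idx)
            seen += len(idx)
        history.train_loss.append(epoch_loss / seen)
    return TrainedModel(
        config=cfg, params=params, feature_dim=model.feature_dim, history=history
    )


# ---------------------------------------------------------------------------
# random hyperparameter search


def random_search(
    space: Mapping[str, object],
    trials: int,
    train_graphs: Sequence[GuideGraph],
    val_graphs: Sequence[GuideGraph],
    seed: int = 0,
    base_cfg: ModelConfig | None = None,
) -> tuple[ModelConfig, list[dict]]:
    """Seeded uniform random search over a config space, MSE objective.

    ``space`` maps :class:`ModelConfig` field names to either a list of
    choices or a ``(low, high)`` tuple sampled uniformly (integer fields get
    integers, inclusive). Returns the config with the lowest validation MSE
    and the full trial table.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not space:
        raise ValueError("empty search space")
    base_cfg = base_cfg or ModelConfig()
    valid_fields = set(asdict(base_cfg))
    unknown = set(space) - valid_fields
    if unknown:
        raise ValueError(f"unknown config fields in space: {sorted(unknown)}")
    int_fields = {
        k for k, v in asdict(base_cfg).items() if isinstance(v, int) and k != "dropout"
    }
    rng = np.random.default_rng(seed)
    table: list[dict] = []
    best_cfg, best_mse = None, np.inf
    feature_dim = train_graphs[0].feature_dim
    for t in range(trials):
        overrides = {}
        for name, spec in space.items():
            if isinstance(spec, (list, tuple)) and len(spec) == 2 and not isinstance(
                spec, list
            ):
                low, high = spec
                if name in int_fields:
                    overrides[name] = int(rng.integers(int(low), int(high) + 1))
                else:
                    overrides[name] = float(rng.uniform(low, high))
            else:
                choices = list(spec)
                overrides[name] = choices[int(rng.integers(len(choices)))]
        cfg = replace(base_cfg, **overrides)
        model = init_model(cfg, feature_dim)
        fitted = train(model, train_graphs, val_graphs, cfg)
        val_mse = min(fitted.history.val_loss)
        table.append({"trial": t, **overrides, "val_mse": val_mse})
        if val_mse < best_mse:
            best_mse, best_cfg = val_mse, cfg
    return best_cfg, table


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: TrainedModel, path: str | Path) -> None:
    """Save parameters to ``path`` (npz) plus a text metadata sidecar.

    The sidecar ``<path>.meta.json`` records config, feature_dim, seed, code
    version, and a checksum of the parameter file for integrity verification.
    """
    path = Path(path)
    np.savez(
        path,
        **model.params,
        __history_train=np.array(model.history.train_loss),
        __history_val=np.array(model.history.val_loss),
        __best_epoch=np.array(model.history.best_epoch),
    )
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    meta = {
        "format": "guidegraph-checkpoint",
        "version": _VERSION,
        "config": asdict(model.config),
        "feature_dim": model.feature_dim,
        "seed": model.config.seed,
        "sha256": digest,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def load_checkpoint(path: str | Path) -> TrainedModel:
    """Load a checkpoint; predictions reproduce bit-identically."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    meta_path = Path(str(path) + ".meta.json")
    if not path.exists() or not meta_path.exists():
        raise CheckpointError(f"checkpoint {path} or its metadata sidecar is missing")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise CheckpointError(f"corrupted metadata sidecar: {exc}") from exc
    if meta.get("format") != "guidegraph-checkpoint":
        raise CheckpointError("not a guidegraph checkpoint")
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != meta["sha256"]:
        raise CheckpointError("checkpoint checksum mismatch (file corrupted?)")
    try:
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
    except Exception as exc:
        raise CheckpointError(f"unreadable checkpoint: {exc}") from exc
    history = TrainingHistory(
        train_loss=arrays.pop("__history_train").tolist(),
        val_loss=arrays.pop("__history_val").tolist(),
        best_epoch=int(arrays.pop("__best_epoch")),
    )
    cfg = ModelConfig(**meta["config"])
    model = TrainedModel(
        config=cfg,
        params=arrays,
        feature_dim=int(meta["feature_dim"]),
        history=history,
    )
    expected = init_model(cfg, model.feature_dim).params
    if set(arrays) != set(expected):
        raise CheckpointError("checkpoint parameters do not match its config")
    for k, v in expected.items():
        if arrays[k].shape != v.shape:
            raise CheckpointError(
                f"parameter {k!r} has shape {arrays[k].shape}, "
                f"config implies {v.shape}"
            )
    return model
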