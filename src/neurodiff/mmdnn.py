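"""Two-stage multi-scale multi-type fusion network.

Six branch MLPs (one per feature-set block) are pretrained independently
with temporary softmax heads; their 50-unit embeddings are concatenated
into a fusion MLP, which is trained on frozen embeddings and then the
whole network is fine-tuned jointly.  Training uses weighted cross-entropy
(inverse class-frequency weights), Adam, dropout 0.5 and early stopping
with patience 20 on a validation split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from neurodiff._nn import (
    MLP,
    EarlyStopper,
    early_stopping_controller,
    make_optimizer,
    softmax,
)
from neurodiff.datamodel import FeatureSetSpec, FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "ClassifierModel",
    "branch_layer_sizes",
    "fusion_layer_sizes",
    "class_weights",
    "weighted_cross_entropy",
    "pretrain_branches",
    "train_fusion_and_finetune",
    "train_mmdnn",
    "predict",
    "early_stopping_controller",
]


def branch_layer_sizes(n: int) -> list[int]:
    """Hidden sizes of a branch for input width ``n``: [3n, round(3n/4), 50]."""
    if n < 1:
        raise ValueError("input dimension must be >= 1")
    return [3 * n, int(round(3 * n / 4)), 50]


def fusion_layer_sizes(n_in: int = 300) -> list[int]:
    """Default fusion hidden sizes, same reduction rule on the 300-d input."""
    return branch_layer_sizes(n_in)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (defaults follow the published protocol)."""

    lr: float = 5e-5
    batch_size: int = 100
    dropout: float = 0.5
    patience: int = 20
    max_epochs: int = 200
    pretrain_epochs: int | None = None  # fall back to max_epochs
    fusion_epochs: int | None = None
    finetune_epochs: int | None = None
    val_fraction: float = 0.1
    seed: int = 0
    fusion_hidden: tuple | None = None  # None -> fusion_layer_sizes(300)
    optimizer: str = "adam"

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not self.lr > 0:
            raise ValueError("lr must be > 0")

    def with_seed(self, seed: int) -> "TrainConfig":
        return replace(self, seed=seed)


# -- losses ----------------------------------------------------------------


def class_weights(labels: Sequence[int], n_classes: int) -> np.ndarray:
    """Inverse-proportion class weights: W_j = N_total / count_j.

    Classes absent from ``labels`` get weight 0.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label list")
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("labels out of range")
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    weights = np.zeros(n_classes)
    present = counts > 0
    weights[present] = labels.size / counts[present]
    return weights


def weighted_cross_entropy(
    probs: np.ndarray, labels: Sequence[int], weights: np.ndarray
) -> float:
    """−(1/N) Σ_i W_{y_i} log p_{i,y_i}, probabilities clipped to [1e-12, 1]."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    weights = np.asarray(weights, dtype=float)
    if probs.ndim != 2 or probs.shape[0] != labels.shape[0]:
        raise ValueError("probs/labels shape mismatch")
    if weights.shape[0] != probs.shape[1]:
        raise ValueError("weights length must equal number of classes")
    p = np.clip(probs[np.arange(labels.size), labels], 1e-12, 1.0)
    return float(-(weights[labels] * np.log(p)).mean())


def wce_logit_gradient(
    probs: np.ndarray, labels: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Gradient of the weighted CE wrt softmax logits."""
    n = labels.shape[0]
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (weights[labels] / n)[:, None]
    return grad


# -- model -----------------------------------------------------------------


class ClassifierModel:
    """Six branch MLPs plus a fusion MLP over their concatenated embeddings.

    ``n_classes`` is 3 (NC/AD/FTD) or 4 when the model doubles as a GAN
    discriminator with a fake channel.
    """

    EMBED_DIM = 50

    def __init__(
        self,
        specs: Sequence[FeatureSetSpec],
        n_classes: int = 3,
        fusion_hidden: Sequence[int] | None = None,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.specs = tuple(specs)
        self.n_classes = n_classes
        self.branches = [
            MLP(
                [s.dimension] + branch_layer_sizes(s.dimension),
                ["relu", "relu", "relu"],
                rng,
            )
            for s in self.specs
        ]
        fused_in = self.EMBED_DIM * len(self.branches)
        hidden = list(fusion_hidden) if fusion_hidden else fusion_layer_sizes(fused_in)
        self.fusion = MLP(
            [fused_in] + hidden + [n_classes],
            ["relu"] * len(hidden) + ["linear"],
            rng,
        )

    # -- structure --------------------------------------------------------

    @property
    def n_mlp_blocks(self) -> int:
        return len(self.branches) + 1

    @property
    def input_dim(self) -> int:
        return sum(s.dimension for s in self.specs)

    def block_slices(self) -> list[slice]:
        out, start = [], 0
        for s in self.specs:
            out.append(slice(start, start + s.dimension))
            start += s.dimension
        return out

    def param_arrays(self, include_branches: bool = True) -> list[np.ndarray]:
        params = []
        if include_branches:
            for b in self.branches:
                params.extend(b.param_arrays())
        params.extend(self.fusion.param_arrays())
        return params

    # -- forward / backward ----------------------------------------------

    def forward_logits(self, x, *, train=False, dropout=0.0, rng=None):
        x = np.asarray(x, dtype=float)
        embs, caches, masks = [], [], []
        for b, sl in zip(self.branches, self.block_slices()):
            emb, cache = b.forward(x[:, sl], train=train, dropout=dropout, rng=rng)
            mask = None
            if train and dropout > 0.0:
                # the 50-unit embedding is a hidden layer of the full network
                mask = (rng.random(emb.shape) >= dropout) / (1.0 - dropout)
                emb = emb * mask
            embs.append(emb)
            caches.append(cache)
            masks.append(mask)
        fused = np.concatenate(embs, axis=1)
        logits, fcache = self.fusion.forward(
            fused, train=train, dropout=dropout, rng=rng
        )
        return logits, (caches, masks, fcache)

    def backward(self, ctx, grad_logits, include_branches=True):
        """Return (param grads, grad wrt input); input grad is None when
        ``include_branches`` is False."""
        caches, masks, fcache = ctx
        fgrads, grad_fused = self.fusion.backward(fcache, grad_logits)
        grads = []
        grad_input = None
        if include_branches:
            start = 0
            input_parts = []
            for b, cache, mask in zip(self.branches, caches, masks):
                g = grad_fused[:, start : start + self.EMBED_DIM]
                start += self.EMBED_DIM
                if mask is not None:
                    g = g * mask
                bgrads, g_in = b.backward(cache, g)
                input_parts.append(g_in)
                for gw, gb in bgrads:
                    grads.extend([gw, gb])
            grad_input = np.concatenate(input_parts, axis=1)
        for gw, gb in fgrads:
            grads.extend([gw, gb])
        return grads, grad_input

    # -- inference --------------------------------------------------------

    def predict_proba(self, x) -> np.ndarray:
        logits, _ = self.forward_logits(x, train=False)
        return softmax(logits)

    def predict_proba_real(self, x) -> np.ndarray:
        """Softmax over the first three channels only (GAN test-time rule)."""
        logits, _ = self.forward_logits(x, train=False)
        return softmax(logits[:, :3])

    def get_state(self):
        return [p.copy() for p in self.param_arrays()]

    def set_state(self, state):
        for p, s in zip(self.param_arrays(), state):
            p[...] = s


def predict(model: ClassifierModel, rows) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (ties -> lowest class index)."""
    x = rows.values if isinstance(rows, FeatureTable) else np.asarray(rows, float)
    if x.shape[1] != model.input_dim:
        raise ValueError(
            f"input dimension {x.shape[1]} != model dimension {model.input_dim}"
        )
    probs = model.predict_proba(x)
    return probs, probs.argmax(axis=1)


# -- training --------------------------------------------------------------


@dataclass
class TrainHistory:
    train_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)
    best_epoch: int | None = None
    stop_epoch: int | None = None


def _check_finite(loss: float, where: str) -> None:
    if not np.isfinite(loss):
        raise RuntimeError(f"non-finite loss during {where}: {loss}")


def _split_validation(n_rows: int, val_fraction: float, rng: np.random.Generator):
    n_val = max(1, int(round(n_rows * val_fraction)))
    perm = rng.permutation(n_rows)
    return perm[n_val:], perm[:n_val]


def _train_loop(
    *,
    forward,
    backward,
    params,
    x_train,
    y_train,
    x_val,
    y_val,
    weights,
    cfg: TrainConfig,
    epochs: int,
    rng: np.random.Generator,
    where: str,
) -> TrainHistory:
    """Generic minibatch loop with early stopping and best-state restore.

    ``forward(xb, train)`` returns (probs, ctx); ``backward(ctx, grad)``
    returns gradients aligned with ``params``.
    """
    opt = make_optimizer(cfg.optimizer, params, cfg.lr)
    stopper = EarlyStopper(cfg.patience)
    hist = TrainHistory()
    n = x_train.shape[0]
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probs, ctx = forward(x_train[idx], True)
            loss = weighted_cross_entropy(probs, y_train[idx], weights)
            _check_finite(loss, where)
            epoch_loss += loss * idx.size
            grads = backward(ctx, wce_logit_gradient(probs, y_train[idx], weights))
            opt.step(grads)
        hist.train_losses.append(epoch_loss / n)
        val_probs, _ = forward(x_val, False)
        val_loss = weighted_cross_entropy(val_probs, y_val, weights)
        _check_finite(val_loss, where)
        hist.val_losses.append(val_loss)
        if stopper.update(val_loss, params):
            break
    if stopper.best_state is not None:
        for p, s in zip(params, stopper.best_state):
            p[...] = s
    hist.best_epoch = stopper.best_epoch
    hist.stop_epoch = stopper.epoch if stopper.epoch < epochs else None
    return hist


def _resolve_rows(table_or_x, specs=None):
    if isinstance(table_or_x, FeatureTable):
        return table_or_x.values, table_or_x.specs
    if specs is None:
        raise ValueError("specs required when passing a bare array")
    return np.asarray(table_or_x, dtype=float), tuple(specs)


def pretrain_branches(
    train,
    labels,
    cfg: TrainConfig,
    *,
    specs=None,
    n_classes: int = 3,
    val_idx=None,
):
    """Stage 1: train each branch independently with a temporary head.

    Returns (list of branch MLPs, list of TrainHistory).  The temporary
    K-way heads are discarded; the 50-unit layer is the branch embedding.
    """
    x, specs = _resolve_rows(train, specs)
    y = np.asarray(labels, dtype=int)
    ss = np.random.SeedSequence(cfg.seed)
    rng_init, rng_split, rng_batch = [np.random.default_rng(s) for s in ss.spawn(3)]
    if val_idx is None:
        tr_idx, va_idx = _split_validation(x.shape[0], cfg.val_fraction, rng_split)
    else:
        va_idx = np.asarray(val_idx, dtype=int)
        tr_idx = np.setdiff1d(np.arange(x.shape[0]), va_idx)
    weights = class_weights(y[tr_idx], n_classes)
    epochs = cfg.pretrain_epochs or cfg.max_epochs

    branches, histories = [], []
    start = 0
    for spec in specs:
        sl = slice(start, start + spec.dimension)
        start += spec.dimension
        branch = MLP(
            [spec.dimension] + branch_layer_sizes(spec.dimension),
            ["relu", "relu", "relu"],
            rng_init,
        )
        head = MLP([ClassifierModel.EMBED_DIM, n_classes], ["linear"], rng_init)
        params = branch.param_arrays() + head.param_arrays()

        def fwd(xb, train_mode, branch=branch, head=head):
            emb, bc = branch.forward(
                xb, train=train_mode, dropout=cfg.dropout, rng=rng_batch
            )
            mask = None
            if train_mode and cfg.dropout > 0:
                mask = (rng_batch.random(emb.shape) >= cfg.dropout) / (1 - cfg.dropout)
                emb = emb * mask
            logits, hc = head.forward(emb)
            return softmax(logits), (bc, mask, hc)

        def bwd(ctx, grad_logits, branch=branch, head=head):
            bc, mask, hc = ctx
            hgrads, g_emb = head.backward(hc, grad_logits)
            if mask is not None:
                g_emb = g_emb * mask
            bgrads, _ = branch.backward(bc, g_emb)
            grads = []
            for gw, gb in bgrads:
                grads.extend([gw, gb])
            for gw, gb in hgrads:
                grads.extend([gw, gb])
            return grads

        hist = _train_loop(
            forward=fwd,
            backward=bwd,
            params=params,
            x_train=x[tr_idx][:, sl],
            y_train=y[tr_idx],
            x_val=x[va_idx][:, sl],
            y_val=y[va_idx],
            weights=weights,
            cfg=cfg,
            epochs=epochs,
            rng=rng_batch,
            where=f"branch pretraining ({spec.name})",
        )
        branches.append(branch)
        histories.append(hist)
        logger.debug(
            "pretrained branch %s: best epoch %s val loss %.4f",
            spec.name, hist.best_epoch,
            hist.val_losses[hist.best_epoch - 1] if hist.best_epoch else float("nan"),
        )
    return branches, histories


def train_fusion_and_finetune(
    branches,
    train,
    labels,
    cfg: TrainConfig,
    *,
    specs=None,
    n_classes: int = 3,
    val_idx=None,
):
    """Stage 2: fusion MLP on frozen embeddings, then joint fine-tuning."""
    x, specs = _resolve_rows(train, specs)
    y = np.asarray(labels, dtype=int)
    ss = np.random.SeedSequence(cfg.seed + 1)
    rng_init, rng_split, rng_batch = [np.random.default_rng(s) for s in ss.spawn(3)]
    if val_idx is None:
        tr_idx, va_idx = _split_validation(x.shape[0], cfg.val_fraction, rng_split)
    else:
        va_idx = np.asarray(val_idx, dtype=int)
        tr_idx = np.setdiff1d(np.arange(x.shape[0]), va_idx)
    weights = class_weights(y[tr_idx], n_classes)

    model = ClassifierModel.__new__(ClassifierModel)
    model.specs = tuple(specs)
    model.n_classes = n_classes
    model.branches = list(branches)
    fused_in = ClassifierModel.EMBED_DIM * len(branches)
    hidden = list(cfg.fusion_hidden) if cfg.fusion_hidden else fusion_layer_sizes(fused_in)
    model.fusion = MLP(
        [fused_in] + hidden + [n_classes], ["relu"] * len(hidden) + ["linear"], rng_init
    )

    # stage 2a: fusion on frozen branch embeddings
    slices = model.block_slices()
    emb_all = np.concatenate(
        [b.forward(x[:, sl])[0] for b, sl in zip(model.branches, slices)], axis=1
    )

    def f_fwd(xb, train_mode):
        logits, fc = model.fusion.forward(
            xb, train=train_mode, dropout=cfg.dropout, rng=rng_batch
        )
        return softmax(logits), fc

    def f_bwd(ctx, grad_logits):
        fgrads, _ = model.fusion.backward(ctx, grad_logits)
        grads = []
        for gw, gb in fgrads:
            grads.extend([gw, gb])
        return grads

    hist_fusion = _train_loop(
        forward=f_fwd,
        backward=f_bwd,
        params=model.fusion.param_arrays(),
        x_train=emb_all[tr_idx],
        y_train=y[tr_idx],
        x_val=emb_all[va_idx],
        y_val=y[va_idx],
        weights=weights,
        cfg=cfg,
        epochs=cfg.fusion_epochs or cfg.max_epochs,
        rng=rng_batch,
        where="fusion training",
    )

    # stage 2b: joint fine-tuning of all seven blocks
    def j_fwd(xb, train_mode):
        logits, ctx = model.forward_logits(
            xb, train=train_mode, dropout=cfg.dropout, rng=rng_batch
        )
        return softmax(logits), ctx

    def j_bwd(ctx, grad_logits):
        grads, _ = model.backward(ctx, grad_logits, include_branches=True)
        return grads

    hist_finetune = _train_loop(
        forward=j_fwd,
        backward=j_bwd,
        params=model.param_arrays(),
        x_train=x[tr_idx],
        y_train=y[tr_idx],
        x_val=x[va_idx],
        y_val=y[va_idx],
        weights=weights,
        cfg=cfg,
        epochs=cfg.finetune_epochs or cfg.max_epochs,
        rng=rng_batch,
        where="joint fine-tuning",
    )
    return model, {"fusion": hist_fusion, "finetune": hist_finetune}


def train_mmdnn(
    train,
    labels,
    cfg: TrainConfig,
    *,
    specs=None,
    n_classes: int = 3,
    val_idx=None,
):
    """Full two-stage training; returns (ClassifierModel, histories)."""
    branches, pre_hist = pretrain_branches(
        train, labels, cfg, specs=specs, n_classes=n_classes, val_idx=val_idx
    )
    model, hist = train_fusion_and_finetune(
        branches, train, labels, cfg, specs=specs, n_classes=n_classes, val_idx=val_idx
    )
    hist["pretrain"] = pre_hist
    return model, hist


# -- checkpoint container --------------------------------------------------


def save_model(model: ClassifierModel, path) -> None:
    """Single-file npz container with a JSON manifest and all weights."""
    manifest = {
        "n_classes": model.n_classes,
        "specs": [
            {"feature_type": s.feature_type, "scale": s.scale, "dimension": s.dimension}
            for s in model.specs
        ],
        "fusion_sizes": model.fusion.sizes,
    }
    arrays = {"manifest": np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8)}
    for bi, b in enumerate(model.branches):
        for li, layer in enumerate(b.layers):
            arrays[f"branch{bi}_l{li}_W"] = layer.W
            arrays[f"branch{bi}_l{li}_b"] = layer.b
    for li, layer in enumerate(model.fusion.layers):
        arrays[f"fusion_l{li}_W"] = layer.W
        arrays[f"fusion_l{li}_b"] = layer.b
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path) -> ClassifierModel:
    with np.load(path) as data:
        manifest = json.loads(bytes(data["manifest"]).decode())
        specs = [FeatureSetSpec(**s) for s in manifest["specs"]]
        fusion_sizes = manifest["fusion_sizes"]
        model = ClassifierModel(
            specs,
            n_classes=manifest["n_classes"],
            fusion_hidden=fusion_sizes[1:-1],
            rng=np.random.default_rng(0),
        )
        for bi, b in enumerate(model.branches):
            for li, layer in enumerate(b.layers):
                layer.W = data[f"branch{bi}_l{li}_W"]
                layer.b = data[f"branch{bi}_l{li}_b"]
        for li, layer in enumerate(model.fusion.layers):
            layer.W = data[f"fusion_l{li}_W"]
            layer.b = data[f"fusion_l{li}_b"]
    return model
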