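"""GAN augmentation over 1-D feature vectors.

The generator maps 100-d standard-normal noise through a 512-unit ReLU
hidden layer to a tanh output the width of the concatenated feature vector,
so synthesized rows live in (-1, 1) — the range real rows are mapped to by
:class:`RangeNormalizer`.  The discriminator is the fusion classifier with
a fourth "fake" channel; both are optimized alternately with the weighted
cross-entropy objective.  The printed generator objective ``log(-D(G(z)))``
is not a real-valued function of probabilities, so the non-saturating form
``-log(1 - p_fake)`` is used, matching the stated motivation of avoiding
vanishing gradients and mode collapse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from neurodiff._nn import MLP, EarlyStopper, make_optimizer, softmax
from neurodiff.datamodel import FeatureTable
from neurodiff.mmdnn import (
    TrainConfig,
    class_weights,
    pretrain_branches,
    train_fusion_and_finetune,
    wce_logit_gradient,
    weighted_cross_entropy,
)

logger = logging.getLogger(__name__)

FAKE_CLASS = 3  # index of the fake channel in the 4-way discriminator


@dataclass(frozen=True)
class GanConfig:
    noise_dim: int = 100
    hidden: int = 512
    epochs: int | None = None  # fall back to TrainConfig.max_epochs
    d_steps: int = 1
    g_steps: int = 1
    fake_ratio: float = 1.0  # fake batch size relative to the real batch
    g_lr: float | None = None  # fall back to TrainConfig.lr


class Generator:
    """Noise-to-feature generator: [noise, hidden(relu), out(tanh)]."""

    def __init__(self, out_dim: int, cfg: GanConfig = GanConfig(), rng=None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.out_dim = out_dim
        self.net = MLP([cfg.noise_dim, cfg.hidden, out_dim], ["relu", "tanh"], rng)

    def forward(self, z):
        return self.net.forward(z)

    def param_arrays(self):
        return self.net.param_arrays()


def generate(gen: Generator, n: int, seed: int = 0) -> np.ndarray:
    """``n`` synthetic rows on the range-normalized scale, in (-1, 1)."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, gen.cfg.noise_dim))
    out, _ = gen.forward(z)
    return out


class RangeNormalizer:
    """Per-feature min/max map to [-1, 1], fitted on the training split.

    Out-of-range values are clipped before mapping; degenerate features
    (min == max) map to 0 with a warning.
    """

    def __init__(self):
        self.min_ = None
        self.max_ = None

    def fit(self, x: np.ndarray) -> "RangeNormalizer":
        x = np.asarray(x, dtype=float)
        self.min_ = x.min(axis=0)
        self.max_ = x.max(axis=0)
        degenerate = self.max_ == self.min_
        if degenerate.any():
            logger.warning(
                "%d degenerate feature(s) (min == max) map to 0", degenerate.sum()
            )
        return self

    def _check(self):
        if self.min_ is None:
            raise RuntimeError("normalizer not fitted")

    def transform(self, x: np.ndarray) -> np.ndarray:
        self._check()
        x = np.clip(np.asarray(x, dtype=float), self.min_, self.max_)
        span = self.max_ - self.min_
        out = np.zeros_like(x)
        ok = span > 0
        out[:, ok] = -1.0 + 2.0 * (x[:, ok] - self.min_[ok]) / span[ok]
        return out

    def inverse(self, v: np.ndarray) -> np.ndarray:
        self._check()
        v = np.asarray(v, dtype=float)
        span = self.max_ - self.min_
        return self.min_ + (v + 1.0) / 2.0 * span


def range_normalize(table: FeatureTable, normalizer: RangeNormalizer) -> FeatureTable:
    return table.with_values(normalizer.transform(table.values))


def range_denormalize(table: FeatureTable, normalizer: RangeNormalizer) -> FeatureTable:
    return table.with_values(normalizer.inverse(table.values))


# -- losses ----------------------------------------------------------------


def discriminator_loss(
    real_probs: np.ndarray,
    real_labels,
    fake_probs: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Weighted CE over the merged real+fake batch; fake rows carry class 3.

    When ``weights`` is None the inverse-proportion weights are computed
    from the merged batch itself (per-batch rule).
    """
    real_probs = np.asarray(real_probs, dtype=float)
    fake_probs = np.asarray(fake_probs, dtype=float)
    if real_probs.shape[0] + fake_probs.shape[0] == 0:
        raise ValueError("empty batch")
    probs = np.vstack([real_probs, fake_probs])
    labels = np.concatenate(
        [np.asarray(real_labels, dtype=int), np.full(fake_probs.shape[0], FAKE_CLASS)]
    )
    if weights is None:
        weights = class_weights(labels, 4)
    return weighted_cross_entropy(probs, labels, weights)


def generator_loss(p_fake) -> float:
    """Non-saturating objective: −mean log(1 − p_fake), clipped at 1e-12."""
    p_fake = np.asarray(p_fake, dtype=float)
    return float(-np.log(np.clip(1.0 - p_fake, 1e-12, 1.0)).mean())


def _generator_logit_gradient(probs: np.ndarray) -> np.ndarray:
    """d/dlogits of mean −log(1 − p_fake) under a 4-way softmax."""
    n = probs.shape[0]
    p_fake = probs[:, FAKE_CLASS]
    s = np.clip(1.0 - p_fake, 1e-12, 1.0)
    grad = -(p_fake / s)[:, None] * probs
    grad[:, FAKE_CLASS] = p_fake
    return grad / n


# -- training --------------------------------------------------------------


def train_gan(
    real,
    labels,
    cfg: TrainConfig,
    gan_cfg: GanConfig = GanConfig(),
    *,
    specs=None,
    val_idx=None,
):
    """Alternating GAN training; returns (Generator, ClassifierModel).

    ``real`` must already be range-normalized to [-1, 1].  The
    discriminator is the fusion classifier with four channels: its branches
    and fusion block are first trained on real data alone (the fake class
    is absent, so its weight is 0), then discriminator and generator are
    optimized alternately; early stopping watches the 3-class validation
    loss of the real channels.
    """
    if isinstance(real, FeatureTable):
        x, specs = real.values, real.specs
    else:
        if specs is None:
            raise ValueError("specs required when passing a bare array")
        x = np.asarray(real, dtype=float)
    y = np.asarray(labels, dtype=int)

    # stage 1 and fusion, with the 4-way head (fake class absent -> weight 0)
    branches, _ = pretrain_branches(
        x, y, cfg, specs=specs, n_classes=4, val_idx=val_idx
    )
    model, _ = train_fusion_and_finetune(
        branches, x, y, cfg, specs=specs, n_classes=4, val_idx=val_idx
    )

    ss = np.random.SeedSequence(cfg.seed + 2)
    rng_init, rng_batch, rng_noise = [np.random.default_rng(s) for s in ss.spawn(3)]
    gen = Generator(x.shape[1], gan_cfg, rng_init)

    if val_idx is None:
        n_val = max(1, int(round(x.shape[0] * cfg.val_fraction)))
        perm = np.random.default_rng(cfg.seed + 3).permutation(x.shape[0])
        va_idx, tr_idx = perm[:n_val], perm[n_val:]
    else:
        va_idx = np.asarray(val_idx, dtype=int)
        tr_idx = np.setdiff1d(np.arange(x.shape[0]), va_idx)
    x_tr, y_tr = x[tr_idx], y[tr_idx]
    x_va, y_va = x[va_idx], y[va_idx]
    w3 = class_weights(y_tr, 3)

    d_params = model.param_arrays()
    g_params = gen.param_arrays()
    d_opt = make_optimizer(cfg.optimizer, d_params, cfg.lr)
    g_opt = make_optimizer(cfg.optimizer, g_params, gan_cfg.g_lr or cfg.lr)
    stopper = EarlyStopper(cfg.patience)
    epochs = gan_cfg.epochs or cfg.max_epochs
    n = x_tr.shape[0]
    history = {"d_loss": [], "g_loss": [], "val_loss": []}

    def snapshot():
        return d_params + g_params

    diverged = False
    for epoch in range(1, epochs + 1):
        order = rng_batch.permutation(n)
        d_epoch, g_epoch, n_batches = 0.0, 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            n_fake = max(1, int(round(idx.size * gan_cfg.fake_ratio)))
            for _ in range(gan_cfg.d_steps):
                z = rng_noise.standard_normal((n_fake, gan_cfg.noise_dim))
                fake, _ = gen.forward(z)
                xb = np.vstack([x_tr[idx], fake])
                yb = np.concatenate([y_tr[idx], np.full(n_fake, FAKE_CLASS)])
                wb = class_weights(yb, 4)
                logits, ctx = model.forward_logits(
                    xb, train=True, dropout=cfg.dropout, rng=rng_batch
                )
                probs = softmax(logits)
                d_loss = weighted_cross_entropy(probs, yb, wb)
                if not np.isfinite(d_loss):
                    diverged = True
                    break
                grads, _ = model.backward(
                    ctx, wce_logit_gradient(probs, yb, wb), include_branches=True
                )
                d_opt.step(grads)
                d_epoch += d_loss
            if diverged:
                break
            for _ in range(gan_cfg.g_steps):
                z = rng_noise.standard_normal((n_fake, gan_cfg.noise_dim))
                fake, g_cache = gen.net.forward(z)
                logits, ctx = model.forward_logits(fake, train=False)
                probs = softmax(logits)
                g_loss = generator_loss(probs[:, FAKE_CLASS])
                if not np.isfinite(g_loss):
                    diverged = True
                    break
                _, grad_x = model.backward(
                    ctx, _generator_logit_gradient(probs), include_branches=True
                )
                g_grads, _ = gen.net.backward(g_cache, grad_x)
                flat = []
                for gw, gb in g_grads:
                    flat.extend([gw, gb])
                g_opt.step(flat)
                g_epoch += g_loss
            if diverged:
                break
            n_batches += 1
        if diverged:
            logger.warning("non-finite GAN loss at epoch %d; restoring best state", epoch)
            break
        history["d_loss"].append(d_epoch / max(1, n_batches * gan_cfg.d_steps))
        history["g_loss"].append(g_epoch / max(1, n_batches * gan_cfg.g_steps))
        val_probs = model.predict_proba_real(x_va)
        val_loss = weighted_cross_entropy(val_probs, y_va, w3)
        history["val_loss"].append(val_loss)
        if stopper.update(val_loss, snapshot()):
            break
    if stopper.best_state is not None:
        for p, s in zip(snapshot(), stopper.best_state):
            p[...] = s
    if diverged and stopper.best_state is None:
        raise RuntimeError("GAN diverged before any stable checkpoint")
    return gen, model, history
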