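"""Sequential training of the consensus multi-autoencoder.

Every mini-batch draws the *same* particle indices from all landscapes, so
the merging term compares projections of identical particles.  The batch is
then forwarded sequentially through the decoders: for each decoder ``n`` a
step loss

    sum_m sum_i ||x_i^n - D_n(E_m(x_i^m))||^2  +  (L1 + L2 + L3) / N

is computed, backpropagated, and one Adam update applied to the parameters
in that step's graph (all encoders plus decoder ``n``).  N updates are
performed per batch.  Dividing the regularisers by N keeps their total
weight per batch equal to the written objective while honouring the
per-decoder schedule.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .landscapes import LandscapeSet
from .losses import (
    BatchViews,
    LossWeights,
    distance_distribution_grads,
    distance_distribution_loss,
    latent_pair_mse,
    latent_pair_mse_grads,
    shannon_stress,
    shannon_stress_grad,
)
from .network import ConsensusNetwork, _mlp_backward, _mlp_forward

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainHistory", "AdamOptimizer", "sample_paired_batch", "train_step", "train"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimiser and schedule settings (Adam, lr 1e-5, batch 1024 by default)."""

    learning_rate: float = 1e-5
    batch_size: int = 1024
    epochs: int = 50
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    reduction: str = "sum"
    regularizer_schedule: str = "per_step"  # or "first_step_only"
    latent_dim_override: int | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.reduction not in ("sum", "mean"):
            raise ValueError("reduction must be 'sum' or 'mean'")
        if self.regularizer_schedule not in ("per_step", "first_step_only"):
            raise ValueError("regularizer_schedule must be 'per_step' or 'first_step_only'")


@dataclass
class TrainHistory:
    """Per-(epoch, batch, decoder-step) loss records."""

    records: list = field(default_factory=list)
    epoch_seconds: list = field(default_factory=list)

    def append(self, epoch: int, batch: int, decoder: int, losses: dict) -> None:
        self.records.append({"epoch": epoch, "batch": batch, "decoder_index": decoder, **losses})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def epoch_mean_total(self) -> pd.Series:
        df = self.to_dataframe()
        return df.groupby("epoch")["total"].mean()

    def save_csv(self, path) -> None:
        df = self.to_dataframe()[
            ["epoch", "batch", "decoder_index", "rep_loss", "l1", "l2", "l3", "total"]
        ]
        df.to_csv(path, index=False)


class AdamOptimizer:
    """Adam with standard moment defaults; one slot pair per parameter array."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t: dict = {}

    def update(self, key, param: np.ndarray, grad: np.ndarray) -> None:
        m = self.m.get(key)
        if m is None:
            m = self.m[key] = np.zeros_like(param)
            self.v[key] = np.zeros_like(param)
            self.t[key] = 0
        v = self.v[key]
        self.t[key] += 1
        t = self.t[key]
        m *= self.beta1
        m += (1 - self.beta1) * grad
        v *= self.beta2
        v += (1 - self.beta2) * grad**2
        mhat = m / (1 - self.beta1**t)
        vhat = v / (1 - self.beta2**t)
        param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sample_paired_batch(lset: LandscapeSet, batch_size: int, rng: np.random.Generator) -> BatchViews:
    """Draw one particle-index subset and apply it to every landscape."""
    n = lset.num_particles
    if batch_size > n:
        logger.warning("batch_size %d exceeds %d particles; using the full set", batch_size, n)
        batch_size = n
    idx = rng.choice(n, size=batch_size, replace=False)
    return BatchViews([l.X[idx] for l in lset], indices=idx)


def _check_finite(losses: dict, epoch: int, decoder: int) -> None:
    for name, v in losses.items():
        if not np.isfinite(v):
            raise FloatingPointError(
                f"non-finite loss term {name!r}={v} at epoch {epoch}, decoder {decoder}"
            )


def train_step(
    net: ConsensusNetwork,
    views: BatchViews,
    optimizer: AdamOptimizer,
    config: TrainConfig,
    history: TrainHistory | None = None,
    epoch: int = 0,
    batch: int = 0,
) -> list:
    """One paired batch through the sequential decoder schedule.

    Returns the per-decoder loss records (also appended to ``history``).
    """
    N = net.spec.N
    w = config.weights
    B = views.batch_size
    rep_scale = 1.0 / B if config.reduction == "mean" else 1.0
    records = []
    for n in range(N):
        # fresh forward pass: parameters changed in the previous decoder step
        enc_caches = [[] for _ in range(N)]
        Z = [net.encode(m, x, _cache=enc_caches[m]) for m, x in enumerate(views.inputs)]

        if config.regularizer_schedule == "per_step":
            reg_scale = 1.0 / N
        else:
            reg_scale = 1.0 if n == 0 else 0.0

        # regularizer values and gradients w.r.t. the encoded batches
        l1 = latent_pair_mse(BatchViews(views.inputs, Z), config.reduction)
        l2 = sum(shannon_stress(x, z) for x, z in zip(views.inputs, Z))
        l3 = distance_distribution_loss(BatchViews(views.inputs, Z))
        dZ = [np.zeros_like(z) for z in Z]
        if reg_scale > 0.0:
            if w.w1 > 0.0:
                for m, g in enumerate(latent_pair_mse_grads(Z, config.reduction)):
                    dZ[m] += reg_scale * w.w1 * g
            if w.w2 > 0.0:
                for m, (x, z) in enumerate(zip(views.inputs, Z)):
                    dZ[m] += reg_scale * w.w2 * shannon_stress_grad(x, z)
            if w.w3 > 0.0:
                for m, g in enumerate(distance_distribution_grads(Z)):
                    dZ[m] += reg_scale * w.w3 * g

        # decoder n reconstructs space n from every space's projection
        target = views.inputs[n]
        rep_n = 0.0
        dec_grads = None
        for m in range(N):
            cache: list = []
            Y = _mlp_forward(net.decoders[n], Z[m], cache)
            resid = Y - target
            rep_n += float(np.sum(resid**2)) * rep_scale
            dY = 2.0 * rep_scale * w.w_rep * resid
            g, dz = _mlp_backward(net.decoders[n], cache, dY)
            if dec_grads is None:
                dec_grads = g
            else:
                for acc, gi in zip(dec_grads, g):
                    acc[0] += gi[0]
                    acc[1] += gi[1]
            dZ[m] += dz

        losses = {
            "rep_loss": rep_n,
            "l1": l1,
            "l2": l2,
            "l3": l3,
            "total": w.w_rep * rep_n + reg_scale * (w.w1 * l1 + w.w2 * l2 + w.w3 * l3),
        }
        _check_finite(losses, epoch, n)

        # backprop through every encoder and apply one Adam update
        for m in range(N):
            enc_grads, _ = _mlp_backward(net.encoders[m], enc_caches[m], dZ[m])
            for k, (gW, gb) in enumerate(enc_grads):
                optimizer.update(("enc", m, k, "W"), net.encoders[m][k][0], gW)
                optimizer.update(("enc", m, k, "b"), net.encoders[m][k][1], gb)
        for k, (gW, gb) in enumerate(dec_grads):
            optimizer.update(("dec", n, k, "W"), net.decoders[n][k][0], gW)
            optimizer.update(("dec", n, k, "b"), net.decoders[n][k][1], gb)

        if history is not None:
            history.append(epoch, batch, n, losses)
        records.append(losses)
    return records


def train(
    net: ConsensusNetwork,
    lset: LandscapeSet,
    config: TrainConfig | None = None,
    checkpoint_path=None,
) -> TrainHistory:
    """Run the full schedule: shuffled paired batches for ``config.epochs``.

    The network is updated in place; the loss history is returned.  A
    checkpoint is written at the end when ``checkpoint_path`` is given.
    """
    config = config or TrainConfig()
    if lset.dims != net.spec.input_dims:
        raise ValueError(
            f"landscape dims {lset.dims} do not match network dims {net.spec.input_dims}"
        )
    rng = np.random.default_rng(config.seed)
    optimizer = AdamOptimizer(config.learning_rate)
    history = TrainHistory()
    n = lset.num_particles
    bs = min(config.batch_size, n)
    if config.batch_size > n:
        logger.warning("batch_size %d exceeds %d particles; using the full set", config.batch_size, n)
    X = lset.matrices()
    for epoch in range(config.epochs):
        t0 = time.perf_counter()
        perm = rng.permutation(n)
        batch_no = 0
        for start in range(0, n, bs):
            idx = perm[start : start + bs]
            if idx.size < 2:  # a 1-row tail batch has no distance structure
                continue
            views = BatchViews([x[idx] for x in X], indices=idx)
            train_step(net, views, optimizer, config, history, epoch=epoch, batch=batch_no)
            batch_no += 1
        history.epoch_seconds.append(time.perf_counter() - t0)
        if epoch == 0 or (epoch + 1) % 25 == 0:
            mean_total = np.mean([r["total"] for r in history.records if r["epoch"] == epoch])
            logger.info("epoch %d: mean step total %.6g", epoch, mean_total)
    if checkpoint_path is not None:
        net.save(checkpoint_path)
    return history
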