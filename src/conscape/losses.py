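"""Loss terms driving the merging of landscapes in the consensus space.

The total training objective is the sum of four terms:

* a *representation* term — squared reconstruction error of every decoder
  against every encoder's consensus projection (self and cross pairs);
* ``L1`` — squared distances between the consensus projections of the same
  particle from different spaces (the merging term);
* ``L2`` — a Sammon/Shannon-mapping stress per space, preserving the
  pairwise-distance structure of each input batch in the consensus space;
* ``L3`` — the 1-D Wasserstein distance between the pairwise-distance
  distributions of the encoded batches, matching the spread of the spaces.

Double sums over spaces run over ordered pairs ``(n, m)`` including
``n == m`` (those terms vanish for L1/L3), and batch reductions are sums,
as the objective is written; a ``mean`` reduction is available as an
option.  All functions also have gradient companions with respect to the
encoded batches, used by the sequential trainer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import wasserstein_distance

__all__ = [
    "LossWeights",
    "BatchViews",
    "self_distance_matrix",
    "latent_pair_mse",
    "shannon_stress",
    "wasserstein_1d",
    "distance_distribution_loss",
    "representation_loss",
    "total_loss",
]


class DegenerateBatchError(ValueError):
    """A batch whose points are all coincident has no distance structure."""


@dataclass(frozen=True)
class LossWeights:
    """Non-negative weights for the four loss terms (all 1 by default,
    which reproduces the plain unweighted sum)."""

    w_rep: float = 1.0
    w1: float = 1.0
    w2: float = 1.0
    w3: float = 1.0

    def __post_init__(self):
        for name in ("w_rep", "w1", "w2", "w3"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
            object.__setattr__(self, name, v)


@dataclass
class BatchViews:
    """One mini-batch seen through every space.

    ``inputs[n]`` holds the same particle rows (identical order) drawn from
    landscape ``n``; ``latents[n]`` holds the corresponding consensus
    projections ``E_n(X^n)``.
    """

    inputs: list
    latents: list | None = None
    indices: np.ndarray | None = None

    def __post_init__(self):
        rows = {x.shape[0] for x in self.inputs}
        if len(rows) != 1:
            raise ValueError(f"inconsistent batch row counts across spaces: {sorted(rows)}")
        if self.latents is not None:
            if len(self.latents) != len(self.inputs):
                raise ValueError("latents/inputs space count mismatch")
            if {z.shape[0] for z in self.latents} != rows:
                raise ValueError("latents row count differs from inputs")

    @property
    def N(self) -> int:
        return len(self.inputs)

    @property
    def batch_size(self) -> int:
        return self.inputs[0].shape[0]

    def with_latents(self, net) -> "BatchViews":
        return BatchViews(
            self.inputs, [net.encode(n, x) for n, x in enumerate(self.inputs)], self.indices
        )

    def _require_latents(self) -> list:
        if self.latents is None:
            raise ValueError("BatchViews has no encoded batches; call with_latents(net) first")
        return self.latents


def self_distance_matrix(P: np.ndarray) -> np.ndarray:
    """All-versus-all Euclidean distance matrix (symmetric, zero diagonal)."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if P.shape[0] < 2:
        raise ValueError(f"need at least 2 points, got {P.shape[0]}")
    D = cdist(P, P)
    np.fill_diagonal(D, 0.0)
    return D


def _offdiag(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    return D[~np.eye(n, dtype=bool)]


# ---------------------------------------------------------------------------
# L1: merging term


def latent_pair_mse(views: BatchViews, reduction: str = "sum") -> float:
    """Sum over ordered space pairs of per-particle squared latent distances."""
    Z = views._require_latents()
    total = 0.0
    for n in range(len(Z)):
        for m in range(len(Z)):
            total += float(np.sum((Z[n] - Z[m]) ** 2))
    if reduction == "mean":
        total /= views.batch_size
    return total


def latent_pair_mse_grads(Z: Sequence[np.ndarray], reduction: str = "sum") -> list:
    """d L1 / d Z_n for every space n."""
    N = len(Z)
    S = np.sum(Z, axis=0)
    scale = 4.0
    if reduction == "mean":
        scale /= Z[0].shape[0]
    return [scale * (N * Z[n] - S) for n in range(N)]


# ---------------------------------------------------------------------------
# L2: Sammon/Shannon stress


def _stress_parts(X: np.ndarray, Z: np.ndarray):
    DX = self_distance_matrix(X)
    DZ = self_distance_matrix(Z)
    off = ~np.eye(DX.shape[0], dtype=bool)
    den = float(DX[off].sum())
    if den == 0.0:
        raise DegenerateBatchError("all input points coincide; stress is undefined")
    mask = off & (DX > 0.0)  # zero-distance input pairs carry no stress
    return DX, DZ, mask, den


def shannon_stress(X: np.ndarray, Z: np.ndarray) -> float:
    """Distance-preservation stress of the embedding ``Z`` of batch ``X``.

    ``sum_ij (d_ij(X) - d_ij(Z))^2 / d_ij(X) / sum_ij d_ij(X)`` over ordered
    off-diagonal pairs; zero exactly when ``Z`` is an isometry of ``X``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[0] != Z.shape[0]:
        raise ValueError("X and Z must have the same number of rows")
    DX, DZ, mask, den = _stress_parts(X, Z)
    num = float((((DX - DZ) ** 2 / np.where(mask, DX, 1.0)) * mask).sum())
    return num / den


def shannon_stress_grad(X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """d stress / d Z (same shape as Z)."""
    DX, DZ, mask, den = _stress_parts(X, Z)
    G = np.where(mask, -2.0 * (DX - DZ) / np.where(mask, DX, 1.0), 0.0) / den
    # d d_ij(Z)/d z_i = (z_i - z_j)/d_ij(Z); G is symmetric here
    safe = np.where(DZ > 0.0, DZ, 1.0)
    C = 2.0 * G / safe * (DZ > 0.0)
    return C.sum(axis=1)[:, None] * Z - C @ Z


# ---------------------------------------------------------------------------
# L3: distance-distribution matching


def wasserstein_1d(a, b) -> float:
    """Order-1 Wasserstein distance between two 1-D empirical distributions.

    For equal sample sizes this is the mean absolute difference of the
    sorted samples.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("wasserstein_1d requires non-empty samples")
    return float(wasserstein_distance(a, b))


def distance_distribution_loss(views: BatchViews) -> float:
    """Sum over ordered space pairs of the 1-D Wasserstein distance between
    the encoded batches' pairwise-distance samples (off-diagonal entries)."""
    Z = views._require_latents()
    if views.batch_size < 2:
        raise ValueError("need at least 2 rows per batch")
    samples = [_offdiag(self_distance_matrix(z)) for z in Z]
    total = 0.0
    for n in range(len(Z)):
        for m in range(len(Z)):
            if n != m:
                total += wasserstein_1d(samples[n], samples[m])
    return total


def distance_distribution_grads(Z: Sequence[np.ndarray]) -> list:
    """d L3 / d Z_n for every space n (equal-size sorted-sample gradient)."""
    N = len(Z)
    B = Z[0].shape[0]
    off = ~np.eye(B, dtype=bool)
    D = [self_distance_matrix(z) for z in Z]
    flat = [d[off] for d in D]
    order = [np.argsort(f, kind="stable") for f in flat]
    srt = [f[o] for f, o in zip(flat, order)]
    M = flat[0].size
    dflat = [np.zeros(M) for _ in range(N)]
    for n in range(N):
        for m in range(n + 1, N):
            s = np.sign(srt[n] - srt[m]) / M
            # ordered pairs (n,m) and (m,n) each contribute once
            contrib = np.zeros(M)
            contrib[order[n]] = 2.0 * s
            dflat[n] += contrib
            contrib = np.zeros(M)
            contrib[order[m]] = -2.0 * s
            dflat[m] += contrib
    grads = []
    for n in range(N):
        G = np.zeros((B, B))
        G[off] = dflat[n]
        safe = np.where(D[n] > 0.0, D[n], 1.0)
        C = (G + G.T) / safe * (D[n] > 0.0)
        grads.append(C.sum(axis=1)[:, None] * Z[n] - C @ Z[n])
    return grads


# ---------------------------------------------------------------------------
# representation term and total


def representation_loss(views: BatchViews, net, reduction: str = "sum") -> float:
    """Squared reconstruction error over all (target, source) space pairs:
    ``sum_n sum_m sum_i ||x_i^n - D_n(E_m(x_i^m))||^2``."""
    Z = views.latents if views.latents is not None else [
        net.encode(m, x) for m, x in enumerate(views.inputs)
    ]
    total = 0.0
    for n, x in enumerate(views.inputs):
        for m in range(len(Z)):
            total += float(np.sum((x - net.decode(n, Z[m])) ** 2))
    if reduction == "mean":
        total /= views.batch_size
    return total


def total_loss(views: BatchViews, net, weights: LossWeights | None = None,
               reduction: str = "sum") -> dict:
    """All four terms plus their weighted total, for logging and evaluation."""
    w = weights or LossWeights()
    if views.latents is None:
        views = views.with_latents(net)
    rep = representation_loss(views, net, reduction)
    l1 = latent_pair_mse(views, reduction)
    l2 = sum(shannon_stress(x, z) for x, z in zip(views.inputs, views.latents))
    l3 = distance_distribution_loss(views)
    return {
        "rep": rep,
        "l1": l1,
        "l2": l2,
        "l3": l3,
        "total": w.w_rep * rep + w.w1 * l1 + w.w2 * l2 + w.w3 * l3,
    }
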