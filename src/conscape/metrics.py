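"""Per-particle consensus diagnostics after training.

The trained encoders project every landscape into the consensus space.
From those projections two per-particle diagnostics follow:

* the *consensus error* — the mean distance between a particle's
  projections from different spaces; methods agree on a particle exactly
  when its projections coincide;
* the *representation error* — the distance between a particle's original
  coordinates in a target space and its reconstruction decoded from any
  source space's projection.

Errors are reported as Euclidean norms (not squared) so they live on the
coordinate scale of the spaces; squared norms appear only inside training
losses.  Because raw errors inherit each input space's arbitrary scale, a
per-space normalisation by the root-mean-square pairwise distance of the
input cloud is provided to make spaces comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .landscapes import LandscapeSet
from .network import ConsensusNetwork

__all__ = [
    "ConsensusMapping",
    "map_to_consensus",
    "consensus_errors",
    "rms_pairwise_distance",
    "normalize_errors",
    "error_histograms",
    "cluster_representatives",
]


@dataclass
class ConsensusMapping:
    """Consensus projections and per-particle error metrics.

    ``latents[n]`` is ``E_n(X^n)`` (num_particles x latent_dim);
    ``representation_errors[n, m, i]`` is ``||x_i^n - D_n(E_m(x_i^m))||``.
    """

    ids: tuple
    labels: tuple
    latents: list
    consensus_error: np.ndarray
    representation_errors: np.ndarray | None = None
    input_scales: np.ndarray | None = None

    @property
    def N(self) -> int:
        return len(self.latents)

    @property
    def num_particles(self) -> int:
        return self.latents[0].shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"id": list(self.ids)}
        for n, Z in enumerate(self.latents):
            for k in range(Z.shape[1]):
                cols[f"z{k + 1}_{self.labels[n]}"] = Z[:, k]
        cols["consensus_error"] = self.consensus_error
        if self.representation_errors is not None:
            for n in range(self.N):
                for m in range(self.N):
                    cols[f"rep_error_{self.labels[n]}_from_{self.labels[m]}"] = (
                        self.representation_errors[n, m]
                    )
                if self.input_scales is not None:
                    cols[f"rep_error_{self.labels[n]}_self_norm"] = (
                        self.representation_errors[n, n] / self.input_scales[n]
                    )
        return pd.DataFrame(cols)


def consensus_errors(latents: list) -> np.ndarray:
    """Mean over unordered space pairs of per-particle projection distance."""
    N = len(latents)
    if N < 2:
        raise ValueError("consensus error needs at least 2 spaces")
    pairs = list(combinations(range(N), 2))
    acc = np.zeros(latents[0].shape[0])
    for n, m in pairs:
        acc += np.linalg.norm(latents[n] - latents[m], axis=1)
    return acc / len(pairs)


def rms_pairwise_distance(X: np.ndarray, max_points: int = 2000, seed: int = 0) -> float:
    """Root-mean-square off-diagonal pairwise distance of a point cloud.

    Subsamples to ``max_points`` rows for large clouds (seeded) — the RMS
    distance is a U-statistic and stabilises quickly.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if X.shape[0] > max_points:
        idx = np.random.default_rng(seed).choice(X.shape[0], max_points, replace=False)
        X = X[idx]
    d = pdist(X)
    rms = float(np.sqrt(np.mean(d**2)))
    if rms == 0.0:
        raise ValueError("degenerate space: all points coincide")
    return rms


def map_to_consensus(net: ConsensusNetwork, lset: LandscapeSet) -> ConsensusMapping:
    """Project every landscape into the consensus space and fill all metrics."""
    if lset.dims != net.spec.input_dims:
        raise ValueError(
            f"landscape dims {lset.dims} do not match network dims {net.spec.input_dims}"
        )
    X = lset.matrices()
    Z = [net.encode(n, x) for n, x in enumerate(X)]
    N = lset.N
    rep = np.zeros((N, N, lset.num_particles))
    for n in range(N):
        for m in range(N):
            rep[n, m] = np.linalg.norm(X[n] - net.decode(n, Z[m]), axis=1)
    scales = np.array([rms_pairwise_distance(x) for x in X])
    return ConsensusMapping(
        ids=lset.ids,
        labels=lset.labels,
        latents=Z,
        consensus_error=consensus_errors(Z),
        representation_errors=rep,
        input_scales=scales,
    )


def consensus_error(mapping: ConsensusMapping, i: int) -> float:
    """Consensus error of particle ``i`` (row index)."""
    return float(mapping.consensus_error[i])


def representation_error(net: ConsensusNetwork, lset: LandscapeSet, i: int,
                         target: int, source: int) -> float:
    """``||x_i^target - D_target(E_source(x_i^source))||`` for one particle."""
    x_src = lset.landscapes[source].X[i : i + 1]
    recon = net.decode(target, net.encode(source, x_src))
    return float(np.linalg.norm(lset.landscapes[target].X[i] - recon[0]))


def normalize_errors(errors: np.ndarray, scale: float) -> np.ndarray:
    """Divide raw errors by a per-space scale (> 0); order-preserving."""
    if not scale > 0:
        raise ValueError(f"scale must be positive, got {scale}")
    return np.asarray(errors, dtype=float) / scale


def error_histograms(mapping: ConsensusMapping, bins: int = 50, normalized: bool = True) -> dict:
    """Per-space histograms of self representation errors.

    Returns ``{label: (counts, edges)}``; counts sum to the particle count.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    out = {}
    for n, label in enumerate(mapping.labels):
        err = mapping.representation_errors[n, n]
        if normalized and mapping.input_scales is not None:
            err = normalize_errors(err, mapping.input_scales[n])
        out[label] = np.histogram(err, bins=bins)
    return out


def cluster_representatives(points: np.ndarray, k: int, seed: int = 0):
    """K-means representatives of a (latent) point cloud.

    Returns ``(centroids, assignments)``; centroids can be fed to
    ``ConsensusNetwork.decode``/``convert`` to recover input-space states.
    """
    points = np.asarray(points, dtype=float)
    if k > points.shape[0]:
        raise ValueError(f"k={k} exceeds the number of points {points.shape[0]}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    assignments = km.fit_predict(points)
    return km.cluster_centers_, assignments
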