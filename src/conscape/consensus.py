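"""Statistical selection of the consensus particle set.

Particles are ranked by their consensus error (agreement across spaces).
For an increasing number K of best-agreeing particles, the distributions of
their projections from the different spaces are compared with a sliced
Wasserstein distance — the mean 1-D Wasserstein distance over kappa random
unit-vector projections — and the distance's significance is assessed by a
label-permutation test (default 100 randomisations, shared projection
vectors between the observed and permuted statistics).  As K grows past the
well-agreeing core, the distributions become distinguishable; the largest K
whose p-value stays at or above the significance level (default 0.05)
defines the consensus set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .losses import wasserstein_1d
from .metrics import ConsensusMapping

__all__ = [
    "SlicedWassersteinConfig",
    "PermutationTestResult",
    "ConsensusSelection",
    "agreement_ranking",
    "sliced_wasserstein",
    "permutation_pvalue",
    "threshold_sweep",
]


@dataclass(frozen=True)
class SlicedWassersteinConfig:
    """Number of random unit projection vectors and the seed that draws them."""

    kappa: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")


@dataclass
class PermutationTestResult:
    d_obs: float
    permuted: np.ndarray
    p_value: float


@dataclass
class ConsensusSelection:
    """The p-value-vs-K sweep and the selected consensus particle ids."""

    sweep: list  # of (K, d_obs, p_value)
    K_star: int
    selected_ids: tuple
    ranking: tuple = field(default=(), repr=False)


def agreement_ranking(mapping: ConsensusMapping):
    """Particle ids sorted by ascending consensus error; ties break by id."""
    ids = np.asarray(mapping.ids, dtype=object)
    order = np.lexsort((ids, mapping.consensus_error))
    return tuple(ids[order]), order


def _unit_projections(d: int, kappa: int, rng: np.random.Generator) -> np.ndarray:
    U = rng.normal(size=(d, kappa))
    U /= np.linalg.norm(U, axis=0, keepdims=True)
    return U


def _sliced_from_projections(PA: np.ndarray, PB: np.ndarray) -> float:
    """Mean 1-D Wasserstein over projection columns; equal-size fast path."""
    if PA.shape[0] == PB.shape[0]:
        return float(np.mean(np.abs(np.sort(PA, axis=0) - np.sort(PB, axis=0))))
    return float(np.mean([wasserstein_1d(PA[:, k], PB[:, k]) for k in range(PA.shape[1])]))


def sliced_wasserstein(A: np.ndarray, B: np.ndarray, cfg: SlicedWassersteinConfig | None = None,
                       projections: np.ndarray | None = None) -> float:
    """Sliced Wasserstein distance between point sets in the same dimension.

    ``projections`` (a ``d x kappa`` matrix of unit columns) overrides the
    seeded draw, allowing several evaluations to share one projection set.
    """
    cfg = cfg or SlicedWassersteinConfig()
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("sliced_wasserstein requires non-empty point sets")
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    if projections is None:
        projections = _unit_projections(A.shape[1], cfg.kappa, np.random.default_rng(cfg.seed))
    return _sliced_from_projections(A @ projections, B @ projections)


def permutation_pvalue(A: np.ndarray, B: np.ndarray, cfg: SlicedWassersteinConfig | None = None,
                       n_perm: int = 100, direction: str = "ge") -> PermutationTestResult:
    """Label-permutation test of "A and B come from the same distribution".

    The observed statistic is the sliced Wasserstein distance between A and
    B.  Each randomisation pools the two sets, splits them into two equal
    groups at random, and recomputes the statistic with the *same*
    projection vectors.  The p-value uses the add-one-smoothed estimator
    ``p = (1 + #{permuted >= d_obs}) / (1 + n_perm)``; ``direction="le"``
    gives the opposite-tail variant (the proportion of randomised distances
    at or below the observed one).
    """
    cfg = cfg or SlicedWassersteinConfig()
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape != B.shape:
        raise ValueError(f"A and B must have identical shape, got {A.shape} vs {B.shape}")
    if direction not in ("ge", "le"):
        raise ValueError("direction must be 'ge' or 'le'")
    K, d = A.shape
    rng = np.random.default_rng(cfg.seed)
    U = _unit_projections(d, cfg.kappa, rng)
    pooled = np.vstack([A, B]) @ U  # project once; permutations only re-index rows
    d_obs = _sliced_from_projections(pooled[:K], pooled[K:])
    permuted = np.empty(n_perm)
    for r in range(n_perm):
        perm = rng.permutation(2 * K)
        permuted[r] = _sliced_from_projections(pooled[perm[:K]], pooled[perm[K:]])
    if direction == "ge":
        extreme = int(np.sum(permuted >= d_obs))
    else:
        extreme = int(np.sum(permuted <= d_obs))
    p = (1 + extreme) / (1 + n_perm)
    return PermutationTestResult(d_obs=d_obs, permuted=permuted, p_value=p)


def default_k_grid(num_particles: int, size: int = 20, k_min: int = 100) -> list:
    """Geometrically spaced K values from ``k_min`` to the particle count."""
    k_min = min(max(2, k_min), num_particles)
    grid = np.unique(
        np.round(np.geomspace(k_min, num_particles, size)).astype(int)
    )
    return [int(k) for k in grid if 2 <= k <= num_particles]


def threshold_sweep(mapping: ConsensusMapping, cfg: SlicedWassersteinConfig | None = None,
                    alpha: float = 0.05, K_grid: list | None = None,
                    n_perm: int = 100) -> ConsensusSelection:
    """Sweep K over the agreement ranking and select the consensus set.

    For every K the top-K best-agreeing particles' projections from the
    spaces are compared by the permutation test; ``K_star`` is the largest
    K whose p-value is >= ``alpha``.  With more than two spaces the test is
    run for every space pair and the p-value is Bonferroni-combined
    (``min(1, n_pairs * min_pair_p)``).
    """
    cfg = cfg or SlicedWassersteinConfig()
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    n = mapping.num_particles
    if K_grid is None:
        K_grid = default_k_grid(n)
    K_grid = sorted(set(int(k) for k in K_grid))
    if not K_grid:
        raise ValueError("K_grid is empty")
    if K_grid[0] < 2 or K_grid[-1] > n:
        raise ValueError(f"K_grid must lie within [2, {n}]")
    ranked_ids, order = agreement_ranking(mapping)
    pairs = list(combinations(range(mapping.N), 2))
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(K_grid))
    sweep = []
    for k_i, K in enumerate(K_grid):
        top = order[:K]
        pair_seeds = seeds[k_i].spawn(len(pairs))
        d_max, p_min = 0.0, 1.0
        for (a, b), ss in zip(pairs, pair_seeds):
            sub_cfg = SlicedWassersteinConfig(cfg.kappa, int(ss.generate_state(1)[0] % 2**31))
            res = permutation_pvalue(
                mapping.latents[a][top], mapping.latents[b][top], sub_cfg, n_perm=n_perm
            )
            d_max = max(d_max, res.d_obs)
            p_min = min(p_min, res.p_value)
        p = min(1.0, len(pairs) * p_min)
        sweep.append((K, d_max, p))
    passing = [K for K, _, p in sweep if p >= alpha]
    K_star = max(passing) if passing else 0
    return ConsensusSelection(
        sweep=sweep,
        K_star=K_star,
        selected_ids=tuple(ranked_ids[:K_star]),
        ranking=ranked_ids,
    )
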