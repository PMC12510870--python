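"""Synthetic paired landscapes with known ground truth.

Emulates the input regime of a multi-method heterogeneity analysis: every
"method" observes the same per-particle ground-truth conformational state
(drawn from a three-component Gaussian mixture, mimicking a discrete-plus-
continuous state distribution) through its own smooth distortion — an
affine map plus an optional mild coordinate-wise tanh nonlinearity — and
its own Gaussian noise.  Two kinds of planted disagreement are supported:

* *discordant* particles, displaced in an independent random direction in
  every space (methods place them inconsistently);
* a *method-exclusive cluster*, displaced coherently in one space only
  (states only one method can see, e.g. compositional variability
  invisible to a deformation-field method).

The ground-truth cloud is rescaled so its root-mean-square pairwise
distance is 1; noise sigmas and displacement magnitudes are therefore
directly expressed as fractions of the landscape scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .landscapes import Landscape, LandscapeSet

__all__ = ["SpaceConfig", "SimulationConfig", "SpaceModel", "SimulationTruth",
           "generate", "standard_fixtures", "sample_truth"]


@dataclass(frozen=True)
class SpaceConfig:
    """One emulated method: output dim, distortion and noise level."""

    dim: int
    affine: str = "random"  # "random" (seeded rotation-like map) or "identity"
    nonlinearity_amplitude: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.dim < 1:
            raise ValueError("space dim must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.affine not in ("random", "identity"):
            raise ValueError("affine must be 'random' or 'identity'")


@dataclass(frozen=True)
class SimulationConfig:
    num_particles: int = 2000
    truth_dim: int = 2
    spaces: tuple = (SpaceConfig(dim=2), SpaceConfig(dim=2))
    mixture_weights: tuple = (0.45, 0.35, 0.20)
    discordant_fraction: float = 0.0
    discordant_displacement: float = 0.0
    # spaces in which discordant particles are displaced (None = all).
    # Displacing in all spaces (independent directions) breaks the pairing
    # but leaves each space's marginal distribution unchanged; displacing in
    # a subset also shifts that space's marginal, which is what a
    # distribution-level test can detect.
    discordant_spaces: tuple | None = None
    exclusive_fraction: float = 0.0
    exclusive_space: int = 0
    exclusive_displacement: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.num_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.truth_dim < 1:
            raise ValueError("truth_dim must be >= 1")
        if len(self.spaces) < 2:
            raise ValueError("need at least 2 spaces")
        if not 0.0 <= self.discordant_fraction < 1.0:
            raise ValueError("discordant_fraction must lie in [0, 1)")
        if not 0.0 <= self.exclusive_fraction < 1.0:
            raise ValueError("exclusive_fraction must lie in [0, 1)")
        object.__setattr__(self, "spaces", tuple(self.spaces))
        object.__setattr__(self, "mixture_weights", tuple(self.mixture_weights))
        if self.discordant_spaces is not None:
            ds = tuple(int(s) for s in self.discordant_spaces)
            if any(not 0 <= s < len(self.spaces) for s in ds):
                raise ValueError(f"discordant_spaces out of range: {ds}")
            object.__setattr__(self, "discordant_spaces", ds)


@dataclass(frozen=True)
class SpaceModel:
    """The realised (noise-free) map of one space: x = f(A t + b)."""

    A: np.ndarray
    b: np.ndarray
    nonlinearity_amplitude: float

    def transform(self, truth: np.ndarray) -> np.ndarray:
        y = truth @ self.A.T + self.b
        if self.nonlinearity_amplitude:
            y = y + self.nonlinearity_amplitude * np.tanh(y)
        return y


@dataclass
class SimulationTruth:
    """Ground truth accompanying a generated LandscapeSet."""

    coords: np.ndarray
    discordant: np.ndarray
    exclusive: np.ndarray
    space_models: tuple

    def to_dataframe(self, ids) -> pd.DataFrame:
        df = pd.DataFrame({"id": list(ids)})
        df["discordant"] = self.discordant.astype(int)
        df["exclusive"] = self.exclusive.astype(int)
        for k in range(self.coords.shape[1]):
            df[f"t{k + 1}"] = self.coords[:, k]
        return df


def sample_truth(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ground-truth states: 3-component Gaussian mixture, RMS pairwise
    distance rescaled to 1."""
    d = config.truth_dim
    w = np.asarray(config.mixture_weights, dtype=float)
    w = w / w.sum()
    mean_rng = np.random.default_rng(config.seed + 977)  # component layout is part of the model
    means = mean_rng.normal(0.0, 1.5, size=(len(w), d))
    comp = rng.choice(len(w), size=n, p=w)
    t = means[comp] + rng.normal(0.0, 0.5, size=(n, d))
    # rescale so the RMS pairwise distance is 1: E d^2 = 2 tr(cov)
    cov_scale = np.sqrt(2.0 * np.trace(np.cov(t.T).reshape(d, d)))
    return t / cov_scale


def _space_model(cfg_space: SpaceConfig, truth_dim: int, rng: np.random.Generator) -> SpaceModel:
    if cfg_space.affine == "identity":
        if cfg_space.dim != truth_dim:
            raise ValueError("identity affine requires space dim == truth_dim")
        A = np.eye(truth_dim)
        b = np.zeros(truth_dim)
    else:
        # orthonormal-column map (scale-preserving) plus a small offset
        G = rng.normal(size=(max(cfg_space.dim, truth_dim), truth_dim))
        Q, _ = np.linalg.qr(G)
        A = Q[: cfg_space.dim, :truth_dim]
        b = rng.normal(0.0, 0.1, size=cfg_space.dim)
    return SpaceModel(A=A, b=b, nonlinearity_amplitude=cfg_space.nonlinearity_amplitude)


def _planted_labels(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    count = int(round(fraction * n))
    labels = np.zeros(n, dtype=bool)
    if count:
        labels[rng.choice(n, size=count, replace=False)] = True
    return labels


def generate(config: SimulationConfig):
    """Generate a :class:`LandscapeSet` plus its :class:`SimulationTruth`."""
    rng = np.random.default_rng(config.seed)
    n = config.num_particles
    truth = sample_truth(config, n, rng)
    discordant = _planted_labels(n, config.discordant_fraction, rng)
    exclusive = _planted_labels(n, config.exclusive_fraction, rng)
    models = tuple(_space_model(s, config.truth_dim, rng) for s in config.spaces)
    if config.exclusive_fraction and not 0 <= config.exclusive_space < len(config.spaces):
        raise ValueError("exclusive_space out of range")
    exclusive_dir = rng.normal(size=config.truth_dim)
    exclusive_dir /= np.linalg.norm(exclusive_dir)

    landscapes = []
    for s_i, (s_cfg, model) in enumerate(zip(config.spaces, models)):
        t_seen = truth.copy()
        displace_here = (
            config.discordant_spaces is None or s_i in config.discordant_spaces
        )
        if discordant.any() and config.discordant_displacement and displace_here:
            # independent direction per particle and per space
            dirs = rng.normal(size=(int(discordant.sum()), config.truth_dim))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            t_seen[discordant] += config.discordant_displacement * dirs
        if exclusive.any() and s_i == config.exclusive_space:
            t_seen[exclusive] += config.exclusive_displacement * exclusive_dir
        X = model.transform(t_seen)
        if s_cfg.noise_sigma:
            X = X + rng.normal(0.0, s_cfg.noise_sigma, size=X.shape)
        landscapes.append(Landscape(f"space{s_i + 1}", tuple(range(n)), X))

    return LandscapeSet(tuple(landscapes)), SimulationTruth(
        coords=truth, discordant=discordant, exclusive=exclusive, space_models=models
    )


def standard_fixtures() -> dict:
    """Named simulation configs used throughout the test-bed.

    * ``affine-pair`` — two 2-D views of the same states through different
      rotations, mild noise; the basic merging/conversion benchmark.
    * ``discordant-10`` — 10% of particles displaced independently in every
      space (displacement 1.0 of the landscape scale, noise 0.05); breaks
      the pairing while keeping the marginals equal.
    * ``discordant-30`` — 30% of particles displaced in space 2 only; the
      planted disagreement also shifts that space's marginal distribution,
      the regime the consensus-set sweep is designed to detect.
    * ``exclusive-cluster`` — 15% of particles form a cluster only space 1
      can see.
    * ``null-identical`` — both spaces are the identical noise-free
      embedding; the calibration null.
    """
    noisy = SpaceConfig(dim=2, affine="random", noise_sigma=0.05)
    ident = SpaceConfig(dim=2, affine="identity", noise_sigma=0.05)
    clean_ident = SpaceConfig(dim=2, affine="identity", noise_sigma=0.0)
    return {
        "affine-pair": SimulationConfig(
            num_particles=2000, spaces=(noisy, noisy), seed=11
        ),
        "discordant-10": SimulationConfig(
            num_particles=2000, spaces=(noisy, noisy),
            discordant_fraction=0.10, discordant_displacement=1.0, seed=23
        ),
        "discordant-30": SimulationConfig(
            num_particles=2000, spaces=(ident, ident),
            discordant_fraction=0.30, discordant_displacement=1.0,
            discordant_spaces=(1,), seed=37
        ),
        "exclusive-cluster": SimulationConfig(
            num_particles=2000, spaces=(ident, ident),
            exclusive_fraction=0.15, exclusive_space=0, exclusive_displacement=1.0, seed=41
        ),
        "null-identical": SimulationConfig(
            num_particles=2000, spaces=(clean_ident, clean_ident), seed=53
        ),
    }
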