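"""The consensus multi-autoencoder.

N encoders map each input landscape into one shared *consensus* latent
space; N decoders map consensus coordinates back into each input space.
Each encoder/decoder is a fully connected ReLU network (default three
hidden layers of 1024 units) with a linear output layer.  The consensus
bottleneck dimension defaults to the minimum dimension among the inputs.

The networks are implemented directly on NumPy arrays; forward passes cache
pre-activations so the training module can run reverse-mode gradients
through them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["NetworkSpec", "ConsensusNetwork", "default_latent_dim", "build_network", "load_network"]


def default_latent_dim(input_dims: Sequence[int]) -> int:
    """Default consensus dimensionality: the minimum input-space dimension."""
    dims = list(input_dims)
    if not dims:
        raise ValueError("input_dims must be non-empty")
    if any(d < 1 for d in dims):
        raise ValueError(f"input dimensions must be positive, got {dims}")
    return int(min(dims))


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyper-parameters of the consensus network."""

    input_dims: tuple
    latent_dim: int
    hidden_width: int = 1024
    hidden_depth: int = 3
    seed: int = 0

    def __post_init__(self):
        dims = tuple(int(d) for d in self.input_dims)
        if len(dims) < 2:
            raise ValueError(f"need at least 2 input spaces, got {len(dims)}")
        if any(d < 1 for d in dims):
            raise ValueError(f"input dimensions must be positive, got {dims}")
        for name in ("latent_dim", "hidden_width", "hidden_depth"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        object.__setattr__(self, "input_dims", dims)
        object.__setattr__(self, "latent_dim", int(self.latent_dim))
        object.__setattr__(self, "hidden_width", int(self.hidden_width))
        object.__setattr__(self, "hidden_depth", int(self.hidden_depth))

    @property
    def N(self) -> int:
        return len(self.input_dims)

    def layer_dims(self, kind: str, space: int) -> list:
        """Layer sizes of one sub-network, input first."""
        w, d = self.hidden_width, self.hidden_depth
        if kind == "encoder":
            return [self.input_dims[space]] + [w] * d + [self.latent_dim]
        if kind == "decoder":
            return [self.latent_dim] + [w] * d + [self.input_dims[space]]
        raise ValueError(kind)

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_dims": list(self.input_dims),
                "latent_dim": self.latent_dim,
                "hidden_width": self.hidden_width,
                "hidden_depth": self.hidden_depth,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        return cls(
            input_dims=tuple(d["input_dims"]),
            latent_dim=d["latent_dim"],
            hidden_width=d["hidden_width"],
            hidden_depth=d["hidden_depth"],
            seed=d["seed"],
        )


def _init_mlp(rng: np.random.Generator, dims: Sequence[int]) -> list:
    """He-normal weights (fan-in scaled, suits ReLU), zero biases."""
    layers = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        b = np.zeros(d_out)
        layers.append([W, b])
    return layers


def _mlp_forward(layers: list, x: np.ndarray, cache: list | None = None) -> np.ndarray:
    """Forward pass: ReLU on every layer but the last, linear output.

    When ``cache`` is a list it receives the input of each layer and the
    layer pre-activations, as needed by :func:`_mlp_backward`.
    """
    h = x
    last = len(layers) - 1
    for k, (W, b) in enumerate(layers):
        pre = h @ W + b
        out = pre if k == last else np.maximum(pre, 0.0)
        if cache is not None:
            cache.append((h, pre))
        h = out
    return h


def _mlp_backward(layers: list, cache: list, dout: np.ndarray):
    """Reverse pass. Returns (gradient list matching ``layers``, dL/dinput)."""
    grads = [None] * len(layers)
    last = len(layers) - 1
    d = dout
    for k in range(last, -1, -1):
        h_in, pre = cache[k]
        if k != last:
            d = d * (pre > 0.0)
        grads[k] = [h_in.T @ d, d.sum(axis=0)]
        d = d @ layers[k][0].T
    return grads, d


class ConsensusNetwork:
    """N encoders + N decoders sharing one consensus bottleneck.

    Encode/decode are deterministic for fixed weights, and row-wise
    independent (no normalisation layers), so per-point and batched
    evaluation agree.
    """

    def __init__(self, spec: NetworkSpec, encoders: list, decoders: list):
        self.spec = spec
        self.encoders = encoders
        self.decoders = decoders

    # -- evaluation ---------------------------------------------------------

    def _check_space(self, space_index: int) -> int:
        if not 0 <= space_index < self.spec.N:
            raise IndexError(f"space index {space_index} out of range for N={self.spec.N}")
        return int(space_index)

    def encode(self, space_index: int, points: np.ndarray, _cache: list | None = None) -> np.ndarray:
        n = self._check_space(space_index)
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[0] and points.shape[1] != self.spec.input_dims[n]:
            raise ValueError(
                f"space {n} expects dimension {self.spec.input_dims[n]}, got {points.shape[1]}"
            )
        if points.shape[0] == 0:
            return np.zeros((0, self.spec.latent_dim))
        return _mlp_forward(self.encoders[n], points, _cache)

    def decode(self, space_index: int, latent_points: np.ndarray, _cache: list | None = None) -> np.ndarray:
        n = self._check_space(space_index)
        z = np.atleast_2d(np.asarray(latent_points, dtype=float))
        if z.shape[0] and z.shape[1] != self.spec.latent_dim:
            raise ValueError(f"latent dimension is {self.spec.latent_dim}, got {z.shape[1]}")
        if z.shape[0] == 0:
            return np.zeros((0, self.spec.input_dims[n]))
        return _mlp_forward(self.decoders[n], z, _cache)

    def convert(self, from_index: int, to_index: int, points: np.ndarray) -> np.ndarray:
        """Map points of one input space into another via the consensus space."""
        return self.decode(to_index, self.encode(from_index, points))

    # -- parameters ---------------------------------------------------------

    def parameters(self):
        """Yield ``(key, array)`` for every trainable array."""
        for kind, nets in (("enc", self.encoders), ("dec", self.decoders)):
            for n, layers in enumerate(nets):
                for k, (W, b) in enumerate(layers):
                    yield (kind, n, k, "W"), W
                    yield (kind, n, k, "b"), b

    @property
    def n_parameters(self) -> int:
        return sum(a.size for _, a in self.parameters())

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Write spec + weights to a single ``.npz`` checkpoint."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {"__".join(map(str, key)): a for key, a in self.parameters()}
        arrays["spec_json"] = np.frombuffer(self.spec.to_json().encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ConsensusNetwork":
        with np.load(Path(path)) as data:
            spec = NetworkSpec.from_json(bytes(data["spec_json"]).decode())
            net = build_network(spec)
            for key, a in net.parameters():
                a[...] = data["__".join(map(str, key))]
        return net


def build_network(spec: NetworkSpec) -> ConsensusNetwork:
    """Initialise a consensus network from ``spec`` (seeded, reproducible)."""
    rng = np.random.default_rng(spec.seed)
    encoders = [_init_mlp(rng, spec.layer_dims("encoder", n)) for n in range(spec.N)]
    decoders = [_init_mlp(rng, spec.layer_dims("decoder", n)) for n in range(spec.N)]
    return ConsensusNetwork(spec, encoders, decoders)


def load_network(path) -> ConsensusNetwork:
    return ConsensusNetwork.load(path)
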