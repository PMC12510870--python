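"""Shared fixtures: tiny landscape sets and the desk-scale trained runs.

The two training runs (the affine-pair merging benchmark and the 10%-
discordant recovery benchmark) are session-scoped because they take a
couple of minutes each; every test that needs a trained network shares
them.
"""

import numpy as np
import pytest

import conscape as cs
from conscape.losses import BatchViews, latent_pair_mse
from conscape.synthetic import sample_truth, standard_fixtures

# desk-scale training configuration: the printed Adam/lr defaults with a
# narrower network and smaller batch sized to the 2,000-particle fixtures
DESK_WIDTH = 64
DESK_BATCH = 128
NET_SEED = 100
TRAIN_SEED = 7


def full_set_l1(net, lset):
    X = lset.matrices()
    Z = [net.encode(n, x) for n, x in enumerate(X)]
    return latent_pair_mse(BatchViews(X, Z))


@pytest.fixture(scope="session")
def affine_pair():
    config = standard_fixtures()["affine-pair"]
    lset, truth = cs.generate(config)
    return config, lset, truth


@pytest.fixture(scope="session")
def affine_trained(affine_pair):
    """Train the consensus network on the affine-pair fixture (200 epochs)."""
    config, lset, truth = affine_pair
    spec = cs.NetworkSpec(lset.dims, cs.default_latent_dim(lset.dims),
                          hidden_width=DESK_WIDTH, seed=NET_SEED)
    net = cs.build_network(spec)
    l1_init = full_set_l1(net, lset)
    train_cfg = cs.TrainConfig(learning_rate=1e-5, batch_size=DESK_BATCH,
                               epochs=200, seed=TRAIN_SEED)
    history = cs.train(net, lset, train_cfg)
    return {
        "config": config,
        "lset": lset,
        "truth": truth,
        "net": net,
        "history": history,
        "l1_init": l1_init,
        "l1_final": full_set_l1(net, lset),
    }


@pytest.fixture(scope="session")
def discordant_trained():
    """Train on the 10%-discordant fixture (150 epochs)."""
    config = standard_fixtures()["discordant-10"]
    lset, truth = cs.generate(config)
    spec = cs.NetworkSpec(lset.dims, cs.default_latent_dim(lset.dims),
                          hidden_width=DESK_WIDTH, seed=NET_SEED)
    net = cs.build_network(spec)
    train_cfg = cs.TrainConfig(learning_rate=1e-5, batch_size=DESK_BATCH,
                               epochs=150, seed=TRAIN_SEED)
    cs.train(net, lset, train_cfg)
    return {"config": config, "lset": lset, "truth": truth, "net": net}


@pytest.fixture
def tiny_lset():
    """A deterministic 40-particle, two-space set for fast unit tests."""
    lset, _ = cs.generate(
        cs.SimulationConfig(
            num_particles=40,
            spaces=(cs.SpaceConfig(dim=2, noise_sigma=0.05),
                    cs.SpaceConfig(dim=3, noise_sigma=0.05)),
            seed=5,
        )
    )
    return lset


@pytest.fixture
def small_net(tiny_lset):
    spec = cs.NetworkSpec(tiny_lset.dims, 2, hidden_width=8, hidden_depth=2, seed=3)
    return cs.build_network(spec)


@pytest.fixture
def held_out_pair(affine_pair):
    """500 noise-free held-out point pairs under the affine-pair maps."""
    config, _, truth = affine_pair
    t = sample_truth(config, 500, np.random.default_rng(99))
    x1 = truth.space_models[0].transform(t)
    x2 = truth.space_models[1].transform(t)
    return x1, x2
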