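import dataclasses

import numpy as np
import pytest

from cetriad import pipeline
from cetriad.synthetic import PRESETS, generate_benchmark


@pytest.fixture(scope="session")
def tiny_bundle():
    return generate_benchmark(PRESETS["tiny"])


@pytest.fixture(scope="session")
def fast_cfg():
    """Tiny-preset experiment config with a shortened walk corpus.

    The walk corpus size only affects embedding quality, not any contract
    under test, so unit tests use a light corpus to stay quick.
    """
    cfg = pipeline.ExperimentConfig(synth=PRESETS["tiny"], seed=0).reseeded(0)
    return dataclasses.replace(
        cfg,
        walk=dataclasses.replace(cfg.walk, walk_length=20, walks_per_node=4),
        sg_epochs=2,
        train=dataclasses.replace(cfg.train, epochs=80),
    )


@pytest.fixture(scope="session")
def tiny_stages(tiny_bundle, fast_cfg):
    """Shared pipeline stages on the tiny bundle: sims + adjacencies."""
    train_pos, _ = pipeline.split_positives(tiny_bundle.positives, 0.8, seed=0)
    g = pipeline.training_graph(tiny_bundle, train_pos)
    sims = pipeline.compute_similarities(g, tiny_bundle.dag, fast_cfg)
    adj = pipeline.build_adjacencies(g, sims, fast_cfg)
    return {"graph": g, "sims": sims, "adj": adj, "train_pos": train_pos}


def random_graph(rng, n_max=30, p=0.2):
    import networkx as nx

    n = int(rng.integers(4, n_max + 1))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return g
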