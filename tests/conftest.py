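import numpy as np
import pytest

import relmap as rm


@pytest.fixture(scope="session")
def reduced_graph():
    return rm.default_reduced_graph()


@pytest.fixture(scope="session")
def training_graph():
    return rm.default_training_graph()


@pytest.fixture(scope="session")
def two_node_graph():
    return rm.RelationalGraph(["a", "b"], [("a", "b")])


@pytest.fixture(scope="session")
def full_ensemble():
    """The exhaustive null over connected 7-edge graphs on 7 labelled nodes.

    Session-scoped: enumeration scans 116,280 candidate edge sets and is
    shared by the map-recovery and acceptance tests.
    """
    return rm.enumerate_null_graphs(7, 7)


@pytest.fixture(scope="session")
def noisy_cohort(reduced_graph):
    """A seeded 23-subject cohort generated from communicability."""
    cfg = rm.CohortConfig(
        n_subjects=23,
        generative_metric="communicability",
        beta_metric=1.0,
        object_effect_sd=0.5,
        noise_sd=1.0,
        seed=7,
    )
    return rm.simulate_adaptation_cohort(cfg, reduced_graph)


def random_connected_graph(n_nodes, n_edges, seed):
    """Seeded random connected graph for property tests (rejection over
    edge subsets with a hand-rolled reachability check)."""
    rng = np.random.default_rng(seed)
    import itertools

    possible = list(itertools.combinations(range(1, n_nodes + 1), 2))
    while True:
        idx = rng.choice(len(possible), size=n_edges, replace=False)
        edges = [possible[k] for k in idx]
        try:
            return rm.RelationalGraph(range(1, n_nodes + 1), edges)
        except ValueError:
            continue
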