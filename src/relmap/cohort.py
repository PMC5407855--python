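"""Synthetic cohorts of adaptation estimates and response times.

The generative model is the minimal structure the downstream analyses
presuppose: a scalar response to the object on trial t that grows linearly
with a chosen proximity metric between that object and its predecessor,
plus an object-specific offset and Gaussian trial noise,

    response(s, i -> j) = beta * m(i, j) + u_s(j) + eps,

with u_s(j) ~ N(0, object_effect_sd^2) drawn once per subject and object,
and eps ~ N(0, noise_sd^2) per measurement.  Response times use the same
structure on the log scale around ``rt_baseline``.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .graphs import RelationalGraph, TransitionCountMatrix, proximity_matrix
from .sequences import generate_behaviour_block, generate_training_walk, transition_counts

__all__ = [
    "CohortConfig",
    "TransitionResponseTable",
    "simulate_adaptation_cohort",
    "simulate_rt_cohort",
    "simulate_training_histories",
]

_METRIC_KINDS = ("link", "euclidean", "communicability", "successor")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the generative model for a synthetic cohort.

    Defaults mirror the study conditions: 23 scanned subjects, responses
    generated from communicability with unit effect size, object offsets of
    SD 0.5 and trial noise of SD 1.0 (arbitrary units), and a response-time
    baseline of log(700 ms).
    """

    n_subjects: int = 23
    generative_metric: str = "communicability"
    beta_metric: float = 1.0
    object_effect_sd: float = 0.5
    noise_sd: float = 1.0
    rt_baseline: float = float(np.log(700.0))
    gamma_fraction: float = 0.85
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.object_effect_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.generative_metric not in _METRIC_KINDS:
            raise ValueError(
                f"unknown generative_metric {self.generative_metric!r}; "
                f"choose one of {_METRIC_KINDS}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TransitionResponseTable:
    """One subject's scalar response per ordered object pair (i -> j, i != j).

    The response is an adaptation parameter estimate in arbitrary units or a
    demeaned log response time; by convention it increases with graph
    distance between predecessor and object.
    """

    subject: str
    data: pd.DataFrame = field(compare=False)  # predecessor, object, response

    def __post_init__(self):
        required = {"predecessor", "object", "response"}
        if not required <= set(self.data.columns):
            raise ValueError(f"data must have columns {sorted(required)}")
        if (self.data["predecessor"] == self.data["object"]).any():
            raise ValueError("diagonal (repeated-object) entries are not allowed")

    def matrix(self, node_labels) -> np.ndarray:
        """Responses as a square matrix (predecessor row, object column);
        diagonal 0."""
        labels = list(node_labels)
        idx = {v: k for k, v in enumerate(labels)}
        m = np.zeros((len(labels), len(labels)))
        for pred, obj, resp in self.data[["predecessor", "object", "response"]].itertuples(
            index=False
        ):
            m[idx[pred], idx[obj]] = resp
        return m


def _subject_rngs(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(int(seed) % 2**31)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def _ordered_pairs(labels) -> list[tuple]:
    return [(i, j) for i in labels for j in labels if i != j]


def simulate_adaptation_cohort(
    config: CohortConfig, graph: RelationalGraph
) -> list[TransitionResponseTable]:
    """Per-subject adaptation estimates for every ordered object pair.

    Each subject contributes n(n-1) responses following the linear
    generative model; with 7 objects that is the 42 modelled transitions.
    """
    metric = proximity_matrix(graph, config.generative_metric, config.gamma_fraction)
    labels = graph.node_labels
    pairs = _ordered_pairs(labels)
    tables = []
    for s, rng in enumerate(_subject_rngs(config.seed, config.n_subjects)):
        offsets = dict(zip(labels, rng.normal(0.0, config.object_effect_sd, len(labels))))
        rows = []
        for i, j in pairs:
            resp = (
                config.beta_metric * metric.value(i, j)
                + offsets[j]
                + rng.normal(0.0, config.noise_sd)
            )
            rows.append((i, j, resp))
        tables.append(
            TransitionResponseTable(
                subject=f"sub-{s + 1:02d}",
                data=pd.DataFrame(rows, columns=["predecessor", "object", "response"]),
            )
        )
    return tables


def simulate_rt_cohort(
    config: CohortConfig,
    graph: RelationalGraph,
    blocks: int = 10,
    reps: int = 3,
    error_rate: float = 0.0,
) -> pd.DataFrame:
    """Per-trial response times over balanced behavioural blocks.

    Each subject performs ``blocks`` transition-balanced blocks (each
    ordered pair ``reps`` times per block); log-RT on each trial follows the
    linear generative model around ``rt_baseline``.  The first trial of a
    block has no predecessor and is omitted from the table.  Returns a long
    table: subject, block, trial, predecessor, object, rt_ms, correct.
    """
    metric = proximity_matrix(graph, config.generative_metric, config.gamma_fraction)
    labels = graph.node_labels
    rows = []
    for s, rng in enumerate(_subject_rngs(config.seed, config.n_subjects)):
        subject = f"sub-{s + 1:02d}"
        offsets = dict(zip(labels, rng.normal(0.0, config.object_effect_sd, len(labels))))
        for b in range(blocks):
            block_seed = int(rng.integers(2**31))
            seq = generate_behaviour_block(labels, reps, seed=block_seed)
            for t, (pred, obj) in enumerate(seq.transitions(), start=1):
                log_rt = (
                    config.rt_baseline
                    + config.beta_metric * metric.value(pred, obj)
                    + offsets[obj]
                    + rng.normal(0.0, config.noise_sd)
                )
                rows.append(
                    (
                        subject,
                        b + 1,
                        t,
                        pred,
                        obj,
                        float(np.exp(log_rt)),
                        bool(rng.random() >= error_rate),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["subject", "block", "trial", "predecessor", "object", "rt_ms", "correct"],
    )


def simulate_training_histories(
    graph: RelationalGraph,
    n_subjects: int = 23,
    blocks: int = 12,
    items_per_block: int = 133,
    exclusion_window: int = 3,
    seed: int = 0,
) -> list[TransitionCountMatrix]:
    """Per-subject transition counts aggregated over all training blocks.

    Each block is an independent window-constrained random walk on the
    training graph; counts land only on graph edges and sum to
    blocks * (items_per_block - 1) per subject.
    """
    histories = []
    for rng in _subject_rngs(seed, n_subjects):
        total = np.zeros((graph.n_nodes, graph.n_nodes), dtype=int)
        for _ in range(blocks):
            walk_seed = int(rng.integers(2**31))
            seq = generate_training_walk(
                graph, items_per_block, exclusion_window, seed=walk_seed
            )
            total += transition_counts(seq, graph.node_labels).counts
        histories.append(TransitionCountMatrix(total, graph.node_labels))
    return histories
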