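"""Stimulus-sequence designs and sequence-derived statistics.

Three designs are generated here:

* **training walk** — a random walk on the (12-node) training graph in which
  only directly connected objects may follow one another and an object may
  not recur until at least ``exclusion_window`` other objects have appeared;
* **scanner run** — a transition-balanced sequence over the reduced object
  set in which every ordered pair of distinct objects occurs as a
  consecutive pair exactly ``reps_per_transition`` times (a randomised
  Eulerian circuit on the complete directed multigraph);
* **behaviour block** — the same balanced design at the behavioural
  experiment's repetition count.

Derived statistics (transition counts, mean temporal gaps, presentation
counts) feed the asymmetry, edge-length and time-regressor analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .graphs import RelationalGraph, TransitionCountMatrix

__all__ = [
    "StimulusSequence",
    "generate_training_walk",
    "generate_scanner_run",
    "generate_behaviour_block",
    "annotate_cover_task",
    "transition_counts",
    "mean_gap_matrix",
    "presentation_counts",
    "events_table",
]


@dataclass(frozen=True)
class StimulusSequence:
    """An ordered stimulus sequence with per-trial cover-task flags.

    ``orientation`` is 'normal' or 'mirrored' per trial (the orientation
    cover task); ``patch``/``probe``/``excluded`` support the patch-detection
    cover task used in the scanner.
    """

    items: tuple
    orientation: tuple
    patch: tuple = field(default=())
    probe: tuple = field(default=())
    excluded: tuple = field(default=())

    def __post_init__(self):
        items = tuple(self.items)
        n = len(items)
        for a, b in zip(items, items[1:]):
            if a == b:
                raise ValueError("consecutive identical items")
        object.__setattr__(self, "items", items)
        object.__setattr__(self, "orientation", tuple(self.orientation))
        for name in ("patch", "probe", "excluded"):
            v = tuple(getattr(self, name))
            if not v:
                v = (False,) * n
            object.__setattr__(self, name, v)
        for name in ("orientation", "patch", "probe", "excluded"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} flags length != sequence length")

    def __len__(self) -> int:
        return len(self.items)

    def transitions(self) -> list[tuple]:
        """Consecutive ordered pairs (predecessor, object)."""
        return list(zip(self.items, self.items[1:]))


def _orientations(n: int, rng: np.random.Generator) -> tuple:
    return tuple(np.where(rng.random(n) < 0.5, "normal", "mirrored"))


# ---------------------------------------------------------------------------
# Training walk
# ---------------------------------------------------------------------------


def generate_training_walk(
    graph: RelationalGraph,
    n_items: int = 133,
    exclusion_window: int = 3,
    seed: int = 0,
    max_backtracks: int = 50,
    max_restarts: int = 20,
) -> StimulusSequence:
    """Random walk on the graph with a local-repetition exclusion window.

    Every consecutive pair is a graph edge, and an object never recurs
    within ``exclusion_window`` subsequent positions (window 3 means at
    least three other objects separate two presentations of the same
    object).  Dead ends trigger bounded backtracking; if a walk cannot be
    completed after ``max_restarts`` restarts (each with a derived seed), a
    ``RuntimeError`` is raised.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    neighbors = {v: graph.neighbors(v) for v in graph.node_labels}
    for attempt in range(max_restarts):
        rng = np.random.default_rng((int(seed) + 7919 * attempt) % 2**31)
        walk = [graph.node_labels[rng.integers(graph.n_nodes)]]
        # per-position candidate stacks for backtracking
        options: list[list] = []
        backtracks = 0
        while len(walk) < n_items:
            recent = set(walk[-exclusion_window:]) if exclusion_window > 0 else {walk[-1]}
            cands = [v for v in neighbors[walk[-1]] if v not in recent]
            rng.shuffle(cands)
            options.append(cands)
            advanced = False
            while options:
                if options[-1]:
                    walk.append(options[-1].pop())
                    advanced = True
                    break
                options.pop()
                if len(walk) > 1:
                    walk.pop()
                backtracks += 1
                if backtracks > max_backtracks:
                    break
            if not advanced:
                break
        if len(walk) == n_items:
            return StimulusSequence(items=walk, orientation=_orientations(n_items, rng))
    raise RuntimeError(
        f"no valid walk of {n_items} items with exclusion window "
        f"{exclusion_window} found after {max_restarts} restarts"
    )


# ---------------------------------------------------------------------------
# Balanced sequences (randomised Eulerian circuit)
# ---------------------------------------------------------------------------


def _eulerian_balanced_sequence(
    nodes: Sequence, reps: int, rng: np.random.Generator
) -> list:
    """Hierholzer's algorithm on the complete directed multigraph where every
    ordered pair of distinct nodes is an arc with multiplicity ``reps``.

    In- and out-degrees are all equal, so an Eulerian circuit exists; the
    resulting node sequence contains every ordered pair exactly ``reps``
    times as a consecutive pair and has length n(n-1)·reps + 1.
    """
    nodes = list(nodes)
    arcs = {u: [v for v in nodes if v != u for _ in range(reps)] for u in nodes}
    for u in arcs:
        rng.shuffle(arcs[u])
    start = nodes[int(rng.integers(len(nodes)))]
    stack = [start]
    circuit: list = []
    while stack:
        u = stack[-1]
        if arcs[u]:
            stack.append(arcs[u].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    return circuit


def generate_scanner_run(
    nodes: Sequence, reps_per_transition: int = 10, seed: int = 0
) -> StimulusSequence:
    """One transition-balanced scanner run.

    Every ordered pair of distinct objects occurs exactly
    ``reps_per_transition`` times as a consecutive pair; with 7 objects and
    10 repetitions this gives 7·6·10 + 1 = 421 items.  Objects never repeat
    immediately (the multigraph has no self-arcs).
    """
    nodes = list(nodes)
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes")
    if reps_per_transition <= 0:
        raise ValueError("reps_per_transition must be positive")
    rng = np.random.default_rng(int(seed) % 2**31)
    items = _eulerian_balanced_sequence(nodes, reps_per_transition, rng)
    return StimulusSequence(items=items, orientation=_orientations(len(items), rng))


def generate_behaviour_block(
    nodes: Sequence, reps_per_transition: int = 3, seed: int = 0
) -> StimulusSequence:
    """One transition-balanced behavioural test block (7 objects at 3
    repetitions per ordered pair gives 127 items)."""
    return generate_scanner_run(nodes, reps_per_transition, seed)


# ---------------------------------------------------------------------------
# Cover-task annotation
# ---------------------------------------------------------------------------


def annotate_cover_task(
    seq: StimulusSequence,
    patch_prob: float = 0.5,
    probes_per_transition: int = 1,
    seed: int = 0,
) -> StimulusSequence:
    """Attach patch flags and probe trials to a balanced sequence.

    A patch appears independently on each trial with probability
    ``patch_prob``.  For every ordered transition type, exactly
    ``probes_per_transition`` of its occurrences (the trial completing the
    transition) are marked as probes; each probe trial and the two trials
    after it are flagged for exclusion from response modelling.
    """
    rng = np.random.default_rng(int(seed) % 2**31)
    n = len(seq)
    patch = rng.random(n) < patch_prob
    positions: dict[tuple, list[int]] = {}
    for t, pair in enumerate(seq.transitions(), start=1):
        positions.setdefault(pair, []).append(t)
    probe = np.zeros(n, dtype=bool)
    for pair in sorted(positions, key=str):
        pos = positions[pair]
        if probes_per_transition > len(pos):
            raise ValueError(
                f"requested {probes_per_transition} probes for transition "
                f"{pair!r} but only {len(pos)} occurrences exist"
            )
        chosen = rng.choice(len(pos), size=probes_per_transition, replace=False)
        for c in chosen:
            probe[pos[c]] = True
    excluded = np.zeros(n, dtype=bool)
    for t in np.flatnonzero(probe):
        excluded[t : t + 3] = True
    return replace(
        seq, patch=tuple(patch), probe=tuple(probe), excluded=tuple(excluded)
    )


# ---------------------------------------------------------------------------
# Sequence statistics
# ---------------------------------------------------------------------------


def transition_counts(
    seq: StimulusSequence, node_labels: Sequence | None = None
) -> TransitionCountMatrix:
    """Directed counts of consecutive pairs in a sequence."""
    if node_labels is None:
        node_labels = sorted(set(seq.items), key=str)
    node_labels = tuple(node_labels)
    idx = {v: i for i, v in enumerate(node_labels)}
    counts = np.zeros((len(node_labels), len(node_labels)), dtype=int)
    for a, b in seq.transitions():
        counts[idx[a], idx[b]] += 1
    return TransitionCountMatrix(counts, node_labels)


def mean_gap_matrix(
    seq: StimulusSequence,
    node_labels: Sequence | None = None,
    symmetrise: bool = True,
) -> pd.DataFrame:
    """Mean number of intervening items between occurrences of a node pair.

    For each occurrence of j, the gap to the most recent prior occurrence of
    i is the number of items strictly between them; entry (i, j) averages
    those gaps.  By default the matrix is symmetrised by averaging (i, j)
    with (j, i), matching its use as a symmetric time regressor.  Pairs that
    never co-occur are NaN.
    """
    if node_labels is None:
        node_labels = sorted(set(seq.items), key=str)
    node_labels = tuple(node_labels)
    idx = {v: i for i, v in enumerate(node_labels)}
    n = len(node_labels)
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    last_pos: dict = {}
    for t, item in enumerate(seq.items):
        j = idx[item]
        for other, s in last_pos.items():
            i = idx[other]
            if i == j:
                continue
            total[i, j] += t - s - 1
            count[i, j] += 1
        last_pos[item] = t
    with np.errstate(invalid="ignore", divide="ignore"):
        directed = total / count
    if not symmetrise:
        np.fill_diagonal(directed, 0.0)
        return pd.DataFrame(directed, index=node_labels, columns=node_labels)
    sym_total = np.where(np.isnan(directed), 0, directed) + np.where(
        np.isnan(directed.T), 0, directed.T
    )
    sym_n = (~np.isnan(directed)).astype(int) + (~np.isnan(directed.T)).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        sym = np.where(sym_n > 0, sym_total / sym_n, np.nan)
    np.fill_diagonal(sym, 0.0)
    return pd.DataFrame(sym, index=node_labels, columns=node_labels)


def presentation_counts(seq: StimulusSequence) -> dict:
    """Occurrence count per node; sums to the sequence length."""
    out: dict = {}
    for item in seq.items:
        out[item] = out.get(item, 0) + 1
    return out


# ---------------------------------------------------------------------------
# Events export
# ---------------------------------------------------------------------------


def events_table(
    seq: StimulusSequence,
    stimulus_duration: float = 1.0,
    iti_mean: float = 2.0,
    iti_min: float = 1.0,
    iti_max: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Events table with synthesised onsets (BIDS-style columns).

    Inter-trial intervals are drawn from a Poisson distribution with the
    given mean, resampled until they fall within [iti_min, iti_max].
    """
    rng = np.random.default_rng(int(seed) % 2**31)
    n = len(seq)
    itis = np.empty(n)
    for k in range(n):
        v = rng.poisson(iti_mean)
        while not (iti_min <= v <= iti_max):
            v = rng.poisson(iti_mean)
        itis[k] = v
    onsets = np.concatenate([[0.0], np.cumsum(stimulus_duration + itis[:-1])])
    predecessors = [""] + [str(x) for x in seq.items[:-1]]
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": stimulus_duration,
            "object": [str(x) for x in seq.items],
            "predecessor": predecessors,
            "orientation": list(seq.orientation),
            "patch": list(seq.patch),
            "probe": list(seq.probe),
            "excluded": list(seq.excluded),
        }
    )
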