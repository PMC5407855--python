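"""Response-time analysis of the behavioural cohort.

Trials from the balanced behavioural blocks are reduced to one demeaned
log-RT per ordered object pair per subject (log transform, per-object
demeaning, per-transition-per-block mean, across-block mean), then fed
through the same competitive regression used for the adaptation estimates,
and summarised as equal-count communicability bins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import TransitionResponseTable
from .graphs import ProximityMatrix
from .models import TransitionRegressionResults, competitive_regression

__all__ = ["preprocess_rt", "rt_regression", "communicability_bins"]


def preprocess_rt(
    trials: pd.DataFrame, exclude_incorrect: bool = True
) -> list[TransitionResponseTable]:
    """Reduce per-trial response times to one value per transition per subject.

    Pipeline (within subject): log-transform RTs; subtract the mean log-RT
    for each object (removing object-specific speed differences); average
    the demeaned values per transition within each block; average those
    block means across blocks.  Requires every transition to appear in every
    block; a missing transition raises an error naming the pair and block.
    """
    required = {"subject", "block", "predecessor", "object", "rt_ms"}
    if not required <= set(trials.columns):
        raise ValueError(f"trials table must have columns {sorted(required)}")
    df = trials.copy()
    if exclude_incorrect and "correct" in df.columns:
        df = df[df["correct"]]
    if (df["rt_ms"] <= 0).any():
        raise ValueError("response times must be positive")
    df["log_rt"] = np.log(df["rt_ms"].astype(float))
    tables = []
    all_pairs = None
    for subject, sub in df.groupby("subject", sort=True):
        sub = sub.copy()
        sub["demeaned"] = sub["log_rt"] - sub.groupby("object")["log_rt"].transform(
            "mean"
        )
        if all_pairs is None:
            objs = sorted(set(sub["object"]) | set(sub["predecessor"]), key=str)
            all_pairs = [(i, j) for i in objs for j in objs if i != j]
        per_block = sub.groupby(["block", "predecessor", "object"])["demeaned"].mean()
        for block in sorted(sub["block"].unique()):
            present = set(per_block.loc[block].index)
            missing = [p for p in all_pairs if p not in present]
            if missing:
                raise ValueError(
                    f"subject {subject!r}, block {block}: missing transitions "
                    f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
                )
        across = per_block.groupby(["predecessor", "object"]).mean()
        rows = [(i, j, float(across.loc[(i, j)])) for i, j in all_pairs]
        tables.append(
            TransitionResponseTable(
                subject=str(subject),
                data=pd.DataFrame(rows, columns=["predecessor", "object", "response"]),
            )
        )
    return tables


def rt_regression(
    responses: list[TransitionResponseTable],
    regressors: dict[str, ProximityMatrix],
    demean: bool | str = "object",
) -> TransitionRegressionResults:
    """Competitive regression of preprocessed response times on proximity
    metrics (typically communicability, link and Euclidean distance).

    Because the preprocessed responses have object-specific means removed,
    the regressors are by default demeaned within each object as well
    (``demean="object"``), which keeps the design consistent with the
    response transformation.
    """
    return competitive_regression(responses, regressors, demean=demean)


def communicability_bins(
    responses: list[TransitionResponseTable],
    comm: ProximityMatrix,
    n_bins: int = 6,
) -> pd.DataFrame:
    """Equal-count communicability bins of mean demeaned log-RT.

    Ordered pairs are sorted by communicability (stable order breaks ties),
    split into ``n_bins`` bins with equal pair counts (remainders spread
    over the leading bins), and the across-subject mean response per bin is
    reported alongside the mean communicability.
    """
    if not responses:
        raise ValueError("need at least one subject")
    first = responses[0].data
    pairs = list(zip(first["predecessor"], first["object"]))
    if n_bins > len(pairs):
        raise ValueError(f"{n_bins} bins requested for only {len(pairs)} pairs")
    comm_vals = np.array([comm.value(i, j) for i, j in pairs])
    order = np.argsort(comm_vals, kind="stable")
    splits = np.array_split(order, n_bins)
    mean_resp = np.zeros(len(pairs))
    for table in responses:
        resp = dict(
            zip(
                zip(table.data["predecessor"], table.data["object"]),
                table.data["response"],
            )
        )
        mean_resp += np.array([resp[p] for p in pairs], dtype=float)
    mean_resp /= len(responses)
    rows = []
    for b, sel in enumerate(splits):
        rows.append(
            {
                "bin": b + 1,
                "n_pairs": len(sel),
                "mean_communicability": float(comm_vals[sel].mean()),
                "mean_response": float(mean_resp[sel].mean()),
            }
        )
    return pd.DataFrame(rows)
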