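"""Model objects for the adaptation analysis chain.

Three fitted-model surfaces, in the statsmodels idiom (a Model constructed
from data whose ``fit()`` returns a Results object with a ``summary()``):

* :class:`TransitionRegressionModel` — per-subject ordinary least squares of
  transition responses on one or more competing proximity regressors, with
  group inference by a two-tailed one-sample t-test on the per-subject
  coefficients.
* :class:`DistanceContrastModel` — responses binned by link distance
  (1, 2, 3): paired contrasts (connected vs non-connected, link 2 vs link 3)
  and a one-way repeated-measures ANOVA across the three bins.
* :class:`MapRecoveryModel` — group transition matrix -> dissimilarity ->
  two-dimensional (non)metric MDS -> correlation with the true graph's link
  distances, judged against an exhaustive permutation null over connected
  graph topologies, plus the planar line-crossing test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.manifold import MDS

from .graphs import (
    NullGraphEnsemble,
    ProximityMatrix,
    RelationalGraph,
    count_line_crossings,
    ensemble_crossing_counts,
    ensemble_link_correlations,
    enumerate_null_graphs,
    link_distance_matrix,
)
from .cohort import TransitionResponseTable

__all__ = [
    "GroupTransitionMatrix",
    "group_transition_matrix",
    "prepare_dissimilarity",
    "mds_embed",
    "map_recovery_test",
    "MapRecoveryModel",
    "MapRecoveryResults",
    "TransitionRegressionModel",
    "TransitionRegressionResults",
    "competitive_regression",
    "DistanceContrastModel",
    "DistanceContrastResults",
    "distance_contrasts",
    "rm_anova_oneway",
]


# ---------------------------------------------------------------------------
# Group matrix and dissimilarity preparation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupTransitionMatrix:
    """Across-subject mean response per ordered pair; diagonal fixed at 0."""

    values: np.ndarray
    node_labels: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.node_labels), len(self.node_labels)):
            raise ValueError("matrix shape does not match node labels")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly 0")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))


def group_transition_matrix(
    tables: list[TransitionResponseTable], node_labels
) -> GroupTransitionMatrix:
    """Cell-wise mean of per-subject response matrices, diagonal zero."""
    if not tables:
        raise ValueError("need at least one subject")
    labels = tuple(node_labels)
    pair_sets = {frozenset(zip(t.data["predecessor"], t.data["object"])) for t in tables}
    if len(pair_sets) != 1:
        raise ValueError("subjects do not cover identical transition pairs")
    stack = np.stack([t.matrix(labels) for t in tables])
    mean = stack.mean(axis=0)
    np.fill_diagonal(mean, 0.0)
    return GroupTransitionMatrix(mean, labels)


def prepare_dissimilarity(matrix: GroupTransitionMatrix) -> np.ndarray:
    """Shift and symmetrise a group transition matrix for MDS.

    The upper and lower triangles are averaged, the off-diagonal entries are
    shifted so their minimum is exactly 1 (making every dissimilarity
    positive), and the diagonal is reset to 0 as a dissimilarity matrix
    requires.
    """
    v = 0.5 * (matrix.values + matrix.values.T)
    n = v.shape[0]
    off = ~np.eye(n, dtype=bool)
    v[off] = v[off] - v[off].min() + 1.0
    np.fill_diagonal(v, 0.0)
    return v


# ---------------------------------------------------------------------------
# MDS embedding
# ---------------------------------------------------------------------------


def mds_embed(
    dissimilarity,
    node_labels=None,
    n_dims: int = 2,
    seed: int = 0,
    metric: bool = False,
    n_init: int = 20,
) -> dict:
    """Embed a dissimilarity matrix in ``n_dims`` dimensions by MDS.

    Nonmetric by default (Kruskal stress-1 on rank order, ``n_init`` random
    restarts, best solution kept); set ``metric=True`` for classical metric
    stress.  Returns node -> coordinate mapping.
    """
    if isinstance(dissimilarity, pd.DataFrame):
        if node_labels is None:
            node_labels = tuple(dissimilarity.columns)
        d = dissimilarity.to_numpy(dtype=float)
    else:
        d = np.asarray(dissimilarity, dtype=float)
        if node_labels is None:
            node_labels = tuple(range(d.shape[0]))
    node_labels = tuple(node_labels)
    if d.shape != (len(node_labels), len(node_labels)):
        raise ValueError("dissimilarity shape does not match labels")
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity must be symmetric")
    off = d[~np.eye(d.shape[0], dtype=bool)]
    if np.ptp(off) == 0:
        raise ValueError("degenerate (constant) dissimilarity; MDS undefined")
    mds = MDS(
        n_components=n_dims,
        metric=metric,
        n_init=n_init,
        max_iter=2000,
        eps=1e-9,
        dissimilarity="precomputed",
        random_state=int(seed) % 2**31,
        normalized_stress="auto",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        coords = mds.fit_transform(d)
    return {lab: tuple(coords[k]) for k, lab in enumerate(node_labels)}


def _embedded_distance_vector(embedding: dict, node_labels) -> np.ndarray:
    pts = np.array([embedding[v] for v in node_labels], dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(len(node_labels), k=1)
    return d[iu]


# ---------------------------------------------------------------------------
# Map recovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MapRecoveryResults:
    """Outcome of the map-recovery permutation test."""

    embedding: dict = field(compare=False)
    correlation_with_link: float
    permutation_p: float
    observed_crossings: int
    null_crossing_fraction: float
    ensemble_size: int
    null_correlations: np.ndarray = field(compare=False, repr=False)

    def summary(self) -> str:
        lines = [
            "Map recovery (MDS vs graph link distances)",
            "=" * 46,
            f"correlation with link distance   r = {self.correlation_with_link:+.4f}",
            f"permutation null (topologies)    {self.ensemble_size} graphs",
            f"permutation p (null r >= obs)    p = {self.permutation_p:.4f}",
            f"line crossings at embedding      {self.observed_crossings}",
            f"null fraction with 0 crossings   {self.null_crossing_fraction:.4f}",
        ]
        return "\n".join(lines)

    def plot(self, graph: "RelationalGraph", ax=None):
        """Draw the recovered 2-D embedding with the true graph's edges."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        for e in graph.edges:
            a, b = tuple(e)
            xs, ys = zip(self.embedding[a], self.embedding[b])
            ax.plot(xs, ys, color="0.6", lw=1.5, zorder=1)
        for node, (x, y) in self.embedding.items():
            ax.scatter([x], [y], s=120, zorder=2)
            ax.annotate(str(node), (x, y), ha="center", va="center", zorder=3)
        ax.set_aspect("equal")
        ax.set_title(
            f"recovered map (r = {self.correlation_with_link:.2f}, "
            f"p = {self.permutation_p:.3g})"
        )
        return ax


def map_recovery_test(
    embedding: dict, graph: RelationalGraph, ensemble: NullGraphEnsemble
) -> MapRecoveryResults:
    """Judge an embedding against the true graph and a topology null.

    The observed statistic is the Pearson correlation between embedded
    pairwise distances and the true graph's link distances (upper-triangle
    pairs); the permutation p is the fraction of null topologies whose link
    distances correlate at least as strongly with the same embedding.
    """
    if set(ensemble.node_labels) != set(graph.node_labels):
        raise ValueError("ensemble and graph are defined on different node sets")
    labels = graph.node_labels
    if not set(labels) <= set(embedding):
        raise ValueError("embedding does not cover all graph nodes")
    emb_d = _embedded_distance_vector(embedding, labels)
    link = link_distance_matrix(graph).upper_triangle()
    observed_r = float(np.corrcoef(emb_d, link)[0, 1])
    # the ensemble's canonical pair order must match the graph's label order
    ens = ensemble
    if ens.node_labels != labels:
        ens = NullGraphEnsemble(node_labels=labels, members=ensemble.members)
    null_r = ensemble_link_correlations(ens, emb_d)
    permutation_p = float(np.mean(null_r >= observed_r))
    observed_crossings = count_line_crossings(
        embedding, [tuple(e) for e in graph.edges]
    )
    null_crossings = ensemble_crossing_counts(ens, embedding)
    return MapRecoveryResults(
        embedding=dict(embedding),
        correlation_with_link=observed_r,
        permutation_p=permutation_p,
        observed_crossings=int(observed_crossings),
        null_crossing_fraction=float(np.mean(null_crossings == 0)),
        ensemble_size=len(ens),
        null_correlations=null_r,
    )


class MapRecoveryModel:
    """Recover a 2-D map from transition responses and test it.

    Parameters
    ----------
    data : list of TransitionResponseTable or GroupTransitionMatrix
        Per-subject response tables (averaged internally) or an
        already-averaged group matrix.
    graph : RelationalGraph
        The true relational graph whose structure the map should mirror.
    ensemble : NullGraphEnsemble, optional
        Permutation null; enumerated from the graph's node and edge counts
        when omitted.
    metric_mds : bool
        Use metric instead of nonmetric MDS.
    """

    def __init__(self, data, graph: RelationalGraph, ensemble=None, metric_mds=False):
        if isinstance(data, GroupTransitionMatrix):
            self.group_matrix = data
        else:
            self.group_matrix = group_transition_matrix(data, graph.node_labels)
        self.graph = graph
        self.ensemble = ensemble
        self.metric_mds = metric_mds

    def fit(self, seed: int = 0, n_init: int = 20) -> MapRecoveryResults:
        dissim = prepare_dissimilarity(self.group_matrix)
        embedding = mds_embed(
            dissim,
            node_labels=self.graph.node_labels,
            n_dims=2,
            seed=seed,
            metric=self.metric_mds,
            n_init=n_init,
        )
        ensemble = self.ensemble
        if ensemble is None:
            ensemble = enumerate_null_graphs(
                self.graph.n_nodes, self.graph.n_edges, self.graph.node_labels
            )
        return map_recovery_test(embedding, self.graph, ensemble)


# ---------------------------------------------------------------------------
# Competitive regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransitionRegressionResults:
    """Per-subject OLS coefficients with group-level one-sample t-tests."""

    params: pd.DataFrame = field(compare=False)  # subjects x regressors
    group_mean: pd.Series = field(compare=False)
    tvalues: pd.Series = field(compare=False)
    pvalues: pd.Series = field(compare=False)
    df: int = 0
    flags: tuple = ()

    @property
    def regressor_names(self) -> list[str]:
        return [c for c in self.params.columns if c != "intercept"]

    def summary(self) -> str:
        lines = [
            "Competitive transition regression",
            "=" * 62,
            f"{'regressor':<22}{'beta (group)':>14}{'t':>10}{'p':>12}",
            "-" * 62,
        ]
        for name in self.params.columns:
            t = self.tvalues[name]
            p = self.pvalues[name]
            lines.append(
                f"{name:<22}{self.group_mean[name]:>14.4f}"
                f"{t:>10.3f}{p:>12.4g}"
            )
        lines.append("-" * 62)
        lines.append(f"subjects: {len(self.params)}   group df: {self.df}")
        for fl in self.flags:
            lines.append(f"note: {fl}")
        return "\n".join(lines)


class TransitionRegressionModel:
    """Per-subject OLS of transition responses on competing proximity
    regressors; group inference across subjects.

    Each subject's n(n-1) responses are regressed (with an intercept) on
    the regressor values for the corresponding ordered pairs.  Regressors
    are mean-centred by default; with ``demean="object"`` each regressor is
    instead demeaned within the current object (across predecessors), the
    transformation that matches response tables whose object-specific means
    have been removed (equivalent to object fixed effects).  Group-level
    significance is a two-tailed one-sample t-test of the per-subject
    coefficients against zero.
    """

    def __init__(
        self,
        tables: list[TransitionResponseTable],
        regressors: dict[str, ProximityMatrix | np.ndarray],
        node_labels=None,
        demean: bool | str = True,
        zscore: bool = False,
    ):
        if not tables:
            raise ValueError("need at least one subject")
        if not regressors:
            raise ValueError("need at least one regressor")
        self.tables = list(tables)
        first = self.tables[0].data
        self.pairs = list(zip(first["predecessor"], first["object"]))
        if node_labels is None:
            node_labels = tuple(sorted({v for p in self.pairs for v in p}, key=str))
        self.node_labels = tuple(node_labels)
        cols = {}
        for name, reg in regressors.items():
            if isinstance(reg, ProximityMatrix):
                col = np.array([reg.value(i, j) for i, j in self.pairs])
            else:
                reg = np.asarray(reg, dtype=float)
                idx = {v: k for k, v in enumerate(self.node_labels)}
                col = np.array([reg[idx[i], idx[j]] for i, j in self.pairs])
            if demean == "object":
                objs = np.array([j for _, j in self.pairs], dtype=object)
                for obj in set(objs):
                    sel = objs == obj
                    col[sel] = col[sel] - col[sel].mean()
            elif demean or zscore:
                col = col - col.mean()
            if zscore:
                sd = col.std(ddof=0)
                if sd > 0:
                    col = col / sd
            cols[name] = col
        self.design = pd.DataFrame(cols)
        x = sm.add_constant(self.design.to_numpy(), prepend=True)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            names = list(self.design.columns)
            corr = np.corrcoef(self.design.to_numpy().T)
            collinear = [
                (names[a], names[b])
                for a in range(len(names))
                for b in range(a + 1, len(names))
                if abs(corr[a, b]) > 1 - 1e-10
            ]
            raise ValueError(
                f"rank-deficient design; collinear regressors: {collinear or names}"
            )
        self._x = x

    def fit(self) -> TransitionRegressionResults:
        col_names = ["intercept"] + list(self.design.columns)
        rows = []
        for table in self.tables:
            resp = dict(
                zip(
                    zip(table.data["predecessor"], table.data["object"]),
                    table.data["response"],
                )
            )
            y = np.array([resp[p] for p in self.pairs], dtype=float)
            res = sm.OLS(y, self._x).fit()
            rows.append(res.params)
        params = pd.DataFrame(
            rows, columns=col_names, index=[t.subject for t in self.tables]
        )
        flags = []
        tvals, pvals = {}, {}
        n = len(params)
        for name in col_names:
            coefs = params[name].to_numpy()
            if np.std(coefs, ddof=1) == 0 or n < 2:
                if np.allclose(coefs, 0):
                    tvals[name] = 0.0
                    pvals[name] = 1.0
                else:
                    tvals[name] = np.nan
                    pvals[name] = np.nan
                    flags.append(
                        f"group t undefined for {name!r} (zero variance across subjects)"
                    )
            else:
                t, p = scipy.stats.ttest_1samp(coefs, 0.0)
                tvals[name] = float(t)
                pvals[name] = float(p)
        return TransitionRegressionResults(
            params=params,
            group_mean=params.mean(),
            tvalues=pd.Series(tvals),
            pvalues=pd.Series(pvals),
            df=n - 1,
            flags=tuple(flags),
        )


def competitive_regression(
    tables, regressors, node_labels=None, demean=True, zscore=False
) -> TransitionRegressionResults:
    """Convenience wrapper: build and fit a TransitionRegressionModel."""
    return TransitionRegressionModel(
        tables, regressors, node_labels=node_labels, demean=demean, zscore=zscore
    ).fit()


# ---------------------------------------------------------------------------
# Distance contrasts
# ---------------------------------------------------------------------------


def rm_anova_oneway(data: np.ndarray) -> tuple[float, int, int, float]:
    """One-way repeated-measures ANOVA on a subjects x conditions array.

    Classic sum-of-squares decomposition: F = MS_condition / MS_error with
    (k-1, (k-1)(n-1)) degrees of freedom.  Returns (F, df1, df2, p).
    """
    y = np.asarray(data, dtype=float)
    n, k = y.shape
    grand = y.mean()
    ss_cond = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        f = 0.0 if ms_cond == 0 else np.inf
    else:
        f = ms_cond / ms_err
    p = float(scipy.stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return float(f), df1, df2, p


@dataclass(frozen=True)
class DistanceContrastResults:
    """Distance-binned responses with paired contrasts and RM-ANOVA."""

    bin_means: pd.DataFrame = field(compare=False)  # subjects x distance bins
    t_connected: float = np.nan
    p_connected: float = np.nan
    t_link23: float = np.nan
    p_link23: float = np.nan
    anova_f: float = np.nan
    anova_df: tuple = (0, 0)
    anova_p: float = np.nan

    def summary(self) -> str:
        means = self.bin_means.mean()
        lines = [
            "Distance contrasts (responses binned by link distance)",
            "=" * 58,
            "group bin means: "
            + ", ".join(f"d={int(c)}: {means[c]:+.4f}" for c in self.bin_means.columns),
            f"connected vs non-connected   t = {self.t_connected:+.3f}, "
            f"p = {self.p_connected:.4g}",
            f"link 2 vs link 3             t = {self.t_link23:+.3f}, "
            f"p = {self.p_link23:.4g}",
            f"RM-ANOVA across bins         F({self.anova_df[0]},{self.anova_df[1]}) "
            f"= {self.anova_f:.3f}, p = {self.anova_p:.4g}",
        ]
        return "\n".join(lines)


class DistanceContrastModel:
    """Contrast transition responses by link distance between the pair.

    With link distances in {1, 2, 3}: per-subject mean response per distance
    bin; paired two-tailed t-tests for connected (distance 1) versus
    non-connected (distance 2 or 3) and for link 2 versus link 3; a one-way
    repeated-measures ANOVA across the three bins.  Optionally removes
    object-specific mean activity first (``demean_objects``).
    """

    def __init__(
        self,
        tables: list[TransitionResponseTable],
        link: ProximityMatrix,
        demean_objects: bool = False,
    ):
        self.tables = list(tables)
        self.link = link
        self.demean_objects = demean_objects

    def fit(self) -> DistanceContrastResults:
        dists = sorted(
            {
                int(self.link.value(i, j))
                for i in self.link.node_labels
                for j in self.link.node_labels
                if i != j
            }
        )
        per_subject_bins = []
        per_subject_conn = []
        for table in self.tables:
            df = table.data.copy()
            if self.demean_objects:
                df["response"] = df["response"] - df.groupby("object")[
                    "response"
                ].transform("mean")
            d = np.array(
                [self.link.value(i, j) for i, j in zip(df["predecessor"], df["object"])]
            ).astype(int)
            means = {}
            for dist in dists:
                sel = d == dist
                if not sel.any():
                    raise ValueError(f"distance bin {dist} is empty")
                means[dist] = float(df.loc[sel, "response"].mean())
            per_subject_bins.append(means)
            per_subject_conn.append(
                (
                    float(df.loc[d == 1, "response"].mean()),
                    float(df.loc[d > 1, "response"].mean()),
                )
            )
        bins = pd.DataFrame(per_subject_bins, index=[t.subject for t in self.tables])
        conn = np.array(per_subject_conn)
        t_conn, p_conn = _paired_t(conn[:, 0], conn[:, 1])
        if 2 in bins.columns and 3 in bins.columns:
            t_23, p_23 = _paired_t(bins[2].to_numpy(), bins[3].to_numpy())
        else:
            t_23, p_23 = np.nan, np.nan
        f, df1, df2, p_f = rm_anova_oneway(bins.to_numpy())
        return DistanceContrastResults(
            bin_means=bins,
            t_connected=t_conn,
            p_connected=p_conn,
            t_link23=t_23,
            p_link23=p_23,
            anova_f=f,
            anova_df=(df1, df2),
            anova_p=p_f,
        )


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    diff = a - b
    if np.std(diff, ddof=1) == 0:
        return (0.0, 1.0) if np.allclose(diff, 0) else (np.inf, 0.0)
    t, p = scipy.stats.ttest_rel(a, b)
    return float(t), float(p)


def distance_contrasts(
    tables, link, demean_objects: bool = False
) -> DistanceContrastResults:
    """Convenience wrapper: build and fit a DistanceContrastModel."""
    return DistanceContrastModel(tables, link, demean_objects=demean_objects).fit()
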