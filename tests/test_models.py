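"""Model objects: group matrix, MDS map recovery, regressions, contrasts."""

import numpy as np
import pandas as pd
import pytest

import relmap as rm
from relmap.cohort import TransitionResponseTable
from relmap.models import rm_anova_oneway


def _table(subject, labels, fn):
    rows = [(i, j, fn(i, j)) for i in labels for j in labels if i != j]
    return TransitionResponseTable(
        subject=subject,
        data=pd.DataFrame(rows, columns=["predecessor", "object", "response"]),
    )


# ---------------------------------------------------------------------------
# Group transition matrix and dissimilarity preparation
# ---------------------------------------------------------------------------


def test_group_matrix_single_subject_and_cancellation(reduced_graph):
    labels = reduced_graph.node_labels
    t1 = _table("s1", labels, lambda i, j: i + 10 * j)
    gm = rm.group_transition_matrix([t1], labels)
    assert np.allclose(gm.values, t1.matrix(labels))
    assert np.all(np.diag(gm.values) == 0)
    t2 = _table("s2", labels, lambda i, j: -(i + 10 * j))
    gm2 = rm.group_transition_matrix([t1, t2], labels)
    assert np.allclose(gm2.values, 0.0)


def test_group_matrix_matches_streaming_mean(noisy_cohort, reduced_graph):
    labels = reduced_graph.node_labels
    gm = rm.group_transition_matrix(noisy_cohort, labels)
    running = np.zeros((7, 7))
    for k, t in enumerate(noisy_cohort, start=1):
        running += (t.matrix(labels) - running) / k  # streaming-mean oracle
    np.fill_diagonal(running, 0.0)
    assert np.allclose(gm.values, running, atol=1e-10)


def test_group_matrix_rejects_inconsistent_coverage(reduced_graph):
    labels = reduced_graph.node_labels
    t1 = _table("s1", labels, lambda i, j: 1.0)
    t2 = _table("s2", labels, lambda i, j: 1.0)
    t2 = TransitionResponseTable(subject="s2", data=t2.data.iloc[:-1])
    with pytest.raises(ValueError, match="identical"):
        rm.group_transition_matrix([t1, t2], labels)


def test_prepare_dissimilarity_properties(reduced_graph):
    labels = reduced_graph.node_labels
    rng = np.random.default_rng(2)
    v = rng.normal(size=(7, 7))
    np.fill_diagonal(v, 0.0)
    gm = rm.GroupTransitionMatrix(v, labels)
    d = rm.prepare_dissimilarity(gm)
    off = ~np.eye(7, dtype=bool)
    assert d[off].min() == pytest.approx(1.0)
    assert np.allclose(d, d.T)
    assert np.all(np.diag(d) == 0)
    # asymmetric entries are averaged, then shifted
    sym = 0.5 * (v + v.T)
    shift = -sym[off].min() + 1.0
    i, j = 0, 3
    assert d[i, j] == pytest.approx(0.5 * (v[i, j] + v[j, i]) + shift)


def test_dissimilarity_pipeline_commutes_with_relabelling(noisy_cohort, reduced_graph):
    labels = reduced_graph.node_labels
    perm = (3, 1, 7, 5, 2, 6, 4)
    p = [labels.index(v) for v in perm]
    d1 = rm.prepare_dissimilarity(rm.group_transition_matrix(noisy_cohort, labels))
    relabelled = []
    for t in noisy_cohort:
        relabelled.append(TransitionResponseTable(subject=t.subject, data=t.data))
    d2 = rm.prepare_dissimilarity(rm.group_transition_matrix(relabelled, perm))
    assert np.allclose(d2, d1[np.ix_(p, p)])


# ---------------------------------------------------------------------------
# MDS embedding
# ---------------------------------------------------------------------------


def test_mds_recovers_collinear_configuration():
    pts = np.array([[0.0], [1.0], [2.5]])
    d = np.abs(pts - pts.T)
    emb = rm.mds_embed(d, node_labels=("a", "b", "c"), n_dims=2, seed=0, metric=True)
    coords = np.array([emb[v] for v in ("a", "b", "c")])
    diff = coords[:, None, :] - coords[None, :, :]
    got = np.sqrt((diff**2).sum(-1))
    assert np.allclose(got, d, atol=1e-3)


def test_mds_on_link_distances_recovers_structure(reduced_graph):
    ld = rm.link_distance_matrix(reduced_graph)
    emb = rm.mds_embed(ld.values, node_labels=reduced_graph.node_labels, seed=1)
    pts = np.array([emb[v] for v in reduced_graph.node_labels])
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(7, k=1)
    r = np.corrcoef(dist[iu], ld.values[iu])[0, 1]
    assert r >= 0.95


def test_mds_rejects_degenerate_input():
    d = np.ones((4, 4)) - np.eye(4)
    d[:] = 0.0
    with pytest.raises(ValueError, match="degenerate"):
        rm.mds_embed(d, seed=0)


# ---------------------------------------------------------------------------
# Map recovery
# ---------------------------------------------------------------------------


def test_map_recovery_self_ensemble_gives_p_one(reduced_graph):
    ensemble = rm.NullGraphEnsemble(
        node_labels=reduced_graph.node_labels, members=(reduced_graph.edges,)
    )
    res = rm.map_recovery_test(reduced_graph.layout, reduced_graph, ensemble)
    assert res.permutation_p == 1.0
    assert res.observed_crossings == 0


def test_map_recovery_exact_layout_beats_null(reduced_graph, full_ensemble):
    """The true planar layout ranks above the 99th percentile of the
    topology null and shows no line crossings."""
    res = rm.map_recovery_test(reduced_graph.layout, reduced_graph, full_ensemble)
    assert res.ensemble_size == 68295
    assert res.permutation_p <= 0.01
    assert res.observed_crossings == 0
    assert np.percentile(res.null_correlations, 99) < res.correlation_with_link


def test_map_recovery_plot_draws_all_nodes_and_edges(reduced_graph):
    import matplotlib

    matplotlib.use("Agg")
    ensemble = rm.NullGraphEnsemble(
        node_labels=reduced_graph.node_labels, members=(reduced_graph.edges,)
    )
    res = rm.map_recovery_test(reduced_graph.layout, reduced_graph, ensemble)
    ax = res.plot(reduced_graph)
    assert len(ax.lines) == reduced_graph.n_edges
    assert len(ax.collections) == reduced_graph.n_nodes


def test_map_recovery_mismatched_nodes_error(reduced_graph):
    ens = rm.enumerate_null_graphs(3, 2)
    with pytest.raises(ValueError, match="node set"):
        rm.map_recovery_test(reduced_graph.layout, reduced_graph, ens)


def test_end_to_end_noiseless_map_recovery(reduced_graph, full_ensemble):
    """Cohort generated from link distance with no noise: the recovered map
    correlates with the true structure far beyond the permutation null and
    embeds without line crossings."""
    cfg = rm.CohortConfig(
        n_subjects=3,
        generative_metric="link",
        beta_metric=1.0,
        object_effect_sd=0.0,
        noise_sd=0.0,
        seed=2,
    )
    tables = rm.simulate_adaptation_cohort(cfg, reduced_graph)
    res = rm.MapRecoveryModel(tables, reduced_graph, ensemble=full_ensemble).fit(seed=4)
    assert res.permutation_p <= 0.01
    assert res.observed_crossings == 0
    assert res.correlation_with_link > 0.9


def test_high_noise_map_recovery_p_is_not_degenerate(reduced_graph, full_ensemble):
    """With noise ten times the signal the permutation p scatters over the
    unit interval instead of piling up near zero (sanity of the null)."""
    ps = []
    for seed in range(6):
        cfg = rm.CohortConfig(
            n_subjects=5,
            generative_metric="link",
            beta_metric=0.1,
            object_effect_sd=0.0,
            noise_sd=1.0,
            seed=seed,
        )
        tables = rm.simulate_adaptation_cohort(cfg, reduced_graph)
        res = rm.MapRecoveryModel(tables, reduced_graph, ensemble=full_ensemble).fit(
            seed=seed
        )
        ps.append(res.permutation_p)
    assert max(ps) > 0.2  # not uniformly tiny
    assert np.ptp(ps) > 0.1  # genuinely scattered


# ---------------------------------------------------------------------------
# Competitive regression
# ---------------------------------------------------------------------------


def test_regression_exact_coefficients(reduced_graph, training_graph):
    labels = reduced_graph.node_labels
    link = rm.link_distance_matrix(reduced_graph)
    walk = rm.generate_training_walk(training_graph, 400, 3, seed=1)
    gap = rm.mean_gap_matrix(walk, training_graph.node_labels)
    gap7 = gap.loc[list(labels), list(labels)].to_numpy()
    tables = [
        _table(f"s{k}", labels, lambda i, j: 2.0 * link.value(i, j)) for k in range(3)
    ]
    res = rm.competitive_regression(tables, {"link": link, "gap": gap7}, node_labels=labels)
    assert np.allclose(res.params["link"], 2.0, atol=1e-8)
    assert np.allclose(res.params["gap"], 0.0, atol=1e-8)


def test_regression_all_zero_responses(reduced_graph):
    labels = reduced_graph.node_labels
    tables = [_table(f"s{k}", labels, lambda i, j: 0.0) for k in range(4)]
    res = rm.competitive_regression(
        tables, {"link": rm.link_distance_matrix(reduced_graph)}
    )
    assert np.allclose(res.params.to_numpy(), 0.0)
    assert res.tvalues["link"] == 0.0


def test_regression_invariant_to_per_subject_shift(noisy_cohort, reduced_graph):
    regs = {
        "communicability": rm.communicability_matrix(reduced_graph),
        "link": rm.link_distance_matrix(reduced_graph),
    }
    res1 = rm.competitive_regression(noisy_cohort, regs)
    shifted = []
    for k, t in enumerate(noisy_cohort):
        df = t.data.copy()
        df["response"] = df["response"] + 5.0 * (k + 1)
        shifted.append(TransitionResponseTable(subject=t.subject, data=df))
    res2 = rm.competitive_regression(shifted, regs)
    for name in ("communicability", "link"):
        assert np.allclose(res1.params[name], res2.params[name], atol=1e-9)


def test_regression_rejects_collinear_design(reduced_graph):
    labels = reduced_graph.node_labels
    link = rm.link_distance_matrix(reduced_graph)
    double = rm.ProximityMatrix(2.0 * link.values, "link", labels)
    tables = [_table("s1", labels, lambda i, j: 1.0)]
    with pytest.raises(ValueError, match="collinear"):
        rm.competitive_regression(tables, {"link": link, "double": double})


def test_model_competition_identifies_generative_metric(noisy_cohort, reduced_graph):
    """Communicability-generated data analysed with the three-regressor
    model shows a group effect for communicability only."""
    regs = {k: rm.proximity_matrix(reduced_graph, k) for k in
            ("communicability", "link", "euclidean")}
    res = rm.competitive_regression(noisy_cohort, regs)
    assert res.pvalues["communicability"] < 0.05
    assert res.pvalues["link"] > 0.05
    assert res.pvalues["euclidean"] > 0.05
    assert "Competitive transition regression" in res.summary()


def test_directional_vs_symmetrised_path_regression(training_graph, reduced_graph):
    """Symmetric experience-weighted paths predict symmetric responses when
    the signal is non-directional (mirrors the directionality analysis)."""
    histories = rm.simulate_training_histories(
        training_graph, n_subjects=8, blocks=4, items_per_block=133, seed=3
    )
    labels = reduced_graph.node_labels
    link = rm.link_distance_matrix(reduced_graph)
    tables = []
    rng = np.random.default_rng(4)
    for k in range(8):
        tables.append(
            _table(f"s{k}", labels, lambda i, j: link.value(i, j) + rng.normal(0, 0.3))
        )
    sub = histories[0]
    idx = [training_graph.index(v) for v in labels]
    counts7 = rm.TransitionCountMatrix(sub.counts[np.ix_(idx, idx)], labels)
    w = rm.empirical_edge_lengths(counts7, reduced_graph)
    directional = rm.directed_shortest_paths(w, reduced_graph)
    symmetric = rm.directed_shortest_paths(w, reduced_graph, symmetrised=True)
    res = rm.competitive_regression(
        tables, {"directional": directional, "symmetric": symmetric}, node_labels=labels
    )
    assert set(res.params.columns) == {"intercept", "directional", "symmetric"}


# ---------------------------------------------------------------------------
# Distance contrasts and RM-ANOVA
# ---------------------------------------------------------------------------


def test_contrasts_equal_bins_give_zero_statistics(reduced_graph):
    labels = reduced_graph.node_labels
    tables = [_table(f"s{k}", labels, lambda i, j: float(k)) for k in range(5)]
    res = rm.distance_contrasts(tables, rm.link_distance_matrix(reduced_graph))
    assert res.t_connected == 0.0
    assert res.anova_f == 0.0


def test_contrasts_monotone_when_response_is_distance(reduced_graph):
    link = rm.link_distance_matrix(reduced_graph)
    tables = [_table(f"s{k}", labels := reduced_graph.node_labels,
                     lambda i, j: link.value(i, j)) for k in range(3)]
    res = rm.distance_contrasts(tables, link)
    means = res.bin_means
    assert ((means[2] > means[1]) & (means[3] > means[2])).all()
    assert "RM-ANOVA" in res.summary()


def test_contrast_errors_on_empty_bin(reduced_graph):
    # a table covering only adjacent pairs leaves the distance-2/3 bins empty
    link = rm.link_distance_matrix(reduced_graph)
    rows = [
        (i, j, 1.0)
        for e in reduced_graph.edges
        for i, j in (tuple(e), tuple(e)[::-1])
    ]
    table = TransitionResponseTable(
        subject="s1",
        data=pd.DataFrame(rows, columns=["predecessor", "object", "response"]),
    )
    with pytest.raises(ValueError, match="empty"):
        rm.distance_contrasts([table], link)


@pytest.mark.parametrize("seed", range(20))
def test_rm_anova_matches_pingouin_oracle(seed):
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(seed)
    n, k = 12, 3
    y = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
    f, df1, df2, p = rm_anova_oneway(y)
    df = pd.DataFrame(
        {
            "y": y.ravel(),
            "cond": np.tile(np.arange(k), n),
            "subj": np.repeat(np.arange(n), k),
        }
    )
    aov = pingouin.rm_anova(data=df, dv="y", within="cond", subject="subj")
    assert f == pytest.approx(float(aov["F"][0]), abs=1e-8)
    assert (df1, df2) == (int(aov["ddof1"][0]), int(aov["ddof2"][0]))
    assert p == pytest.approx(float(aov["p_unc"][0]), abs=1e-10)


@pytest.mark.parametrize("seed", range(10))
def test_paired_t_matches_closed_form(reduced_graph, seed):
    rng = np.random.default_rng(100 + seed)
    labels = reduced_graph.node_labels
    tables = [
        _table(f"s{k}", labels, lambda i, j: rng.normal()) for k in range(9)
    ]
    res = rm.distance_contrasts(tables, rm.link_distance_matrix(reduced_graph))
    # closed-form paired t oracle on the link-2 vs link-3 bin means
    d = res.bin_means[2].to_numpy() - res.bin_means[3].to_numpy()
    t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    assert res.t_link23 == pytest.approx(t_oracle, abs=1e-10)


def test_object_demeaning_preserves_distance_effect(noisy_cohort, reduced_graph):
    """Removing object-specific mean activity leaves the distance contrast
    intact when the signal is distance-driven (control analysis)."""
    link = rm.link_distance_matrix(reduced_graph)
    raw = rm.distance_contrasts(noisy_cohort, link)
    dem = rm.distance_contrasts(noisy_cohort, link, demean_objects=True)
    assert raw.anova_p < 0.01 and dem.anova_p < 0.01
    assert np.sign(raw.t_connected) == np.sign(dem.t_connected)
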