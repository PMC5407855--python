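"""Readers/writers for artifact formats, run configuration and orchestration.

Formats are plain text: graph JSON ({"nodes", "edges", "layout"}), proximity
matrices as labelled CSV, cohort responses as long CSV (subject,
predecessor, object, response), behavioural trials as TSV, ensemble
statistics as CSV.  A :class:`RunConfig` drives the deterministic
simulate -> analyze -> recover-map pipeline; every randomised stage consumes
a seed derived from the run seed plus the stage name, so stages can be
re-run in isolation reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import graphs
from .cohort import CohortConfig, TransitionResponseTable, simulate_adaptation_cohort
from .graphs import NullGraphEnsemble, ProximityMatrix, RelationalGraph
from .models import MapRecoveryModel, competitive_regression, group_transition_matrix

__all__ = [
    "read_graph_json",
    "write_graph_json",
    "read_proximity_csv",
    "write_proximity_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_trials_tsv",
    "write_trials_tsv",
    "write_ensemble_csv",
    "RunConfig",
    "load_validate_config",
    "stage_seed",
    "run_pipeline",
]

logger = logging.getLogger("relmap")


# ---------------------------------------------------------------------------
# Graph JSON
# ---------------------------------------------------------------------------


def write_graph_json(graph: RelationalGraph, path) -> None:
    payload = {
        "nodes": list(graph.node_labels),
        "edges": [list(e) for e in graph.edge_list()],
    }
    if graph.layout is not None:
        payload["layout"] = {str(k): list(v) for k, v in graph.layout.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_graph_json(path) -> RelationalGraph:
    payload = json.loads(Path(path).read_text())
    nodes = payload["nodes"]
    layout = payload.get("layout")
    if layout is not None:
        by_str = {str(n): n for n in nodes}
        layout = {by_str[k]: tuple(v) for k, v in layout.items()}
    return RelationalGraph(nodes, [tuple(e) for e in payload["edges"]], layout=layout)


# ---------------------------------------------------------------------------
# Matrices and tables
# ---------------------------------------------------------------------------


def write_proximity_csv(matrix: ProximityMatrix, path) -> None:
    df = pd.DataFrame(
        matrix.values, index=matrix.node_labels, columns=matrix.node_labels
    )
    df.to_csv(path, index_label="node")


def read_proximity_csv(path, metric_kind: str = "unknown") -> ProximityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ProximityMatrix(df.to_numpy(), metric_kind, tuple(df.columns))


def write_cohort_csv(tables: list[TransitionResponseTable], path) -> None:
    frames = []
    for t in tables:
        df = t.data.copy()
        df.insert(0, "subject", t.subject)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_cohort_csv(path) -> list[TransitionResponseTable]:
    df = pd.read_csv(path)
    tables = []
    for subject, sub in df.groupby("subject", sort=True):
        tables.append(
            TransitionResponseTable(
                subject=str(subject),
                data=sub[["predecessor", "object", "response"]].reset_index(drop=True),
            )
        )
    return tables


def write_trials_tsv(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, sep="\t", index=False)


def read_trials_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ensemble_csv(
    ensemble: NullGraphEnsemble,
    path,
    correlations: np.ndarray | None = None,
    crossings: np.ndarray | None = None,
) -> None:
    rows = []
    for k, member in enumerate(ensemble.members):
        edges = ";".join(
            "-".join(str(v) for v in sorted(e, key=str)) for e in sorted(member, key=str)
        )
        row = {"edge_set": edges}
        if correlations is not None:
            row["correlation"] = float(correlations[k])
        if crossings is not None:
            row["crossings"] = int(crossings[k])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_ANALYSIS_DEFAULTS = {
    "regressors": ["communicability", "link", "euclidean"],
    "mds_metric": False,
    "mds_n_init": 20,
    "n_bins": 6,
    "gamma_fraction": 0.85,
    "zscore": False,
    "null_edges": None,
}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full pipeline run."""

    seed: int
    graph_path: str | None = None
    output_dir: str = "relmap_out"
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    analysis: dict = dataclasses.field(default_factory=lambda: dict(_ANALYSIS_DEFAULTS))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "graph_path": self.graph_path,
            "output_dir": self.output_dir,
            "cohort": self.cohort.to_dict(),
            "analysis": dict(self.analysis),
        }

    def canonical_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def config_hash(self) -> str:
        # hash the scientific configuration, not where the outputs land
        payload = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        canon = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def load_graph(self) -> RelationalGraph:
        if self.graph_path is None:
            return graphs.default_reduced_graph()
        return read_graph_json(self.graph_path)


def load_validate_config(path) -> RunConfig:
    """Load a JSON/YAML run config, validate it, and apply defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known = {"seed", "graph_path", "output_dir", "cohort", "analysis"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ValueError("config must specify a seed")
    seed = int(raw["seed"])
    graph_path = raw.get("graph_path")
    if graph_path is not None and not Path(graph_path).exists():
        raise ValueError(f"graph_path does not exist: {graph_path}")
    cohort_raw = raw.get("cohort", {})
    unknown = set(cohort_raw) - {f.name for f in dataclasses.fields(CohortConfig)}
    if unknown:
        raise ValueError(f"unknown cohort keys: {sorted(unknown)}")
    cohort = CohortConfig(**{**cohort_raw, "seed": cohort_raw.get("seed", seed)})
    analysis = dict(_ANALYSIS_DEFAULTS)
    analysis_raw = raw.get("analysis", {})
    unknown = set(analysis_raw) - set(_ANALYSIS_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown analysis keys: {sorted(unknown)}")
    analysis.update(analysis_raw)
    gf = analysis["gamma_fraction"]
    if not (0 <= gf < 1):
        raise ValueError(f"gamma_fraction must lie in [0, 1), got {gf}")
    if analysis["n_bins"] < 1:
        raise ValueError("n_bins must be >= 1")
    return RunConfig(
        seed=seed,
        graph_path=graph_path,
        output_dir=raw.get("output_dir", "relmap_out"),
        cohort=cohort,
        analysis=analysis,
    )


def stage_seed(run_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed and stage name."""
    digest = hashlib.sha256(f"{run_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _stamp(config: RunConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed}


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> analyze -> recover-map and write a result bundle.

    Every output JSON embeds the config hash and seed; the run is
    byte-for-byte reproducible for a fixed config.  Returns a manifest of
    written paths.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph = config.load_graph()
    manifest = {}

    def _run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
        return result

    # simulate
    cohort_cfg = dataclasses.replace(
        config.cohort, seed=stage_seed(config.seed, "simulate")
    )

    def _simulate():
        tables = simulate_adaptation_cohort(cohort_cfg, graph)
        path = out / "cohort.csv"
        write_cohort_csv(tables, path)
        logger.info("simulated %d subjects x %d transitions", len(tables), len(tables[0].data))
        return tables, path

    tables, cohort_path = _run_stage("simulate", _simulate)
    manifest["cohort"] = str(cohort_path)

    # analyze
    def _analyze():
        regs = {
            name: graphs.proximity_matrix(graph, name, config.analysis["gamma_fraction"])
            for name in config.analysis["regressors"]
        }
        res = competitive_regression(
            tables, regs, zscore=config.analysis["zscore"]
        )
        report = {
            **_stamp(config),
            "n_subjects": len(tables),
            "regressors": {
                name: {
                    "group_mean": float(res.group_mean[name]),
                    "t": float(res.tvalues[name]),
                    "p": float(res.pvalues[name]),
                }
                for name in res.params.columns
            },
        }
        path = out / "regression_report.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        return path

    manifest["regression_report"] = str(_run_stage("analyze", _analyze))

    # recover-map
    def _recover():
        gm = group_transition_matrix(tables, graph.node_labels)
        n_edges = config.analysis["null_edges"] or graph.n_edges
        ensemble = graphs.enumerate_null_graphs(
            graph.n_nodes, n_edges, graph.node_labels
        )
        model = MapRecoveryModel(
            gm, graph, ensemble=ensemble, metric_mds=config.analysis["mds_metric"]
        )
        res = model.fit(
            seed=stage_seed(config.seed, "recover-map"),
            n_init=config.analysis["mds_n_init"],
        )
        payload = {
            **_stamp(config),
            "embedding": {str(k): list(v) for k, v in res.embedding.items()},
            "correlation_with_link": res.correlation_with_link,
            "permutation_p": res.permutation_p,
            "observed_crossings": res.observed_crossings,
            "null_crossing_fraction": res.null_crossing_fraction,
            "ensemble_size": res.ensemble_size,
        }
        path = out / "map_recovery.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path

    manifest["map_recovery"] = str(_run_stage("recover-map", _recover))

    (out / "config_echo.json").write_text(config.canonical_json() + "\n")
    manifest["config_echo"] = str(out / "config_echo.json")
    return manifest
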