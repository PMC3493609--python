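"""End-to-end orchestration: simulate -> qc -> stats -> indices -> model ->
networks, emitting a reproducible report bundle.

A single :class:`PipelineConfig` (YAML-serializable) drives every stage.
All artifacts land in one output directory together with a run manifest
recording the seed, the thresholds actually applied, and a hash of the
canonical configuration; rerunning with the same configuration reproduces
every deterministic artifact bitwise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import CohortTable, ValidationError, read_cohort, write_annotations, write_cohort
from .indices import indices_to_frame, summarize_indices
from .ivs import IVSConfig, build_final_model, ivs_ensemble
from .multivariate import external_validation
from .networks import build_pathway_graph, build_pcn, heatmap_matrix, spearman_pair
from .synth import default_paper_spec, generate_cohort
from .univariate import results_to_frame, summarize_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    When ``cohort_path`` is unset a synthetic cohort is generated from the
    packaged study recipe with ``seed``.
    """

    output_dir: str = "lipid-run"
    seed: int = 0
    cohort_path: str | None = None
    annotation_path: str | None = None
    q: float = 0.1
    n_orthogonal: int = 1
    n_folds: int = 7
    ivs_runs: int = 20
    ivs_subsets: int | None = None
    pcn_p_thresholds: tuple[float | None, float | None] = (None, None)
    mds_method: str = "stress-majorization"

    def canonical_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "pcn_p_thresholds" in raw and raw["pcn_p_thresholds"] is not None:
        raw["pcn_p_thresholds"] = tuple(raw["pcn_p_thresholds"])
    return PipelineConfig(**raw)


def _load_table(config: PipelineConfig) -> CohortTable:
    if config.cohort_path is None:
        spec = default_paper_spec(seed=config.seed)
        return generate_cohort(spec)
    if config.annotation_path is None:
        raise PipelineError("load", "cohort_path given without annotation_path")
    for p in (config.cohort_path, config.annotation_path):
        if not Path(p).exists():
            raise PipelineError("load", f"input path does not exist: {p}")
    return read_cohort(config.cohort_path, config.annotation_path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a manifest dict (also written to disk).

    On a stage failure, artifacts produced so far are kept and an empty
    ``failed/<stage>`` marker is written before the error propagates.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "lipidcohort",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.canonical_hash(),
        "config": asdict(config),
        "artifacts": [],
        "thresholds": {},
    }

    def emit(name: str) -> Path:
        manifest["artifacts"].append(name)
        return out / name

    stage = "load"
    try:
        table = _load_table(config)
        write_cohort(table, emit("cohort.csv"))
        write_annotations(table.panel, emit("annotations.csv"))

        stage = "univariate"
        univ = summarize_cohort(table, q=config.q)
        results_to_frame(univ).to_csv(emit("univariate.csv"), index=False)
        manifest["thresholds"]["fdr_q"] = config.q

        stage = "indices"
        idx = summarize_indices(table, q=config.q)
        indices_to_frame(idx).to_csv(emit("indices.csv"), index=False)

        stage = "model"
        features = table.modeling_metabolites()
        X = table.concentrations[features].to_numpy()
        y = table.labels01()
        ivs_cfg = IVSConfig(
            n_runs=config.ivs_runs,
            n_subsets=config.ivs_subsets,
            seed=config.seed,
            n_folds=config.n_folds,
        )
        best, runs = ivs_ensemble(X, y, features, ivs_cfg)
        with open(emit("ivs_runs.jsonl"), "w") as fh:
            for r in runs:
                fh.write(
                    json.dumps(
                        {
                            "run_seed": r.run_seed,
                            "selected": r.selected_variables,
                            "trajectory": r.objective_trajectory,
                            "final_q2": r.final_q2,
                        }
                    )
                    + "\n"
                )
        model, pre = build_final_model(
            X, y, features, best.selected_variables, n_orthogonal=config.n_orthogonal
        )
        report = external_validation(
            table.concentrations[best.selected_variables].to_numpy(),
            y,
            n_orthogonal=config.n_orthogonal,
            n_folds=config.n_folds,
            seed=config.seed,
        )
        model_doc = model.to_dict()
        model_doc["selected_variables"] = best.selected_variables
        model_doc["ivs_best_q2"] = best.final_q2
        model_doc["external_validation"] = {
            "test_q2": report.test_q2,
            "test_auroc": report.test_auroc,
            "mean_test_q2": report.mean_test_q2,
            "sd_test_q2": report.sd_test_q2,
            "mean_test_auroc": report.mean_test_auroc,
            "sd_test_auroc": report.sd_test_auroc,
        }
        with open(emit("model.json"), "w") as fh:
            json.dump(model_doc, fh, indent=1)
        pd.DataFrame(
            {"subject": table.subjects, "group": table.group.to_numpy(),
             "score": model.scores[:, 0]}
        ).to_csv(emit("scores.csv"), index=False)
        pd.DataFrame(
            {"variable": best.selected_variables, "loading": model.loadings[:, 0],
             "weight": model.weights[:, 0]}
        ).to_csv(emit("loadings.csv"), index=False)
        manifest["thresholds"]["n_folds"] = config.n_folds
        manifest["thresholds"]["ivs_runs"] = config.ivs_runs

        stage = "networks"
        pair = spearman_pair(table)
        heatmap_matrix(pair).to_csv(emit("heatmap.csv"))
        import networkx as nx

        for g, thr in zip(table.group_order, config.pcn_p_thresholds):
            net = build_pcn(
                table, g, p_threshold=thr, method=config.mds_method,
                seed=config.seed,
            )
            tag = "group0" if g == table.group_order[0] else "group1"
            net.nodes_frame().to_csv(emit(f"pcn_{tag}_nodes.csv"), index=False)
            net.edges_frame().to_csv(emit(f"pcn_{tag}_edges.csv"), index=False)
            nx.write_graphml(net.to_networkx(), emit(f"pcn_{tag}.graphml"))
            manifest["thresholds"][f"pcn_p_{tag}"] = net.p_threshold

        pathway = build_pathway_graph(univ, idx, table)
        nx.write_graphml(pathway.graph, emit("pathway.graphml"))
        with open(emit("pathway.json"), "w") as fh:
            json.dump(pathway.to_json(), fh, indent=1)

    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / stage).touch()
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
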