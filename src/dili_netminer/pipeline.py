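"""End-to-end orchestration: mine → select → refine → assemble → merge.

Each stage persists its artifacts under the run directory and is
independently re-runnable (``run_stage``); artifact checksums recorded in
the run report make cached upstream outputs auditable across resumed runs.
Outputs contain no timestamps and are deterministically ordered, so a rerun
with identical inputs and configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import yaml

from . import io as dio
from .association import build_association_db, mine_frequent_itemsets, query_disease_genes, score_gene_disease_rules
from .network import build_disease_network, merge_networks
from .references import select_reference_chemicals, summarize_overlap
from .refinement import RefinementConfig, export_curation_views, refine_disease_genes
from .simulate import SimulationConfig, SyntheticBundle, gen_all

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "PipelineError",
    "STAGES",
    "run_pipeline",
    "run_stage",
    "materialize_bundle",
]

STAGES = ("mine", "select", "refine", "assemble", "merge")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    records_tsv: str
    gmt: str
    hierarchy_tsv: str
    labels_tsv: str
    expression_dir: str
    network_path: str
    out_dir: str
    diseases: list[str]
    annotation_json: str | None = None
    min_support: float = 0.1
    max_itemset_len: int = 3
    top_k: int = 250
    min_set_size: int = 4
    refinement: RefinementConfig = field(default_factory=RefinementConfig)
    max_connectors: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.diseases:
            raise ValueError("diseases must be non-empty")
        if isinstance(self.refinement, dict):
            self.refinement = RefinementConfig(**self.refinement)

    def validate_paths(self) -> None:
        paths = [self.records_tsv, self.gmt, self.hierarchy_tsv, self.labels_tsv,
                 self.expression_dir, self.network_path]
        if self.annotation_json:
            paths.append(self.annotation_json)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input paths: {missing}")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_yaml(self, path: Path | str) -> None:
        raw = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _artifact_map(paths: list[Path], root: Path) -> dict[str, str]:
    return {str(p.relative_to(root)): _sha256(p) for p in sorted(paths)}


# ---------------------------------------------------------------------------
# stages


def _stage_mine(cfg: RunConfig, out: Path) -> dict:
    stage_dir = out / "mine"
    stage_dir.mkdir(parents=True, exist_ok=True)
    records = dio.read_interaction_records(cfg.records_tsv)
    hierarchy = dio.read_pathway_hierarchy(cfg.gmt, cfg.hierarchy_tsv)
    db = build_association_db(records, hierarchy)
    logger.info(
        "mining %d transactions at min_support=%.3g max_len=%d",
        db.n_transactions, cfg.min_support, cfg.max_itemset_len,
    )
    itemsets = mine_frequent_itemsets(db, cfg.min_support, cfg.max_itemset_len)
    candidates: dict[str, list[str]] = {}
    artifacts: list[Path] = []
    for disease in cfg.diseases:
        scores = score_gene_disease_rules(db, itemsets, disease)
        genes = query_disease_genes(scores, cfg.top_k)
        candidates[disease] = genes
        score_path = stage_dir / f"scores_{disease}.tsv"
        dio.write_scores(scores, score_path)
        artifacts.append(score_path)
    cand_path = stage_dir / "candidates.json"
    dio.dump_json(candidates, cand_path)
    artifacts.append(cand_path)
    counts = {
        "n_records": len(records),
        "n_transactions": db.n_transactions,
        "n_frequent_itemsets": len(itemsets),
        "candidates_per_disease": {d: len(g) for d, g in candidates.items()},
    }
    return {"counts": counts, "artifacts": artifacts}


def _stage_select(cfg: RunConfig, out: Path) -> dict:
    stage_dir = out / "select"
    stage_dir.mkdir(parents=True, exist_ok=True)
    labels = dio.read_labels(cfg.labels_tsv)
    sets = {}
    for disease in cfg.diseases:
        sets[disease] = select_reference_chemicals(labels, disease, cfg.min_set_size)
        logger.info(
            "disease %s: %d positive / %d negative reference chemicals",
            disease, len(sets[disease].positives), len(sets[disease].negatives),
        )
    ref_path = stage_dir / "reference_sets.json"
    dio.write_reference_sets(sets, ref_path)
    artifacts = [ref_path]
    if len(sets) >= 2:
        overlap = summarize_overlap(list(sets.values()))
        overlap_path = stage_dir / "overlap.tsv"
        overlap.to_csv(overlap_path, sep="\t", index=False)
        artifacts.append(overlap_path)
    counts = {
        d: {"positives": len(s.positives), "negatives": len(s.negatives)}
        for d, s in sets.items()
    }
    return {"counts": counts, "artifacts": artifacts}


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing upstream artifact: {path}")
    return path


def _stage_refine(cfg: RunConfig, out: Path) -> dict:
    stage_dir = out / "refine"
    stage_dir.mkdir(parents=True, exist_ok=True)
    candidates = json.loads(_require(out / "mine" / "candidates.json").read_text())
    ref_sets = dio.read_reference_sets(_require(out / "select" / "reference_sets.json"))
    rcfg = cfg.refinement
    logger.info(
        "refinement thresholds: |log2FC| > %.3g, p < %.3g, recurrence >= %d, "
        "consistency >= %.3g, negative cap %.3g",
        rcfg.fc_threshold, rcfg.p_threshold, rcfg.min_recurrent_chemicals,
        rcfg.pos_fraction_min, rcfg.neg_fc_cap,
    )
    artifacts: list[Path] = []
    counts: dict[str, dict] = {}
    for disease in cfg.diseases:
        refset = ref_sets[disease]
        pos_studies = [
            dio.read_expression_study(cfg.expression_dir, c) for c in sorted(refset.positives)
        ]
        neg_studies = [
            dio.read_expression_study(cfg.expression_dir, c) for c in sorted(refset.negatives)
        ]
        selection = refine_disease_genes(
            pos_studies, neg_studies, candidates[disease], rcfg, disease_id=disease
        )
        sel_path = stage_dir / f"selection_{disease}.json"
        dio.write_gene_selection(selection, sel_path)
        artifacts.append(sel_path)
        heatmap, timeseries = export_curation_views(selection, pos_studies, neg_studies, rcfg)
        hm_path = stage_dir / f"curation_heatmap_{disease}.tsv"
        ts_path = stage_dir / f"curation_timeseries_{disease}.tsv"
        heatmap.to_csv(hm_path, sep="\t", index=False, float_format="%.6f")
        timeseries.to_csv(ts_path, sep="\t", index=False, float_format="%.6f")
        artifacts.extend([hm_path, ts_path])
        counts[disease] = {
            "candidates": len(candidates[disease]),
            "cells_with_hits": len(selection.per_cell_genes),
            "refined_genes": len(selection.refined_genes),
        }
    return {"counts": counts, "artifacts": artifacts}


def _stage_assemble(cfg: RunConfig, out: Path) -> dict:
    stage_dir = out / "assemble"
    stage_dir.mkdir(parents=True, exist_ok=True)
    net = dio.read_interaction_network(cfg.network_path)
    annotation = (
        json.loads(Path(cfg.annotation_json).read_text()) if cfg.annotation_json else {}
    )
    artifacts: list[Path] = []
    counts: dict[str, dict] = {}
    for disease in cfg.diseases:
        selection = dio.read_gene_selection(
            _require(out / "refine" / f"selection_{disease}.json")
        )
        network = build_disease_network(selection, net, annotation, cfg.max_connectors)
        if network.partial:
            logger.warning("disease %s: seeds could not be fully interlinked", disease)
        gml = stage_dir / f"network_{disease}.graphml"
        sif = stage_dir / f"network_{disease}.sif"
        dio.write_disease_network_graphml(network, gml)
        dio.write_disease_network_sif(network, sif)
        artifacts.extend([gml, sif])
        counts[disease] = {
            "seeds": len(network.seed_genes),
            "connectors": len(network.connector_genes),
            "edges": len(network.edges),
            "partial": network.partial,
        }
    return {"counts": counts, "artifacts": artifacts}


def _stage_merge(cfg: RunConfig, out: Path) -> dict:
    stage_dir = out / "merge"
    stage_dir.mkdir(parents=True, exist_ok=True)
    net = dio.read_interaction_network(cfg.network_path)
    annotation = (
        json.loads(Path(cfg.annotation_json).read_text()) if cfg.annotation_json else {}
    )
    networks = []
    for disease in cfg.diseases:
        selection = dio.read_gene_selection(
            _require(out / "refine" / f"selection_{disease}.json")
        )
        networks.append(build_disease_network(selection, net, annotation, cfg.max_connectors))
    merged = merge_networks(networks)
    gml = stage_dir / "merged.graphml"
    dio.write_merged_network_graphml(merged, gml)
    report_path = stage_dir / "process_report.json"
    dio.dump_json(
        {
            "shared_processes": {
                p: sorted(ds) for p, ds in merged.shared_processes.items()
            },
            "shared_by_all": sorted(merged.processes_shared_by_all()),
        },
        report_path,
    )
    counts = {
        "n_nodes": len(merged.nodes),
        "n_edges": len(merged.edges),
        "n_processes_shared_by_all": len(merged.processes_shared_by_all()),
    }
    return {"counts": counts, "artifacts": [gml, report_path]}


_STAGE_FUNCS: dict[str, Callable[[RunConfig, Path], dict]] = {
    "mine": _stage_mine,
    "select": _stage_select,
    "refine": _stage_refine,
    "assemble": _stage_assemble,
    "merge": _stage_merge,
}


def run_stage(name: str, cfg: RunConfig) -> dict:
    """Run a single stage against existing upstream artifacts."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; expected one of {STAGES}")
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        result = _STAGE_FUNCS[name](cfg, out)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {name}\ncause: {exc}\n")
        raise PipelineError(name, exc) from exc
    return result


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write the run report.

    The merge stage runs only with two or more diseases.  Returns the
    report dict (also persisted as ``report.json`` in the run directory).
    """
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    stages = list(STAGES)
    if len(cfg.diseases) < 2:
        stages.remove("merge")
    report: dict = {
        "version": _package_version(),
        "config": _config_echo(cfg),
        "stages": [],
        "warnings": [],
    }
    if len(cfg.diseases) < 2:
        report["warnings"].append("single disease: merge stage skipped")
    for name in stages:
        result = run_stage(name, cfg)
        report["stages"].append(
            {
                "name": name,
                "status": "completed",
                "counts": result["counts"],
                "artifacts": _artifact_map(result["artifacts"], out),
            }
        )
    dio.dump_json(report, out / "report.json")
    return report


def _package_version() -> str:
    from . import __version__

    return __version__


def _config_echo(cfg: RunConfig) -> dict:
    raw = dataclasses.asdict(cfg)
    return raw


# ---------------------------------------------------------------------------
# synthetic run directories


def materialize_bundle(bundle: SyntheticBundle, directory: Path | str) -> RunConfig:
    """Write a synthetic bundle as the on-disk formats the pipeline consumes
    and return a ready RunConfig pointing at them."""
    directory = Path(directory)
    inputs = directory / "inputs"
    expr = inputs / "expression"
    inputs.mkdir(parents=True, exist_ok=True)
    expr.mkdir(parents=True, exist_ok=True)
    dio.write_interaction_records(bundle.records, inputs / "records.tsv")
    dio.write_pathway_hierarchy(
        bundle.hierarchy, inputs / "pathways.gmt", inputs / "hierarchy.tsv"
    )
    dio.write_labels(bundle.labels, inputs / "labels.tsv")
    for study in bundle.studies:
        dio.write_expression_study(study, expr)
    dio.write_interaction_network(bundle.network, inputs / "network.tsv")
    dio.dump_json(bundle.annotation, inputs / "annotation.json")
    cfg = RunConfig(
        records_tsv=str(inputs / "records.tsv"),
        gmt=str(inputs / "pathways.gmt"),
        hierarchy_tsv=str(inputs / "hierarchy.tsv"),
        labels_tsv=str(inputs / "labels.tsv"),
        expression_dir=str(expr),
        network_path=str(inputs / "network.tsv"),
        annotation_json=str(inputs / "annotation.json"),
        out_dir=str(directory / "run"),
        diseases=[bundle.config.disease_id],
        min_support=0.1,
        max_itemset_len=2,
        seed=bundle.config.seed,
    )
    cfg.to_yaml(directory / "run_config.yaml")
    return cfg
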