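"""File formats consumed and produced by the pipeline.

All formats are plain text: interaction records and label tables as TSV,
pathway membership as GMT with a two-column child/parent hierarchy TSV,
expression studies as one genes × replicate-columns TSV per chemical with a
sidecar JSON design descriptor, interaction networks as 3/4-column TSV or
SIF, and assembled networks as GraphML/SIF.  Writers emit deterministically
ordered output so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .association import AssociationScore, InteractionRecord, PathwayHierarchy
from .network import DiseaseNetwork, InteractionNetwork, MergedNetwork
from .references import ChemicalLabel, ReferenceSet
from .refinement import ExperimentDesign, ExpressionStudy, GeneSelection

__all__ = [
    "read_interaction_records",
    "write_interaction_records",
    "read_pathway_hierarchy",
    "write_pathway_hierarchy",
    "read_labels",
    "write_labels",
    "write_scores",
    "read_expression_study",
    "write_expression_study",
    "read_interaction_network",
    "write_interaction_network",
    "write_gene_selection",
    "read_gene_selection",
    "write_reference_sets",
    "read_reference_sets",
    "write_disease_network_graphml",
    "write_disease_network_sif",
    "write_merged_network_graphml",
    "dump_json",
]

RECORD_COLUMNS = ["chemical_id", "target_id", "target_kind", "direction", "source"]
LABEL_COLUMNS = ["chemical_id", "disease_id", "evidence", "in_expression_db", "in_livertox"]


def dump_json(obj, path: Path | str) -> None:
    """Write JSON with sorted keys and a trailing newline (deterministic)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# interaction records and pathway hierarchy


def read_interaction_records(path: Path | str) -> list[InteractionRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"record table {path} lacks columns: {missing}")
    return [
        InteractionRecord(
            chemical_id=row.chemical_id,
            target_id=row.target_id,
            target_kind=row.target_kind,
            direction=row.direction,
            source=row.source,
        )
        for row in frame.itertuples(index=False)
    ]


def write_interaction_records(records: Sequence[InteractionRecord], path: Path | str) -> None:
    frame = pd.DataFrame(
        [
            {
                "chemical_id": r.chemical_id,
                "target_id": r.target_id,
                "target_kind": r.target_kind.value,
                "direction": r.direction.value,
                "source": r.source.value,
            }
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_pathway_hierarchy(gmt_path: Path | str, hierarchy_tsv: Path | str | None = None) -> PathwayHierarchy:
    """GMT rows: pathway_id <tab> name <tab> gene...; hierarchy TSV rows:
    child <tab> parent."""
    names: dict[str, str] = {}
    members: dict[str, frozenset[str]] = {}
    for line in Path(gmt_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed GMT line: {line!r}")
        pid, name, *genes = parts
        names[pid] = name
        members[pid] = frozenset(g for g in genes if g)
    parent: dict[str, str | None] = {}
    if hierarchy_tsv is not None:
        for line in Path(hierarchy_tsv).read_text().splitlines():
            if not line.strip():
                continue
            child, par = line.rstrip("\n").split("\t")[:2]
            parent[child] = par or None
    return PathwayHierarchy(names=names, parent=parent, members=members)


def write_pathway_hierarchy(
    hierarchy: PathwayHierarchy, gmt_path: Path | str, hierarchy_tsv: Path | str
) -> None:
    lines = []
    for pid in sorted(hierarchy.names):
        genes = sorted(hierarchy.members.get(pid, frozenset()))
        lines.append("\t".join([pid, hierarchy.names[pid], *genes]))
    Path(gmt_path).write_text("\n".join(lines) + "\n")
    rows = [
        f"{child}\t{par}"
        for child, par in sorted(hierarchy.parent.items())
        if par is not None
    ]
    Path(hierarchy_tsv).write_text("\n".join(rows) + ("\n" if rows else ""))


# ---------------------------------------------------------------------------
# labels and reference sets


def read_labels(path: Path | str) -> list[ChemicalLabel]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in LABEL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"label table {path} lacks columns: {missing}")
    truthy = {"true", "1", "yes"}
    return [
        ChemicalLabel(
            chemical_id=row.chemical_id,
            disease_id=row.disease_id,
            evidence=row.evidence,
            in_expression_db=str(row.in_expression_db).lower() in truthy,
            in_livertox=str(row.in_livertox).lower() in truthy,
        )
        for row in frame.itertuples(index=False)
    ]


def write_labels(labels: Sequence[ChemicalLabel], path: Path | str) -> None:
    frame = pd.DataFrame(
        [
            {
                "chemical_id": l.chemical_id,
                "disease_id": l.disease_id,
                "evidence": l.evidence.value,
                "in_expression_db": str(l.in_expression_db).lower(),
                "in_livertox": str(l.in_livertox).lower(),
            }
            for l in labels
        ],
        columns=LABEL_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def write_reference_sets(sets: Mapping[str, ReferenceSet], path: Path | str) -> None:
    dump_json(
        {
            d: {"positives": sorted(s.positives), "negatives": sorted(s.negatives)}
            for d, s in sets.items()
        },
        path,
    )


def read_reference_sets(path: Path | str) -> dict[str, ReferenceSet]:
    raw = json.loads(Path(path).read_text())
    return {
        d: ReferenceSet(d, frozenset(v["positives"]), frozenset(v["negatives"]))
        for d, v in raw.items()
    }


# ---------------------------------------------------------------------------
# association scores


def write_scores(scores: Sequence[AssociationScore], path: Path | str) -> None:
    frame = pd.DataFrame(
        [
            {
                "disease": s.disease_id,
                "gene": s.gene,
                "support": s.support,
                "confidence": s.confidence,
                "n_chemicals": s.n_cooccurring_chemicals,
            }
            for s in scores
        ],
        columns=["disease", "gene", "support", "confidence", "n_chemicals"],
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# expression studies


def write_expression_study(study: ExpressionStudy, directory: Path | str) -> tuple[Path, Path]:
    """One TSV (genes × replicate columns) plus a sidecar design JSON.

    Column names encode the cell: ``<time>|<dose>|<group>|r<i>``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    design = study.design
    columns: dict[str, np.ndarray] = {}
    for ci, (t, d) in enumerate(design.cells):
        for group, arr in (("treated", study.treated), ("control", study.control)):
            for r in range(design.replicates_per_cell):
                columns[f"{t}|{d}|{group}|r{r + 1}"] = arr[ci, :, r]
    frame = pd.DataFrame(columns, index=list(study.genes))
    frame.index.name = "gene"
    tsv = directory / f"{study.chemical_id}.expr.tsv"
    frame.to_csv(tsv, sep="\t", float_format="%.6f")
    meta = directory / f"{study.chemical_id}.design.json"
    dump_json(
        {
            "chemical_id": study.chemical_id,
            "time_points": list(design.time_points),
            "dose_levels": list(design.dose_levels),
            "replicates_per_cell": design.replicates_per_cell,
        },
        meta,
    )
    return tsv, meta


def read_expression_study(directory: Path | str, chemical_id: str) -> ExpressionStudy:
    directory = Path(directory)
    meta = json.loads((directory / f"{chemical_id}.design.json").read_text())
    design = ExperimentDesign(
        time_points=tuple(meta["time_points"]),
        dose_levels=tuple(meta["dose_levels"]),
        replicates_per_cell=int(meta["replicates_per_cell"]),
    )
    frame = pd.read_csv(directory / f"{chemical_id}.expr.tsv", sep="\t", index_col="gene")
    genes = tuple(frame.index)
    n_cells = len(design.cells)
    reps = design.replicates_per_cell
    treated = np.empty((n_cells, len(genes), reps))
    control = np.empty((n_cells, len(genes), reps))
    for ci, (t, d) in enumerate(design.cells):
        for group, arr in (("treated", treated), ("control", control)):
            for r in range(reps):
                arr[ci, :, r] = frame[f"{t}|{d}|{group}|r{r + 1}"].to_numpy()
    return ExpressionStudy(chemical_id, design, genes, treated, control)


# ---------------------------------------------------------------------------
# interaction networks


def read_interaction_network(path: Path | str) -> InteractionNetwork:
    """3/4-column TSV (gene_a, gene_b, weight[, kind]) or SIF
    (gene_a <tab> kind <tab> gene_b, weight 1.0)."""
    net = InteractionNetwork()
    path = Path(path)
    is_sif = path.suffix.lower() == ".sif"
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("gene_a\t"):
            continue
        parts = line.rstrip("\n").split("\t")
        if is_sif:
            a, kind, b = parts[0], parts[1], parts[2]
            weight = 1.0
        else:
            a, b = parts[0], parts[1]
            weight = float(parts[2]) if len(parts) > 2 else 1.0
            kind = parts[3] if len(parts) > 3 else "other"
        net.add_edge(a, b, weight=weight, kind=kind)
    return net


def write_interaction_network(net: InteractionNetwork, path: Path | str) -> None:
    lines = ["gene_a\tgene_b\tweight\tkind"]
    for a, b, data in sorted(net.graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
        a, b = sorted((a, b))
        for kind in sorted(data["kinds"]):
            lines.append(f"{a}\t{b}\t{data['kinds'][kind]:.6g}\t{kind}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# selections and assembled networks


def write_gene_selection(selection: GeneSelection, path: Path | str) -> None:
    dump_json(
        {
            "disease_id": selection.disease_id,
            "per_cell_genes": {
                f"{t}|{d}": sorted(genes)
                for (t, d), genes in sorted(selection.per_cell_genes.items())
            },
            "refined_genes": [
                {"gene": g, "direction": direction, "consistency_score": round(s, 6)}
                for g, direction, s in selection.refined_genes
            ],
        },
        path,
    )


def read_gene_selection(path: Path | str) -> GeneSelection:
    raw = json.loads(Path(path).read_text())
    per_cell = {
        tuple(key.split("|")): set(genes) for key, genes in raw["per_cell_genes"].items()
    }
    refined = [
        (r["gene"], r["direction"], float(r["consistency_score"]))
        for r in raw["refined_genes"]
    ]
    return GeneSelection(raw["disease_id"], per_cell, refined)


def _disease_graph(net: DiseaseNetwork) -> nx.Graph:
    g = nx.Graph()
    for node in sorted(net.nodes):
        role = "seed" if node in net.seed_genes else "connector"
        g.add_node(
            node,
            role=role,
            direction=net.seed_genes.get(node, ""),
            processes=";".join(sorted(net.process_annotations.get(node, frozenset()))),
        )
    for (a, b) in sorted(net.edges):
        g.add_edge(a, b, weight=net.edges[(a, b)])
    return g


def write_disease_network_graphml(net: DiseaseNetwork, path: Path | str) -> None:
    nx.write_graphml(_disease_graph(net), str(path))


def write_disease_network_sif(net: DiseaseNetwork, path: Path | str) -> None:
    lines = [f"{a}\tinteracts\t{b}" for (a, b) in sorted(net.edges)]
    isolated = sorted(net.nodes - {n for e in net.edges for n in e})
    lines.extend(isolated)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_merged_network_graphml(merged: MergedNetwork, path: Path | str) -> None:
    g = nx.Graph()
    for node in sorted(merged.nodes):
        g.add_node(node, diseases=";".join(sorted(merged.node_diseases[node])))
    for (a, b) in sorted(merged.edges):
        g.add_edge(a, b, weight=merged.edges[(a, b)])
    nx.write_graphml(g, str(path))
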