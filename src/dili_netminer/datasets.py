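"""Packaged reference fixtures for the four drug-induced liver diseases.

* ``candidate_table(disease)`` — the per-time-point candidate gene tables
  for cholestasis, steatosis, hepatitis and cirrhosis, transcribed from the
  published per-disease results (7–8 time-point columns, 3 h to 29 days).
* ``refined_genes(disease)`` — the final consistency-curated gene lists
  with direction labels (5, 4, 9 and 8 genes respectively).
* ``process_annotations()`` — the curated gene → biological-process map
  (NRF2 activation, oxidative stress, cytoprotection, ...) used to label
  assembled networks; curated, not computed by enrichment.
* ``disease_network(disease)`` — an assembled network per disease whose
  seeds and annotations are the curated lists above and whose connector
  scaffold is a synthetic stand-in (the published figures' connector genes
  are not available as data); useful for merge/shared-process analyses.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .network import DiseaseNetwork, InteractionNetwork, MergedNetwork, build_disease_network, merge_networks
from .refinement import GeneSelection, parse_candidate_table

__all__ = [
    "DISEASES",
    "candidate_table",
    "candidate_genes",
    "refined_genes",
    "refined_gene_selection",
    "process_annotations",
    "disease_network",
    "all_disease_networks",
    "merged_disease_network",
]

DISEASES = ("cholestasis", "steatosis", "hepatitis", "cirrhosis")

_DATA = resources.files(__package__) / "fixtures" / "data"


def _check_disease(disease: str) -> None:
    if disease not in DISEASES:
        raise ValueError(f"unknown disease {disease!r}; expected one of {DISEASES}")


def candidate_table(disease: str) -> pd.DataFrame:
    """Long-format (time_point, gene) candidate table for one disease."""
    _check_disease(disease)
    with resources.as_file(_DATA / "candidates" / f"{disease}.tsv") as path:
        return pd.read_csv(path, sep="\t", dtype=str)


def candidate_genes(disease: str) -> tuple[dict[str, set[str]], int]:
    """Parsed per-time-point gene sets plus the unique gene count."""
    return parse_candidate_table(candidate_table(disease))


def refined_genes(disease: str) -> list[tuple[str, str]]:
    """The curated final gene list as (gene, direction) pairs."""
    _check_disease(disease)
    raw = json.loads((_DATA / "refined_genes.json").read_text())
    return [tuple(pair) for pair in raw[disease]]


def refined_gene_selection(disease: str) -> GeneSelection:
    """The curated list wrapped as a GeneSelection (score 1.0 by convention,
    per-cell sets folded to a single published per-time shape)."""
    genes = refined_genes(disease)
    per_cell = {("29 days", "all"): {g for g, _ in genes}}
    return GeneSelection(
        disease_id=disease,
        per_cell_genes=per_cell,
        refined_genes=[(g, direction, 1.0) for g, direction in genes],
    )


def process_annotations() -> dict[str, list[str]]:
    """Curated gene → process labels across all four diseases."""
    return json.loads((_DATA / "process_annotations.json").read_text())


def _connector_scaffold(disease: str) -> InteractionNetwork:
    """Synthetic connector scaffold: a per-disease hub gene linked to every
    seed.  Stand-in topology only — the curated parts of the fixture are the
    seed lists and the process annotations."""
    net = InteractionNetwork()
    hub = f"HUB-{disease.upper()[:4]}"
    for gene, _direction in refined_genes(disease):
        net.add_edge(hub, gene, weight=0.5, kind="predicted")
    return net


def disease_network(disease: str) -> DiseaseNetwork:
    """Assembled fixture network for one disease (synthetic scaffold)."""
    _check_disease(disease)
    return build_disease_network(
        refined_gene_selection(disease),
        _connector_scaffold(disease),
        annotation=process_annotations(),
        max_connectors=5,
    )


def all_disease_networks() -> list[DiseaseNetwork]:
    return [disease_network(d) for d in DISEASES]


def merged_disease_network() -> MergedNetwork:
    """The joint DILI network merged over the four disease fixtures."""
    return merge_networks(all_disease_networks())
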