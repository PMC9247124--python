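"""Synthetic inputs with planted, recoverable structure.

Every pipeline stage can be exercised without external downloads: the
generator emits chemical–gene/disease interaction records with exactly
realised planted itemsets, reference-chemical label tables, per-chemical
treated/control expression studies with planted disease genes, and a
weighted interaction network with planted hub connectors.  All generators
are pure functions of the configuration (including its seed).

The defaults define the simulated study conditions: 6 positive and 6
negative reference chemicals, 200 genes of which 5 are planted disease
genes shifted by 2.0 log2 units, Gaussian noise with SD 0.3 on the log2
scale, 3 replicates per design cell, and a 150-gene background network
with 2 planted hub connectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .association import (
    Direction,
    InteractionRecord,
    PathwayHierarchy,
    RecordSource,
    TargetKind,
    disease_item,
    gene_item,
)
from .network import InteractionNetwork
from .references import ChemicalLabel, Evidence
from .refinement import DEFAULT_TIME_POINTS, ExperimentDesign, ExpressionStudy

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticBundle",
    "gen_expression_studies",
    "gen_association_records",
    "gen_interaction_network",
    "gen_labels",
    "gen_all",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_chemicals_pos: int = 6
    n_chemicals_neg: int = 6
    n_filler_chemicals: int = 8
    n_genes: int = 200
    n_planted_disease_genes: int = 5
    effect_size: float = 2.0  # log2 units
    noise_sd: float = 0.3
    baseline: float = 8.0  # mean log2 intensity
    replicates: int = 3
    design: ExperimentDesign = field(
        default_factory=lambda: ExperimentDesign(
            time_points=DEFAULT_TIME_POINTS,
            dose_levels=("low", "middle", "high"),
            replicates_per_cell=3,
        )
    )
    disease_id: str = "disease_1"
    #: (items, support) pairs; items are (kind, identifier) tuples.  None →
    #: one {planted gene, disease} pair per planted gene, realised in the
    #: positive chemicals.
    planted_itemsets: tuple[tuple[tuple[tuple[str, str], ...], float], ...] | None = None
    time_ramp: bool = False  # scale the planted effect linearly with time index
    heavy_tailed: bool = False  # Student-t(3) noise instead of Gaussian
    network_size: int = 150
    planted_connectors: int = 2
    background_edge_prob: float = 0.02
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_planted_disease_genes > self.n_genes:
            raise ValueError("n_planted_disease_genes exceeds n_genes")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.replicates != self.design.replicates_per_cell:
            object.__setattr__(
                self, "design", replace(self.design, replicates_per_cell=self.replicates)
            )


@dataclass
class GroundTruth:
    """What was planted, for recovery tests."""

    planted_genes: dict[str, str] = field(default_factory=dict)  # gene → up/down
    planted_itemsets: list[tuple[frozenset[str], float]] = field(default_factory=list)
    planted_connectors: set[str] = field(default_factory=set)
    connector_wiring: dict[str, set[str]] = field(default_factory=dict)
    positives: set[str] = field(default_factory=set)
    negatives: set[str] = field(default_factory=set)


def _gene_names(cfg: SimulationConfig) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(cfg.n_genes)]


def planted_gene_directions(cfg: SimulationConfig) -> dict[str, str]:
    genes = _gene_names(cfg)[: cfg.n_planted_disease_genes]
    return {g: ("up" if i % 2 == 0 else "down") for i, g in enumerate(genes)}


def chemical_names(cfg: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    pos = [f"POS{i + 1:02d}" for i in range(cfg.n_chemicals_pos)]
    neg = [f"NEG{i + 1:02d}" for i in range(cfg.n_chemicals_neg)]
    filler = [f"CHEM{i + 1:02d}" for i in range(cfg.n_filler_chemicals)]
    return pos, neg, filler


def gen_expression_studies(
    cfg: SimulationConfig,
) -> tuple[list[ExpressionStudy], GroundTruth]:
    """Treated/control studies with planted disease genes.

    Controls are Normal(baseline, noise_sd) per replicate; treated values
    for planted genes in *positive* chemicals are shifted by ±effect_size
    (direction fixed per gene), optionally ramped linearly over the time
    course.  Negative chemicals carry no planted effect.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg)
    planted = planted_gene_directions(cfg)
    pos, neg, _filler = chemical_names(cfg)
    design = cfg.design
    n_cells = len(design.cells)
    shape = (n_cells, cfg.n_genes, design.replicates_per_cell)

    def noise(size) -> np.ndarray:
        if cfg.heavy_tailed:
            return rng.standard_t(3, size=size) * cfg.noise_sd
        return rng.normal(0.0, cfg.noise_sd, size=size)

    time_index = {t: i for i, t in enumerate(design.time_points)}
    ramp = np.array(
        [
            (time_index[t] + 1) / len(design.time_points) if cfg.time_ramp else 1.0
            for (t, _d) in design.cells
        ]
    )
    shift = np.zeros((n_cells, cfg.n_genes))
    for gi, g in enumerate(genes):
        if g in planted:
            sign = 1.0 if planted[g] == "up" else -1.0
            shift[:, gi] = sign * cfg.effect_size * ramp

    studies: list[ExpressionStudy] = []
    for chem in pos + neg:
        control = cfg.baseline + noise(shape)
        treated = cfg.baseline + noise(shape)
        if chem in pos:
            treated = treated + shift[:, :, None]
        studies.append(
            ExpressionStudy(
                chemical_id=chem,
                design=design,
                genes=tuple(genes),
                treated=treated,
                control=control,
            )
        )
    gt = GroundTruth(
        planted_genes=planted, positives=set(pos), negatives=set(neg)
    )
    return studies, gt


def default_planted_itemsets(
    cfg: SimulationConfig,
) -> list[tuple[frozenset[str], float]]:
    """One {gene, disease} pair per planted gene, supported by the positive
    chemicals."""
    n_total = cfg.n_chemicals_pos + cfg.n_chemicals_neg + cfg.n_filler_chemicals
    support = cfg.n_chemicals_pos / n_total
    d = disease_item(cfg.disease_id)
    out: list[tuple[frozenset[str], float]] = []
    for g in planted_gene_directions(cfg):
        out.append((frozenset({gene_item(g), d}), support))
    return out


def _resolve_planted_itemsets(cfg: SimulationConfig) -> list[tuple[frozenset[str], float]]:
    if cfg.planted_itemsets is None:
        return default_planted_itemsets(cfg)
    out = []
    for items, support in cfg.planted_itemsets:
        tagged = frozenset(f"{kind}:{ident}" for kind, ident in items)
        out.append((tagged, float(support)))
    return out


def gen_association_records(
    cfg: SimulationConfig,
) -> tuple[list[InteractionRecord], PathwayHierarchy, GroundTruth]:
    """Interaction records realising the planted itemsets exactly.

    Each planted itemset is placed into an exact count of transactions
    (``round(support × n_chemicals)``), never sampled; default planted
    pairs live in the positive reference chemicals.  Filler records draw
    from a disjoint vocabulary (filler genes only) so planted supports
    cannot drift.  A small pathway hierarchy places the planted genes in a
    child pathway whose parent enables ancestor-closure tests.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    pos, neg, filler = chemical_names(cfg)
    chems = pos + neg + filler
    n = len(chems)
    planted_sets = _resolve_planted_itemsets(cfg)

    genes = _gene_names(cfg)
    planted = list(planted_gene_directions(cfg))
    hierarchy = PathwayHierarchy(
        names={
            "PW_ROOT": "Hepatic stress response",
            "PW_PLANTED": "Planted disease pathway",
            "PW_FILLER": "Background metabolism",
        },
        parent={"PW_PLANTED": "PW_ROOT", "PW_FILLER": None},
        members={
            "PW_PLANTED": frozenset(planted),
            "PW_FILLER": frozenset(genes[cfg.n_planted_disease_genes:
                                          cfg.n_planted_disease_genes + 10]),
        },
    )

    records: list[InteractionRecord] = []
    gt_itemsets: list[tuple[frozenset[str], float]] = []
    default_pairs = cfg.planted_itemsets is None
    for k, (items, support) in enumerate(planted_sets):
        count = round(support * n)
        if not 1 <= count <= n:
            raise ValueError(
                f"target support {support} infeasible for {n} chemicals "
                f"(itemset {sorted(items)})"
            )
        if default_pairs and count <= len(pos):
            hosts = pos[:count]  # planted pairs live in the positive chemicals
        else:
            start = (k * 3) % n
            hosts = [chems[(start + j) % n] for j in range(count)]
        for chem in hosts:
            for item in items:
                kind, _, ident = item.partition(":")
                records.append(
                    InteractionRecord(
                        chemical_id=chem,
                        target_id=ident,
                        target_kind=TargetKind(kind),
                        direction=Direction.UNSPECIFIED,
                        source=RecordSource.CTD_LIKE,
                    )
                )
        gt_itemsets.append((items, count / n))

    # filler noise from a disjoint vocabulary: background genes (index >=
    # n_planted + 10 so they are also outside PW_FILLER membership)
    filler_genes = genes[cfg.n_planted_disease_genes + 10:]
    if filler_genes:
        for chem in chems:
            k = int(rng.integers(1, 4))
            for g in rng.choice(filler_genes, size=min(k, len(filler_genes)), replace=False):
                records.append(
                    InteractionRecord(
                        chemical_id=chem,
                        target_id=str(g),
                        target_kind=TargetKind.GENE,
                        direction=Direction.ACTIVE,
                        source=RecordSource.TOXCAST_LIKE,
                    )
                )
    if records:
        records.append(records[0])  # deliberate duplicate; build must dedupe

    gt = GroundTruth(
        planted_genes=planted_gene_directions(cfg),
        planted_itemsets=gt_itemsets,
        positives=set(pos),
        negatives=set(neg),
    )
    return records, hierarchy, gt


def gen_interaction_network(
    cfg: SimulationConfig,
) -> tuple[InteractionNetwork, GroundTruth]:
    """Background graph plus planted hub connectors.

    Hubs partition the planted disease genes into overlapping runs (each
    hub wired to >= 2 of them, consecutive hubs sharing one gene) so that
    interlinking all seeds requires every hub.  Background edges connect
    only non-seed, non-hub genes, with weights below the hub edge weight.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    planted = list(planted_gene_directions(cfg))
    genes = _gene_names(cfg)
    background = [g for g in genes[: cfg.network_size] if g not in planted]
    hubs = [f"HUB{i + 1:02d}" for i in range(cfg.planted_connectors)]

    net = InteractionNetwork()
    for g in planted + background:
        net.add_node(g)

    wiring: dict[str, set[str]] = {}
    if hubs:
        k = len(hubs)
        # overlapping runs over the planted genes, each of length >= 2
        bounds = np.linspace(0, len(planted) - 1, k + 1).round().astype(int)
        for i, hub in enumerate(hubs):
            lo, hi = bounds[i], bounds[i + 1]
            members = planted[lo: hi + 1]
            if len(members) < 2:  # few planted genes: wire to first two
                members = planted[:2]
            wiring[hub] = set(members)
            for s in members:
                net.add_edge(hub, s, weight=0.9, kind="predicted")

    for i, a in enumerate(background):
        for b in background[i + 1:]:
            if rng.random() < cfg.background_edge_prob:
                w = float(rng.uniform(0.1, 0.5))
                kind = str(rng.choice(["physical", "coexpression", "pathway"]))
                net.add_edge(a, b, weight=w, kind=kind)

    gt = GroundTruth(
        planted_genes=planted_gene_directions(cfg),
        planted_connectors=set(hubs),
        connector_wiring=wiring,
    )
    return net, gt


def gen_labels(cfg: SimulationConfig) -> list[ChemicalLabel]:
    """Evidence table reproducing the ground-truth reference membership.

    Positives get corroborated literature + post-market rows; negatives get
    no-association rows with expression data; filler chemicals carry a
    no-association row without expression data, so selection excludes them.
    """
    pos, neg, filler = chemical_names(cfg)
    d = cfg.disease_id
    labels: list[ChemicalLabel] = []
    for c in pos:
        labels.append(ChemicalLabel(c, d, Evidence.LITERATURE_POSITIVE,
                                    in_expression_db=True, in_livertox=True))
        labels.append(ChemicalLabel(c, d, Evidence.POSTMARKET_REPORT,
                                    in_expression_db=True, in_livertox=True))
    for c in neg:
        labels.append(ChemicalLabel(c, d, Evidence.NO_ASSOCIATION, in_expression_db=True))
    for c in filler:
        labels.append(ChemicalLabel(c, d, Evidence.NO_ASSOCIATION, in_expression_db=False))
    return labels


@dataclass
class SyntheticBundle:
    """Everything one pipeline run consumes, plus the ground truth."""

    config: SimulationConfig
    records: list[InteractionRecord]
    hierarchy: PathwayHierarchy
    labels: list[ChemicalLabel]
    studies: list[ExpressionStudy]
    network: InteractionNetwork
    annotation: dict[str, list[str]]
    truth: GroundTruth


def gen_all(cfg: SimulationConfig | None = None) -> SyntheticBundle:
    """Generate a coherent full-pipeline input bundle."""
    cfg = cfg or SimulationConfig()
    records, hierarchy, gt_assoc = gen_association_records(cfg)
    labels = gen_labels(cfg)
    studies, gt_expr = gen_expression_studies(cfg)
    net, gt_net = gen_interaction_network(cfg)
    processes = ["oxidative stress", "inflammation", "apoptosis"]
    annotation = {
        g: [processes[i % len(processes)]]
        for i, g in enumerate(sorted(gt_expr.planted_genes))
    }
    truth = GroundTruth(
        planted_genes=gt_expr.planted_genes,
        planted_itemsets=gt_assoc.planted_itemsets,
        planted_connectors=gt_net.planted_connectors,
        connector_wiring=gt_net.connector_wiring,
        positives=gt_expr.positives,
        negatives=gt_expr.negatives,
    )
    return SyntheticBundle(
        config=cfg,
        records=records,
        hierarchy=hierarchy,
        labels=labels,
        studies=studies,
        network=net,
        annotation=annotation,
        truth=truth,
    )
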