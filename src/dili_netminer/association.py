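"""Chemical–gene–pathway–disease association mining.

Chemicals are treated as transactions whose items are the genes, diseases
and pathways they are linked to across heterogeneous interaction sources
(high-throughput activity calls, curated expression/activity interactions,
inferred chemical–disease associations).  Frequent itemsets are mined with
a level-wise Apriori search, and disease→gene association rules are scored
by confidence, the fraction of disease-linked chemicals that are also
linked to the gene — the operational reading of "the genes most probably
connected to a disease".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "TargetKind",
    "Direction",
    "RecordSource",
    "InteractionRecord",
    "PathwayHierarchy",
    "AssociationDB",
    "AssociationScore",
    "gene_item",
    "disease_item",
    "pathway_item",
    "split_item",
    "build_association_db",
    "mine_frequent_itemsets",
    "score_gene_disease_rules",
    "query_disease_genes",
]


class TargetKind(str, Enum):
    GENE = "gene"
    DISEASE = "disease"
    PATHWAY = "pathway"


class Direction(str, Enum):
    INCREASE = "increase"
    DECREASE = "decrease"
    ACTIVE = "active"
    UNSPECIFIED = "unspecified"


class RecordSource(str, Enum):
    TOXCAST_LIKE = "toxcast_like"
    CTD_LIKE = "ctd_like"
    CURATED = "curated"


# Items inside a transaction are namespaced so that a gene and a pathway
# sharing an identifier can never collide.
def gene_item(symbol: str) -> str:
    return f"gene:{symbol}"


def disease_item(disease_id: str) -> str:
    return f"disease:{disease_id}"


def pathway_item(pathway_id: str) -> str:
    return f"pathway:{pathway_id}"


def split_item(item: str) -> tuple[str, str]:
    """Split a namespaced item into (kind, identifier)."""
    kind, _, ident = item.partition(":")
    return kind, ident


@dataclass(frozen=True)
class InteractionRecord:
    """One chemical→target link from an activity or association table.

    ``direction`` is carried as metadata only; mining is presence-based and
    directionality re-enters downstream, at the expression-refinement tier.
    """

    chemical_id: str
    target_id: str
    target_kind: TargetKind
    direction: Direction = Direction.UNSPECIFIED
    source: RecordSource = RecordSource.CURATED

    def __post_init__(self) -> None:
        if not self.chemical_id:
            raise ValueError("chemical_id must be non-empty")
        if not self.target_id:
            raise ValueError("target_id must be non-empty")
        # accept plain strings for convenience
        object.__setattr__(self, "target_kind", TargetKind(self.target_kind))
        object.__setattr__(self, "direction", Direction(self.direction))
        object.__setattr__(self, "source", RecordSource(self.source))


@dataclass
class PathwayHierarchy:
    """A forest of pathways with gene membership.

    ``parent`` maps a pathway to its parent (absent or None = root).  Member
    gene symbols are normalised to uppercase HGNC style on construction.
    """

    names: dict[str, str] = field(default_factory=dict)
    parent: dict[str, str | None] = field(default_factory=dict)
    members: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.members = {
            pid: frozenset(g.upper() for g in genes)
            for pid, genes in self.members.items()
        }
        for pid in list(self.members):
            self.names.setdefault(pid, pid)
        for pid, par in self.parent.items():
            self.names.setdefault(pid, pid)
            if par is not None:
                self.names.setdefault(par, par)
        self._check_forest()
        self._gene_index: dict[str, set[str]] = {}
        for pid, genes in self.members.items():
            for g in genes:
                self._gene_index.setdefault(g, set()).add(pid)

    def _check_forest(self) -> None:
        for start in self.parent:
            seen = {start}
            node = self.parent.get(start)
            while node is not None:
                if node in seen:
                    raise ValueError(f"pathway hierarchy contains a cycle through {node!r}")
                seen.add(node)
                node = self.parent.get(node)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.names

    def ancestors(self, pathway_id: str) -> list[str]:
        """All strict ancestors of a pathway, nearest first."""
        out: list[str] = []
        node = self.parent.get(pathway_id)
        while node is not None:
            out.append(node)
            node = self.parent.get(node)
        return out

    def pathways_of_gene(self, gene: str) -> set[str]:
        """Pathways that directly list the gene as a member."""
        return set(self._gene_index.get(gene.upper(), set()))

    @property
    def is_empty(self) -> bool:
        return not self.names


@dataclass
class AssociationDB:
    """Chemical-centric transaction store over tagged items."""

    transactions: dict[str, frozenset[str]]
    hierarchy: PathwayHierarchy = field(default_factory=PathwayHierarchy)

    @property
    def n_transactions(self) -> int:
        return len(self.transactions)

    def item_support(self, items: Iterable[str]) -> float:
        """Fraction of transactions containing every given item."""
        wanted = frozenset(items)
        if not self.transactions:
            return 0.0
        hits = sum(1 for t in self.transactions.values() if wanted <= t)
        return hits / len(self.transactions)


@dataclass(frozen=True)
class AssociationScore:
    """Scored {disease} → {gene} association rule."""

    disease_id: str
    gene: str
    support: float
    confidence: float
    n_cooccurring_chemicals: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.support <= self.confidence <= 1.0:
            raise ValueError(
                f"invalid score for {self.gene}: support={self.support} "
                f"confidence={self.confidence}"
            )


def build_association_db(
    records: Sequence[InteractionRecord],
    hierarchy: PathwayHierarchy | None = None,
) -> AssociationDB:
    """Fold interaction records into one deduplicated transaction per chemical.

    Gene items induce the pathways that list the gene as a member; any
    pathway item (direct or induced) is closed over its hierarchy ancestors,
    mirroring a pathway resource that clusters pathways by functional
    similarity.  Unknown pathway identifiers are a hard error; duplicate
    records are silently collapsed.
    """
    if hierarchy is None:
        hierarchy = PathwayHierarchy()
    if not records:
        raise ValueError("empty record set")
    transactions: dict[str, set[str]] = {}
    for rec in records:
        items = transactions.setdefault(rec.chemical_id, set())
        if rec.target_kind is TargetKind.GENE:
            symbol = rec.target_id.upper()
            items.add(gene_item(symbol))
            induced = hierarchy.pathways_of_gene(symbol)
            for pid in induced:
                items.add(pathway_item(pid))
                items.update(pathway_item(a) for a in hierarchy.ancestors(pid))
        elif rec.target_kind is TargetKind.DISEASE:
            items.add(disease_item(rec.target_id))
        else:
            pid = rec.target_id
            if pid not in hierarchy:
                raise ValueError(f"unknown pathway id: {pid!r}")
            items.add(pathway_item(pid))
            items.update(pathway_item(a) for a in hierarchy.ancestors(pid))
    return AssociationDB(
        transactions={c: frozenset(items) for c, items in transactions.items()},
        hierarchy=hierarchy,
    )


def mine_frequent_itemsets(
    db: AssociationDB,
    min_support: float = 0.1,
    max_len: int = 3,
) -> dict[frozenset[str], float]:
    """Level-wise Apriori search for frequent itemsets.

    Returns every itemset of size ≤ ``max_len`` whose support (fraction of
    transactions containing it) is ≥ ``min_support``.  The result is
    downward closed: every non-empty subset of a returned itemset is
    itself returned, with support at least as large.
    """
    if not 0.0 < min_support <= 1.0:
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    if max_len < 1:
        raise ValueError(f"max_len must be >= 1, got {max_len}")
    transactions = list(db.transactions.values())
    n = len(transactions)
    if n == 0:
        return {}
    min_count = min_support * n

    counts: dict[str, int] = {}
    for t in transactions:
        for item in t:
            counts[item] = counts.get(item, 0) + 1
    frequent: dict[frozenset[str], float] = {
        frozenset([item]): c / n for item, c in counts.items() if c >= min_count
    }
    level = sorted(frequent, key=sorted)  # deterministic candidate order
    k = 1
    while level and k < max_len:
        k += 1
        # join step: unite pairs sharing k-2 items, prune by downward closure
        candidates: set[frozenset[str]] = set()
        for i, a in enumerate(level):
            for b in level[i + 1:]:
                union = a | b
                if len(union) != k:
                    continue
                if all(union - {x} in frequent for x in union):
                    candidates.add(union)
        next_level: list[frozenset[str]] = []
        for cand in candidates:
            c = sum(1 for t in transactions if cand <= t)
            if c >= min_count:
                frequent[cand] = c / n
                next_level.append(cand)
        level = sorted(next_level, key=sorted)
    return frequent


def score_gene_disease_rules(
    db: AssociationDB,
    itemsets: Mapping[frozenset[str], float],
    disease_id: str,
) -> list[AssociationScore]:
    """Score {disease} → {gene} rules from mined itemsets.

    confidence = support({disease, gene}) / support({disease}); genes are
    returned sorted by (confidence, support) descending with lexicographic
    gene order breaking ties.  A disease absent from every transaction
    yields an empty list and a warning in the run log.
    """
    d_item = disease_item(disease_id)
    present = any(d_item in t for t in db.transactions.values())
    if not present:
        logger.warning("disease %r absent from all transactions; no rules scored", disease_id)
        return []
    d_support = itemsets.get(frozenset([d_item]))
    if d_support is None or d_support == 0.0:
        logger.info(
            "disease %r is present but below the mining support threshold; no rules scored",
            disease_id,
        )
        return []
    n = db.n_transactions
    scores: list[AssociationScore] = []
    for itemset, support in itemsets.items():
        if len(itemset) != 2 or d_item not in itemset:
            continue
        (other,) = itemset - {d_item}
        kind, ident = split_item(other)
        if kind != "gene":
            continue
        scores.append(
            AssociationScore(
                disease_id=disease_id,
                gene=ident,
                support=support,
                confidence=support / d_support,
                n_cooccurring_chemicals=round(support * n),
            )
        )
    scores.sort(key=lambda s: (-s.confidence, -s.support, s.gene))
    return scores


def query_disease_genes(scores: Sequence[AssociationScore], top_k: int = 250) -> list[str]:
    """First ``top_k`` genes in score order (the per-disease candidate list)."""
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    return [s.gene for s in scores[:top_k]]
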