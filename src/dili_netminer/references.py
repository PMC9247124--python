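"""Positive / negative reference chemical selection.

For each liver disease, positive reference chemicals are those with
literature evidence of inducing the disease, available expression data,
a listing in a DILI knowledge base, and post-market report corroboration;
negatives are chemicals with expression data and no literature association
to the disease.  The intersection strategy guarantees that every reference
chemical has usable transcriptomics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Evidence",
    "ChemicalLabel",
    "ReferenceSet",
    "select_reference_chemicals",
    "summarize_overlap",
]


class Evidence(str, Enum):
    LITERATURE_POSITIVE = "literature_positive"
    NO_ASSOCIATION = "no_association"
    POSTMARKET_REPORT = "postmarket_report"


@dataclass(frozen=True)
class ChemicalLabel:
    """One evidence row linking a chemical to a disease."""

    chemical_id: str
    disease_id: str
    evidence: Evidence
    in_expression_db: bool = False
    in_livertox: bool = False

    def __post_init__(self) -> None:
        if not self.chemical_id or not self.disease_id:
            raise ValueError("chemical_id and disease_id must be non-empty")
        object.__setattr__(self, "evidence", Evidence(self.evidence))


@dataclass(frozen=True)
class ReferenceSet:
    disease_id: str
    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positives", frozenset(self.positives))
        object.__setattr__(self, "negatives", frozenset(self.negatives))
        if self.positives & self.negatives:
            raise ValueError(
                f"positive and negative sets overlap for {self.disease_id}: "
                f"{sorted(self.positives & self.negatives)}"
            )

    def to_labels(self) -> list[ChemicalLabel]:
        """Re-express the selection as an evidence table (round-trip helper)."""
        labels: list[ChemicalLabel] = []
        for c in sorted(self.positives):
            labels.append(
                ChemicalLabel(c, self.disease_id, Evidence.LITERATURE_POSITIVE,
                              in_expression_db=True, in_livertox=True)
            )
            labels.append(
                ChemicalLabel(c, self.disease_id, Evidence.POSTMARKET_REPORT,
                              in_expression_db=True, in_livertox=True)
            )
        for c in sorted(self.negatives):
            labels.append(
                ChemicalLabel(c, self.disease_id, Evidence.NO_ASSOCIATION,
                              in_expression_db=True)
            )
        return labels


def select_reference_chemicals(
    labels: Sequence[ChemicalLabel],
    disease_id: str,
    min_set_size: int = 4,
) -> ReferenceSet:
    """Intersect evidence sources into per-disease reference sets.

    Positives require a literature-positive row that is present both in the
    expression compendium and in the DILI knowledge base, corroborated by at
    least one post-market report row for the same disease.  Negatives
    require a no-association row with expression data, and must not carry
    any literature-positive row for this disease.  Either set falling below
    ``min_set_size`` makes the disease non-analyzable (hard error), since
    the downstream recurrence filter needs several deregulating chemicals.
    """
    rows = [l for l in labels if l.disease_id == disease_id]
    if not rows:
        raise ValueError(f"no labels cover disease {disease_id!r}")
    lit_positive = {
        l.chemical_id
        for l in rows
        if l.evidence is Evidence.LITERATURE_POSITIVE
        and l.in_expression_db
        and l.in_livertox
    }
    any_positive_claim = {
        l.chemical_id for l in rows if l.evidence is Evidence.LITERATURE_POSITIVE
    }
    postmarket = {
        l.chemical_id for l in rows if l.evidence is Evidence.POSTMARKET_REPORT
    }
    positives = lit_positive & postmarket
    negatives = {
        l.chemical_id
        for l in rows
        if l.evidence is Evidence.NO_ASSOCIATION and l.in_expression_db
    } - any_positive_claim
    if len(positives) < min_set_size or len(negatives) < min_set_size:
        raise ValueError(
            f"disease {disease_id!r} not analyzable: {len(positives)} positive and "
            f"{len(negatives)} negative reference chemicals "
            f"(need >= {min_set_size} of each)"
        )
    return ReferenceSet(disease_id, frozenset(positives), frozenset(negatives))


def summarize_overlap(sets: Sequence[ReferenceSet], which: str = "positives") -> pd.DataFrame:
    """Exclusive Venn-cell chemical counts over per-disease reference sets.

    One row per non-empty disease subset; ``count`` is the number of
    chemicals belonging to exactly that subset, so counts sum to the size
    of the union.  ``which`` selects positives (default) or negatives.
    """
    if len(sets) < 2:
        raise ValueError("need at least two reference sets to summarize overlap")
    if which not in ("positives", "negatives"):
        raise ValueError(f"which must be 'positives' or 'negatives', got {which!r}")
    membership = {s.disease_id: getattr(s, which) for s in sets}
    diseases = sorted(membership)
    chem_profile: dict[str, frozenset[str]] = {}
    for c in set().union(*membership.values()):
        chem_profile[c] = frozenset(d for d in diseases if c in membership[d])
    rows = []
    for k in range(1, len(diseases) + 1):
        for subset in combinations(diseases, k):
            cell = frozenset(subset)
            count = sum(1 for prof in chem_profile.values() if prof == cell)
            rows.append({"diseases": "&".join(subset), "n_diseases": k, "count": count})
    return pd.DataFrame(rows)
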