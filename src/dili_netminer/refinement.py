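"""Transcriptomic refinement of candidate disease genes.

Second-tier filtering of the mined candidate genes against per-chemical
treated/control expression studies (log2 intensities over a time×dose
design, in the style of a large rat-liver toxicogenomics compendium):

1. per (gene, chemical, time, dose) cell: log2 fold change = difference of
   mean log2 intensities, Welch two-sample t-test for significance;
2. a gene is deregulated in a cell iff |log2FC| > 1 and p < 0.05 (strict);
3. group-specific genes recur across >= 3 chemicals of a reference group
   in the same cell, applied identically to positive and negative groups;
4. positive-specificity: keep genes deregulated in the positive group and
   not in the matched negative-group cell;
5. the manual bar-chart / heatmap curation of gene profiles is formalized
   as a deterministic consistency score in [0, 1] (see
   :func:`consistency_score`), retaining genes that respond in a common
   direction across positive chemicals while negatives stay flat or move
   the other way.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_TIME_POINTS",
    "parse_time_label",
    "ExperimentDesign",
    "ExpressionStudy",
    "DEResult",
    "RefinementConfig",
    "GeneSelection",
    "welch_t_test",
    "log2_fold_change",
    "flag_deregulated",
    "differential_expression",
    "group_specific_genes",
    "positive_specificity_filter",
    "consistency_score",
    "refine_disease_genes",
    "parse_candidate_table",
    "export_curation_views",
]

#: Canonical sampling times of the emulated repeat-dose liver study.
DEFAULT_TIME_POINTS: tuple[str, ...] = (
    "3 h", "6 h", "9 h", "1 day", "4 days", "8 days", "15 days", "29 days",
)

_TIME_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(h|hr|hrs|hour|hours|d|day|days)\s*$", re.I)


def parse_time_label(label: str) -> float:
    """Convert a time-point label such as '3 h' or '29 days' to hours."""
    m = _TIME_RE.match(label)
    if not m:
        raise ValueError(f"unrecognized time-point label: {label!r}")
    value = float(m.group(1))
    unit = m.group(2).lower()
    return value * 24.0 if unit.startswith("d") else value


@dataclass(frozen=True)
class ExperimentDesign:
    """Time × dose layout shared by all studies of one run."""

    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS
    dose_levels: tuple[str, ...] = ("low", "middle", "high")
    replicates_per_cell: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_points", tuple(self.time_points))
        object.__setattr__(self, "dose_levels", tuple(self.dose_levels))
        hours = [parse_time_label(t) for t in self.time_points]
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise ValueError("time points must be strictly increasing")
        if not self.dose_levels:
            raise ValueError("at least one dose level is required")
        if self.replicates_per_cell < 2:
            raise ValueError("replicates_per_cell must be >= 2")

    @property
    def cells(self) -> list[tuple[str, str]]:
        return [(t, d) for t in self.time_points for d in self.dose_levels]


@dataclass
class ExpressionStudy:
    """Treated/control replicate matrices for one chemical.

    ``treated`` and ``control`` have shape (n_cells, n_genes, n_replicates)
    of log2 intensities, with cells ordered as ``design.cells``.
    """

    chemical_id: str
    design: ExperimentDesign
    genes: tuple[str, ...]
    treated: np.ndarray
    control: np.ndarray

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        expected = (len(self.design.cells), len(self.genes), self.design.replicates_per_cell)
        for name, arr in (("treated", self.treated), ("control", self.control)):
            if arr.shape != expected:
                raise ValueError(
                    f"{name} matrix for {self.chemical_id} has shape {arr.shape}, "
                    f"expected {expected}"
                )
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._cell_index = {c: i for i, c in enumerate(self.design.cells)}

    def replicates(self, gene: str, time: str, dose: str, group: str) -> np.ndarray:
        arr = self.treated if group == "treated" else self.control
        return arr[self._cell_index[(time, dose)], self._gene_index[gene]]


@dataclass(frozen=True)
class DEResult:
    """Differential-expression call for one (gene, chemical, cell)."""

    gene: str
    chemical_id: str
    time: str
    dose: str
    log2fc: float
    p_value: float
    deregulated: bool
    direction: str  # up / down / none


@dataclass(frozen=True)
class RefinementConfig:
    """Thresholds of the refinement tier.

    fc_threshold / p_threshold implement the strict |log2FC| > 1, p < 0.05
    deregulation cutoff; min_recurrent_chemicals the >= 3-chemical
    recurrence rule; pos_fraction_min the acceptance bound on the
    consistency score; neg_fc_cap the magnitude (log2 units) under which a
    negative chemical's strongest response still counts as flat.
    """

    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    min_recurrent_chemicals: int = 3
    pos_fraction_min: float = 0.5
    neg_fc_cap: float = 0.5
    log2_input: bool = True  # False: raw intensities, log2-transform internally

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or self.p_threshold <= 0 or self.neg_fc_cap <= 0:
            raise ValueError("thresholds must be > 0")
        if self.min_recurrent_chemicals < 1:
            raise ValueError("min_recurrent_chemicals must be >= 1")
        if not 0.0 < self.pos_fraction_min <= 1.0:
            raise ValueError("pos_fraction_min must be in (0, 1]")


@dataclass
class GeneSelection:
    """Per-disease refinement output.

    ``per_cell_genes`` maps (time, dose) to the positive-specific gene set;
    ``per_time_genes`` collapses doses by union (the shape of the published
    candidate tables, which are indexed by time only); ``refined_genes``
    holds (gene, direction, consistency_score) for the curated final list.
    """

    disease_id: str
    per_cell_genes: dict[tuple[str, str], set[str]]
    refined_genes: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def per_time_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for (t, _d), genes in self.per_cell_genes.items():
            out.setdefault(t, set()).update(genes)
        return out

    @property
    def refined_gene_names(self) -> list[str]:
        return [g for g, _dir, _s in self.refined_genes]


# ---------------------------------------------------------------------------
# elementary statistics


def _welch_arrays(a: np.ndarray, b: np.ndarray, axis: int = -1):
    """Vectorised Welch t statistic, Welch–Satterthwaite df and two-sided p.

    Degenerate cells where both groups have zero variance map to p = 1 when
    the means agree and p = 0 (infinite t) when they differ.
    """
    na, nb = a.shape[axis], b.shape[axis]
    ma, mb = a.mean(axis=axis), b.mean(axis=axis)
    va, vb = a.var(axis=axis, ddof=1), b.var(axis=axis, ddof=1)
    sa, sb = va / na, vb / nb
    denom = np.sqrt(sa + sb)
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    degenerate = denom == 0
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.sign(diff) * np.inf, t)
    t = np.where(degenerate & (diff == 0), 0.0, t)
    df = np.where(degenerate, float(na + nb - 2), df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    return t, df, p


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t-test (unequal variances), two-sided.

    Returns (t, df, p) with df by Welch–Satterthwaite.  Requires at least
    two replicates per group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_test requires >= 2 replicates per group")
    t, df, p = _welch_arrays(a, b)
    return float(t), float(df), float(p)


def log2_fold_change(a: Sequence[float], b: Sequence[float]) -> float:
    """Difference of mean log2 intensities (treated − control)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("log2_fold_change requires non-empty replicate vectors")
    return float(a.mean() - b.mean())


def flag_deregulated(
    log2fc: float, p: float, cfg: RefinementConfig | None = None
) -> tuple[bool, str]:
    """Strict deregulation call: |log2FC| > threshold AND p < threshold."""
    cfg = cfg or RefinementConfig()
    dereg = abs(log2fc) > cfg.fc_threshold and p < cfg.p_threshold
    direction = ("up" if log2fc > 0 else "down") if dereg else "none"
    return dereg, direction


# ---------------------------------------------------------------------------
# study-level differential expression


def differential_expression(
    study: ExpressionStudy,
    cfg: RefinementConfig | None = None,
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """All per-cell DE calls for one study as a long-format frame.

    Columns: gene, chemical_id, time, dose, log2fc, p_value, deregulated,
    direction.  Vectorised over genes within each design cell.
    """
    cfg = cfg or RefinementConfig()
    if genes is None:
        idx = np.arange(len(study.genes))
    else:
        wanted = set(genes)
        idx = np.array([i for i, g in enumerate(study.genes) if g in wanted], dtype=int)
    gene_names = [study.genes[i] for i in idx]
    frames = []
    treated, control = study.treated, study.control
    if not cfg.log2_input:
        treated = np.log2(treated)
        control = np.log2(control)
    for ci, (time, dose) in enumerate(study.design.cells):
        a = treated[ci, idx]  # genes × reps
        b = control[ci, idx]
        fc = a.mean(axis=1) - b.mean(axis=1)
        _t, _df, p = _welch_arrays(a, b, axis=1)
        dereg = (np.abs(fc) > cfg.fc_threshold) & (p < cfg.p_threshold)
        direction = np.where(dereg, np.where(fc > 0, "up", "down"), "none")
        frames.append(
            pd.DataFrame(
                {
                    "gene": gene_names,
                    "chemical_id": study.chemical_id,
                    "time": time,
                    "dose": dose,
                    "log2fc": fc,
                    "p_value": p,
                    "deregulated": dereg,
                    "direction": direction,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _as_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    rows = [
        r.__dict__ if isinstance(r, DEResult) else dict(r)  # dataclass or mapping
        for r in results
    ]
    return pd.DataFrame(rows)


def group_specific_genes(
    results,
    chemicals: Iterable[str],
    cfg: RefinementConfig | None = None,
) -> dict[tuple[str, str], set[str]]:
    """Genes deregulated in >= min_recurrent_chemicals chemicals per cell.

    Applied identically to the positive and the negative reference group at
    each time-point × dose combination.
    """
    cfg = cfg or RefinementConfig()
    frame = _as_frame(results)
    chems = set(chemicals)
    out: dict[tuple[str, str], set[str]] = {}
    if frame.empty:
        return out
    sub = frame[frame["deregulated"] & frame["chemical_id"].isin(chems)]
    counts = (
        sub.groupby(["time", "dose", "gene"])["chemical_id"].nunique().reset_index()
    )
    hits = counts[counts["chemical_id"] >= cfg.min_recurrent_chemicals]
    for row in hits.itertuples(index=False):
        out.setdefault((row.time, row.dose), set()).add(row.gene)
    return out


def positive_specificity_filter(
    pos_cells: Mapping[tuple[str, str], set[str]],
    neg_cells: Mapping[tuple[str, str], set[str]],
) -> dict[tuple[str, str], set[str]]:
    """Keep a gene in a cell iff present in the positive and absent from the
    corresponding negative-group cell."""
    return {
        cell: set(genes) - set(neg_cells.get(cell, set()))
        for cell, genes in pos_cells.items()
    }


def consistency_score(
    gene: str,
    results_pos,
    results_neg,
    cfg: RefinementConfig | None = None,
) -> tuple[float, str]:
    """Deterministic surrogate for manual time-series / heatmap curation.

    score = f_sign · f_neg where

    * f_sign — over all (positive chemical, cell) pairs whose |log2FC|
      exceeds fc_threshold, the fraction whose sign matches the
      positive-group majority sign (common-direction consistency);
    * f_neg — the fraction of negative chemicals that stay flat (max |log2FC|
      over cells below neg_fc_cap) or whose strongest response opposes the
      positive majority sign (divergence from the negative group).

    A gene is "consistent" when score >= cfg.pos_fraction_min.  Genes with
    no positive-group response above threshold score 0.  With no negative
    chemicals f_neg is 1 by convention.
    """
    cfg = cfg or RefinementConfig()
    pos = _as_frame(results_pos)
    pos = pos[pos["gene"] == gene] if not pos.empty else pos
    if pos.empty:
        raise ValueError(f"gene {gene!r} absent from positive-group results")
    strong = pos[pos["log2fc"].abs() > cfg.fc_threshold]
    if strong.empty:
        return 0.0, "none"
    signs = np.sign(strong["log2fc"].to_numpy())
    majority = 1.0 if signs.sum() >= 0 else -1.0
    f_sign = float((signs == majority).mean())
    direction = "up" if majority > 0 else "down"

    neg = _as_frame(results_neg)
    if neg.empty or neg[neg["gene"] == gene].empty:
        f_neg = 1.0
    else:
        sub = neg[neg["gene"] == gene]
        ok = 0
        neg_chems = sub["chemical_id"].unique()
        for chem in neg_chems:
            fc = sub.loc[sub["chemical_id"] == chem, "log2fc"].to_numpy()
            peak = fc[np.argmax(np.abs(fc))]
            if abs(peak) < cfg.neg_fc_cap or np.sign(peak) == -majority:
                ok += 1
        f_neg = ok / len(neg_chems)
    return f_sign * f_neg, direction


def refine_disease_genes(
    pos_studies: Sequence[ExpressionStudy],
    neg_studies: Sequence[ExpressionStudy],
    candidate_genes: Iterable[str],
    cfg: RefinementConfig | None = None,
    disease_id: str = "disease",
) -> GeneSelection:
    """Full second tier: DE → recurrence → specificity → consistency.

    ``candidate_genes`` is the mined per-disease candidate list; only those
    genes are eligible.  Requires at least ``cfg.min_recurrent_chemicals``
    positive studies (fewer can never satisfy the recurrence rule).
    """
    cfg = cfg or RefinementConfig()
    if not pos_studies:
        raise ValueError("no positive-reference studies supplied")
    if len(pos_studies) < cfg.min_recurrent_chemicals:
        raise ValueError(
            f"{len(pos_studies)} positive studies < min_recurrent_chemicals="
            f"{cfg.min_recurrent_chemicals}"
        )
    candidates = {g.upper() for g in candidate_genes}
    de_pos = pd.concat(
        [differential_expression(s, cfg, genes=candidates) for s in pos_studies],
        ignore_index=True,
    )
    de_neg = (
        pd.concat(
            [differential_expression(s, cfg, genes=candidates) for s in neg_studies],
            ignore_index=True,
        )
        if neg_studies
        else pd.DataFrame(columns=de_pos.columns)
    )
    pos_cells = group_specific_genes(de_pos, [s.chemical_id for s in pos_studies], cfg)
    neg_cells = group_specific_genes(de_neg, [s.chemical_id for s in neg_studies], cfg)
    per_cell = positive_specificity_filter(pos_cells, neg_cells)
    survivors = sorted(set().union(*per_cell.values())) if per_cell else []
    refined: list[tuple[str, str, float]] = []
    for gene in survivors:
        score, direction = consistency_score(gene, de_pos, de_neg, cfg)
        if score >= cfg.pos_fraction_min:
            refined.append((gene, direction, score))
    refined.sort(key=lambda r: (-r[2], r[0]))
    return GeneSelection(disease_id=disease_id, per_cell_genes=per_cell, refined_genes=refined)


# ---------------------------------------------------------------------------
# candidate tables and curation exports

_SYMBOL_RE = re.compile(r"^[A-Za-z0-9]+$")


def parse_candidate_table(source) -> tuple[dict[str, set[str]], int]:
    """Parse a per-disease candidate gene table into per-time-point sets.

    ``source`` is a path to a two-column TSV (time_point, gene) or an
    equivalent DataFrame; the published tables use 7 or 8 time-point
    columns, flattened here to long format.  Returns (per-time gene sets,
    number of unique genes over the union).  Malformed (non-alphanumeric)
    symbols are a hard error naming the offending row.
    """
    if isinstance(source, pd.DataFrame):
        frame = source.copy()
    else:
        frame = pd.read_csv(source, sep="\t", dtype=str)
    if frame.empty:
        return {}, 0
    if list(frame.columns[:2]) != ["time_point", "gene"]:
        frame = frame.iloc[:, :2]
        frame.columns = ["time_point", "gene"]
    per_time: dict[str, set[str]] = {}
    for i, row in enumerate(frame.itertuples(index=False)):
        symbol = str(row.gene).strip()
        if not _SYMBOL_RE.match(symbol):
            raise ValueError(
                f"malformed gene symbol {symbol!r} at row {i + 1}, column 'gene'"
            )
        per_time.setdefault(str(row.time_point).strip(), set()).add(symbol.upper())
    unique = len(set().union(*per_time.values())) if per_time else 0
    return per_time, unique


def export_curation_views(
    selection: GeneSelection,
    pos_studies: Sequence[ExpressionStudy],
    neg_studies: Sequence[ExpressionStudy],
    cfg: RefinementConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready tables mirroring the manual curation views.

    Returns (heatmap, timeseries): the heatmap frame has one row per
    (gene, chemical, time, dose) with the verbatim log2FC and a PC/NC group
    label from reference membership; the timeseries frame aggregates per
    (gene, group, time) for bar-chart rendering.
    """
    cfg = cfg or RefinementConfig()
    genes = selection.refined_gene_names
    frames = []
    for group, studies in (("PC", pos_studies), ("NC", neg_studies)):
        for s in studies:
            de = differential_expression(s, cfg, genes=genes)
            de = de[["gene", "chemical_id", "time", "dose", "log2fc"]].copy()
            de.insert(2, "group", group)
            frames.append(de)
    if frames:
        heatmap = pd.concat(frames, ignore_index=True)
    else:
        heatmap = pd.DataFrame(
            columns=["gene", "chemical_id", "group", "time", "dose", "log2fc"]
        )
    if heatmap.empty:
        timeseries = pd.DataFrame(columns=["gene", "group", "time", "mean_log2fc", "sd_log2fc"])
    else:
        timeseries = (
            heatmap.groupby(["gene", "group", "time"], sort=False)["log2fc"]
            .agg(mean_log2fc="mean", sd_log2fc="std")
            .reset_index()
        )
    return heatmap, timeseries
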