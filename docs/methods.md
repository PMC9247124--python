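# Methods

## Scope and data model

The pipeline turns heterogeneous chemical-centric evidence into small
per-disease gene signatures and networks.  Its in-memory containers are:

- **AssociationDB** — one deduplicated transaction per chemical over
  namespaced items (`gene:`, `disease:`, `pathway:`).  Gene items induce
  the pathways that list them as members, and every pathway item is closed
  over its hierarchy ancestors, so co-occurrence is measured at all levels
  of the pathway forest at once.
- **ExpressionStudy** — per-chemical treated/control replicate matrices of
  log2 intensities over a shared time × dose design (canonically 3 h – 29
  days, three dose levels), emulating a repeat-dose rat-liver
  toxicogenomics compendium.
- **ReferenceSet / GeneSelection / DiseaseNetwork / MergedNetwork** — the
  per-disease reference chemicals, refinement output, and assembled
  networks.

## Association mining

Apriori with level-wise candidate generation and downward-closure pruning;
supports are exact fractions of transactions.  Itemsets are capped at
size 3 by default (a gene–disease pair plus at most one pathway) to bound
the search; the cap is configurable.  Direction metadata on interaction
records is deliberately ignored during mining — transactions are
presence-based, and directionality re-enters at the refinement tier where
it is actually measurable.

"The genes most probably connected to a disease" is operationalised as
association-rule confidence P(gene | disease) over chemical transactions,
with support and then lexicographic gene order as tie-breaks.  Confidence
is preferred over support alone because it conditions on the disease's own
prevalence among chemicals.  Defaults: `min_support = 0.1`,
`top_k = 250` (matching the reported scale of 200–300 candidate genes per
disease).  Both are configuration, not estimates: the upstream mining
literature does not fix them.

## Reference-chemical selection

Set intersection over an evidence table: positives require a
literature-positive row flagged as present in the expression compendium
and in the DILI knowledge base, plus at least one post-market report row
for the same disease; negatives require a no-association row with
expression data and no positive claim.  Post-market corroboration is a
boolean gate rather than a report-count threshold (report counts are
resource-specific and no per-chemical cutoff is defensible).
`min_set_size` defaults to 4 for both sets because the downstream
recurrence rule needs ≥ 3 deregulating chemicals; smaller sets make a
disease non-analyzable, which is reported as a hard error rather than a
silently weak result.

## Differential expression and refinement

- **Fold change**: difference of mean log2 intensities (inputs are assumed
  log2; a config flag log2-transforms raw intensities).
- **Welch t-test**: implemented directly (statistic, Welch–Satterthwaite
  df, two-sided Student-t tail) and cross-checked in the test suite
  against an independent reference implementation to |Δp| < 1e-10.
  Degenerate cells where both groups are constant give p = 1 when means
  agree and p = 0 (infinite t) otherwise; the latter is logged as
  degenerate rather than masked.
- **Deregulation cutoff**: |log2FC| > 1 and p < 0.05, both strict.  The
  symmetric ±1 bounds make the absolute-value reading the only coherent
  one.  No multiple-testing correction is applied — the procedure is a
  screen whose specificity comes from the later recurrence, specificity
  and consistency stages, not from per-test calibration.
- **Recurrence**: a gene is group-specific in a (time, dose) cell iff
  deregulated there for ≥ 3 distinct chemicals of the group.  The
  threshold is inclusive at three (a gene deregulated by exactly three
  chemicals qualifies), configurable via `min_recurrent_chemicals`.
- **Positive specificity**: per-cell set difference against the matched
  negative-group cell, computed with the identical rule on both groups.

### Consistency score

Manual curation of per-gene bar-chart time series and heatmaps is replaced
by a deterministic surrogate with auditable parameters:

    score = f_sign × f_neg

- `f_sign`: over all (positive chemical, cell) pairs with |log2FC| above
  the fold-change threshold, the fraction whose sign matches the
  positive-group majority sign.  A 50/50 split yields 0.5 by symmetry.
- `f_neg`: the fraction of negative chemicals that stay flat (max |log2FC|
  over all cells < `neg_fc_cap` = 0.5 log2 units) or whose strongest
  response opposes the majority sign.  No negative chemicals → 1.

A gene is retained iff score ≥ `pos_fraction_min` = 0.5.  The two factors
capture the two stated curation criteria — within-group consistency and
divergence from the negative group.  Known limitation: `f_neg` takes a
maximum over all design cells, so with the full 24-cell design a negative
chemical exceeds the 0.5-log2 cap by chance in at least one cell with
probability ≈ 0.6 under noise SD 0.3; individual genes therefore carry
scores well below 1 even when truly disease-specific, and recovery of all
planted genes is guaranteed at the documented simulation conditions rather
than uniformly over random seeds.  Raising `neg_fc_cap` or restricting the
design trades this off against sensitivity to genuinely shared
deregulation.

### Candidate tables

The packaged per-disease candidate tables are indexed by time point only;
per-cell results are collapsed over dose by union when compared against
them.  Parsing validates gene symbols as alphanumeric and reports the
offending row on failure.  Transcription note: the cirrhosis table's
source text yields 36 recoverable unique symbols while its accompanying
prose counts 37; the packaged fixture carries the 36 recoverable symbols
rather than an invented 37th.  The hepatitis refined list records one gene
(EBNA1BP2) with direction "unspecified" because no direction is stated for
it in the source prose.

## Network assembly

A local, deterministic replacement for a web-based gene-function-
prediction service: the user supplies a weighted undirected edge list
(3/4-column TSV or SIF; a real exported edge list works unchanged), and
connectors are recruited greedily — repeatedly take the non-seed node with
the most neighbors among seeds ∪ selected connectors, ties broken by
higher summed edge weight then lexicographic name, requiring each
connector to have ≥ 2 such neighbors spanning ≥ 2 of the current
seed-containing components.  The component-spanning requirement
implements "stop when the seed components cannot be merged further" and
prevents degree-1 pendants and no-op additions; it also means two-hop
connectors (reachable only through another unselected node) are not
found — the greedy reports a partial result instead, which the assembled
network flags.  `max_connectors` defaults to 10 per disease.

Process annotation is a curated gene → process fixture (restriction, with
an `unannotated` sentinel), not an enrichment computation.  Merging unions
nodes and edges (never inventing edges), tags nodes with disease
membership, and intersects annotations to expose shared processes.

The packaged per-disease networks use the curated refined gene lists and
process annotations as seeds/labels; their connector scaffold is a
synthetic single-hub stand-in (the published network figures are not
available as data), so topology-level conclusions should come from a real
edge list, while shared-process conclusions depend only on the curated
parts.  One curation choice: oxidative stress is carried on SGK1 for
steatosis — the steatosis narrative names a stress-response trigger while
the cross-disease summary attributes oxidative stress to all four
diseases; annotating the trigger gene reconciles the two.

## Synthetic data

The generator emulates the *shapes* of the real resources, not their
content: Gaussian noise on the log2 scale with no mean–variance trend (the
minimal model satisfying the Welch assumptions; a Student-t(3) option
exists for robustness checks), planted expression effects of fixed sign
per gene applied only in positive chemicals, planted itemsets realised at
exact transaction counts (never sampled, so mining tests are
deterministic), filler association records drawn from a disjoint
vocabulary so planted supports cannot drift, and planted network hubs
wired to overlapping runs of the planted genes so that interlinking all
seeds requires every hub.  Background network edges avoid seeds and hubs
entirely, which makes connector recovery exact; consequently the
synthetic network does not test robustness to decoy connectors.  Passing
tests on this generator demonstrate correctness of the pipeline's logic
and statistics under its stated assumptions — they do not demonstrate
performance on real microarray data, which is noisier, heteroscedastic,
probe-mapped and batch-affected.

Defaults (the documented study conditions): 6 positive + 6 negative
chemicals, 8 filler chemicals, 200 genes with 5 planted (alternating
up/down), effect 2.0 log2 units, noise SD 0.3, 3 replicates per cell,
8 time points × 3 doses, 150-node network with 2 planted hubs
(hub edge weight 0.9 vs background ≤ 0.5), seed 42.

## Numerical and testing choices

- Type-I calibration of the deregulation flag is checked under a
  heteroscedastic Gaussian null (SD 0.3 vs 0.6, 6 replicates per group),
  the regime the Welch correction targets, where the test attains nominal
  size and a ±3·SE Monte-Carlo band around 0.05 is a fair implementation
  check.  At 3 replicates per group the Welch–Satterthwaite approximation
  is conservative (empirical size ≈ 0.036); the suite asserts that
  conservative direction explicitly rather than pretending nominal
  calibration at n = 3.
- Mining is verified exactly (itemsets and supports) against brute-force
  subset enumeration on random instances with ≤ 12 items and ≤ 20
  transactions.
- All artifacts are written with sorted keys/rows and no timestamps;
  end-to-end reruns with identical inputs are byte-identical, which the
  suite checks by hashing the run directories.
- Problem sizes in the test suite use a reduced design (2–3 time points,
  1–2 doses) where the full 24-cell design adds nothing to the property
  under test; the full defaults are exercised in the parameter-recovery
  and determinism checks.

## Known limitations

- The consistency surrogate is one formalisation of an inherently visual
  curation step; its parameters (`pos_fraction_min`, `neg_fc_cap`) are
  package choices, and the max-over-cells behaviour discussed above is its
  main fragility.
- The greedy connector search is not a Steiner-tree solver; it can report
  partial connectivity where an exact solver would succeed via two-hop
  connectors.
- Reference-chemical selection consumes pre-extracted evidence labels; no
  literature or knowledge-base text mining is performed.
- Process annotations are static curation, not computed enrichment.
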