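# dili-netminer

Semi-automated generation of per-disease and merged gene networks for
drug-induced liver injury (DILI): cholestasis (impaired bile flow),
steatosis (hepatic fat retention), hepatitis (liver inflammation) and
cirrhosis (irreversible scarring).

The package is aimed at computational toxicologists who want to go from
heterogeneous chemical–gene–pathway–disease evidence (high-throughput
activity calls, curated interaction tables, pathway hierarchies,
repeat-dose liver transcriptomics) to small, auditable disease gene
signatures and seed-and-connector networks suitable for adverse-outcome-
pathway (AOP) hypothesis generation.

## Method

The pipeline has two evidence tiers and a network stage:

1. **Association mining.** Each chemical is a transaction whose items are
   the genes, diseases and pathways it is linked to (pathway items are
   closed over their hierarchy ancestors).  Frequent itemsets are mined
   with Apriori at support ≥ *s* = n(X)/N, and disease→gene rules are
   scored by confidence

   &nbsp;&nbsp;conf({D}→{g}) = supp({D, g}) / supp({D}),

   i.e. the fraction of disease-linked chemicals also linked to the gene.
   The top-*k* genes (default 250) form the per-disease candidate list.

2. **Transcriptomic refinement.**  For each reference chemical (positive =
   induces the disease, negative = no literature association), each gene
   and each (time, dose) cell of a treated/control replicate design, the
   log2 fold change is the difference of mean log2 intensities and
   significance comes from the Welch two-sample t-test
   t = (x̄−ȳ)/√(s²ₓ/m + s²ᵧ/n) with Welch–Satterthwaite degrees of
   freedom.  A gene is *deregulated* iff |log2FC| > 1 and p < 0.05
   (strict); it is *group-specific* if deregulated for ≥ 3 chemicals of
   the group in the same cell; it is *positive-specific* if the matched
   negative-group cell does not also show it.  A deterministic
   consistency score (fraction of sign-consistent positive responses ×
   fraction of flat-or-opposing negative chemicals) replaces manual
   bar-chart/heatmap curation; genes scoring ≥ 0.5 make the refined list.

3. **Network assembly.**  Refined genes seed a network over a supplied
   weighted gene–gene interaction edge list; where direct seed–seed links
   are sparse, connector genes are recruited greedily (most active
   neighbors, ties by summed edge weight then name, each connector
   requiring ≥ 2 neighbors spanning ≥ 2 seed components).  Networks carry
   curated gene→process annotations and merge across diseases to expose
   shared processes.

A synthetic-data module generates every input with planted, recoverable
structure (planted itemsets realised at exact supports, planted
differentially expressed genes, planted hub connectors), so the full
pipeline is testable offline.

## Worked example

`python examples/03_refine_expression.py` refines 200 genes against the
default synthetic study (6 positive + 6 negative chemicals, 5 planted
genes at ±2.0 log2 units, noise SD 0.3, 3 replicates, seed 42):

```
planted: G0001(up), G0002(down), G0003(up), G0004(down), G0005(up)
refined:
  G0003: up, consistency=0.83
  G0004: down, consistency=0.83
  G0002: down, consistency=0.67
  G0005: up, consistency=0.67
  G0001: up, consistency=0.50
```

Exactly the five planted genes survive, with their planted directions;
none of the 195 null genes do.  `python examples/04_assemble_networks.py`
builds the four packaged disease networks (seeds = the curated refined
lists: 5, 4, 9 and 8 genes) and merges them:

```
shared by all four diseases: ['oxidative stress']
cholestasis & hepatitis: ['cytoprotection', 'hepatic differentiation', 'oxidative stress']
steatosis & cirrhosis: ['apoptosis', 'inflammation', 'oxidative stress']
```

Oxidative stress is the process common to all four disease networks.

The same workflow is available from the shell:

```sh
dili-netminer simulate --seed 42 --out run_dir
dili-netminer run --config run_dir/run_config.yaml
dili-netminer stage refine --config run_dir/run_config.yaml   # re-run one stage
```

## Layout

- `src/dili_netminer/association.py` — transactions, Apriori, rule scoring
- `src/dili_netminer/references.py` — reference-chemical selection, overlap
- `src/dili_netminer/refinement.py` — Welch/fold-change filtering, consistency
- `src/dili_netminer/network.py` — seed/connector assembly, merging
- `src/dili_netminer/simulate.py` — synthetic inputs with planted structure
- `src/dili_netminer/pipeline.py`, `cli.py` — staged orchestration, CLI
- `src/dili_netminer/datasets.py` — packaged curated fixtures
- `docs/methods.md` — modelling choices, parameters, limitations
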