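# synergyscreen

`synergyscreen` is a network-pharmacology pipeline for identifying
candidate *synergistic* active compounds shared across several multi-herb
prescriptions. Classical herbal formulas are mixtures of hundreds of
compounds acting on overlapping protein targets; the practical question is
which few compounds carry the formulas' joint activity. The package
implements the full in-silico screening chain — ADMET property filtering,
compound–target (C–T) network construction from unioned target
predictions, a collaborative-filtering network reduction, original-vs-
filtered network comparison, hypergeometric pathway enrichment, a
docking-affinity screen and a network-based synergy score — together with
a seeded synthetic-data generator that emulates every external input
(compound property exports, target-prediction servers, disease-gene
databases, pathway annotations, docking runs), so the whole pipeline runs
and is testable offline.

## The method

**ADMET screen.** A compound is *active* when all ten inclusive criteria
hold: MW ≤ 500, Hdon ≤ 5, Hacc ≤ 10, AlogP ≤ 5, RBN ≤ 10, OB ≥ 30 %,
DL ≥ 0.1, BBB ≥ 0.3, Caco-2 ≥ 0.4 and TPSA ≤ 60 Å².

**C–T networks.** Per-compound target sets are the union of several
prediction servers' outputs; each prescription's bipartite network links
its active compounds to their predicted targets. The disease
(pathological) gene set is `GeneCards ∩ (Integrity ∪ TTD ∪ DisGeNet)`.

**Collaborative filter.** With `C = [c_ij]` the ECFP6 Tanimoto matrix of
the *n* compounds and `T = [t_ij]` the binary *n × m* compound–target
matrix, the recommendation matrix is `X = C·T` and

```
s_i = (1/m) · Σ_j x_ij
```

Compounds whose chemical neighbours share their targets score high. The
top 50 % (`⌈n/2⌉`) of compounds and the targets still attached to them
form the filtered network. The reduction is validated by comparing
topology (degree, average shortest path length, closeness, neighbourhood
connectivity, radiality; two-sided Mann–Whitney U per metric) and by
retention ratios of targets, pathological genes and significant GO terms.

**Enrichment and docking screen.** Over-representation of the filtered
targets in GMT gene sets uses the upper-tail hypergeometric test with
Benjamini–Hochberg FDR (significant at q ≤ 0.05; sets with fewer than 10
genes are removed). Compound–target pairs inside the shared significant
pathways are screened at docking affinity ≤ −8 kcal/mol.

**Synergy score.** After collapsing structurally redundant compounds
(Tanimoto > 0.5; the compound with the most screened targets survives per
similarity component), each compound is scored on the
prescription–herb–compound–target–pathway network:

```
S_i = |Σ_j A_ij| · Σ_j[(D_j + 1 − d_ij)·N_j / D_j] / (m_i · Σ_j d_ij)
```

where `A_ij` is the docking affinity, `d_ij` the shortest-path distance
from compound *i* to target *j*, `D_j` the maximum compound distance to
target *j* and `N_j` the number of compounds hitting *j*. The top 5
compounds are the synergy candidates.

## Worked example

```python
from synergyscreen import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(out_dir="demo_out", seed=1))
print(summary.counts)
```

prints (about 35 s on one CPU):

```
{'compounds_total': 539, 'compounds_active': 258, 'pathological_genes': 1745,
 'shared_pathways': 10, 'curated_pathways': 6, 'pathway_targets': 130,
 'docking_pairs': 6155, 'screened_pairs': 1515, 'screened_compounds': 127,
 'deduplicated_compounds': 87,
 'multilevel_nodes': {'prescription': 3, 'herb': 28, 'compound': 87,
                      'target': 110, 'pathway': 6},
 'multilevel_edges': 1416}
```

Of 539 generated compounds, 258 pass the ADMET screen; the three
prescription networks (89/99/104 compounds) are halved to 45/50/52
compounds while retaining 81–83 % of their targets and 81–84 % of the
pathological genes (`summary.prescriptions`). Ten enriched pathways are
shared by all prescriptions; pairs inside the six carried forward are
docking-screened (1,515 of 6,155 pairs at ≤ −8 kcal/mol), 127 compounds
collapse to 87 after similarity deduplication, and the five top-scoring
candidates appear in `summary.candidates` — for seed 1 the best is
`C0181` with S = 265.1 over 2 targets. Each run writes `verdicts.tsv`,
per-prescription score and network files, `topology.tsv`,
`comparison.tsv`, enrichment tables, `affinities.tsv`, `ranking.tsv`,
`multilevel.graphml` and `summary.json` under the output directory.

The same pipeline is scriptable from the shell:

```
synergyscreen run --seed 1 --out demo_out
synergyscreen simulate --out inputs --seed 1
synergyscreen filter-admet --in inputs/compounds.csv --out verdicts.tsv
```

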