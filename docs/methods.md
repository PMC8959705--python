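# Methods

This note records the model implemented by `synergyscreen`, the design
choices made where the procedure was genuinely open, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Pipeline model

The pipeline treats a multi-herb prescription as a bipartite
compound–target (C–T) graph and asks which compounds carry the joint,
overlapping activity of several such prescriptions.

1. **ADMET screen.** Ten inclusive criteria (MW ≤ 500, Hdon ≤ 5,
   Hacc ≤ 10, AlogP ≤ 5, RBN ≤ 10, OB ≥ 30 %, DL ≥ 0.1, BBB ≥ 0.3,
   Caco-2 ≥ 0.4, TPSA ≤ 60 Å²). All bounds are inclusive because the
   screen is stated with non-strict inequalities; boundary compounds
   pass. Missing values follow a policy: `strict` raises, `fail`
   (default) counts the criterion as failed — an absent database value
   cannot be assumed favourable — and `skip` ignores it.
   Literature-curated compounds enter through an explicit `literature`
   bypass flag rather than a threshold exemption, keeping the screen
   itself untouched.
2. **Network construction.** Per-compound target sets are the union of
   several prediction servers' edge lists. Target symbols are upper-cased
   before set operations because servers disagree on casing; spurious
   non-overlap would otherwise deflate every downstream intersection.
   Compounds with zero predicted targets stay in the compound list (and
   are logged) but contribute a zero matrix row, which gives them score
   zero in the next stage anyway. The pathological gene set is
   `portal ∩ (source₁ ∪ source₂ ∪ source₃)` — a broad disease-portal
   list confirmed by at least one curated database.
3. **Collaborative filter.** `X = C·T` with `C` the Tanimoto matrix of
   ECFP6 fingerprints (circular/Morgan, radius 3, folded to 2048 bits)
   and `T` the binary C–T matrix; `s_i` is the i-th row mean of `X`.
   The score is averaged over all *m* targets, not over the compound's
   own targets. The top 50 % of compounds is `⌈n/2⌉` — the ceiling is
   forced by the arithmetic of the retention counts (77 → 39, 79 → 40,
   109 → 55); ties at the cutoff break by ascending compound id so the
   retention set is reproducible across platforms. Retained targets are
   those with at least one edge to a retained compound.
4. **Comparison.** Node-level degree, average shortest path length,
   closeness, neighbourhood connectivity and radiality on the undirected
   bipartite graph. Metrics are per connected component; closeness uses
   the reachable-only correction `(reachable−1)/Σd`, and radiality uses
   the component diameter. The original/filtered comparison uses a
   two-sided Mann–Whitney U per metric (nonparametric, unequal group
   sizes); Welch's t is available as a config alternative. Results are
   reported pooled and stratified by compound/target partition, since
   either convention is defensible. Retention ratios are
   `|filtered ∩ ref| / |original ∩ ref|`; a zero denominator is reported
   as missing (`None`), never as an error.
5. **Enrichment.** Upper-tail hypergeometric test
   `p = P(X ≥ overlap)` with the population equal to the annotation
   universe (every gene appearing in the GMT resource; a user-supplied
   universe is accepted), Benjamini–Hochberg FDR across tested sets,
   significance at q ≤ 0.05. Sets with fewer than 10 genes are removed
   *after* restriction to the universe, because effective population
   sizes drive the test. Only over-representation is tested.
6. **Docking screen and synergy score.** Pairs with best-pose affinity
   ≤ −8 kcal/mol (inclusive) survive. Structurally redundant compounds
   collapse: pairs with Tanimoto strictly above 0.5 are joined into
   components and each component keeps the compound with the most
   screened targets (ties by id). The synergy score uses the canonical
   parse

   `S_i = |Σ_j A_ij| · Σ_j[(D_j + 1 − d_ij)·N_j / D_j] / (m_i · Σ_j d_ij)`

   with distances measured on the full five-level
   prescription–herb–compound–target–pathway network (a bipartite-only
   mode is configurable). The grouping keeps the per-target proximity
   factor `(D_j+1−d_ij)/D_j` normalised to (0, 1], is dimensionally
   coherent, and makes `S_i` strictly increasing in every |A_ij| and
   strictly decreasing in every d_ij. The parse is isolated in a single
   function (`synergy._score_formula`) so alternative groupings can be
   swapped. `N_j` counts *screened* compound–target edges, since the
   score is computed after the affinity screen.

## Synthetic generator

The generator produces statistically realistic stand-ins for every
external input; realism is statistical, not chemical.

* **Structures** are drawn from a built-in library of 240 drug-like
  SMILES (flavonoids, coumarins, alkaloids, terpenoids,
  phenylpropanoids, small synthetic drugs — the classes dominating
  herbal extracts), optionally decorated with 1–2 small substituents
  (F/Cl/CH₃/OH) at random carbons. MW, Hdon, Hacc, AlogP and RBN are
  computed from the structure; OB, DL, BBB, Caco-2 and TPSA are sampled
  from truncated normals centred near the screening thresholds, which
  makes the screen discriminative by construction. A configurable
  fraction of compounds (default 0.5) is built to pass the full screen;
  fail-designated compounds get at least one sampled field forced into
  its failing range, so planted pass counts are exact.
* **Scale defaults** emulate a three-prescription study: 9–12 herbs per
  prescription with a shared-herb pool (shared fraction 0.2, echoing
  harmonising herbs reused across classical formulas), 14–22 compounds
  per herb, 23–189 predicted targets per compound, ~1,745 pathological
  genes, and a 5,000-symbol gene universe whose first 2,000 symbols form
  the target region. Gene and target identifiers are synthetic
  (`G000001`…); targets live inside the gene-symbol universe so that
  target sets, disease genes and annotation sets intersect the way
  protein-coding genes do in real data.
* **Target popularity** is Zipf-like (exponent 1.3 over the target
  region). Prediction servers concentrate on promiscuous targets, and
  this skew is what makes the collaborative filter lose a realistic
  ~20 % of targets and pathological genes when it halves the compound
  list; with uniform sampling nearly every target survives and the
  comparison stage has nothing to measure.
* **Predictions** realise each compound's drawn union target count
  exactly: every target is reported by all three servers with
  probability `prediction_overlap` (default 0.4) or by a uniform
  non-empty subset otherwise, so full overlap makes the three tables
  identical.
* **Gene sets** (GMT) cycle through GOBP/GOCC/GOMF/KEGG categories with
  sizes spanning the 10-gene filter boundary. A third of the sets are
  "signal" sets biased toward hub targets, emulating disease pathways
  built around well-studied proteins; this guarantees shared enriched
  pathways across prescriptions for any seed.
* **Affinities** are negative-skewed normals: a `fraction_strong`
  (default 0.25) of pairs comes from a truncated tail ≤ −8 kcal/mol,
  the rest from N(−6.5, 1.5²) truncated above −8.
* **Determinism.** A single root seed drives independent per-generator
  substreams (`numpy` SeedSequence with a stream tag), so outputs are
  byte-identical under a fixed seed and adding a generator does not
  perturb the others.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: real TCMSP chemistry of specific herbs,
correlated ADMET properties (sampled fields are independent given the
pass/fail designation), annotation hierarchies (GO terms are flat,
unpropagated sets), structure–affinity correlation (affinities are
independent of the compound's fingerprint), and compound membership in
multiple herbs of the same prescription (each compound belongs to one
herb; cross-prescription sharing arises through shared herbs).

## Numerical choices and degenerate inputs

* Fingerprint length (2048) and radius (3) are the de facto standard;
  bit-level identity with other toolkits is not promised — only the
  pipeline's own Tanimoto values are consumed. Salts keep the largest
  organic fragment.
* The hypergeometric tail is `sf(k−1)`; overlap 0 gives p = 1 exactly.
* Mann–Whitney requires ≥ 3 nodes per group; fewer raises an explicit
  insufficient-data error.
* An empty affinity-screen result aborts the run with a named stage
  error rather than an empty ranking; a positive affinity cutoff is
  rejected as a sign-convention error.
* Pipeline stage sizes (default seed-1 run: 539 compounds, three
  networks of ~90–105 compounds × ~1,500 targets) complete in about half
  a minute on one CPU; the dominant cost is all-pairs BFS for the
  topology profiles.
* Curated pathways for the multilevel network default to the shared
  significant pathways with the smallest mean q (up to 6); an explicit
  id list can be supplied instead, mirroring literature-driven curation.

## Known limitations

* GO-term retention in the default synthetic regime saturates near 1.0:
  hub-biased signal sets remain significant after filtering. Target and
  pathological-gene retention (~0.80) carry the discriminating signal.
* The synergy score's published grouping is ambiguous; the canonical
  parse here is one defensible reading, and ranks — not absolute
  values — are the meaningful output.
* The similarity-deduplication keep-rule uses screened-target counts
  only; it does not consider affinity magnitudes.
* The generator's pass/fail designation makes the ADMET pass rate
  binomial around the configured fraction; it does not model property
  correlations that would make real pass rates herb-dependent.
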