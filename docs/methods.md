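# Methods

## Statistical model and procedure

Each experiment *i* is a two-group design (high- vs low-regeneration) on one
platform and one species.  Because absolute signal is not comparable across
platforms, the only quantity an experiment contributes is, per gene *g*,

    fc_i(g) = log2( max(mean_high, ε) / max(mean_low, ε) )

where the means are arithmetic means of raw intensities across the group's
samples and ε > 0 is a floor that keeps the ratio finite when a gene is
absent in one condition.  By default ε is the smallest positive observed
intensity in the experiment, so no magic constant enters the analysis; it can
be fixed in the config.  Probe-level fold changes are collapsed to one value
per gene by the **median** over the gene's probes (robust to a single
aberrant probe set); `mean` and `max_abs` are available for sensitivity
analysis.

Within each experiment genes are ranked by descending fold change (rank 1 =
highest regeneration ratio).  Ties receive the average of the tied positions,
so every rank table sums to U(U+1)/2 exactly — a conserved quantity the test
suite checks on random instances.  The aggregate statistic is the mean rank
r̄(g) across the k experiments, re-sorted ascending; it is invariant under
experiment reordering and under any strictly increasing transform of one
experiment's fold changes.

Two signature modes exist because published descriptions of such analyses
leave the order of operations open:

* **per-dataset** (default): take each experiment's own top-N list and
  intersect — exactly what a k-way Venn diagram of top-N lists reports;
* **aggregate**: average the ranks first, then take the top N of the
  aggregate ordering.

Exact mean-rank ties at the top-N boundary are broken lexicographically by
gene symbol, deterministically, and every tie-break event is recorded in the
output provenance.

## Annotation

Symbol canonicalization applies an alias→canonical table per species;
canonical symbols are fixed points, so the operation is idempotent.  Ortholog
mapping relabels mouse symbols with human ones from a two-column snapshot
table (HomoloGene/HCOP-style).  A mouse gene mapping to several human symbols
has its probes duplicated under each; two mouse genes mapping to one human
symbol keep both probe sets under that symbol — multiplicity is resolved in
exactly one place, the gene-level probe collapse.  Mouse genes with no record
are dropped and logged.  Symbol matching is case-sensitive; species casing
conventions (Oas1a vs OAS1) are the ortholog map's job, never case-folding.
The common universe is the intersection of the per-experiment gene sets after
mapping; genes excluded per experiment are logged so annotation-version drift
stays diagnosable.

## Overlap statistics

For k ≤ 3 lists all 2^k − 1 Venn regions are materialized.  Under the null
that each list of size nᵢ is an independent uniform draw from the U-gene
universe, the expected central overlap is U·∏(nᵢ/U).  The permutation test
redraws each list uniformly without replacement M times (default 10,000) and
reports p = (1 + #{perm ≥ observed}) / (M + 1) — the add-one Monte-Carlo
convention, which guarantees p ∈ (0, 1].  The paper-style analysis reports
the overlap alone; the expectation and permutation p are this package's
labelled extension.

## Enrichment

Term over-representation uses the one-sided Fisher exact test: with a = |list
∩ term| on a universe of U genes, p = P(X ≥ a) for X hypergeometric — the
convention universal in term-enrichment tools (a zero-overlap term has p = 1).
Term membership is restricted to the universe before testing (default
background; the choice matters and is exposed).  Benjamini–Hochberg and
Bonferroni adjustments are computed over all tested terms (statsmodels
step-up for BH; min(1, m·p) for Bonferroni).  Tests verify the p-value
against exhaustive hypergeometric enumeration for every 2×2 table with
margins ≤ 12 and against scipy's two-route implementation.

## Synthetic-data generator

`generate_study` emulates the real study design: k experiments (the first
mouse-labelled by default, the rest human) over U orthologous genes, with

* per-gene, per-platform baselines ~ Normal(8, 2) on the log2 scale and
  probe offsets ~ Normal(0, 0.25), probes per gene uniform on a configured
  range (default 1–3, microarray-like);
* log2-normal intensity noise with SD sigma per sample (default 1.0);
* S planted genes shifted by delta log2 units (default 3.0 = 3σ, a strong,
  recoverable signature) in every experiment's high-regeneration group —
  all probes of a planted gene carry the effect;
* samples_per_group = 3 by default, typical of the microarray designs being
  emulated;
* a mouse→human ortholog fixture missing a configured fraction of mouse
  genes (default 5%), a fraction of human genes receiving two mouse paralogs
  (default 5%), legacy-alias fixtures covering 10% of symbols (LOC-style for
  human, Gm-style for mouse), and a term database containing one term equal
  to the planted set plus 20 seeded decoy terms of size 10–50 drawn from
  non-planted genes.

Planted genes are never assigned to the unmapped-ortholog fraction: the
planted signature must lie inside the common universe for recovery to be
well defined; random dropping would silently truncate the ground truth.

Everything derives from one integer seed through a single `numpy`
`default_rng` stream with a fixed draw order, so identical config + seed
yields byte-identical fixtures.

What the generator does **not** emulate: platform normalization artifacts
(RMA residual structure), batch effects, correlated genes, RNA-seq count
noise, or asymmetric/heterogeneous effect sizes.  Passing tests therefore
demonstrate the pipeline's correctness and calibration under an idealized
log-normal independent-gene model, not robustness to real-array pathologies.

## Numerical and design choices

* Ranking uses `scipy.stats.rankdata(method="average")`; aggregation sorts by
  (mean rank, gene symbol) so ordering is fully deterministic.
* The universe is stored sorted, making universe construction
  order-invariant.
* `n_top = 0` is legal and produces empty signatures with a logged warning;
  k = 1 degenerates to "the central overlap is the single list, p = 1".
* Config hashing excludes the output directory (it does not alter what is
  computed); every written file carries a JSON provenance sidecar with the
  hash, seed and stage counts, and re-running an identical config is
  byte-identical.
* Fisher's odds ratio is the sample odds ratio a·d/(b·c), reported as
  infinity when b·c = 0; it is descriptive only — inference uses the exact
  p-value.

## Problem sizes

Desk-scale checks run the generator at U = 2000–5000 genes, k = 3, top-200
lists: null calibration uses 200 replicate studies at U = 5000 with
single-probe genes and 2 samples per group (the regime where the closed form
U·(n/U)³ = 0.32 applies and replication dominates runtime); recovery uses the
full default generator (probe multiplicity, 5% unmapped orthologs, aliases)
at U = 2000, S = 20, delta = 3σ.  These sizes exercise every code path while
keeping a full run of suite plus acceptance script in the low minutes.

## Known limitations

* The enrichment background defaults to the common universe; whole-platform
  backgrounds must be supplied as the universe explicitly.
* Venn region materialization is limited to k ≤ 3 (k > 3 still yields the
  plain intersection and permutation statistics).
* The permutation null assumes exchangeable gene labels; correlated ranks
  (co-regulated modules) will make it anti-conservative.
* Reproduction of published accession-based results requires the user to
  supply the downloaded tables and pinned alias/ortholog snapshots via the
  `run` config; annotation drift relative to the originally used snapshots
  changes universe size and is surfaced in the dropped-gene logs.
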