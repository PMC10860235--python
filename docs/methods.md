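# Methods

This note documents the models, conventions and parameter choices behind
`pcoskg`, and what the synthetic-study design does and does not establish.

## The synthetic study

The generator (`pcoskg.simulate`) emulates the study design the pipeline
was built for: granulosa-cell expression from three groups — normal (NM),
normoandrogenic PCOS (NA) and hyperandrogenic PCOS (HA) — with four
subjects per group, plus the four external resources the analysis
consumes (annotation terms, PPI edges, a literature corpus, a drug–gene
table).  Defaults: 2000 genes, 4 samples/group, 10 planted specific genes
per group, fold 4, log-noise 0.2, 10⁴ documents, 40 annotation terms, 12
drugs.

**Expression.** Gene *g* in sample *s* is `exp(μ_g + ε_gs)` with
`μ_g ~ N(1, 1.5²)` (tpm-like positivity and heavy tail; a few genes fall
under the 0.1 filter, as in real data) and `ε_gs ~ N(0, noise_sd²)`,
`noise_sd = 0.2` by default (≈ 20 % coefficient of variation, a tight
microarray-replicate level).  Planted genes draw `μ_g ~ N(2, 0.5²)` so
they safely clear the tpm filter, and are multiplied by `fold` (default 4)
in their target group, so their target-group mean is `fold ×` baseline in
expectation.  NM-elevated genes are planted symmetrically: a three-group
design in which only two groups carry signal would leave the NM
classification pool pure noise, which no real transcriptome resembles.

**Corpus.** Documents draw items independently: background MeSH-like
terms with fixed probabilities (with "PCOS" frequent at 0.30, emulating a
disease-centred query), filler terms at 0.02, and planted causal chains
(a, b, terminal, p_ab, p_bt): the head occurs at its marginal rate
(0.20 for chain heads, 0.10 for other planted genes), the intermediate
occurs *only* in documents containing the head, with probability exactly
p_ab, and the terminal likewise given the intermediate.  Chains that feed
one another are resolved in dependency order so every stated conditional
probability is measured against the head's final presence.  Each document
carries a latent topic (NA / HA / general, shares 0.35/0.35/0.30) and
planted gene mentions are confined to their subtype's topic — abstracts
about one subtype's genes rarely mention the other's — which is what makes
the NA- and HA-centred sub-corpora (and hence the subtype knowledge
graphs) distinguishable.  The default chain set routes two gene heads per
subtype through a shared intermediate plus one gene-to-gene chain, so
every chain node retains total degree ≥ 2 and the planted paths are
recoverable after pruning.

**Annotations, PPI, drugs.** Term category (immunity / immunity-related /
glucose / other) is a data column: the original workflow's manual curation
arrives as input, not code.  Planted NA markers sit on > 5 immunity terms
per source with small p-values (inside the top-20 window); planted HA
markers on > 1 glucose BP term; background genes touch at most one flagged
term.  The PPI generator connects each subtype's markers in a ring plus
sparse random edges.  The drug table plants NA-exclusive, HA-exclusive,
one shared and some background-only drugs.

What passing tests on this design do **not** show: recovery under
realistic microarray noise structure (probe effects, batch effects,
correlated genes), MeSH hierarchy semantics, enrichment-statistics
behaviour, or the published study's own gene lists — those depend on
GSE137684 and live DAVID/STRING/PubMed/GRNdb state and are out of scope.

## Statistical conventions

- **t test**: classic equal-variance two-sample Student's *t*, two-sided,
  on raw tpm values.  Zero-variance genes: equal means → p = 1; unequal
  means with zero pooled variance → p = 0 (a consistent limit that avoids
  NaN propagation).  P-values are **not** multiplicity-adjusted; the gene
  calls deliberately apply the raw p < 0.05 threshold.
- **Fold change** is the ratio of raw group means (the 2 / 0.5 thresholds
  are ratio-scale); a zero denominator yields +∞ (counts as > 2); 0/0 is
  defined as 1.
- **"Expressed highest"** requires a strict maximum; a tied maximum is no
  winner and the gene is excluded (same rule assigns classifier pools).
- **Normalization** for dataset merging is per-sample quantile
  normalization to the pooled reference (the across-sample mean of sorted
  vectors, average reference quantiles on ties) after intersecting gene
  sets — the standard microarray-merge choice; the method is isolated in
  `expression.quantile_normalize` and replaceable.
- **Every stated threshold is a strict inequality** (tpm < 0.1 removed;
  p < 0.05; FC > 2 / < 0.5; frequencies > 5 / > 2 / > 1; co-occurrence
  > 0; summed confidence > 0.6; summed support > 30; literature confidence
  > 0.1 and support > 0.001), except the three-element chain rule, which
  *removes* confidence < 0.1 and therefore keeps an exact 0.1.

## Discretization and expression rules

Samples are ranked ascending per gene with average ranks on ties; the bin
is 1 + the number of quantile cuts strictly below the sample's rank
fraction, so a sample exactly at a cut stays in the lower bin, and values
equal to the gene minimum are always bin 1 (a constant gene is all bin 1,
and contributes nothing to any rule).  The rule equations compare
*discretized bins* — the only reading under which "A = B" is
non-degenerate for continuous data.  A rule with an empty denominator
(lhs gene all at its minimum) has confidence 0.  Candidate pairs default
to all ordered pairs of the supplied gene list; an absolute-Spearman
prefilter (`wlar.spearman_prefilter`) is available for larger lists but
off by default, since the full pair set is a superset of any
co-expression filter.

## Classifier search

Rank 1 is the lowest expression, so "highest mean ranking" means the most
highly expressed set.  Set sizes are drawn independently per group,
uniform on [10, 50] (clamped to the pool when a pool is smaller), and
genes are sampled without replacement.  A tied best group is a no-call and
counts as a misclassification, both in training reservation and in
validation.  Against coarse NM/PCOS labels, an NA or HA prediction matches
PCOS.  Ties in best-triple selection break toward the smallest total gene
count, then lexicographic gene lists, so outputs are deterministic.  The
published procedure ran 5 × 10⁷ iterations; the package defaults to
2 × 10⁴ (CLI flag `--iterations` for more), which the tests show already
reaches a ≥ 0.9 mean validation matching rate on the synthetic design.

## Literature rules and the graph

Item matching is case-insensitive exact string; no MeSH-tree expansion.
The subheading allow-list defaults to {metabolism, chemical, genetics,
drug effects, immunology} and is configurable.  Support is normalized by
corpus size by default so the 0.001 cut is meaningful; a raw-count mode
(`support_mode="count"`) is exposed because the additive-count definition
is also defensible.  Three-element chains are thresholded on confidence
only.  The terminal term ("female infertility") is configuration, not a
constant.

Graph assembly gives each chain edge its own two-element confidence;
expression (WLAR) rules are added only between genes already on the graph,
with their summed confidence (range (0, 2]) as weight — literature and
transcriptome confidences are *not* on one scale, so every edge carries a
provenance set and consumers can separate them.  Duplicate edges keep the
maximal confidence and the union of provenances.  "Less connected" nodes
are pruned as total degree < 2, iteratively to a fixed point (one pass can
strand new leaves); the terminal is always kept.  Mutual-term removal
moves nodes shared by the two subtype graphs (except the terminal) into a
third graph together with their incident edges.

## Drugs

Drug-name matching is case-insensitive exact; a drug qualifies for a
subtype with ≥ 1 marker interaction; the bipartite network keeps drugs
with ≥ `min_drug_marker_edges` (default 1) marker edges and aggregates
duplicate evidence rows by maximum score.

## Determinism and problem sizes

All randomness flows from a single seed through fixed per-generator
seed-sequence streams, so every generator is independently reproducible
and reruns are bit-identical.  The test suite and the acceptance script
use desk-scale sizes chosen to make the statistical checks decisive:
500–2000 genes, 10⁴ documents, 10⁴–2 × 10⁴ search iterations, 20 seeds
for averaged recovery rates (binomial three-standard-error bounds at these
sizes are tighter than every asserted tolerance).

## Known limitations

- The plain (not moderated) *t* statistic is used; with n = 4 per group a
  moderated/shrinkage variance estimator would be more powerful on real
  arrays.
- The corpus model is bag-of-items with independent draws; it cannot
  exhibit negation, aboutness or MeSH-hierarchy effects, so literature
  confidences on real abstracts will be noisier than the planted-recovery
  tests suggest.
- Edge direction in the knowledge graph is the rule direction (conditional
  frequency asymmetry); no promote/suppress sign is inferred.
- A live PubMed adapter is intentionally absent from the core: co-occurrence
  is computed on a local corpus for reproducibility.
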