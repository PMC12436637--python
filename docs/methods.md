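# Methods

`cargoscreen` analyses pooled CRISPR knockout screens read out by FACS
sorting: cells carrying a guide library are exposed to a labelled cargo
(e.g. extracellular tau protein taken up by neurons), sorted into
cargo-low and cargo-high gates, and guide abundance in each gate is
sequenced. A gene whose knockout blocks cargo uptake enriches its guides
in the cargo-low gate. This note records the models, parameter choices and
numerical decisions behind each stage.

## Screen statistics

**Normalization.** Counts are normalized by median-of-ratios size factors
(DESeq convention): per-guide geometric means across samples are computed
over guides positive in every sample; each sample's factor is the median
ratio to that reference, rescaled to geometric mean 1. If the median ratio
is zero or undefined (heavily zero-inflated data), the code falls back to
total-count scaling with a warning. Note the identifiability limit: any
ratio-based normalization determines the normalized matrix only up to one
common scalar, so "depth invariance" means the normalized *profile* is
invariant; tests assert exactly that.

**Per-sgRNA test.** Replicates are grouped into a single comparison. The
control mean mu_i is the mean normalized cargo-high count of guide i. A
single dispersion phi is fitted by least squares of (var_i − mu_i) on
mu_i^2 across control samples (no intercept, clamped at 0), i.e. the
mean–variance model var = mu + phi·mu^2. With a single control sample phi
falls back to a configurable prior (default 0.05, a typical value for
well-covered screens). The one-sided enrichment p-value is
p_i = P(X ≥ round(mean cargo-low count)) with X ~ NB(mu_i, phi)
(gamma–Poisson; Poisson when phi = 0). Control means are floored at 0.01
so the tail stays defined for guides absent from the control gate.
Normalized ranks u_i = rank_i/M are assigned ascending in p_i; ties break
by larger fold change, then guide id, so the rank vector is a
deterministic permutation of i/M.

**alpha-RRA.** For a gene with k guides whose sorted ranks are u_(1) ≤ …
≤ u_(k), the gene score is rho = min over j = 1..k′ of
P(Bin(k, u_(j)) ≥ j), where k′ counts guides individually significant at
level alpha (default 0.05): restricting to individually significant
guides keeps inert guides — which any real library contains — from
diluting the score. Significance is calibrated by permutation: B random
k-subsets of all M ranks (sampled without replacement; subsets are shared
across genes with equal k for speed), the same selection rule applied via
the rank-space cutoff #{p < alpha}/M, and
p = (1 + #{rho_null ≤ rho_obs}) / (B + 1), so p ≥ 1/(B+1) by
construction. Genes with k′ = 0 take rho = 1 and p ≈ 1. Benjamini–
Hochberg adjusts across all guide sets. Default B is 10,000; the test
suite uses 300–2,000 (Monte-Carlo error at these B is well below the
effects asserted; consistency across B is itself tested at 3 Monte-Carlo
SEs).

*Calibration caveat.* With guide selection active (alpha < 1), genes with
no selected guide are assigned p = 1, putting an atom at 1 under a null
screen; global uniformity of gene p-values therefore cannot hold by
construction. The calibration property — permutation p-values uniform
under a no-effect screen (KS < 0.05) — is stated and tested with
selection disabled (alpha = 1), where the rank-based permutation p is
exactly uniform up to the 1/(B+1) grid. The same reasoning applies to the
null hit-fraction check.

**Duplicate guide sets and hits.** Libraries may carry a second guide set
for a subset of genes; after aggregation the higher-ranking set (smaller
p; ties by smaller rho, then first set tag) is kept and the other
discarded, leaving one row per gene. Hits are genes with unadjusted
permutation p below a threshold (default 0.01), exported ranked with
−log10(p) enrichment scores. Only positive selection (enrichment in the
cargo-low gate) is computed by default.

## Set comparison

Overlap between two hit lists is the exact upper-tail hypergeometric
probability of the observed intersection inside a shared universe (sets
are intersected with the universe first); it equals one-sided Fisher on
the 2×2 table and is symmetric in the two sets. Cross-study comparisons
condition on the intersection of the two studies' analysed genes; an
external list without its own universe is an error rather than silently
tested against a global background. Hit definitions for external screens
are declarative (field, comparator, threshold) — e.g. FDR < 0.05 for
CRISPR screens, chi-square probability ≥ 0.95 for RNAi-era screens. Term
enrichment is the same hypergeometric test per GMT term with size filters
(3–500 by default), BH within a collection, and star tiers at
q < 0.05/0.01/0.001. No mid-p or continuity corrections anywhere.

For the within-study screen-vs-screen comparison the universe defaults to
the full library gene count; conditioning on the analysed-gene count
instead is exposed as an input, and the overlap conclusion is insensitive
to the choice at these set sizes.

## Compartment enrichment

Gene-to-compartment localization confidences live on a 0–5 evidence
scale; a gene set's compartment score is the mean over its genes divided
by 5, so S ∈ [0, 1] and genes without evidence contribute 0. Before
testing, compartments are removed when too undescriptive (S ≥ 0.7:
essentially everything localizes there), with low signal (S ≤ 0.02), or
with only weak evidence (no individual query gene scoring ≥ 3.5/5). The
filters are evaluated on the query set — the thresholds describe the
query's evidence profile — with background-based filtering available by
flag.

Enrichment compares S_query to random sets of the same size drawn
*without replacement* from the screened library's genes (the null is
"same-size set of library genes", and drawing without replacement matches
that population; the empirical difference to with-replacement draws is
negligible at these sizes). The default draw count is 100,000; random-set
scores are computed as a sparse indicator–matrix product in chunks sized
to ~32 MB, so genome-scale backgrounds run in seconds. Reported per kept
compartment: null mean, fold change FC = S_query/mean(S_null), log2 FC,
p = (1 + #{S_null ≥ S_query})/(n_boot + 1) (one-sided enrichment; the +1
pseudocount keeps p positive), BH q across kept compartments. When the
query equals the background, every random set is drawn from the same
pool and FC = 1 identically. The export table orders kept compartments by
descending log2 FC for diagram rendering.

## Interaction networks

MITAB 2.5 records are reduced to an undirected simple graph on uppercase
gene symbols: reciprocal duplicates collapse (sorted-pair
canonicalization) with merged source-database lists, self-interactions
are dropped, and an optional taxon filter (default human, 9606) removes
cross-species records; records without taxon annotation are kept. "Most
densely connected" is read as highest degree, ranked within the induced
subnetwork of hit genes (isolated hits retained at degree 0), with ties
broken alphabetically; each top node's neighbours among the other top
nodes are listed. Community detection and betweenness alternatives are
deliberately out of scope.

## Synthetic data generator

The generator is a forward model of the sorted-population design and
defines the conditions under which the pipeline is validated:

- **Library**: configurable genes × 5 guides, with a second 5-guide set
  for 10% of genes (mirroring a genome-wide library of ~18k genes and
  ~100k guides where ~1,900 genes carry a second set), unique random
  19-nt sequences.
- **Counts**: each guide's abundance a_g is log-normal (sigma 0.5,
  plasmid skew), drawn once and shared across replicates since replicates
  derive from the same library prep. A cell sorts into the cargo-low gate
  with probability p = 0.9 if its gene is required *and* its guide is
  efficacious (Bernoulli, 80% functional fraction — inert guides are the
  reason alpha-RRA exists), else p = 0.5 (the two collected gates split a
  neutral population evenly). Expected counts are 2·depth·a_g·p (low
  gate) and 2·depth·a_g·(1−p) (high gate), drawn as gamma–Poisson with
  dispersion phi = 0.05 (variance mu + phi·mu^2). Sorting is modelled at
  the guide level, not per cell.
- **Default desk scale**: 1,000 genes, 50 required, depth 500, 2
  replicates — the full pipeline runs in seconds at this size while
  preserving the statistical structure (rank granularity, guide
  multiplicity, dispersion regime) of a genome-wide screen.
- **Localization / networks / external lists**: sparse right-skewed
  background scores with an additive planted effect in one compartment;
  Erdos–Renyi background with a planted dense module; external hit lists
  with a controlled fraction of the planted required genes plus noise.
- Ground truth (required genes, per-guide efficacy flags, planted
  compartment, module members) is written separately and never read by
  analysis code.

What the generator does **not** emulate: multiplicity of infection,
FACS spillover/compensation, PCR jackpotting, gene-length or copy-number
biases, correlated guide efficacies, or realistic gene-symbol structure.
Passing recovery tests therefore demonstrates the statistics behave
correctly under the declared generative model, not that any particular
biological screen is reproduced.

## Guide counting

Reads carry the guide directly (19-bp single-end protocol), so counting
is an exact hash match of the read subsequence at a fixed, user-supplied
offset; optional one-mismatch rescue scans the Hamming-1 neighbourhood
and counts ties (≥2 candidate guides) as unmapped rather than assigning
fractionally. Matching is forward-strand only. Conservation
(mapped + unmapped = total) holds by construction and is tested, as is
exact recovery of a count matrix from noiselessly emitted reads.

## Determinism and seeds

Every stochastic operation takes an explicit seed. The pipeline runner
fans a single ambient seed out to per-stage child seeds by stable hashing
(CRC32) of stage names, so adding a stage does not shift the streams of
the others. Outputs carry the tool version, configuration hash and seed
in a header comment.

## Known limitations

- The per-sgRNA NB test treats the fitted dispersion as shared across all
  guides; no empirical-Bayes shrinkage of per-guide dispersions.
- Permutation nulls are shared per guide-multiplicity bucket; genes with
  equal k therefore share Monte-Carlo noise.
- Published hit counts from any specific screen depend on the exact
  upstream tool version and invocation; this package documents its own
  defaults rather than promising bit-identical reproduction, and
  validates the ranking machinery by parameter recovery on synthetic
  screens instead.
- GMT annotations are treated as flat sets (no ontology propagation).
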