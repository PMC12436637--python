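# cargoscreen

Analysis of FACS-sorted pooled CRISPR knockout screens.

In this screen design, cells carrying a genome-wide knockout library are
exposed to a labelled cargo — for example extracellular tau protein taken
up by human neurons — and sorted into cargo-low and cargo-high gates.
Knockouts of genes *required* for uptake enrich their guides in the
cargo-low gate. `cargoscreen` takes the sorted-population guide counts to
gene-level results and the downstream comparative analyses:

- **guide counting** from single-end reads by exact library match;
- **gene ranking**: median-ratio normalization, a one-sided per-sgRNA
  negative-binomial enrichment test (variance μ + φμ²), and **α-RRA**
  gene aggregation — the gene score is
  ρ = minⱼ P(Bin(k, u₍ⱼ₎) ≥ j) over the gene's k guide ranks u₍ⱼ₎,
  restricted to guides individually significant at level α, with a
  permutation p-value p = (1 + #{ρ_null ≤ ρ}) / (B + 1); genes with two
  guide sets keep the higher-ranking set; hits are called at unadjusted
  p < 0.01;
- **set comparison**: exact hypergeometric overlap between hit lists
  (conditioning on the genes analysed in both studies) and term/complex
  over-representation against GMT collections, BH-adjusted;
- **compartment enrichment**: a gene set's localization score per
  subcellular compartment, S = mean gene score / 5 ∈ [0, 1], filtered
  (S ≥ 0.7 undescriptive, S ≤ 0.02 low signal, no gene ≥ 3.5/5 weak
  evidence) and compared to 100,000 random same-size gene sets for an
  empirical p and a log2 fold change over the random average;
- **interaction networks**: PSI-MITAB ingestion with reciprocal/self-edge
  removal and degree-ranked connectivity of the hit-gene subnetwork;
- a **synthetic screen generator** with planted ground truth, so the whole
  pipeline is testable without any external downloads.

## Worked example

Simulate a desk-scale screen (1,000 genes, 5 guides each plus second
guide sets for 10% of genes, 50 planted required genes, 2 replicates) and
run the full pipeline:

```bash
cat > demo.yaml <<'YAML'
alpha: 0.05
permutations: 2000
p_threshold: 0.01
n_boot: 10000
seed: 7
inputs:
  scenario:
    n_genes: 1000
    n_required_genes: 50
    n_replicates: 2
    reads_per_guide: 500.0
YAML
cargoscreen run --config demo.yaml --out demo_run
```

which prints

```
{"hits": 50, "config_hash": "08c617877535", "seed": 7}
```

and writes, among other tables, `demo_run/gene_stats.tsv`:

```
# cargoscreen 0.1.0 config=08c617877535 seed=7
gene    guide_set  k  k_prime  rho            p                q            rank
G00129  set1       5  5        5.3701e-09     0.00049975       0.010779     1
G00209  set1       5  5        1.4109e-08     0.00049975       0.010779     2
```

Reading the top row: gene G00129 has k = 5 guides, all k′ = 5
individually significant at α = 0.05; its aggregated rank score
ρ ≈ 5.4×10⁻⁹ was never reached by 2,000 random rank sets, so its
permutation p sits at the floor 1/(B+1) ≈ 5×10⁻⁴, well below the 0.01
hit threshold. Of the 50 called hits, 49 are planted required genes
(sensitivity 0.98, precision 0.98 against `demo_run/truth.json`). The
compartment table shows the planted compartment C001 with fold change
≈ 8.7 (log2 FC ≈ 3.1, p ≈ 10⁻⁴) while unplanted compartments sit near
fold 1, and `connectivity.tsv` ranks the planted dense module at the top
of the hit-subnetwork degree ranking.

Each stage is also available separately (`simulate`, `count`, `test`,
`rra`, `hits`, `overlap`, `enrich`, `compartments`, `network`); see
`cargoscreen --help`. All commands accept explicit seeds and write the
tool version, config hash and seed into every output header.

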