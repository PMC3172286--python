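# marrownet

Hub-gene discovery in short expression time courses, built for studies of
bone-marrow recovery after irradiation injury but applicable to any small
multi-timepoint design (a baseline plus a handful of later timepoints with a
few replicates each).

Whole-genome expression profiling of recovering tissue yields thousands of
genes; the scientific question is which few of them sit at the center of the
transcriptional response. `marrownet` narrows the gene list in the sequence a
systems-biology analyst would: differential calling over the time course,
temporal clustering, functional enrichment, and two complementary network
views (data-driven co-expression and database-derived protein interactions),
each stage feeding the next. A synthetic-data generator with planted ground
truth makes every stage testable end to end.

## Methods at a glance

- **Differential expression.** For each gene and each post-baseline timepoint
  *t*, a two-sample t-test of the log2 intensities against the baseline group
  (Welch by default, pooled-variance Student via `equal_var`), with
  log2 fold change = mean(log2 *t*) − mean(log2 baseline). Per-timepoint
  Benjamini–Hochberg q-values are reported; a gene is differential when
  p < α at one or more timepoints.
- **Model-profile clustering** (short time-series style). Candidate profiles
  are all integer trajectories starting at 0 with per-step change ≤ *c*
  ((2c+1)^(T−1) − 1 of them); a max–min greedy pick under d = 1 − r keeps
  *m* = 50 distinct model profiles. Each gene's log-ratio trajectory joins
  its nearest profile; a profile's significance is the upper binomial tail
  of its observed gene count against the fraction expected under permuted
  timepoint orderings (all 4! = 24 enumerated at T = 5), Bonferroni-corrected.
- **Enrichment.** One-tailed Fisher exact test per term,
  p = P(X ≥ k) for X ~ Hypergeom(N, K, n), with BH q-values, the enrichment
  ratio (k/n)/(K/N), an advisory Pearson χ², the conservative EASE (k−1)
  variant for pathway sets, and a child→parent map of significant terms
  (transitive reduction over the significant set).
- **Co-expression network.** Pearson correlation of trajectory pairs; edge
  iff |r| ≥ 0.8 and correlation-test p < 0.05 (both configurable). Node
  degree, local clustering coefficient 2t/(deg(deg−1)), and coreness by
  iterative k-core peeling; per connected subnetwork, the genes attaining
  the maximum coreness are the core (hub) genes.
- **PPI subnetwork.** Differential genes ∩ literature gene list (uppercased
  symbols) become seeds; the subnetwork is the induced subgraph on seeds +
  first neighbors; hubs are nodes with degree above a cutoff (default > 10).
- **qPCR validation.** 2^−ΔΔCt with ΔCt = Ct(target) − Ct(reference),
  ΔΔCt from condition means (Livak aggregation), and per-replicate-fold
  standard deviations; direction concordance against the array fold changes.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Generate a synthetic experiment (500 genes, 100 differential, one planted
40-gene co-expression module, 5 timepoints × 4 replicates) and run the full
pipeline:

```python
from marrownet import RunConfig, run_pipeline
from marrownet.pipeline import PipelineInputs
from marrownet.simulate import SimConfig, simulate_bundle

paths = simulate_bundle(SimConfig(n_genes=500, n_de=100, module_size=40, seed=1), "demo")
inputs = PipelineInputs.from_paths(
    paths["expression"], paths["gmt"], paths["dag"],
    paths["ppi"], paths["literature"], ct=paths["ct"],
)
result = run_pipeline(RunConfig(seed=1), inputs, "demo_out")
for stage, count in result.counts.items():
    print(f"{stage:22s} {count}")
print(f"qPCR direction concordance: {result.qpcr_concordance:.2f}")
```

prints

```
genes_in               500
differential_genes     153
clustered_genes        45
go_selected_genes      40
network_genes          40
core_genes             40
overlap_genes          77
ppi_hubs               34
qPCR direction concordance: 1.00
```

Reading: of 500 genes, 153 test differential at p < 0.05 at some timepoint
(the 100 planted plus raw-p false positives — the q-value column is what
controls the FDR); 45 fall in Bonferroni-significant temporal profiles,
led by the planted module's profile; 40 of those sit in significantly
enriched annotation terms and form one co-expression subnetwork whose
members all reach the maximum coreness (the planted module plus its
profile-mates); 77 differential genes also occur in the literature list and
seed the PPI subnetwork, where 34 nodes exceed degree 10; and every qPCR
assay agrees in direction with the array. `demo_out/` holds one TSV per
stage (differential table, profile table, enrichment table, network node
and edge lists, core genes, PPI subnetwork, qPCR folds).

The same analysis is scriptable from a shell via the `marrownet` CLI
(`simulate`, `de`, `cluster`, `enrich`, `network`, `ppi`, `qpcr`,
`pipeline` subcommands; see `marrownet --help`).

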