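# Methods

This note documents the statistical procedures, their assumptions, the
defaults and the deliberate design choices behind `marrownet`. The package
analyses a short expression time course — a baseline (day 0) group plus a
few post-baseline timepoints (default 3, 7, 11, 21 days) with a few
replicate chips each — and narrows the genome down to hub genes through a
fixed sequence of stages.

## Differential expression

Tests run on log2-transformed normalized intensities, which makes the
additive-noise assumption reasonable for array data. Each post-baseline
timepoint is compared to the baseline group with a two-sample t-test:

- **Welch (unequal variance) by default.** With 4-vs-4 replicates a pooled
  variance estimate is fragile when a treatment changes variability, so the
  Satterthwaite-df form is the safer default; `equal_var=True` restores the
  classical Student test. A relevant numerical property: at these sample
  sizes the Welch test is mildly *conservative* — its empirical size at
  nominal 0.05 is about 0.041 under an equal-variance normal null (measured
  in the test suite), while the Student test is exact there. Power
  comparisons in the recovery experiments are unaffected.
- **Degenerate inputs.** Two constant groups with equal means give p = 1,
  with unequal means p = 0 (logged); both are conventions, not computed
  statistics.
- **Selection rule.** A gene is flagged differential when its *raw* p falls
  below `alpha_de` (default 0.05) at ≥ 1 timepoint — the rule used by the
  kind of study this package targets. Benjamini–Hochberg q-values across
  genes (per timepoint, step-up definition, clipped at 1) are always
  reported alongside so an FDR-controlled call (`q < 0.05`) is available;
  the planted-recovery validation uses the q-based call precisely because
  the raw-p any-timepoint rule does not control FDR.
- **Baseline replication.** The default requires ≥ 2 baseline chips. For
  designs with one sham chip hybridized alongside each timepoint,
  `baseline_pooled=True` pools every chip whose metadata group is
  `baseline` into one reference group; this is the documented fallback, and
  it requires a metadata sidecar (the `t{days}_r{rep}` header convention
  can only mark day-0 chips as baseline).

## Model-profile clustering

The clustering follows the model-profile approach for short time series:
cluster prototypes are chosen *before* seeing the data, which avoids the
overfitting of data-driven prototypes at T = 5.

- **Candidates.** All integer step sequences of length T starting at 0 with
  per-step change in {−c, …, +c}, excluding the all-zero profile:
  (2c+1)^(T−1) − 1 of them. `max_unit_change` c defaults to 2 (624
  candidates at T = 5); c = 1 gives 80.
- **Selection.** Greedy max–min under d = 1 − Pearson r of the step
  vectors, seeded at the lexicographically smallest candidate, ties broken
  lexicographically; `n_model_profiles` defaults to 50. The procedure is
  deterministic; profile ids 0..m−1 are assigned in lexicographic step
  order so they are stable across runs.
- **Assignment.** A gene's trajectory is its per-timepoint mean log2
  intensity minus the baseline mean (first element 0 by construction).
  Genes join the profile with minimal d = 1 − r; exact ties go to the
  lowest profile id (correlations are rounded to 12 decimals first so
  floating-point noise cannot break a structural tie); zero-variance
  trajectories go to a reserved "unassigned" bucket.
- **Significance.** The null keeps every gene's values but permutes the
  order of the post-baseline timepoints (the baseline stays fixed because
  trajectories are ratios to it). At T = 5 all 4! = 24 permutations are
  enumerated — no Monte-Carlo noise; for T > 5 a seeded sample of 240
  permutations that always includes the identity is used. The expected
  assignment fraction per profile over permutations feeds an upper-tail
  binomial p at the observed count; profiles with zero observed count get
  p = 1 by convention. Because the identity permutation is always included,
  a profile with observed genes necessarily has a positive expected
  fraction. Significance applies `alpha_profile` (default 0.001) after
  Bonferroni correction over the m profiles. Note the permutation null
  retains autocorrelated signal: genes whose profile is nearly
  permutation-invariant inflate their own expected count, so small planted
  clusters (≈ 10 genes) may not reach Bonferroni significance — this is a
  property of the method, not a defect.

## Enrichment

One-tailed over-representation only: p = P(X ≥ k) for
X ~ Hypergeom(N, K, n), where N is the background size, K the term size in
background, n the study size and k the study hits. The background defaults
to the full gene universe of the expression matrix, since an array defines
the set of genes that *could* have been called. BH q-values run across the
tested terms; terms with K = 0 are skipped. The Pearson χ² p (1 df, no
continuity correction) is emitted as an advisory statistic — flagged
unreliable when an expected cell is < 1, and never used for selection
(the χ² is two-sided, so it also fires on depletion; its ordering agrees
with Fisher's only on the over-represented side). Pathway enrichment
reuses the machinery with two display options: the EASE variant (Fisher on
k−1, so singleton hits are never significant) and a percentage-scale FDR
column. The significant-term map connects each significant term to its
nearest significant ancestors in the term DAG: an edge (a, b) survives iff
b is an ancestor of a and no other significant term lies on a path between
them (transitive reduction of the reachability relation restricted to
significant terms).

All cross-list gene comparisons in the package (annotations, PPI,
literature) are performed on uppercased symbols, because mixed-species
analyses mix casings (mouse *Junb* vs human *JUNB*); an explicit mapping
table (e.g. an orthology map) can be supplied where uppercasing is not the
right join.

## Co-expression network and k-core hubs

Correlation is computed between per-timepoint mean log-ratio trajectories
(T points including the structural 0 at baseline) — the same object the
clustering sees — rather than between per-sample vectors; `per_sample=True`
switches. With only T = 5 points, null correlations are wide
(P(|r| ≥ 0.8) ≈ 0.10), which is why the edge rule combines |r| ≥ 0.8
*and* correlation-test p < 0.05 (two-sided t transform; jointly an
effective |r| ≳ 0.88). Both knobs are configured and logged; zero-variance
genes are excluded.

Coreness is computed by iterative peeling (remove all nodes of degree ≤ k,
cascading, before raising k) — implemented in-package because k-core
membership is the hub definition itself; tests verify exact agreement with
networkx and with a brute-force delete-until-stable oracle. The local
clustering coefficient 2t/(deg(deg−1)) (0 when deg < 2) is reported per
node. Per connected subnetwork, core genes are the nodes attaining the
component's maximum coreness, ranked by degree (ties alphabetical);
components with < 3 nodes are reported but yield no core genes, since a
2-node component has trivial coreness 1.

## PPI subnetwork

Seeds are the overlap of the differential genes with a literature-mined
gene list. Extraction takes seeds present in the PPI plus their first
neighbors and keeps the induced subgraph (neighbor–neighbor interactions
included; a `star` mode restricts to seed-incident edges). Seeds absent
from the PPI are kept as isolated nodes so the report is complete. Hub
nodes have within-subnetwork degree ≥ `hub_min_degree` (default 11, i.e.
"> 10"); the alternative of ranking by full-network degree is a one-liner
on the input graph and intentionally not the default.

## qPCR validation

2^−ΔΔCt with fixed amplification efficiency 2. Aggregation is
mean-ΔCt-first (the Livak convention): ΔΔCt = mean ΔCt(treated) − mean
ΔCt(control), one fold per gene/timepoint. The reported spread is the
standard deviation of per-replicate folds, each computed against the
control mean ΔCt — one documented convention among several in use for
error propagation on the fold scale. Concordance against the array is the
fraction of shared (gene, timepoint) pairs whose log2 fold changes agree
in sign; pairs with a true fold of exactly 1 have no direction and should
not be planted as validation targets.

## Synthetic data

The generator emulates a normalized two-channel-free array experiment:
per-gene baseline log2 intensity ~ Normal(8, 1.5), additive log2 noise
per sample ~ Normal(0, `noise_sd`), intensities emitted as 2^log2.
Differential genes add `effect_log2` × (step profile); profiles are drawn
from the *selected* model-profile set (m = 50, c = 2 by default) so that
"assigned to the true profile" is well defined. A planted module's genes
share one profile — chosen among profiles whose step vector has sd ≥ 1 so
the module carries real temporal signal — giving within-module trajectory
correlations near 1 at the default noise. Companion generators plant an
enriched annotation term (module genes plus differential genes, padded to
size 50 with 40 differential members), a term DAG (all terms under one
root containing the universe), a random PPI with a densified clique on the
first overlap genes, a literature list with an exact planted overlap with
the differential genes (defaults 514 and 42), and Ct tables at the true
planted folds (reference Ct 20, target Ct 25, noise sd 0.1, 3 replicates).

Defaults: 2000 genes, 260 differential, one 15-gene module, timepoints
(0, 3, 7, 11, 21), 4 replicates per timepoint including baseline,
noise_sd 0.2, effect_log2 1.0. The validation experiments run the
generator at 500 genes / 100 differential over 20 seeds — large enough for
stable rates, small enough that the whole suite runs in seconds.

What the generator does *not* model: probe-level effects, batch and
spatial artifacts, intensity-dependent variance, a single-sham baseline
design, correlated noise between genes outside planted modules, and
annotation bias (term sizes are uniform). Passing the planted-recovery
checks therefore demonstrates the correctness and calibration of the
machinery under the generative model, not performance on real arrays.

## Determinism and numerical choices

Every stochastic step takes a seed (one pipeline-wide seed in `RunConfig`);
identical config + inputs give byte-identical output tables. Tie-breaks
are always deterministic: lexicographic for profile selection, lowest id
for assignment, degree-then-alphabetical for hub rankings. Correlations
are rounded to 12 decimals before argmax comparisons; BH q-values are
clipped at 1; Fisher p for k = 0 is 1 exactly.

## Known limitations

- The raw-p any-timepoint differential rule inflates the false-positive
  count by design (q-values are the controlled alternative).
- Profile significance at T = 5 is exact in its permutation enumeration
  but approximate in using a binomial tail for what is a sum of dependent
  indicator variables.
- Trajectory-level correlation at T = 5 has few degrees of freedom; the
  p gate mitigates, but module detection leans on the |r| threshold.
- The EASE/percentage-FDR display options approximate the conventions of
  a popular web service; numeric identity with that service's internals is
  not guaranteed.
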