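# Methods

`crpcnet` implements a four-stage network analysis of paired
before/after-androgen-deprivation transcriptomes, plus a synthetic-data
generator that produces every input with known ground truth. This note
documents the models, the parameters that matter, the numerical choices, and
the limits of what the synthetic benchmarks can show.

## The analysis

### Differential-expression overlap

The pipeline consumes two per-contrast DE tables (gene, log2 fold change,
p, FDR) — one from a cell-line contrast (androgen-sensitive vs
androgen-independent), one from a clinical contrast (hormone-naive vs
resistant). Genes significant in both tables at `fdr_threshold` (default
0.05) form the **common DE set**. Overlap significance uses the upper-tail
*inclusive* hypergeometric test: with a universe of N jointly tested genes,
K significant in the first table and n in the second,

    p = P(X >= k),  X ~ Hypergeom(N, K, n),  k = |overlap|.

The universe defaults to the intersection of the genes tested in both
tables: only jointly assayed genes can possibly overlap, so a
genome-wide universe would overstate significance. Direction concordance
(`require_concordant_sign`) is off by default and available as a flag.

For synthetic end-to-end runs a **stand-in DE caller** is provided: per-gene
Welch t-tests on log2 normalized counts with Benjamini–Hochberg adjustment.
Library sizes are normalized with median-of-ratios size factors (each
sample's factor is the median, across genes expressed everywhere, of its
counts over the gene's geometric mean). Total-count CPM scaling was
rejected: when the DE genes' fold-change signs are imbalanced by chance, the
composition shift biases every null gene's CPM and, at 50 samples per
condition, produced hundreds of false positives in probe runs; the
median-of-ratios factor is insensitive to a minority of DE genes. Genes
with zero counts in all samples are dropped and counted in the log. Genes
constant in both groups (undefined t statistic) are assigned p = 1 when the
group means agree and p = 0 otherwise. The caller is a stand-in for real
NB-GLM machinery (edgeR/DESeq2) and is intended only for synthetic data;
real analyses should supply their own DE tables.

### Disrupted network

The interactome is a two-column edge list (a PSI-MITAB-derived dialect with
`db:` prefixes is accepted). Loading drops self-loops and duplicate
unordered pairs with logged counts, then removes every node whose degree in
the cleaned graph exceeds `hub_degree_cutoff` (default 5000) — the
treatment applied to extreme hubs such as ubiquitin C, whose thousands of
promiscuous interactions would otherwise connect everything to everything.

Construction: candidates are the common-DE query set plus all their
interaction partners; on the induced subgraph, a non-query node is retained
only if it has at least two query neighbours *and* degree >= 2, and a query
node only while it has at least one edge. Both rules are iterated to a
fixpoint. The retention constraint is monotone (adding nodes never
invalidates a retained node), so the maximal feasible subset is unique and
the result is independent of deletion order; the fixpoint also makes the
construction idempotent. A `single_pass` option applies the rules once,
for comparison — the two differ when removing a weakly attached partner
drops another partner below the thresholds. Nodes are labelled `query`,
`de_one_dataset` (significant in exactly one contrast, when that set is
supplied) or `partner`; the summary statistic `frac_de` is the fraction of
nodes with any DE evidence. A reference gene (e.g. AR) can be force-included
after pruning.

### Regulatory influence shift

Per condition, a GENIE3-style procedure regresses each gene's expression on
the expression of all transcription factors (a user-supplied panel, e.g.
the 48 human nuclear receptors) with a random forest
(`n_trees` default 1000, candidate predictors per split = sqrt(#TFs)); a TF
never predicts itself. A TF's importance for a target is its share of the
forest's total variance reduction; scikit-learn's mean-decrease-in-impurity
importances are used, which are already normalized to sum to one per target.

A TF's **network size** in a condition is the number of targets whose
importance exceeds `importance_threshold`, and its **increased influence**
is network size after minus before. Rows are ranked by increased influence
descending, ties broken lexicographically by TF id — a rule that exactly
reproduces the published top-ten orderings of both worked-example tables —
and truncated to `top_k` (default 10).

The importance cutoff defaults to **2/K** for a K-TF panel rather than a
fixed constant. Under the null a forest spreads each target's unit
importance roughly uniformly over the K candidates, so an irrelevant TF
scores about 1/K; any fixed cutoff below that level counts essentially every
TF–target pair as an edge and the size statistic saturates (measured on the
default synthetic design: ~215 of 219 targets per TF at a 0.02 cutoff,
burying the planted gainer signal). At 2/K an edge requires at least double
the null attribution; the gainer recovery and the recovered size magnitudes
were stable across cutoffs from 1/K to 4/K in sensitivity probes, and a
`threshold_sweep` utility is provided for users to repeat that check on
their own data. Because the discrete network size depends entirely on this
cutoff, absolute sizes from different pipelines are not comparable; only the
shift arithmetic and rankings are.

### Enrichment

Gene sets come from standard GMT files. Each set is scored with the same
inclusive upper-tail hypergeometric test after intersecting query, sets and
universe; correction across sets is Benjamini–Hochberg by default
(Bonferroni optional). The universe defaults to the genes tested in the DE
analysis, standard enrichment practice. A separate raw-count mode reports
per pathway the number of significant DE genes it contains. Enrichment
results depend on the gene-set database version; no live database is
fetched.

## The synthetic generator

`SyntheticDesign` fixes the study conditions; all randomness derives from
one seed through named substreams (DE assignment → counts dataset 1 →
counts dataset 2 → interactome → regulatory truth), so identical
seed+design give byte-identical outputs and stages can be regenerated
independently.

* **Counts** — negative binomial in mean–dispersion form
  (var = mu + phi*mu^2, `nb_dispersion` default 0.1, a typical RNA-seq
  biological CV^2), baseline means log-normal around 100 with a floor of 5.
  Each dataset flags `frac_de_dataset*` (default 0.1) of genes as DE with
  log2 fold changes scattered around `mean_log_fc` (default 2) and random
  sign; the `frac_shared_de` fraction (default 0.05) is DE in both datasets
  with concordant sign per gene (configurable). All-zero rows are resampled
  so downstream stages never see them.
* **Interactome** — preferential attachment (`interactome_nodes` 1000,
  attachment 2), giving the heavy-tailed degree distribution of real
  interactomes, with the top node wired up to `hub_degree` (default 200) as
  a scale-model of a >5000-interaction mega-hub.
* **Regulatory truth** — TF expression i.i.d. standard normal; regulated
  targets are linear combinations of their TFs (weights uniform 0.5–2,
  random sign) plus Gaussian noise (`regulatory_noise_sd` 0.5); unregulated
  background genes are i.i.d. noise. One designated gainer TF regulates
  `gainer_targets` = (2, 40) targets in conditions A and B respectively
  (A's targets a subset of B's), so the true influence shift is +38.

The defaults give 20 TFs, 200 non-TF genes and 50 samples per condition —
large enough for stable forest fits, small enough that a full two-condition
inference runs in about a minute on one core.

What the generator does **not** emulate: library-size confounding and batch
effects, read-level error, isoform structure, non-linear or combinatorial
regulation, feedback loops, and the correlation between a gene's DE status
and its interactome degree. Passing benchmarks therefore demonstrate that
the machinery is correct and well calibrated under the stated statistical
model, not that the biological conclusions of any particular dataset are
right.

## Benchmark problem sizes

The test suite and the acceptance script use: 20 seeded null simulations
(2000 genes, 20 samples/condition) for type-I calibration; 20 seeded power
runs (1000 genes, 5/condition, log2FC ~ 2) for DE recall; 10 seeded
1000-node interactomes with 100-gene queries for the brute-force
equivalence check; 10 seeds of the default design for edge-recovery AUROC;
and 20 seeds of a scaled design (20 TFs, 100 targets, 50 samples) with
100-tree forests for gainer recovery — forest rankings were
indistinguishable between 100 and 1000 trees in probe runs, so the
benchmarks use the smaller ensemble.

## Numerical and design choices

* Hypergeometric tails via `scipy.stats.hypergeom.sf(k-1, ...)` — exact,
  inclusive.
* BH adjustment via `statsmodels.multipletests`; verified against the
  hand-computed step-up definition in the tests.
* Random forests via scikit-learn with `n_jobs=1`; per-target random states
  derived from the run seed through `SeedSequence`, so results do not
  depend on target iteration order.
* Pruning fixpoint chosen over single-pass for idempotence; with the
  original interactome snapshot unavailable, the published network's
  492-protein/1062-interaction composition cannot distinguish the two, and
  both are exposed.
* Expression matrices for GRN inference are assumed normalized; a
  log2(x+1) flag is provided for count-scale input.
* Gene/protein identifier mapping is external (a verbatim two-column file);
  ids are otherwise opaque strings.

## Known limitations

The stand-in DE caller is underpowered relative to NB-GLM callers at very
small n and is not meant for real data. Absolute regulatory network sizes
are threshold-dependent and should only be compared within one pipeline
configuration. The published headline numbers that depend on the original
sequencing data, a specific interactome snapshot and database versions (the
213-gene common set, the 492/1062 disrupted network, specific GO p-values)
are structural guides, not reproduction targets, at synthetic scale.
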