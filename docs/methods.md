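# Methods

## Statistical model

Each locus is a set of CpG cytosines whose per-sample methylated and total
read counts are summed (count-weighted aggregation; a locus with no covered
member CpG in a sample carries an explicit `(0, 0)` missing marker and that
sample is dropped from the fit). Counts are modeled as beta-binomial with
logit-linear mean

    logit(p_ij) = β0 + β_grp·case_j + β_sex·sex_j + β_age·(age_j − mean age)

and fixed per-locus overdispersion φ, parameterized so the mixing Beta has
shape `(p(1−φ)/φ, (1−p)(1−φ)/φ)`; φ = 0 degenerates exactly to the binomial
logistic model. Age is mean-centered inside the fit — inference is invariant
to the shift and conditioning improves. The group contrast is always a
single case indicator; the combined "ABC" and "TDP" comparisons pool several
patient groups into that indicator. Significance is the likelihood-ratio
statistic of the full vs. group-free model on χ²(1); the reported `logFC` is
the group coefficient divided by ln 2, i.e. a log2 odds ratio of methylation
(negative = hypomethylation in cases). This beta-binomial formulation is a
deliberate, documented replacement for a negative-binomial GLM on paired
count channels: it models the same overdispersed-proportion data with an
explicit likelihood whose every numerical step is specified here.

A locus is tested when at least 80% of the samples in each arm (and at
least two) are informative; otherwise it is skipped with a reason. FDR is
Benjamini–Hochberg within one (comparison × level × tissue) stratum,
significance at FDR < 0.05.

### Numerical details

Newton iterations on the exact gradient and observed Hessian of the
penalized log-likelihood, with step-halving (up to 50 halvings per step),
convergence at |Δℓ| < 1e-10, at most 100 iterations, and a deterministic
start: the null model starts from the pooled-proportion intercept, the full
model from the null solution with a zero group coefficient. Fitted
probabilities are clipped to [1e-10, 1−1e-10]. Complete separation (an arm
at 0 or 1 methylation) is detected by non-convergence or |β| > 12 and
handled by refitting both models with a ridge penalty of 1e-4 on all
coefficients; such loci are flagged `ridge` in the output and their LRT uses
the unpenalized likelihoods at the penalized optima. A negative LRT from
round-off is clamped to 0, which forces p = 1.

### Dispersion

φ is estimated per locus by a method-of-moments fit of the Pearson
statistic computed *within* each sample group (so true group differences do
not masquerade as overdispersion), combined across groups, clamped to
[0, 0.5], and shrunk toward the across-locus 20%-trimmed mean with weight
proportional to the number of informative samples (prior weight 20). Loci
with fewer than four informative samples carry no own estimate and take the
prior; with no estimable locus at all the prior falls back to 0.02, a
typical bulk-tissue value. Simulation tests verify recovery (φ = 0 gives
median φ̂ < 0.01 at 30x/40 samples; φ = 0.05 is recovered within
[0.03, 0.07]) and, downstream, that the LRT stays calibrated under the null.

## Locus sets

* **CpG** — the union of covered sites across samples (the 5x floor is
  applied by the reader, mirroring the extraction-time threshold).
* **Promoter** — one locus per transcript, TSS ± 500 bp, clipped at
  chromosome bounds; transcripts of one gene with distinct TSSs stay
  distinct.
* **Window** — 500 bp windows every 250 bp, phase anchored at coordinate 0
  on every chromosome (the upstream tool's phase is unspecified; a fixed
  phase makes outputs deterministic); windows with no covered CpG anywhere
  are dropped.
* **Cluster** — CpGs covered ≥ 5x in at least one sample, chained while the
  inter-CpG gap stays ≤ 100 bp and the span ≤ 500 bp; chains of ≥ 3 CpGs
  become loci. The published region-refinement parameters "r = 5, s = 20"
  do not map unambiguously onto documented options of the originating tool
  (r is most plausibly the per-CpG coverage floor, consistent with the
  dataset-wide 5x; s could be a gap or a minimum-reads bound), so all four
  knobs are exposed explicitly rather than guessing a mapping.

## QC

Common sites are those covered ≥ 5x in *every* sample. PCA runs on centered
methylation fractions at common sites (a logit option exists but raw
fractions are the default, matching how methylation values are usually
compared); the first six PCs are reviewed by a fixed rule replacing visual
inspection: a sample is an outlier when any score exceeds 4 score-SDs, and
a tissue mismatch when its nearest tissue centroid in PC space disagrees
with metadata. Sex is approximated as ρ = chrY/(chrX+chrY) total coverage,
male above ρ = 0.1. Read-level checks (genotype concordance between tissue
pairs, ancestry outliers) are out of scope; the report reserves reason
codes so externally supplied flags can be merged.

## Annotation

Raw contexts per transcript: promoter (TSS ± 500 bp — kept equal to the
promoter-analysis flank for internal consistency), 5′-UTR and 3′-UTR
(exonic sequence strand-up/downstream of the CDS bounds), CDS, exon, intron;
non-coding transcripts contribute exon/intron only. Any ≥ 1 bp overlap
assigns a raw context. Priority: promoter > 5′-UTR > 3′-UTR > CDS > exon >
intron > intergenic. Within a gene the best raw context across transcripts
wins; CDS/exon/intron collapse to `gene_body` only *after* resolution, so an
intron can never demote a promoter hit. Across genes, identical final
contexts collapse to one record carrying all gene ids; differing contexts
keep one record per gene. CGI/enhancer/common-variant flags are plain
half-open interval overlaps.

## Integration

Overlapping DMRs of one gene are merged by transitive overlap; each group
is represented by the *largest member's own coordinates* (width ties to the
smaller start) — the literal reading of "coordinates of the largest
region" — with the union span kept as an auxiliary column. Per-sample DMR
methylation is pooled `Σmeth/Σtotal` over member CpGs (count-weighted,
consistent with aggregation elsewhere; the fraction-averaged alternative
was considered and rejected for coherence). Pearson correlation uses the
two-sided t transform with n−2 df, computed for the all-samples and
patients-only cohorts.

Group expression comparisons follow a normality-gated policy: Shapiro–Wilk
for n ≤ 50, else Kolmogorov–Smirnov against the fitted normal, gate at
α = 0.05 (the sample-size cutoff is this package's choice; the source
policy names both tests without a number). All groups normal → unpaired
t-test (2 groups) or one-way ANOVA (> 2); otherwise Mann–Whitney /
Kruskal–Wallis; > 2-group post-hoc pairwise tests are Bonferroni-adjusted;
constant groups force the nonparametric branch and are flagged. The
methylation-stratified comparison ranks samples by DMR methylation and
compares the top-k to the bottom-k (default k = 10) through the same
policy, with ties at the cutoff broken by sample id and flagged.

Expression genes require ≥ 20 samples with ≥ 10 supporting reads.

## GO enrichment and graph clustering

Enrichment is a self-contained one-sided Fisher exact test against an
explicit universe (all genes annotated to the namespace unless supplied),
replacing web-service statistics. Significant terms (p < 0.05, ≥ 2
overlapping genes) from all groups and tissues are pooled with contribution
tags, then clustered on the ontology graph. Design decisions where the
published algorithm is silent, all deterministic:

* **Adjacency** — only direct is_a/part_of edges between *selected* terms
  connect clusters ("unbroken" read as: no missing intermediate term);
  paths through unselected terms do not connect.
* **Highest parental term** — the member with the most member-descendants;
  ties to the smaller ontology depth, then lexicographic id.
* **Splitting** — clusters ≥ 25 terms, largest first; connectivity is
  recomputed after *each* removal (the per-removal reading).
* **Re-merge** — removed terms, in removal order, join an adjacent cluster
  below the 25-term limit, keyed by higher Jaccard similarity between the
  term's annotated gene set and the cluster's union (the similarity measure
  itself is unspecified upstream; Jaccard is the declared substitute),
  then smaller size, then smaller cluster id; no candidate → singleton.
* Clusters with ≥ 4 terms are exported for visualization.

An exhaustive test compares the full pipeline against an independently
written brute-force reference on every subset of random ontologies of ≤ 8
terms (split limit scaled to 3).

## Validation statistics

Clone bisulfite: sample methylation percentage = 100 × methylated CpG
calls / non-missing CpG calls pooled over all clones and positions (the
study design is 6 clones × 45 cytosines); the clone × position matrix is
emitted for lollipop display; conversion QC is the converted fraction of
non-CpG cytosines, pass at ≥ 0.95 (threshold configurable; unstated
upstream).

Long-read: per-haplotype CpG counts are filtered at ≥ 5x. Per-CpG group
comparisons treat haplotypes as the plotted units and default to the
*unpaired* rank-sum test — the source figure names the signed-rank test,
but the patients-vs-controls contrast is between independent samples;
`paired=True` forces the signed-rank variant for genuinely paired designs.
The region-level test pools haplotypes per sample (samples are the
independent units, avoiding pseudo-replication) and reuses the
beta-binomial engine with sex and age covariates, with φ defaulting to
0.02 for a single region.

## Synthetic data

The generator emulates the target study design: six groups (25 per
patient group, 42 controls), paired FCX/CER tissues, sex frequencies and
age ranges bracketing the published demographics (ages uniform within
group-specific ranges, making age group-confounded as in the cohort);
CpGs in dense clumps of 4–12 sites 5–60 bp apart (the
reduced-representation site distribution), ~20% of clumps being
hypomethylated islands (baseline Beta(2,18)) over a hypermethylated
background (Beta(17,3)); negative-binomial coverage (mean 20, size 5);
beta-binomial counts at φ = 0.02; zero chrY coverage in females and halved
chrX coverage in males; planted DMRs as logit-scale shifts (default |δ| = 2)
in the affected group and tissue. Member CpGs of a planted DMR share one
mid-range baseline (drawn U(0.3, 0.7)): a DMR is modeled as a coherent
region, which also makes the pooled region-level logit shift equal the
per-CpG δ — the quantity the effect-recovery check measures. Expression for
DMR-anchored genes is linear in per-sample DMR methylation (slope −4 on
the normalized scale, noise SD 0.5, clamped at 0); a toy GO DAG is grown by
preferential attachment with annotations propagated to ancestors, and a
subset of terms concentrates the DMR-linked genes so planted effects
propagate into enrichment.

What it does not emulate: read-level artifacts (mapping, conversion
failure in the genome-wide data), cell-type composition, spatial
correlation of methylation beyond planted regions, batch effects, and
realistic LD-like structure among CpGs. Passing tests therefore demonstrate
the *statistical machinery* — calibration, recovery, determinism, rule
semantics — not robustness to those real-data pathologies.

### Problem sizes

Default end-to-end runs and the acceptance script use a reduced cohort
(6–8 subjects per group, one tissue, ~360 CpGs) — enough to exercise every
stage while keeping a full pipeline run in seconds; calibration checks use
purpose-built count matrices (2000 null loci at 20 vs 20 samples; 120
planted window-level DMRs at 25 vs 25). The full study-sized configuration
(25/42 per group, both tissues) is the `SimulationConfig` default and runs
in minutes.

## Coordinates

Internally everything is 0-based half-open; conversion to the 1-based
inclusive printed style happens only in the result-table writer, so printed
width always equals internal width. Published loci tables are themselves
ambiguous at the ±1–2 bp level (a "185 bp" region whose printed coordinates
span 186–187 bases), which is why the convention is fixed at the writer
boundary and documented rather than matched to any single printed width.

## Known limitations

* The beta-binomial engine is not a bit-level reproduction of the
  NB-GLM tooling used upstream; effect sizes agree in expectation but not
  per-locus numerically.
* Dispersion shrinkage uses a global trimmed-mean prior, not a
  coverage-dependent trend.
* The PCA outlier rule is a declared substitute for visual review.
* Fisher enrichment ignores the selection of query genes through the FDR
  step (as does the replaced web service).
* The ontology clustering tie-breaks are deterministic choices where the
  published algorithm is silent; alternative tie-breaks yield different
  (equally defensible) partitions.
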