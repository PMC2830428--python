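# Methods

## Promoter definition

A gene's promoters are defined operationally from TSS evidence: positions
on the same (gene, chromosome, strand) are clustered, and each cluster is
one promoter. Two clustering dialects are provided:

- **linkage** (default): single-linkage chaining on sorted positions — two
  adjacent positions join iff their distance is ≤ the gap (inclusive
  boundary), so runs of ≤ gap steps chain arbitrarily far. It is
  order-independent and uses the gap parameter literally.
- **window**: a fixed window anchored at each cluster's first position; a
  position more than one gap from the anchor opens a new cluster.

The gap defaults to 500 bp, the standard promoter-clustering radius for
full-length-cDNA TSS collections. Duplicate positions are collapsed before
clustering (clone redundancy should not alter architecture), with support
values summed. A gene with TSS evidence on both strands or two chromosomes
keeps the groups separate — opposite-strand TSSs cannot share one
promoter's directional architecture — sums the cluster counts, and warns.

Promoter counts map deterministically to four classes: 1 → SP, 2 → AP2,
3–4 → AP3_4, ≥ 5 → AP5plus. Coordinates are BED-convention 0-based
half-open throughout; a 1-bp BED interval's start is the TSS (for either
strand, the producer's responsibility).

## Differential Expression Ratio

The DE-call matrix is tri-state per gene × dataset: DE, measured-not-DE,
not-measured. DER = n_DE / n_measured, defined only when n_measured > 0.
The measured-fraction filter keeps genes with
n_measured ≥ ⌈min_fraction × n_datasets⌉; the ceiling-with-≥ reading
implements "at least" semantics on an integer count (e.g. 5 % of 476
datasets → threshold 24), and a direct `min_count` override exists because
the floor/ceiling choice at the boundary is a genuine convention choice.
DE calling itself (moderated tests, q-values) is upstream and out of scope.

## Gene structure

Each gene is reduced to one representative transcript: the one with the
longest spliced (mature) length, with deterministic tie-breaks (larger
genomic span, then lexicographically smallest transcript id). Spliced
length is the default because the metrics describe transcript structure;
`criterion="span"` switches to genomic span.

UTR lengths default to genomic coordinate differences — 5′ UTR is the
distance from the transcription start to the coding start on the strand's
upstream side, 3′ UTR from coding end to transcription end — rather than
spliced UTR lengths; `utr_mode="spliced"` counts only exonic bases. CDS
length is always the spliced exonic overlap with the coding span.
Non-coding transcripts (thickStart = thickEnd) report CDS/UTR fields as
missing and are excluded from CDS/UTR summaries while contributing to
genomic/exon/intron metrics. Invariants maintained for every model:
genomic = total exon + total intron, introns = exons − 1, and mirroring a
model's coordinates swaps its UTRs.

## Annotations and network

Gene lists are merged by plain set union ("non-redundant"). Flags are
booleans over the analysis universe; duplicability is tri-state
(duplicate / singleton / unknown) and unknown genes are excluded from
duplicability denominators only. No cross-database identifier mapping is
attempted: all inputs must share one symbol namespace, and the pipeline
fails with an explicit error when fewer than half of an input's ids
overlap the profiled genes (an almost-sure sign of a namespace mismatch).

The interaction network is simple and undirected: self-pairs are dropped,
orientation and duplicates collapse. Degree is the number of distinct
partners. Genes absent from the network get *missing* degree by default —
curated interactome coverage is partial, and degree comparisons should
cover mapped proteins only — with an `absent_degree="zero"` policy
available (used when the quantity of interest is the generative mean of a
simulated degree sequence, where zeros are real).

## Statistical core

Written from first principles; `scipy.stats` implementations serve as
independent cross-checks in the test suite only.

- **Fisher exact test**: cell `a` is hypergeometric with fixed margins;
  masses are computed in log space (log-gamma binomials) for stability at
  large margins. The two-sided rule is the point-probability convention —
  sum the probabilities of all tables whose mass is ≤ the observed mass,
  with a 1 + 1e-7 relative gate to absorb floating-point ties — matching
  R's `fisher.test`.
- **Wilcoxon rank-sum**: the statistic is the sum of midranks of the first
  sample. For ≤ 30 tie-free observations the exact null distribution is
  built by subset-sum recursion; the two-sided p is the mass at least as
  far from the null mean as observed (equal, for the symmetric tie-free
  null, to 2·min(tails) capped at 1). Otherwise a normal approximation
  with the standard tie correction and a 0.5 continuity correction is
  used, matching R's `wilcox.test(correct = TRUE)`. Forced exact mode with
  ties falls back to full enumeration over rank assignments when feasible.
  The approximation is within 0.01 of the exact p once both groups have
  ≥ 10 observations; with smaller groups the discrepancy can reach ≈ 0.04
  mid-distribution, which is why exact mode is the automatic choice there.
- **Ladder**: four comparisons in fixed order — AP (pooled) vs SP, AP2 vs
  SP, AP3_4 vs AP2, AP5plus vs AP3_4 — plus a per-class summary row
  (medians for continuous metrics, percentage fractions for flags). Both
  tests default to two-sided alternatives (the convention of the standard
  analysis environments when sidedness is unstated); no multiple-testing
  correction is applied and raw p-values are reported, with values below
  2.2e-16 *displayed* as `<2.2e-16` but stored at full precision.
  Percentages use half-up rounding (so 12.5 % at 0 decimals prints 13 %,
  not banker's 12 %).

## Synthetic cohort

The generator emulates the five real input kinds with one master seed and
fixed labeled substreams (gene attributes, TSS, DE matrix, gene models,
lists, network), so outputs are byte-reproducible and adding a file type
never perturbs the others. Defaults are the published genome-wide study
conditions: class sizes 7,291 / 3,772 / 2,941 / 1,176; 476 expression
datasets with measurement probability 0.6; DER medians
0.50 / 0.52 / 0.54 / 0.56; cancer-driver fractions 2.9–9.7 %; disease
fractions 16.4–26.6 %; duplicate fractions 67–85 % (with ~3 % of genes of
unknown duplicability); degree means 6.5 and 10.5 at the SP and AP ≥ 5
endpoints with linearly interpolated 8.0 / 9.0 between (the interior
means are interpolations, not published values).

Generative laws, chosen for bounded/overdispersed realism with few knobs:

- **TSS**: each gene's promoter count is drawn inside its assigned class
  (AP3_4 uniformly 3–4, AP5plus uniformly 5–8); clusters carry 1–3 TSSs
  with within-cluster steps < gap/3 and inter-cluster gaps > gap, so the
  profiling stage recovers the intended class *exactly* by construction.
- **DER**: per-gene DE rate ~ Beta with class-specific median and shared
  concentration 20; the Beta shape is found by root-finding on the Beta
  quantile since the median has no closed form. Calls are Bernoulli per
  measured cell, so realized DER adds binomial noise around the rate.
- **Lengths**: lognormal with class-specific scale equal to the class
  median (σ = 1 for total intron length; tighter σ for exon totals, UTRs
  and exon counts), partitioned into per-exon/per-intron pieces by
  Dirichlet weights. About 10 % of multi-exon genes get a shorter second
  isoform to exercise representative selection.
- **Degrees**: negative binomial (dispersion 1) per class, realized as an
  edge list by configuration-model stub matching; an odd stub total is
  repaired by one extra stub (recorded in the manifest). Cleaning removes
  the rare self-loops/multi-edges, biasing class means by ≪ one standard
  error at default sizes.
- **Flags**: independent Bernoulli per gene given class.

Within a gene, quantities are drawn independently given the class: the
generator plants marginal class effects only, not the inter-feature
correlation structure of real genes (real DER, length and degree co-vary
within genes). Passing recovery tests therefore demonstrates that the
pipeline measures planted marginal effects correctly — not that it would
disentangle correlated confounders in real data. The generator also makes
no attempt at realistic microarray noise, tumor genomes, or PPI topology
beyond the degree sequence.

## Problem sizes and calibration checks

The test suite verifies oracle equivalence exhaustively where cheap (all
2×2 tables with N ≤ 40 against exact-rational enumeration; full
permutation enumeration of the rank-sum null for n ≤ 10) and by seeded
sampling elsewhere (1,000 random TSS sets against a connected-components
oracle; 1,000 random gene models; 100 random graphs). Parameter recovery
runs on the full default cohort (15,180 genes × 476 datasets, ≈ 15 s);
null calibration uses 500 replicates at 400 genes/class via an in-memory
DER sampler rather than full file bundles, checking each ladder rung's
rejection rate at α = 0.05 stays within [0.03, 0.07].

## Known limitations

- The clustering dialect of the original promoter-database pipeline is not
  recoverable; both provided dialects agree except on chains that span
  more than one gap, and linkage is the default.
- Identifier harmonization across annotation sources is the caller's
  responsibility; the pipeline only detects gross namespace mismatches.
- The exact Fisher p-value is computed in log space; agreement with
  exact-rational enumeration is to ~1e-12 relative, not bit-exact.
- Flag draws are independent Bernoulli, so a synthetic gene can be both a
  disease gene and a cancer driver but duplicate/singleton are mutually
  exclusive by construction, mirroring the real lists' semantics.
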