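# Methods

## The problem

Adaptive laboratory evolution (ALE) experiments propagate replicate
microbial populations under a fixed selection pressure and sequence the
endpoints. Mutations that recur across independent replicates
(*convergence*) are the primary evidence of selection, but convergence is
often only visible at aggregate scales: different replicates may hit a
gene, its promoter, a ribosome binding site, or another gene in the same
operon or regulon, all pushing on the same function. `aleflow` formalizes
this as a multiscale annotation framework, tests each scale for
statistically significant convergence, and labels the contributing
mutations as *key mutations*.

## The annotation framework

Seven nested annotation scales are analyzed:

1. **genomic_feature** — genes, TFBS, promoters, terminators,
   attenuator-terminators, RBS, and derived intergenic regions. Regulatory
   features may overlap genes; no de-overlapping is attempted.
2. **gene_and_intergenic** — genes plus intergenic regions only: the
   traditional convergence unit, kept as its own scale so the gain from
   richer annotations can be quantified.
3. **TU** — transcription units grouping genes with their regulatory
   features.
4. **operon** — groups of TUs.
5–7. **regulon / pathway / COG** — gene-set functional annotations.

Internal coordinates are 0-based half-open; GFF3 input (1-based inclusive)
is converted on read. Strand is stored but never used: all statistics are
driven by nucleotide footprints. Intergenic regions are derived as the
maximal gene-free intervals and named by their flanking genes
(`geneA/geneB`, with `.` at a chromosome end), so genes plus intergenic
regions tile the genome exactly.

### Length rules

Feature lengths feed the null model, so their definitions matter:

* gene / regulatory feature / intergenic / TU — plain interval length;
* operon — nucleotide **union** of its TUs;
* regulon — union of the spans of its member genes' TUs;
* pathway / COG — the regulon rule minus positions of genes in those TUs
  that do not belong to the annotation (positions shared with a member
  gene are kept).

Overlapping TUs contribute their union, never their sum; summing would
double-count shared nucleotides and overstate the null expectation of
heavily overlapped regulons.

## Mutation ingestion

Only endpoint-flask samples are modeled; all samples sharing an ALE id are
that ALE's endpoint. Three preparation rules apply, in order:

1. population-sample calls with frequency **< 0.5** are dropped (calls at
   exactly 0.5 are kept; clonal calls are exempt);
2. hypermutator-flagged samples are discarded entirely;
3. duplicate calls within one endpoint collapse to a single consolidated
   mutation carrying the maximum observed frequency.

Mutation identity is `(position, span, type)` within an (experiment, ALE)
pair. Alleles are not part of the identity: no downstream statistic uses
them, and collapsing on coordinates is robust to caller-specific allele
representations. The same mutation in two ALEs stays distinct — recurrence
across ALEs is the signal being measured.

## Mapping and the convergence DAG

A mutation occupies the half-open interval `[position, position + span)`
(insertions: their 1-nt point). At the genomic_feature scale it maps to
every gene/regulatory feature sharing a nucleotide with that interval, or
to exactly one intergenic region if none does. Genes and regulatory
features then map to the TUs listing them; intergenic hits map to TUs by
coordinate overlap (possibly none); TUs map to their operons and to the
functional annotations of the genes they host. One mutation can therefore
yield several mutated-feature instances, and several mutations can
converge on one feature.

For pathway and COG the mapping honours the length footprint: a mutation
reaches the annotation only if its interval overlaps the counted
positions (TU union minus non-member genes). Without this restriction
mutations inside excluded non-member genes would count as observations
against a null that assigns those positions no probability, and the test
would be anti-conservative — the effect is large enough to destroy type-I
calibration, which is why the footprint rule is load-bearing and not a
nicety.

The per-experiment convergence DAG records the flow: mutation-type source
nodes → genomic features → TUs → operons and functional annotations. Edge
weights count mutations flowing along each link; every non-source node's
weight equals the sum of its incoming edge weights. A mutation reaching
one broad feature through two children (a gene and a TFBS inside it)
carries both edges in the DAG but counts **once** in that feature's
observed statistic: the flow diagram preserves visual bookkeeping while
the test never counts one mutational event twice. The default flow-table
export contracts TU nodes (their convergence is largely redundant with
operons); `include_tu=True` gives a lossless export that round-trips.

## The convergence test

The null model assumes a uniform per-nucleotide mutation probability, so
feature `f` at a scale is hit with probability
`p_f = length(f) / L_genome`. Scales that do not tile the genome get a
reserved *remainder* pseudo-feature covering the uncovered length;
because features at a scale may overlap, the raw vector is renormalized
to sum to one. The remainder completes the probability space but is never
eligible for significance.

Each of `N = 10,000` iterations (default) distributes the experiment's
`n` consolidated mutations over the scale's features with one multinomial
draw. The empirical p-value for feature `f` with observed count `k_f` is

    p_f = (1 + #{iterations with simulated count >= k_f}) / (1 + N)

Add-one smoothing keeps the minimum attainable p at `1/(N+1)` rather than
an impossible 0. For a single feature the simulated count is
`Binomial(n, p_f)`, giving a closed-form oracle (`exact_tail_oracle`,
`scipy.stats.binom.sf`) that the test suite checks the engine against to
within three Monte-Carlo standard errors.

**Multiple testing.** One experiment is one statistical family. The
all-scales runner corrects with Bonferroni over the **total** number of
feature tests performed across every scale of the experiment; by the
union bound this keeps the per-experiment family-wise false-positive rate
at alpha even though seven mutually dependent scales are tested jointly.
Correcting per scale instead bounds each scale at alpha but compounds to
a per-experiment rate of roughly 20–30% on null data — measured, not
hypothetical — so the per-experiment family was chosen. The single-scale
entry point (`run_enrichment`) uses the per-scale count for standalone
use, and accepts an explicit denominator.

A feature is **significantly enriched** when it hosts more than one
mutation and its corrected p-value is below 0.05. The more-than-one rule
blocks the degenerate case of a single mutation in a tiny feature being
"enriched" with no convergence whatsoever.

**Key mutations.** A mutation is key when at least one feature it maps
to, at any scale considered, is significant; each key mutation carries
its (scale, feature) justifications. The key set grows monotonically as
scales are added — adding an annotation type can only reveal more
convergence, never hide any — and the per-experiment proportion of
mutated genomic features hosting key mutations is reported per cumulative
scale prefix to show that gain.

## Condition association

The replicate unit is the ALE: experiments set conditions, ALEs inherit
their experiment's labels, and each ALE either did or did not acquire a
mutation in a feature. For every (mutated feature, condition label) pair
a 2×2 table counts ALEs by label presence × mutation presence, tested
with a one-sided Fisher's exact test in the enrichment direction — the
question is directional because association is defined as odds ratio > 1.
Bonferroni runs over all pairs actually tested, and the stricter
alpha = 0.01 limits association false positives. Heatmap export uses the
Haldane–Anscombe correction (add 0.5 to every cell) so infinite odds
ratios render finitely; mutation co-occurrence between two features is
the Pearson correlation of their binary per-ALE presence vectors
(undefined for constant vectors, reported as NaN).

## The synthetic-data generator

The generator emulates the anatomy such a study needs, at desk scale:

| parameter | default | rationale |
|---|---|---|
| genome length | 50,000 nt | ~1% of a bacterial chromosome; large enough for ~40 genes plus regulatory features |
| genes | 40 × 600–1400 nt | typical bacterial gene lengths, non-overlapping, ≥ 50 nt gaps |
| TUs / operons | 1–3 genes per TU, 1–2 TUs per operon | shallow but real nesting; every fourth promoter also drives the next TU so one feature can regulate two operons |
| regulatory features | promoter 40 nt + terminator 30 nt per TU, RBS 12 nt on half the genes, 12 TFBS (half inside coding sequence), 4 attenuator-terminators | exercises feature-overlap semantics |
| regulons / pathways / COGs | 6 / 5 / 8 over TU or gene subsets | pathways and COGs draw gene subsets so the length-exclusion rule is active |
| experiments × ALEs | 1 × 8 | an 8-replicate experiment, the convergence unit |
| background mutations | Poisson(2.0)/ALE, uniform positions | uniform placement matches the null exactly, so calibration tests are self-consistent |
| mutation types | 80% SNP, 10% DEL, 5% INS, 5% MOB; indel spans 1–10 | rough ALE-like mixture; configurable |

Planted targets add SNPs uniformly within a feature's nucleotide extent
(2 per ALE across all ALEs by default: 16 per target), optionally only in
experiments carrying a linked condition label. The standard recovery
scenario plants a gene, a promoter and an operon; for the operon the
mutations spread over the whole operon extent, so convergence concentrates
at the operon rather than any single child. Plantable operons are
restricted to a footprint ≤ 10% of the genome: desk-scale packing can
produce operons covering an unrealistic share of the chromosome (real
operons are ~0.1%), and against a length-proportional null such a target's
expected count is so high that no plausible planted signal would be
distinguishable — the plant would violate the generator's own contract
that planted features are recoverable.

The recovery scenario uses a background mean of 1.0 mutation/ALE. Real
cohorts run ≈ 2.8×10⁻⁶ mutations per nucleotide per ALE (≈ 0.14/ALE at
50 kb), so 1.0 is conservative upward; the level matters because every
background mutation that lands inside a significantly converged broad
feature is, by definition, a key mutation, and at this level planted keys
dominate: measured mean precision ≈ 0.95 and recall 1.0 against planted
ground truth over 20 seeds.

What the generator does **not** emulate: position-specific mutation rates
(e.g. indel hotspots in mononucleotide runs), hypermutator genotypes,
clonal interference, midpoint samples, realistic allele spectra, and
multi-label condition structure beyond occasional double labels. Passing
tests therefore demonstrate correctness of the machinery and calibration
under the method's own null — not that the uniform-rate null is true of
any real genome.

## Numerical choices and degenerate inputs

* All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give bit-identical outputs. The all-scales runner derives one seed
  per scale (`seed + i`); the pipeline derives one seed block per
  experiment.
* Ties in the permutation test count toward the tail (`>=`), the
  conservative direction.
* An observed count of zero gives p = 1 without special-casing.
* A scale with no features raises a configuration error; an experiment
  with zero mutated features reports its key proportion as NaN.
* Fisher odds ratios: +inf when `b·c = 0` with `a·d > 0`; NaN (never
  associated) when both products are zero.
* Intergenic derivation with zero genes yields one genome-spanning region.
* Feature order in every exported table is sorted, so reruns are
  byte-identical.

## Problem sizes

The shipped tests and the acceptance script run everything at desk scale:
30 single-feature oracle scenarios at 10,000 iterations; 200 null
cohorts (~40 mutations each) for type-I calibration; 20 seeds of the
50 kb recovery scenario; 200 label shuffles for association calibration;
exhaustive 2×2 enumeration to N = 12. The implementation itself is
size-agnostic — the permutation engine is a vectorized multinomial and
mapping is interval-tree based — so genome-scale inputs are limited by
memory on the `iterations × features` simulation matrix, about 0.8 GB at
10,000 iterations × 10,000 features in int64.

## Known limitations

* The uniform per-nucleotide null is a modeling assumption; features with
  elevated local mutation rates will be over-called. Parameterizing
  per-feature rates is a natural extension (the null-model probabilities
  are a plain vector).
* Mapping uses interval overlap, so multi-nucleotide deletions have a
  slightly larger effective footprint than the point-mass null assumes; at
  ALE-realistic indel fractions the effect on calibration is within
  Monte-Carlo noise, but a cohort dominated by large deletions would need
  a span-aware null.
* Regulatory features listed on a TU they do not physically overlap
  propagate to that TU's broad annotations while contributing no length to
  them; this mirrors how curated regulatory networks describe action at a
  distance and is mildly anti-conservative for those annotations.
* Association treats ALEs within an experiment as exchangeable replicates;
  conditions are constant within an experiment, so effective sample size
  for association is the number of experiments carrying each label.
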