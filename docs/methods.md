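# Methods

This note records the models, conventions and parameter choices behind
`nascentq`, and what the synthetic studies used in its tests do and do
not demonstrate.

## Coordinates and counting

All internal coordinates are 0-based half-open; GTF input/output
converts from the 1-based inclusive convention at the boundary. TSS and
TTS are single base positions in biological orientation (the TSS of a
minus-strand transcript is its rightmost genomic base), and every
"upstream/downstream" statement follows the direction of transcription.

Each read contributes one count at a single representative base. The
default rule is the read's **3' end** — for run-on assays this is the
position of the transcriptionally engaged polymerase, the quantity the
pausing and readthrough statistics are about. A `five_prime` rule is
provided for protocols that preserve 5' ends (e.g. cap-retaining
variants). The rule is stored in cache metadata and caches built under
different rules refuse to be compared, because a silent mix would shift
every promoter window by roughly a read length. Secondary,
supplementary, duplicate and unmapped alignments are excluded by
default.

Counts are kept per (chromosome, strand) at two resolutions: sparse
site arrays and dense 200-bp bin sums tiled from coordinate 0. The
200-bp width balances bin-sum reuse against edge work for gene-scale
intervals; caches with different widths are incompatible, so the width
is changed only by an expert flag. A region query sums whole interior
bins and resolves the two partial edge bins from the site arrays —
by construction identical to pure site summation, which the tests
assert bitwise. Conservation (site sum = bin sum = total, per track) is
checked on every build. bedGraph ingestion assigns an interval's value
to every base it covers (PRO-seq 3'-end tracks are single-base in
practice) and accepts the negative-value convention on minus-strand
files; fractional values are fatal unless explicit rounding is
requested, since downstream statistics assume integer counts.

Per-chromosome processing keeps the resident working set proportional
to the largest chromosome track, not the genome; caches persist as
versioned pickles and a version mismatch raises a typed error (the CLI
responds by rebuilding).

## Promoter windows, gene bodies, major transcripts

The promoter-proximal window of a TSS maximizes sense-strand reads over
50-bp candidates at a 5-bp step spanning ±500 bp of the TSS in
transcription coordinates (191 candidates). Reads are pooled across
**all** samples so every condition is quantified on one region;
per-condition windows would confound region choice with the effect
under test. Ties prefer the window whose start offset is closest to the
TSS, then the more upstream one — deterministic and TSS-anchored. A
fully silent span yields the TSS-centred window flagged `zero_signal`.

The gene body is [TSS + 1 kb, TTS]; genes of ≤ 1 kb have an explicitly
undefined body and never enter body-based statistics (undefined is a
value, not zero). The pausing index is the promoter/body density ratio;
it is undefined (not 0) when the body has no reads, and is invariant to
any library scaling applied to both regions.

Transcript groups collapse transcripts with identical (TSS, TTS).
Members may differ internally; the group's last exon is taken from the
member with the longest terminal exon, an inclusive choice that gives
the readthrough denominator the largest annotated support. Major-
transcript selection ranks groups by pooled promoter count, then pooled
body count (the tiebreak matters exactly when two groups share a TSS),
then span length, then coordinates. Selection uses raw pooled counts
and is invariant to uniform scaling. A gene_id whose transcripts span
several chromosomes or strands is split into suffixed single-locus
genes rather than rejected.

## Differential transcription

The differential model is a negative-binomial GLM over the full design
(condition of interest plus declared covariates), Wald-tested on the
requested contrast with BH correction; PyDESeq2 supplies the fitting
machinery. Normalization factors are median-of-ratios on the gene-body
matrix unless the user supplies factors (spike-ins); either way the
same per-sample factors rescale promoter and enhancer counts so all
regions live on one scale. Confounded designs (condition aliased with a
covariate, detected by a model-matrix rank check) and single-replicate
levels are fatal by default. All-zero features are excluded and
reported, not silently dropped.

The permutation background implements a read permutation between
conditions at count level: each feature's pooled total is redistributed
across samples multinomially with probabilities proportional to library
size — equivalent in distribution to reassigning that feature's reads
to samples at random — and the observed |log2 fold change| (normalized
condition means, pseudocount 0.5) is ranked against `n_perm` permuted
statistics, p = (1 + #{perm ≥ obs}) / (1 + n_perm). With the default
100 permutations the resolution floor is 1/101.

## Alternative TSS/TTS usage

Distinct pausing clusters (or termination clusters) of one gene are
compared between two conditions with the Cochran–Mantel–Haenszel test.
For a site pair, each stratum is a 2×2 table — rows the two sites'
counts, columns one sample from each condition — and the statistic is

chi² = (Σ_k (a_k − E[a_k]))² / Σ_k Var(a_k), 1 df, with hypergeometric
E and Var given each table's margins, no continuity correction by
default (flag available), and the Mantel–Haenszel common odds ratio
(Σ a_k d_k / N_k) / (Σ b_k c_k / N_k). Strata with a zero row or column
margin are uninformative and skipped with a count; a record whose
strata are all degenerate is flagged undefined and excluded from FDR.

**Pairing of samples into strata.** For balanced designs the default is
matched positional pairing: replicate *i* of condition A with replicate
*i* of condition B, giving disjoint strata. Building strata from all
n_A × n_B combinations reuses each sample in several strata; those
strata are positively correlated, the variance denominator understates
Var(Σ(a_k − E_k)), and the test's false-positive rate inflates severely
(measured ≈ 0.17 at nominal 0.05 for a 2v2 null). Matched pairing
measures ≈ 0.05. Unbalanced designs fall back to all combinations —
calibration there is approximate and flagged — and `pairing=` exposes
both modes.

TSS pairs must be ≥ 1 kb apart (closer promoter windows would share
signal); each TSS is quantified by its own data-driven 50-bp window,
keeping the ATSS counts consistent with the quantification engine. TTS
sites are quantified over [−1 kb, +2 kb) around the TTS in
transcription coordinates; a TTS inside another gene or with another
gene within 3 kb downstream is dropped before pairing, and a TTS pair
is tested only when the two windows are disjoint (≥ 3 kb apart) so no
read can sit in both. Pairs whose combined table total across strata is
below 20 reads (configurable) are reported untested with a reason code
rather than contributing noise calls. BH FDR is applied genome-wide
within each family (ATSS and ATTS separately).

## Readthrough

Per sample, the readthrough ratio is raw downstream-window (50 kb past
the TTS, clipped at chromosome ends) count over raw last-exon count —
raw because the ratio is scale-free within a sample; it is undefined
when the last exon has no reads. Genes must be active — promoter reads
> 0 and body density strictly above 4 reads/kb after scaling the
sample's total to 10⁷ — in **every** sample by default (`activity=
"pooled"` relaxes this), and are excluded when a gene active in at
least one sample lies within the 50-kb downstream window on either
strand: co-directional and convergent neighbours both contaminate the
window. Condition changes are tested with the same CMH stratification
(rows = downstream vs last-exon counts), BH across tested genes;
direction is the sign of log2(mean ratio B / mean ratio A).

## Enhancers

De-novo transcript calling is an upstream step (an external caller run
on pooled reads); this package consumes its stranded BED output. Calls
overlapping any gene's exclusion zone — 2 kb upstream of the TSS to
20 kb downstream of the TTS, in that gene's transcription coordinates —
are dropped. Divergent pairing: a minus transcript whose 5' end lies at
most 1 kb (configurable; the upstream tools leave this geometry open)
upstream of a plus transcript's 5' end, matched greedily by 5'
distance after coordinate sorting, each transcript in at most one pair.
Enhancer activity is the both-strand read count over the pair's union
span, normalized with the shared gene-body factors. A minimal
threshold-based transcript caller (`naive_transcript_calls`) ships for
fixtures and tests only and is documented as non-production.

## The synthetic-data generator

`nascentq.simulate` emulates the distinctive shape of run-on data: a
promoter-proximal peak (normal around +40 nt from the TSS, sd 8 —
within the 20–60 nt band where polymerase pauses), uniform gene-body
coverage at a set reads/kb, a termination-zone accumulation within
400 bp upstream of the TTS, and an exponential readthrough tail (mean
decay 8 kb) carrying a per-condition fraction of the terminating mass
past the TTS. Per-gene condition multipliers plant differential
effects, per-gene batch multipliers plant confounders, per-sample
library scales plant depth differences, and per-condition usage vectors
split a gene's output across isoform groups to plant ATSS/ATTS events.
Reads are fixed-length 30-bp perfect alignments whose 3' end is the
sampled site; one seed fixes every draw, and outputs (sorted BAM or
bedGraph pairs, GTF, design table, truth tables) are byte-reproducible.

What the generator does **not** emulate: mappability gaps, multimapping
and alignment error, antisense and intergenic background transcription,
overlapping gene architectures, UMI/duplication structure, or
biological overdispersion beyond Poisson sampling around per-gene
rates (the differential tests add NB dispersion at count level
instead). Passing tests therefore demonstrate correctness of the
statistics and plumbing under clean signal at realistic depths — not
robustness to every artefact of real libraries.

Study sizes used in the verification suite, chosen to give stable
Monte-Carlo estimates at desk scale: 1,000 random tracks for the
window-scan oracle; a 10,000-read alignment with 100 random queries for
the counting oracle; 500 random strata sets for the CMH oracle; 5,000
null genes (2v2, ~200 reads/sample/gene) for type-I calibration; 200
planted ATSS genes (90:10→10:90, ~500 promoter reads/sample), 200
planted ATTS genes (80:20→20:80, ~400 termination reads/sample) and 50
readthrough genes (fraction 0.1→0.6) for power; 250 genes × 8 samples
(50 true 2-fold, gene-specific ~3-fold batch effects on half the genes,
NB dispersion 0.05, base mean 500) for the batch study. At these
settings measured type-I error sits in 0.048–0.051, planted-event power
at 100%, and batch-aware recovery around 84–92% across seeds (a single
draw of 50 true genes has a binomial SD of ~5 percentage points;
null-call rates similarly scatter ±1.5 points around the nominal 5%).

## Known limitations

* Quantification is bound to the supplied annotation; unannotated or
  badly annotated genes are invisible except through the enhancer path.
* The CMH framework tests association, not mechanism: a usage shift at
  two pausing regions can also reflect post-initiation regulation, and
  closely spaced sites below the separation thresholds are untestable.
* The fixed 50-kb readthrough window is a pragmatic stand-in for the
  true, gene-specific polymerase dissociation zone.
* For unbalanced designs the all-combinations stratification is the
  only option and its calibration is approximate (see above).
* bedGraph ingestion of long constant intervals is linear in interval
  length; it is intended for single-base 3'-end tracks.
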