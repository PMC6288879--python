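# Methods

`evoreseq` analyses an evolve-and-resequence (E&R) experiment of the kind
used to select *Nasonia vitripennis* for associative learning: four
replicate pairs of selected and control lines founded from one outbred
base population, ten generations of selection, pooled whole-genome
sequencing of 40 females per line, and head-tissue RNA-seq of the same
eight lines. The package implements the downstream statistics — a
per-variant binomial GLMM divergence scan, pooled F_ST, a three-method
consensus differential-expression screen, and rank-rank hypergeometric
overlap — together with a synthetic-data generator that reproduces the
statistical structure those analyses assume.

## Forward simulation

Each line evolves by Wright-Fisher resampling: per generation,
`2 * n_mothers` gametes (default 100; 50 reproducing females per line) are
drawn binomially from the parental allele frequency. The shared founder
frequency vector is drawn once per run (default uniform on 0.05–0.95,
mimicking a filtered SNP panel from an outbred base population kept at
N_e = 173; the SFS of such a panel is flat over intermediate frequencies
after the alternate-allele coverage filter). Selection acts in the
selected lines only, as the deterministic shift `p* = p(1+s)/(1+ps)`
applied at planted loci before gamete sampling; this emulates consistent
directional selection rather than the experiment's truncation scheme,
which is all the divergence scan requires. Note the shift map is concave,
so under drift the replicate mean lies slightly below the iterated
deterministic recursion (Jensen's inequality); the tests account for this.

Haplodiploidy is available as an option: female and male frequencies are
tracked separately, daughters sample `2 N_f` gametes from the parental
mean `(p_f + p_m)/2` and haploid sons sample `N_m` maternal gametes. With
male transmission disabled the recursion collapses exactly onto the
diploid one (bit-identical female trajectories, since male draws use a
separate random substream). The diploid model is the default: the
divergence statistics are agnostic to ploidy, which only rescales drift.

Hitchhiking is emulated by block-correlated drift: the binomial draws of
loci in the same linkage block are coupled through a Gaussian copula with
correlation `block_rho`, which preserves exact binomial marginals while
making trajectories co-move. This is sufficient to produce clustered
significant SNPs for the region-clustering layer; no recombination map is
simulated.

Pooled sequencing is two-stage: the pool's allele count is
Binomial(2·40, p) (40 diploid females), per-site coverage is negative
binomial around the library mean (`var = mu + d mu^2`; `d = 0` gives
constant coverage; default library means span the 25–139x range of the
emulated data), reads are binomial in the pool frequency, and each read
miscalls to a uniformly chosen other base with probability `error_rate`
(default 1e-3), which is what creates rescuable "triallelic" sites. The
read-frequency variance therefore follows the compound form
`p(1-p) [1/(2n) + (1 - 1/(2n))/C]`, which the tests verify.

RNA-seq counts are negative binomial with mean
`L_j q_g 2^(offset + regime * lfc_g)` and common dispersion phi (default
0.05, a typical within-line biological CV of ~22%). Line offsets are
shared within a replicate pair (SD 0.5 by default) with smaller
line-specific noise (SD 0.1): pair-level structure is what dominates the
emulated data's PCA, and pair is also the blocking factor of the NB GLM.
Planted effects: `n_de` transcripts carry |log2FC| >= 1; a subset of
`n_onoff` is switched to exactly zero expression in one regime; and two
transcripts of one locus always carry opposite planted directions (the
alternative-splice-variant pattern). Library sizes default to 4–6 million
counts, which keeps test runtimes modest while leaving per-transcript
counts deep enough for all three DE methods; the generator does not
emulate transcript-length bias, GC effects, or mapping ambiguity, so
passing tests demonstrate statistical correctness of the pipeline, not
robustness to those artifacts.

## Variant filters

A sync file is reduced to two retained alleles per site. Biallelic sites
pass when total base coverage is strictly > 10 in every library and a
nonreference allele has strictly > 5 reads in at least one library.
Triallelic sites are rescued when coverage passes everywhere and at least
one library has exactly two (not three) alleles with > 5 reads; the
retained pair is the two bases with the greatest summed counts (ties:
alphabetical). Both thresholds are strict inequalities, taken literally
from the published filter. For rescued sites the downstream binomial
denominator is `count1 + count2` — error reads are excluded — keeping the
GLMM response consistent with its two-allele definition. N and deletion
columns are parsed but never counted as alleles or coverage.

## Divergence GLMM

At each variant the two retained allele counts per library form a
binomial response with logit link, selection regime as the fixed effect
and line (8 levels, one library each) as a random intercept. Because each
line contributes one library, the random intercept is an observation-level
effect: it absorbs both genuine drift between replicate lines and the
extra-binomial noise of pooled sequencing, so the Wald test on the regime
coefficient asks specifically for divergence consistent across replicates.

Estimation maximizes the Laplace-approximated marginal likelihood over
(beta0, beta1, log sigma^2) with L-BFGS-B; the conditional modes of the
eight random intercepts decouple into scalar Newton problems. The Wald
covariance is the inverse of `X' W~ X` with `w~ = w/(1 + sigma^2 w)`,
the fixed-effects block of the joint penalized information. At the
sigma^2 = 0 boundary the fit reduces exactly to the plain binomial GLM
(verified against an independently coded Newton GLM); the implementation
matches `lme4::glmer` to about four decimals on beta, SE and P (verified
in the test suite by calling R directly). Complete separation — one
allele absent from every library of one regime — is handled by adding 0.5
to each regime x allele marginal (spread over the regime's libraries) and
refitting, flagged `separated` so users can exclude such sites.
Non-convergent fits are flagged `failed` with P set conservatively to 1.

P values are Benjamini-Hochberg adjusted; a variant is significant when
the adjusted P is strictly below 5e-6. This threshold is unusually
stringent by design: with eight observations and an ML variance
component, the normal-reference Wald test is anti-conservative (its raw
type-I rate at nominal 0.05 is roughly 0.10–0.15 both here and in
`glmer`), and the stringent genome-wide cut is what controls false
positives in practice. Significant SNPs are clustered into regions: a new
region starts wherever the inter-SNP gap is >= 60 kb, so reported regions
are separated by at least that distance; regions never span scaffolds.

## Pooled F_ST

The classical proportion-of-diversity estimator
`(pi_T - pi_S)/pi_T` with a two-stage finite-sample correction: pool
heterozygosity is rescaled by `n/(n-1)` with `n = min(coverage, 2 *
pool_size)` — read depth cannot contribute more information than the
pool's chromosomes — and total diversity uses the unweighted mean of the
two pool frequencies with the `n_a + n_b` correction. Values are reported
unclamped (slightly negative at no differentiation); sites monomorphic in
both pools are skipped. Window summaries average per-SNP values over
non-sliding 10-kb tiles after discarding sites in the top 2% of any
involved library's empirical coverage distribution (the percentile
reading of a maximum-coverage cutoff); the estimator and the cutoff
semantics are pluggable parameters.

## Consensus differential expression

Transcripts are kept at >= 1 CPM in >= 1 of the eight libraries (raw
library sizes); sizes are then recomputed on the retained matrix for
modeling. TMM scaling factors follow the published trimmed-mean-of-M
algorithm (reference library = closest-to-mean upper-quartile CPM; 30%
M-trim, 5% A-trim; precision-weighted mean of surviving log-ratios;
factors rescaled to geometric mean 1) and agree with the edgeR
implementation to well under 1%.

Three methods are combined, each additionally requiring concordant
per-pair log2 fold changes (strictly the same sign in all four pairs;
zero fails) and absolute overall fold change > 2 (mean of the four
per-pair log2 values, each computed on TMM-CPM with a prior count of 0.5):

1. **NB GLM LRT** — log-linear NB models of raw counts with regime and
   pair effects (no interaction; the design cannot estimate it), TMM
   offsets, and a single common dispersion estimated by Cox-Reid-adjusted
   profile likelihood across transcripts (tagwise shrinkage is out of
   scope). The IRLS is vectorized across transcripts with a shared
   design; at dispersion 0 it reproduces statsmodels' Poisson GLM
   deviances. FDR 0.05.
2. **Pairwise chi-square** — per pair, each transcript's raw counts
   against the two libraries' genome-wide subtotals as a 2x2 Pearson
   test; FDR 0.05 within each pair, required in all four pairs.
3. **PCA screen** — PCA of per-transcript mean-centered (unscaled) log2
   TMM-CPM over the eight libraries; the regime axis is the lowest-index
   component whose selected-minus-control score difference has the same
   sign in every pair; transcripts are then Pearson-correlated with that
   component's sample scores (two-sided t, 6 df, deliberately
   uncorrected, P < 0.05). The published description correlates a gene
   with "its loading along the component", which is a scalar; the only
   coherent reading — correlation with the component's sample scores —
   is implemented. The sign rule is fragile when regime signal leaks
   into a dominant variance axis; the screen reports the chosen
   component so users can inspect it.

The consensus is the union of the three methods' survivors with
per-method provenance. Two transcripts of one locus can appear with
opposite directions (isoform switching); the on/off pattern — zero
counts in one regime — is detected by at least two of the three methods
in >= 90% of simulation seeds at the generator's defaults.

## Integration

RRHO compares two ranked lists over a common universe: at every pair of
rank thresholds on a step grid (default step ~ N/100) the overlap of the
top segments is scored by hypergeometric tails; cells are signed -log10 of
the smaller tail (positive = over-enrichment). Tail arguments are
evaluated in a canonical (successes, draws) order so the map is exactly
equal to its transpose with the lists swapped. The DE ranking key is
`sign(log2FC) * -log10(raw LRT P)`; the divergence key is `-log10(GLMM P)`
(unsigned — allele direction has no shared polarity with expression).
Window F_ST and per-pair |log2FC| are correlated per replicate pair
(Pearson, two-sided t with n-2 df), with transcripts assigned to the
10-kb window containing their gene's 5' start.

## Annotation

SNPs are assigned to every gene whose span extended by 10 kb contains
them (flanks truncated at coordinate 1). Coding effects rebuild the
affected codon from CDS segments honoring strand and phase and translate
with the standard genetic code; UTR positions fold into the intron bucket
so summaries use the three-way partition introns / outside genes / coding.
Multi-gene SNPs count once by severity (coding > intron > flank >
intergenic). This is a minimal classifier: splice sites, frameshifts and
regulatory motifs are out of scope.

## Numerical and design notes

- All simulations are deterministic given a seed; the pipeline fans a
  single seed out to per-stage child seeds through fixed stage indices,
  so toggling one stage never shifts another's stream.
- Problem sizes in the test suite and acceptance script (2,000 loci for
  calibration scans, 5,000-transcript DE matrices, 20–100 simulation
  seeds) are desk-scale choices that keep full runs to a few minutes
  while leaving Monte-Carlo error well below the tested margins.
- Degenerate inputs: empty sync files parse to empty streams; empty
  significant sets cluster to empty region lists and render explicit
  "none" report panels; zero-margin chi-square tables return P = 1
  flagged; constant transcripts are excluded from the PCA correlation.
- Known limitations: the Wald-based GLMM scan is anti-conservative at
  raw thresholds (see above) and should be interpreted through the
  stringent adjusted cutoff; pooled F_ST is descriptive (no significance
  testing); the generator's hitchhiking stand-in does not model
  recombination, so region sizes are set by the layout parameters rather
  than by linkage dynamics.
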