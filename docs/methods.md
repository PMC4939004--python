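# Methods

`tevar` re-creates, end to end on synthetic data with known ground truth, an
analysis of chromatin-accessibility variation across inbred mouse strains and
its attribution to transposable elements (TEs). This note documents the
models, the parameters that matter, the synthetic-data design, and the
numerical choices.

## Coordinates and formats

All in-memory coordinates are 0-based half-open. VCF and RepeatMasker `.out`
are 1-based on disk and converted at the parser boundary; RepeatMasker percent
divergence is stored as a fraction. FASTA parsing goes through Biopython, VCF
through pysam/htslib (which requires the mandatory INFO column in the header
line); interval merge/overlap/counting is a small internal numpy engine with
strictly ≥1-bp overlap semantics (book-ended intervals do not overlap).

## Pseudo-genomes and mappability

A strain pseudo-genome substitutes the strain's homozygous SNP alleles into
the reference; coordinates are unchanged, so all strains share one coordinate
system. Indels and structural variants are out of scope.

The mappability score of a position is `M = 1/k`, where `k` is the number of
genomic positions — on either strand, the position itself included — whose
k-mer lies within the allowed Hamming distance of that position's forward
k-mer. Defaults are a 170 bp k-mer (the mean sequenced fragment length) and 2
mismatches. The algorithm is exact: with `m` mismatches allowed, any matching
pair must agree exactly on at least one of `m+1` disjoint seed chunks
(pigeonhole), so candidates are collected by hashing chunk substrings
(wrapping 64-bit polynomial hashes; collisions only add verification work)
and verified with a full vectorised Hamming comparison. Positions within
`k−1` of a chromosome end get no score; windows containing `N` get no score
and never count as matches; both choices are conventions, since the genomes
here are synthetic and N-free. A hard genome-size cap (default 5 Mb) and a
candidate-pair cap keep the exact algorithm at desk scale; extremely
repetitive (low-complexity) input raises rather than thrashing. Tests compare
the whole track against an independent sliding-offset brute-force oracle.

## Peak calling and reproducibility

Accessible sites are called from fragment midpoints with a Gaussian kernel
density (σ = feature_length/6, default feature length 400 bp, evaluated per
bp in fragments/bp). The background threshold is closed-form: under uniform
placement of n fragments on L bp the density has mean `n/L` and variance
`n/L · (1/(2√π σ) − 1/L)`; peaks are maximal runs above
`mean + peak_threshold_sd · SD`. The default multiplier is 7: the relevant
null event is the *maximum* of the smoothed field over ~10⁶ positions, and
Rice's upcrossing formula (confirmed by simulation: the null max z-score has
a 95th percentile near 6.7 for 10⁴ fragments on 1 Mb) shows a 4 SD threshold
is crossed somewhere in most null libraries. The multiplier is configurable.

Replicate reproducibility uses a rank-concordance surrogate for the IDR idea:
candidates are replicate-1 peaks overlapping (≥1 bp) a replicate-2 peak,
walked in decreasing replicate-1 score order; the retained prefix ends where
the rolling mean (window 20) of |normalized rank difference| between the
replicates' scores exceeds 0.5. This is not a copula-mixture IDR fit; window
and cutoff are configurable. It presumes a dynamic range of peak strengths —
with identical expected strengths everywhere, replicate ranks are pure
sampling noise and the filter rightly rejects everything; real peak sets, and
the synthetic scenario, span a wide strength range.

The cross-strain union merges per-strain reproducible peaks (mergeBed
semantics); a fragment is counted for the union site containing its midpoint,
so every fragment counts at most once.

## Variability testing

Counts are quantile normalized (each column's values replaced in rank order
by the across-column means of order statistics; ties receive the mean of the
target values their rank span covers — exact multiset equality across columns
therefore holds only for tie-free columns). The normalized values enter a
negative-binomial (gamma-Poisson, Var = μ + αμ²) likelihood as a continuous
relaxation.

Per site, dispersion is estimated by method of moments pooled over
within-strain replicates (`α̂ = Σ(v_s − m_s) / Σ m_s²`), floored at 1e-8, and
shrunk 50/50 toward a trend `α(μ) = a₀ + a₁/μ` fitted across sites by least
squares. The test statistic is the likelihood ratio of strain-specific means
(MLE = strain sample means at fixed α̂) against one common mean, referred to
χ² with (n_strains − 1) df. All-zero sites are reported untested with
adjusted p = 1 by convention. Benjamini–Hochberg adjustment runs over tested
sites; sites are ranked by adjusted p, ties broken by raw p, then chromosome,
then start. The top and bottom `round(0.05·n)` (half-away-from-zero; for
50,775 sites that is exactly 2539) become the variable and common classes.

With only two replicates per strain the raw moment estimator has ~7 df, so
the LRT carries a heavy dispersion-noise component even after shrinkage;
this, not the mean-signal, limits class separability at desk scale (see the
scenario design below).

## TE ages and enrichment

TE age is `divergence / substitution_rate` with 4.5×10⁻⁹ substitutions per
site per year; 40 Myr separates young from old elements, applied uniformly.
Per-instance realized divergence (not subfamily consensus divergence) defines
age. A site hits a TE at ≥1 bp overlap; for class-level proportions a site
counts once per class, while subfamily tallies count every overlapped
instance. Class enrichment between variable and common sites uses the
two-sided Fisher exact test (probability-mass summation); subfamily tests are
BH-corrected with subfamilies under 5 hit sites excluded; age distributions
are compared with the Wilcoxon rank-sum test — exact permutation enumeration
(midranks, so ties are handled) when min(n,m) ≤ 8 and at most C(20,10)
arrangements, otherwise the normal approximation with tie and continuity
corrections. Boundary profiles bin coverage in 50-bp bins over ±2500 bp
around each element end (3′ rows flipped so outside always faces the same
way), rows age-ascending; per length stratum ({<1, 1–3, 3–6, ≥6} kb,
configurable) aggregate curves rescale the element body to a fixed number of
bins between the two flanks.

## Drivers: SNPs and methylation

SNP association regresses the replicate-averaged normalized accessibility of
the seven strains on the 0/1 genotype vector of each SNP inside the site
(OLS; the F test with 1 and n−2 df equals the slope t-test). Constant
genotype vectors are flagged, not errors. A variable site is "SNP-explained"
when any of its SNPs passes BH at 0.05 over all site–SNP tests; the headline
quantity is the fraction of variable sites explained.

A CpG is differentially methylated (DM) when its cross-strain sample variance
(n−1 denominator) exceeds 0.05 AND its methylation range exceeds 0.75, both
strict inequalities. CpGs coinciding with a SNP (either the C or the G
position) are removed first; CpGs with fewer than two non-missing strains are
untestable. Methylation variance within variable sites is grouped by site
annotation with TE > other-repeat > unique precedence and compared TE vs
unique by rank-sum; DM enrichment in TE sequence is a 2×2 Fisher test.

## Motifs

A PWM is a 4×L count matrix scored as base-2 log-odds with pseudocount
smoothing against a background composition; a hit is any window on either
strand scoring ≥ 0.8 of the maximal attainable score (configurable). Windows
containing N are skipped; reverse-strand hits are reported in forward
coordinates. Backgrounds are sampled from a pool without replacement to match
the targets' GC histogram in 5-percentage-point bins, two backgrounds per
target, relaxing to adjacent bins (logged) when a bin is exhausted.
Enrichment is sequence-level occurrence tested with the one-sided
hypergeometric tail of targets+background; a motif is selected when p < 0.01
and it occurs in more than 10% of targets. Predicted binding sites are
genome-wide hits fully contained in an accessible site (containment, not
overlap). De-novo discovery and motif-similarity merging are out of scope.

## The synthetic scenario

The default study is 7 strains × 2 replicates on a 2 × 1 Mb genome — roughly
1/2500 of mouse genome scale — with ~290 TE copies from seven subfamilies
(young LINEs at 5 and 8 Myr, old LINEs at 80 Myr, SINEs at 10 and 60 Myr,
LTRs at 15 Myr, DNA elements at 70 Myr; each copy is its consensus mutated at
per-site probability age × 4.5e-9), ~1000 planted 400-bp accessible sites
with ≥600 bp gaps, SNPs at 2×10⁻³/bp with random nonempty proper carrier
subsets, and 10% of TEs polymorphic.

Planted site tiers (chosen from the NB Kullback–Leibler expected LRT, not
from Gaussian intuition — the NB's μ²-scaled variance roughly halves the
information a fold-change carries at μ = 100, α = 0.05):

* **variable** (50 sites): fold 8–12 (log-uniform) in 3–4 random strains —
  open-vs-closed chromatin scale; expected LRT ≈ 260–300.
* **SNP-driven** (15 of the 50): means follow μ·8^genotype with a causal SNP
  guaranteed in the central half of the site (peak calling recovers the
  accessible core, not the planted edges; carriers restricted to 2–4 strains
  for regression power). When no eligible segregating SNP exists one is
  planted at the site centre.
* **methylation-driven** (10 of the 50, at young-LINE sites): strain means
  μ·(0.1 + 4(1 − m_s)) with m_s from a planted DM CpG.
* **common** (50 sites): no strain effect at all.
* **background** (remainder): fold 2.0–2.8 in 3–4 strains — modest
  biological strain variation, which is what makes the no-effect common tier
  identifiable at the bottom of the ranking (with a pure-null background the
  bottom 5% would be an arbitrary draw among ~900 exchangeable sites).

Variable sites are concentrated at young LINEs (30/50) and common sites at
old SINEs (20/50), so the class/age enrichment analyses have planted signal;
a GAS-like STAT motif (TTCCAGGAA) is written into half of the young-LINE
variable sites before SNPs are drawn. CpGs (2 per variable, 1 per common
site, plus extras at TE sites) are generated so that planted DM CpGs satisfy
the DM definition with a safety margin and planted non-DM CpGs fail it with
the same margin — DM recovery is therefore exact by construction, which is
the point: it tests the caller's thresholds, not the generator's noise.
TE-site CpGs that are not DM get a wider (still non-DM) spread than
unique-site CpGs, emulating the larger methylation variability of
repeat-derived sequence.

Fragment libraries (80,000 fragments each; lengths Normal(170, 3) rounded,
min 20) draw midpoints from a uniform background plus truncated-normal
components at each planted site, with per-site enrichment log-uniform on
12–40 shared across libraries. The fragment layer exercises peak geometry;
the analysed count matrix is NB-sampled at the *recovered* union sites with
the planted roles carried over by largest overlap. What the generator does
not emulate: sequencing error, mappability bias in coverage, GC bias,
library-size differences, within-strain biological variation beyond NB
dispersion, and indel/SV variation — passing tests therefore demonstrate the
pipeline's statistical machinery, not robustness to those artefacts.

## Determinism and problem sizes

Every generator and stage is a pure function of (config, seed); a single
global seed fans out to stage seeds via a stage-name hash. `run_all` persists
every stage under a run directory and rerunning with the same seed reproduces
each file byte for byte; wall-clock timings go to `run_log.json`, the one
file outside that contract. Default problem sizes (2 Mb genome, 14 libraries
× 80k fragments, ~1000 sites, 2000-site null calibrations, 50 kb mappability
genomes) were chosen so a full run completes in well under a minute on one
core and the whole test suite in a few minutes.

## Known limitations

* The reproducibility filter is a rank surrogate, not the published IDR
  estimator; it degenerates when peak strengths have no dynamic range.
* With 2 replicates per strain the dispersion estimate is noisy; the LRT's
  effective false-positive ordering among near-null sites is dominated by
  that noise, which is why the planted tiers are widely separated.
* Quantile normalization's exact column-multiset equality breaks under ties
  (tie averaging); this is the standard behaviour of tie-aware
  implementations.
* The exact mappability algorithm is for desk-scale genomes; it is not a
  substitute for indexed methods at 2.7 Gb scale.
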