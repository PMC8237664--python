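# Methods

This note documents the models, estimators, and numerical choices behind
`hircus`, and what the synthetic-data validation does and does not show
about real ancient-DNA data.

## The synthetic world

All estimators are validated by recovery on data generated from a fully
specified synthetic world, never on fitted real populations.

**Allele frequencies.** Root frequencies are Uniform(0.05, 0.95) — a flat
prior on common variation that keeps most sites informative after
ascertainment. Each branch of the population tree transforms its parent's
frequency p by a Balding–Nichols draw, Beta(p(1−F)/F, (1−p)(1−F)/F), with
branch drift parameter F ∈ [0, 1). This model was chosen because its first
two moments are closed-form (mean p, variance F·p(1−p)), which makes drift
recovery and Fst calibration analytically testable; F = 0 copies
frequencies exactly and fixed alleles stay fixed. An admixture edge
replaces the destination's frequencies by α·p_source + (1−α)·p_dest.
Default drift for the four-population D-statistic worlds is F = 0.02 per
branch — deep enough to give each branch distinct ancestry while keeping
frequencies in the polymorphic range, comparable to differentiation among
regional wild-goat groups.

**Individuals, reads, pedigrees.** Diploid genotypes are Hardy–Weinberg
draws; inside a planted autozygous tract a single allele is drawn and
duplicated, so planted tracts contain exactly zero true heterozygotes.
Read depth is Poisson(λ) per site (default λ = 2, the coverage to which
heterozygosity analyses are standardized); each read copies a uniformly
chosen chromosome's allele and flips to the other panel allele with
probability ε (default 2 × 10⁻⁵ per bp, a typical post-filter transversion
error). Pedigree simulation transmits alleles Mendelianly and records the
true IBD fraction π (0, 0.5, 0.5, 1 for unrelated, parent–offspring, full
sibs, self). mtDNA pileups mix an endogenous and a contaminant haplotype
with contamination fraction c per read.

**Window-level genome simulation.** The ROH study conditions require a
450-Mb diploid genome at per-bp heterozygosity 10⁻³. Rather than drawing
4.5 × 10⁸ per-bp Bernoulli variables, `simulate_window_track` draws each
500-kb window's heterozygous-site count as Binomial(callable_bp, rate),
with rate = h + 2ε(1−ε)(1−h) outside tracts and 2ε(1−ε) inside (windows
straddling a tract boundary mix the two rates in exact overlap
proportion). For the statistics the diversity module consumes — window
counts, rates, and everything downstream — this is distributionally
identical to per-bp simulation. Callable fraction defaults to 0.9 of each
window.

**Determinism.** One global 64-bit seed; child streams are spawned via
`numpy.random.SeedSequence` per population and per individual, so output
is bit-identical for identical configs regardless of generation order.

**What the generator does not emulate.** Sites are unlinked: linkage
enters only through genomic position labels. This suffices to exercise
window, block-jackknife, and bootstrap machinery, but means the jackknife
"blocks" do not face real autocorrelation; on real data, block size (not
the formula) carries that burden. There is no recombination map, no
selection, and no post-mortem damage — the pipeline restricts itself to
transversions precisely so that C→T deamination is irrelevant, which is
why damage simulation is omitted. Passing recovery tests therefore shows
the estimators are correct under their stated models, not that real-data
complications (reference bias, mapping artifacts, damage leakage into
transversions) are handled.

## Pseudohaploid genotyping

Panels keep biallelic transversion sites polymorphic in the pooled modern
ascertainment set; `min_pops_polymorphic` optionally requires polymorphism
within that many individual populations (default 0: pooled only). Calls
sample exactly one read uniformly at random per covered panel site — no
majority rule, any depth ≥ 1 — giving haploid calls in {ref, alt} and
MISSING for off-panel alleles or zero coverage. One sampled read keeps the
estimator unbiased at any coverage: the expected pseudohaploid frequency
equals the true population frequency, which the test suite verifies by
Monte Carlo. Coordinates are 1-based inclusive throughout; only BED
writers convert to 0-based half-open.

## Windowed heterozygosity and the long-ROH caller

Heterozygosity is the count of transversion heterozygous sites per
callable bp in non-overlapping 500-kb windows; windows with ≤ 50 kb called
are discarded.

**Error threshold.** The male X (outside the pseudoautosomal region) is
haploid, so its apparent window heterozygosity is pure error. The ROH
threshold τ is the mean + 2 sample SD (n−1 denominator) of per-window
rates pooled across all filtered non-PAR male-X windows — pooling rather
than averaging per-male thresholds, since the pooled estimate is the more
stable with few males (a flag exposes the alternative). The goat X PAR is
not a published constant here, so the non-PAR interval is configurable
(default: exclude the first 7 Mb). Under the window-level error model the
closed-form expectation is τ = q + 2√(q(1−q)/N) with q = 2ε(1−ε) and N
the callable bp per window; the calibration recovers this within
sampling noise, and at ε = 2 × 10⁻⁵ it lands near 5.8 × 10⁻⁵ het/bp — the
same order as thresholds reported for comparable 2X ancient-genome data.

**Decision rules.** Filtered windows are scanned per chromosome in
sliding groups of 10 (step 1). A group is putative ROH when at least 9 of
its 10 windows are below τ and any above-τ window is *non-terminal*,
interpreted literally as positions 2–9; an above-τ first or last window
disqualifies the group. Groups are formed over passing windows only —
non-passing windows are invisible except through the gap rule: when the
distance from one passing window's end to the next one's start exceeds
10 Mb, grouping restarts, so no group (and no merged ROH) spans the gap.
This is the reading under which the gap rule does real work; if
non-passing windows broke groups outright, the gap rule would be
unreachable. Overlapping flagged groups merge into ROH intervals from
first-window start to last-window end; the interval's genomic span
(end − start + 1) decides the ≥ 5 Mb test. F_ROH5Mb is the number of
passing windows inside merged ROH of span ≥ 5 Mb divided by all passing
windows genome-wide — a windows-based, not bp-based, inbreeding fraction.
The caller is checked against a brute-force enumeration of these rules on
every track of ≤ 50 windows, and is monotone in τ, idempotent, and
order-independent on sorted tracks.

**Error-corrected heterozygosity.** A base error on either sampled
chromosome at a truly homozygous site fakes a heterozygote, so the
observed rate exceeds truth by 2ε(1−ε) (to first order in h); the
correction is h_corr = max(0, h_obs − 2ε̂(1−ε̂)). ε̂ is estimated by the
subtraction method: the sample's rate of outgroup-discordant transversion
alleles minus that of a designated low-error reference individual at the
same sites, clamped at 0. This is a documented stand-in for
genotype-likelihood-based error estimation; its validity here rests on
recovery tests (injected ε = 5 × 10⁻⁴ recovered within 10%, corrected
heterozygosity within 10% of truth). The estimator carries a small
downward bias of factor (1 − 2p̄) with p̄ the mean derived-allele
frequency at the sites used, so error-estimation sites should be chosen
where the reference individual is mostly ancestral.

## D, f3, and the weighted block jackknife

Per site, ABBA = (1−p₁)p₂p₃(1−p₄) and BABA = p₁(1−p₂)p₃(1−p₄);
D = Σ(ABBA−BABA)/Σ(ABBA+BABA). Outgroup f3(O; A, B) is the plain mean of
(p_O−p_A)(p_O−p_B). Pseudohaploid single-sample populations contribute
frequencies in {0, 1}, which leaves D unbiased. Sites missing in any
required population are dropped per statistic (complete case). Standard
errors use the delete-one-block weighted jackknife with unequal block
sizes (Busing et al. 1999 — the formula used by the standard f-statistic
software), over 5-Mb genomic blocks; 5 Mb matches the scale used for tree
bootstrapping and is configurable, as the analysis this mirrors does not
print its block size. Significance is flagged at |z| ≥ 3 (field
convention). Calibration on 200 replicate null worlds gives an empirical
false-positive rate within binomial noise of the nominal 5% at |z| ≥ 3 and
a mean jackknife SE within 20% of the empirical SD of D; a 20% admixture
pulse is detected with z ≈ 10 at 2 × 10⁵ sites.

## Kinship and IBS/NJ trees

The kinship estimator is a moment method on pseudohaploid mismatch rates:
for a pair sharing IBD fraction π, the expected mismatch is
m̄(1 − π/2) where m̄ is the unrelated baseline, so
π̂ = clamp(2(1 − m/m̄), 0, 1). The baseline is the median mismatch across
pairs (robust to a minority of related pairs), or the mean over designated
unrelated pairs. This deliberately replaces likelihood-based kinship on
genotype likelihoods with an estimator on the same output scale; pedigree
recovery (unrelated ≤ 0.1, parent–offspring 0.5 ± 0.05, self ≥ 0.95 at
5 × 10⁴ sites) is the arbiter of the substitution.

IBS distance is the pairwise mismatch rate itself (branch lengths are raw
IBS, not re-estimated). Neighbor joining follows Saitou–Nei with the
standard Q criterion; Q ties break on the lowest taxon-index pair for
determinism, and negative branch lengths are clamped to zero with the
deficit moved to the sibling edge, preserving path lengths. Bootstrap
supports resample 5-Mb site blocks with replacement to the original block
count, rebuild IBS + NJ per replicate, and report for each internal edge
of the point tree the fraction of replicates containing the same unrooted
bipartition. NJ is consistent on additive matrices (verified exactly on
random trees up to 12 taxa, and cross-checked against an independent NJ
implementation).

## Selection scan

θ_W = S/(a_n · L) per bp with a_n = Σ_{i<n} 1/i. Hudson's Fst uses the
Bhatia et al. ratio-of-averages form: per-site numerator
(p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1), denominator
p₁(1−p₂) + p₂(1−p₁), summed within a window before dividing (ratio of
averages, which is robust where the average of ratios is not), clamped to
[0, 1]. On two populations drifting independently at F = 0.1 the
genome-wide estimate recovers 0.10 ± 0.02. Windows are 50 kb sliding by
10 kb with a ≥ 10 SNP inclusion default (the source workflow does not
print its minimum). The outlier filter flags windows jointly at or above
the empirical 0.99 Fst quantile (linear-interpolation quantile over all
sliding windows, overlaps included — no deduplication) and with strictly
negative log(θ_target/θ_reference); zero-reference-θ windows are excluded
from the ratio test. PBS converts pairwise Fst to branch lengths
T = −log(1−Fst) (Fst clamped at 1 − 10⁻⁶) and isolates the focal branch as
(T₁₂+T₁₃−T₂₃)/2; the identity PBS₁+PBS₂+PBS₃ = (T₁₂+T₁₃+T₂₃)/2 holds to
machine precision. Gene annotation of outlier regions is out of scope;
regions are emitted as BED.

## Mitochondrial analyses

Consensus is majority rule per position, N below depth 3 or on ties.
Contamination is the heteroplasmic rate: pooled discordant-read fraction
at known variant positions, measured against the sample's own consensus
(not an external reference), with a Clopper–Pearson binomial CI. The
estimate is recovered within ±0.005 at c ∈ {0, 0.01, 0.02} and 500×
depth; sequencing error adds directly to the estimate (ε ≈ 10⁻³ inflates
ĉ by about 0.001), so it is an upper bound on contamination at the
positions used. Sequences are treated as linear — circularity is resolved
upstream by realignment to a linearized reference. Mean pairwise
differences skip positions with N in either member of a pair; haplogroup
assignment is nearest labeled reference by Hamming distance, with an
ambiguity flag on ties.

## Problem sizes

Validation runs use deliberately thinned genomes chosen to preserve the
statistics' regimes: a 3 × 150 Mb genome (900 windows) for ROH recovery
with planted 6/8/10-Mb tracts, 120-Mb male X chromosomes for threshold
calibration, 2 × 10⁵ sites × 200 replicates for D calibration, 5 × 10⁴
sites for kinship, and 500× mtDNA pileups of 2 kb. These sizes keep every
recovery well-powered (binomial/Monte-Carlo noise a small fraction of each
tolerance) while the full test suite and the acceptance script each run in
about a minute.

## Known limitations

- The error model is a single per-bp flip rate; real ancient-DNA error is
  context- and fragment-position-dependent.
- The π̂ baseline assumes most pairs are unrelated; in heavily inbred or
  small sample sets the median baseline deflates π̂.
- The ROH caller's 500-kb/10-window granularity cannot resolve ROH
  boundaries below one window, and tracts under ~5 Mb are intentionally
  out of scope.
- f3 here is the plain frequency product; no heterozygosity correction
  for pseudohaploid outgroups is applied (outgroup-f3 comparisons should
  use a consistent call type across tests).
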