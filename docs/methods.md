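# Methods

This note documents the models, estimators and numerical choices behind
each module, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Motif model and exact p-values

A motif is a position weight matrix `p` (length L × 4 over A,C,G,T) with an
i.i.d. background `q`. From an IUPAC consensus, each allowed base at a
position shares `1 − (4−k)·ε` equally (k allowed bases, ε = pseudocount,
default 0.01) and disallowed bases get ε; from aligned sites, counts plus ε
are normalized per column. The default instance is the 10-bp palindrome
TCTCGCGAGA. The window score is the log-odds sum in bits.

Scores are mapped to an integer lattice by rounding each per-position
log-odds to a granularity of 1e-4 bits. The null distribution of the
lattice score is the L-fold convolution of four-point distributions and is
computed by dynamic programming; tail sums give `P(S ≥ s)`. Because the
scanner scores windows **on the same lattice**, the p-value attached to a
hit is exactly the probability that a background window attains at least
that lattice score — no discretization error enters the p-value itself,
which is why the table reproduces full 4^L enumeration to float accuracy
(verified for L = 8 exactly and for the 10-bp motif at ≤1e-9 relative
error). Distinct true scores could in principle collide on the lattice;
at 1e-4-bit granularity this needs score differences below 1e-3 bits over
10 positions and does not occur for consensus- or site-built matrices.
Exact tables are limited to L ≤ 14 (lattice size ~1e6); longer matrices
require an explicit opt-in.

Strand handling: both strands are scanned with the forward table, which is
exact when the background is complement-symmetric; the default background
is uniform and `background_from_sequences` pools both strands, so this
always holds in practice. A perfect palindrome ties on the two strands and
is reported on '+'. Windows containing N are unscored rather than
penalized. Classification tiers follow strict inequalities: bona fide
p < 1e-4, poorly conserved 1e-4 ≤ p < 3e-4, absent otherwise — both
boundaries fall to the weaker class.

Central enrichment over equal-width peaks locates each peak's best site
(ties: nearest the peak centre, then '+', then leftmost), histograms site
centres in 10-bp bins, and for each window W in the fixed ladder
{50, 100, 150, 200, 250} bp computes the binomial tail
`P(X ≥ x | n, p₀)` with `p₀` the exact fraction of admissible start
positions whose site centre falls inside the window (this is slightly
larger, hence more conservative, than `W/(w−L+1)`). The reported
`p_central` is the minimum over the ladder, Bonferroni-corrected by 5.
Calibration under uniform planting was measured directly: each window is
super-uniform (`P(p_W ≤ 0.02)` ≈ 0.015–0.019), and the corrected min-p has
`P(p_central ≤ 0.1)` ≈ 0.054 — comfortably inside the α + 3·√(α/200) band.
An exact multiplicity correction would raise this to ~0.10; Bonferroni's
over-correction is deliberately kept.

The TCT initiator is matched as the 7-mer Y,C,T,Y,T,Y,Y over positions
−1, +1…+6 (no position 0); candidate TSSs within ±`max_tss_shift` of the
annotation are tried nearest-first, downstream preferred on ties.

## ChIP coverage, significance and occupancy

Reads are counted by their strand-aware 5′ ends into fixed-width bins
(default 50 bp) without fragment-shift modelling; the synthetic generator
places its enrichment accordingly (peak centre 100 bp upstream of the
TSS). RPM is count × 1e6 / library size. Per-bin significance is
`−log₁₀ P(X ≥ k | λ)` with the Poisson survival function evaluated by
scipy (verified against a regularized incomplete-gamma oracle to 1e-10)
and `λ = max(λ_global, λ_local)`: the global mean bin count floors a local
mean over a 10-kb window centred on the bin, the bin itself excluded.
Zero-count bins score 0.

Metagene profiles span ±3 kb of the TSS at the track's bin width;
minus-strand rows are reversed so negative offsets are always upstream;
bins off the chromosome are NaN and excluded from the mean curve.
Occupancy is the maximum significance within ±500 bp of the TSS
(upstream-only variant by flag), bound iff score ≥ θ with θ = 5 by
default (no numeric cutoff is standard in the field; the value is exposed
in the config and reported in every output). On synthetic data (90
promoters, 25% bound, 8× enrichment, 1e5 reads on a 2-Mb genome) this
operating point gives sensitivity 1.0 at FDR 0 — the planted peaks are
~70 reads above a λ ≈ 2.5 background, so the margin is large.

k-means clustering runs on log(1+x) rows with seeded restarts (best
within-cluster SS); cluster indices are relabelled by descending mean
signal so cluster 1 is always the high-occupancy group. Permutation
invariance holds whenever the optimum is well separated; it is asserted in
tests on separable data only, since k-means on unstructured data has no
unique optimum for any implementation.

## Spike-in differential expression

The design assumption is a fixed amount of exogenous spike-in material per
fixed number of cells, so spike counts estimate the technical scale of each
library. Size factors are DESeq2-style median-of-ratios restricted to
spike genes (genes with any zero are dropped from the median; factors are
rescaled to geometric mean 1). Under a planted −50% global shift of all
endogenous genes, spike-in factors stay within ~3% of truth while
total-count factors err by >30% — the motivating failure mode of
library-size normalization.

Counts are divided by factors; CPM uses the normalized library sizes; the
expression filter keeps genes with mean CPM strictly >10 and is applied
after normalization (the ordering is not specified by convention; this
choice is flagged here).

The differential test is a deliberately minimal negative-binomial Wald
test, not a DESeq2 re-export: per-gene method-of-moments dispersion
`α = (s² − m̄)/m̄²` pooled over the two conditions, moderated toward the
dataset median dispersion with prior weight 4 against the residual df
(n₁+n₂−2), floored at 1e-4; log₂FC of +0.5-shifted condition means;
delta-method SE `Var(log₂ m̄) ≈ (m̄ + αm̄²)/(n (m̄+0.5)² ln²2)`; and a
Student-t reference with residual + prior df, following the moderated-t
result for hierarchical variance models. This calibration was chosen by a
null-simulation study: the plain normal-reference Wald at n = 3 vs 3 is
anticonservative (type-I ≈ 0.10), while the moderated-t version holds
~0.04 at nominal 0.05. No fold-change shrinkage, no outlier replacement.
Up/down calls use strict |log₂FC| > 0.7 with p ≤ 0.05 inclusive; raw p is
the default (BH-adjusted by flag, since both conventions are common).

Under the benchmark conditions (90 planted genes at log₂FC = −1 among
2,000, dispersion 0.05, n = 3 vs 3) the fold-change estimator has SD
≈ 0.27, so even a test with *known* dispersion has expected down-call FDR
of almost exactly 0.10 at these thresholds; the implemented test measures
0.100 pooled over 200 simulations with recall 0.86. Single benchmark runs
therefore fluctuate around the 0.1 line — a property of the operating
point, not of the estimator.

## TOP3 proteomics

TOP3 is the **mean** of the three most intense peptide areas per (protein,
condition, replicate); with one or two peptides the mean of what exists is
used and flagged (the sum convention differs only by ×3 and cancels in
every ratio). A protein is detected iff quantified in ≥3 replicates of at
least one condition. The replicate correction factor is
`sum TOP3(r) / mean over replicates of the sums`, and values are *divided*
by it, making post-normalization replicate sums exactly equal (to float
tolerance) — the division direction is pinned down by that testable
postcondition. The factor is computed **within each condition** by
default: equalizing sums across conditions would absorb a genuine global
shift in ribosome content (a planted 30% RP reduction, with RPs at 75% of
total mass, would be flattened from log₂FC −0.51 to −0.15), exactly the
pathology spike-ins prevent on the RNA side. A `per_condition=False` flag
restores global equalization.

Differential abundance works on log₂ normalized values with ≥3 replicates
per side: Student's t (Welch) if both groups pass Shapiro–Wilk at α=0.05,
Mann–Whitney otherwise; proteins quantified in only one condition are
labelled condition-unique rather than imputed. RP mass fraction is
`Σ_RP TOP3 / Σ_all TOP3` per replicate; stoichiometry divides each RP's
intensity by the summed RP intensity (condition means by default,
per-replicate by flag), yielding simplex vectors comparable across
conditions. Protein/mRNA "ratios" are differences of log₂ values, with
Spearman correlations between conditions per gene subset.

## Polysome profiles

The baseline is the line through the global minima of the first and last
deciles of the trace — anchoring in the deciles tolerates edge drift; a
moving average (default 5 points) smooths the baseline-corrected signal
for peak finding only. Local maxima with prominence ≥5% of the maximum
signal are peaks; boundaries sit at the minimum between adjacent apexes.
The first three peaks are 40S, 60S, 80S in gradient order; the polysome
region runs from the 80S right boundary to the end of the trace (where
polysomes end is not well defined on a finite gradient; the trace end is
used). Areas are trapezoidal integrals of the baseline-corrected *raw*
signal, and P:M divides the polysome area by the 80S area (40S+60S+80S
denominator by flag). With the default simulated 4-Gaussian trace the
noiseless recovery error is <0.1%, and with 1% amplitude noise the ratio
stays within 10% of truth in 20/20 seeds.

## Exact rank statistics

Mann–Whitney and Wilcoxon signed-rank p-values are exact in the
small-sample regimes (n·m ≤ 400; n ≤ 25): midranks are doubled to
integers and the permutation (or sign-flip) distribution of the rank sum
is computed by subset-sum dynamic programming — identical to full
enumeration, verified against it for all group sizes ≤ 8 including ties.
Larger samples use normal approximations with midrank tie corrections and
a 0.5 continuity correction. All two-sided p-values double the smaller
tail, capped at 1. BH adjustment is the standard step-up with enforced
monotonicity; the normality gate is scipy's Shapiro–Wilk per group.

## Synthetic data: what it does and does not emulate

All generators are pure functions of (parameters, seed) on
`numpy.random.default_rng`; every dataset ships a JSON truth sidecar. The
defaults are the study conditions the benchmarks run at:

- promoters: 500 bp, i.i.d. bases at 50% GC, 25% planted with one
  consensus at normal(centre, 50 bp), round-half-up planting counts;
- ChIP: uniform background reads over a 2-Mb two-chromosome toy genome,
  1e5 reads, bound promoters get normal(TSS−100, 100 bp) reads sized for
  8× density over a 1-kb window;
- counts: NB with dispersion 0.05, n = 3 vs 3; null genes log-normal
  around mean 500 (σ = 0.5), RPGs around 2,000 (they sit in the top
  expression tier in real cells), 500 spike genes around 400 (~15% of the
  library, in line with a 1:4 cell-mixing design); the knockdown shifts
  RPGs by −1 log₂ with spikes untouched;
- peptides: log-normal areas, 6 peptides/protein, 500 proteins of which
  the 90-RP catalog is scaled to 75% of summed TOP3; knockdown multiplies
  RP areas by 0.7; 6 replicates per condition, σ = 0.25 log₂ units of
  per-replicate noise;
- traces: Gaussians at 10/14/18/30 gradient units (SD 0.5/0.5/0.6/2.5,
  amplitudes 0.2/0.3/1.0/0.8) over 800 points, optional linear baseline
  and i.i.d. noise.

Real data differ in ways the generators deliberately ignore: promoter
sequence is not i.i.d. (CpG islands, repeats), ChIP backgrounds have
mappability and copy-number structure, RNA-seq dispersions vary with mean,
peptide detectability is sequence-dependent and missingness is not random,
and polysome peaks overlap and drift. Passing the synthetic benchmarks
therefore demonstrates correctness of the estimators under their stated
models — recovery of planted effects, honest calibration under the null —
not robustness to every artifact of real experiments.

The default RPG catalog (80 canonical + 10 paralog symbols with toy TSS
coordinates, deterministic) exists so every stage can key on a realistic
gene universe offline; real coordinates are always user-supplied.

## Pipeline determinism

`run_pipeline` seeds every stage from one root seed, writes plain TSV/JSON
only, stamps each table with the SHA-256 config hash, and excludes wall
times from the persisted run log, so identical configs reproduce outputs
byte-for-byte.

## Limitations

- The NB test is minimal by design (no trend-fitted dispersions, no lfc
  shrinkage, no independent filtering); at n = 3 its power/FDR trade-off
  at the |log₂FC| > 0.7 threshold is inherently tight (see above).
- Peak calling is not implemented; occupancy comes from binned
  significance, which is adequate for promoter-window calls but not for
  genome-wide peak discovery.
- The motif machinery is order-0 background, fixed-length, ungapped.
- Polysome segmentation assumes three resolvable subunit peaks left of
  the polysome region and does not deconvolve overlapping n-some peaks.
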