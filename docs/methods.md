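# Methods

## Problem and model

regdelta compares the *shape* of the read distribution over a genomic
window between two conditions, not its total. The unit of analysis is a
strand-aware half-open window (BED input); all window-internal vectors
run 5'→3', so minus-strand windows are reversed relative to genome
coordinates and results are comparable across strands.

Per sample, reads are reduced to per-position counts with one of three
attribution modes: `coverage` (every covered base, via aligned blocks),
`end5`, or `end3` (a single base at the read's 5'/3' terminus). The
default is `coverage`; `end3` matches nascent-transcription assays such
as PRO-seq, where the biological signal is the RNA 3' end. Counts are
normalized to densities (sum 1 over the window) per replicate and
averaged within condition. A replicate with zero coverage in a window
has no defined density and is excluded from that window's average; if
all replicates of a condition are zero, the window is skipped and
logged.

The two condition-average densities d1, d2 give the directed score
sequences X12(i) = 100·(d1(i) − d2(i)) − ρ/|w| (and symmetrically X21).
The ×100 scaling and the uniform ρ/|w| subtraction follow the source
model exactly: the subtraction breaks long zero stretches (which would
otherwise bridge distant positive elements into artificially long
regions) and acts as a linear length penalty, so each sequence sums to
exactly −ρ. ρ (the *pseudocount*, default 1, dimensionless) is the main
length tuning knob: larger ρ yields shorter regions.

## Maximal scoring subsequences

A maximal scoring subsequence (MSS) is a contiguous run whose every
proper subsequence (including the empty one, score 0) scores strictly
lower, and which is contained in no larger run with that property. MSS
are disjoint, strictly positive, begin/end on positive elements, and
cover all positive elements. `all_mss` implements the Ruzzo–Tompa
cumulative-total/left-bound bookkeeping with a previous-smaller-value
chain for the leftward search (amortized linear; a benchmark test
checks ~linear scaling). Score comparisons use exact floating-point
comparisons, as the algorithm's correctness argument assumes; oracle
tests use integer-valued sequences so ties are exact, plus continuous
sequences where ties have probability zero. A quadratic brute-force
reference (`brute_force_amss`, guarded at length 2000) checks the two
defining properties literally via the prefix/suffix-positivity
characterization and is the test oracle.

## Permutation filter and merge

Because every positive element lies in an MSS, even pure noise yields
candidates. Each direction sequence is independently shuffled `n_rand`
times (default 1000; sampling without replacement = uniform
permutation), and candidates must score strictly above the maximum MSS
score over all shuffles (≤ is removed). Each (window, direction) pair
derives its own random stream from the global seed via a SHA-256 digest
of its identifier, so results are independent of window order and
thread scheduling; permutations are drawn sequentially from that
stream, making thresholds nested — monotonically non-decreasing in
`n_rand`.

The per-shuffle maximum MSS score is computed as the classical maximum
subarray sum (floored at 0) rather than by full enumeration: the
shortest subarray attaining the global maximum sum has strictly
positive proper prefixes and suffixes, hence satisfies the strict
MSS property, and nothing can score higher — so the two quantities are
equal. This identity is verified against full enumeration in the test
suite and makes 1000 shuffles per sequence cheap (vectorized
cumulative-sum scan, batched).

Surviving MSS from the two directions are merged by a greedy sweep in
descending score order (keep iff no overlap with anything kept), which
reduces to the pairwise highest-score rule for simple overlaps and
resolves cascades deterministically. Score ties prefer the longer
interval, then the c1>c2 member — an arbitrary but documented and
tested convention.

## Differential usage statistics

Windows become "genes" and their regions-plus-fillers tiling becomes
"exons" (fillers are the gaps before, between, and after regions; the
tiling is exact and gap-free). Reads are counted per exon per sample
with ≥1 bp overlap semantics; a read spanning an exon boundary counts
in both exons, since the window — not the read — is the analysis unit.
Paired mates count once per exon in the default fragment mode. Size
factors use DESeq-style median-of-ratios (total-count ratio fallback
when no exon is positive in all samples).

Per testable exon, a negative-binomial GLM is fitted to the 2·S
observations (this-exon and rest-of-window counts per sample):

    log μ = log(size factor) + sample + bin + condition:bin

The interaction is tested by a 1-df likelihood-ratio test and reported
in log2 units, oriented so positive means relatively higher usage in
condition 1. Exons with mean normalized count below `min_count`
(default 10) are excluded before testing and from the BH family
(independent filtering; the boundary value is included). Single-exon
windows cannot be tested (no rest-of-window) and are flagged. Regions
and fillers form a single BH family, so filler significance rates are
observable. The default significance cutoff is padj ≤ 0.01.

Dispersion is estimated per exon by method of moments on normalized
counts (pooled over the four bin × condition groups), then shrunk in
log space toward a trend α(μ) = a0 + a1/μ fitted across exons by least
squares, with weight (S−2)/(S+2) on the raw estimate (S = total
samples) — more shrinkage with fewer replicates. This is deliberately a
reimplementation of the differential-exon-usage paradigm, not a
numerical clone of any particular package: no Cox–Reid adjustment, no
fold-change shrinkage. With Poisson-simulated data the estimates
collapse toward zero and LRT p-values are approximately uniform under
the null (tested, KS < 0.1); with overdispersed counts the type-I rate
at padj ≤ 0.01 stays below 2% in the shipped null simulations.

## Synthetic data

The generator emulates the motivating signal classes: a Gaussian
occupancy peak (default σ = 50 bp, weight 0.5 over a uniform
background) in a 6 kb window whose center shifts between conditions
(default +200 bp — a promoter-proximal pausing shift), or identical
profiles (null). Defaults: 50 000 reads/replicate, k = 3 replicates,
per-replicate depth gamma-Poisson overdispersed (dispersion 0.05),
single-end 50 bp reads placed so the 3' end falls at the sampled
position (consistent with `end3` counting). Reads are written as
coordinate-sorted SAM converted to indexed BAM via samtools; fixed
seeds give byte-identical BAMs through per-(sample, window) random
substreams. `simulate_mixture` combines window classes in one dataset —
real window sets span a range of effect sizes including no-change
windows, and some behaviors (notably the sensitivity/stringency
trade-off in `n_rand`) only manifest on such mixtures, because
homogeneous strong signal clears any permutation threshold while
homogeneous noise clears none.

Ground truth per window is the set of maximal intervals where the two
generating profiles differ by more than 10% of the maximum absolute
profile difference. The margin is needed because Gaussian tails differ
everywhere at negligible magnitude; 10% of the peak difference marks
the region a practitioner would call truly differential. Recovery is
scored per (window, direction) as the Jaccard index between the unions
of significant detected regions and truth intervals, plus direction
accuracy and log2FC-sign consistency.

What the generator does *not* emulate: mappability, sequence content,
alignment artifacts, spliced or paired reads, biological
between-replicate profile variability (only depth varies). Passing the
shipped recovery tests therefore demonstrates correct behavior of the
statistical machinery under the stated generative model, not
performance on any particular real dataset. Detected region borders
systematically extend somewhat beyond the truth margin into flanking
background — border imprecision is an acknowledged property of the
approach — which is why recovery Jaccard sits near 0.5–0.7 even when
direction calls are perfect.

## Problem sizes and numerical choices

Shipped simulation checks use 500 null windows at 5 000 reads/replicate
and 100 peak-shift windows at 50 000 reads/replicate (k = 3, 6 kb
windows, `n_rand` = 1000), and a 30 + 30 signal/null mixture for the
`n_rand` = 10 vs 1000 comparison. Density vectors must sum to 1 within
1e−9; score sequences sum to −ρ within 1e−6 (float accumulation over
≤ 10⁴ positions). Degenerate GLM fits (non-convergence, perfect
separation, non-finite estimates) are flagged untested rather than
propagated. Results TSV coordinates are 1-based inclusive (header
comment says so); BED and GFF outputs use their native conventions.

## Known limitations

Pairwise comparisons only; no analytic null for MSS scores (the filter
is purely permutation-based); exact region borders vary with noise,
`n_rand`, and ρ; the usage model tests relative, not absolute, change —
a uniform fold-change across a whole window is invisible by design.
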