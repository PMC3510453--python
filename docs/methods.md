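# Methods

This note records the models, parameter choices and numerical conventions
behind `tetramap`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Signal model and smoothing

MNase protection coverage is treated as a non-negative per-base signal
`x[i]` on a (usually circular) replicon. Smoothing is the symmetrical
convolution sum `y[i] = Σ_j h[j]·x[i−j]` with j running over
−⌊M/2⌋..+⌊M/2⌋. The Gaussian kernel samples the density
`exp(−j²/2σ²)` at integer offsets with σ = M/6: a length-M window then
spans 6σ, which contains 2Φ(3)−1 ≈ 99.73% of the continuous mass, so
truncation is negligible. Two discretization choices matter:

* The sampled kernel is renormalized to sum exactly 1. The continuous
  density sampled discretely sums only approximately to 1; renormalizing
  makes a constant track an exact fixed point and conserves total mass on
  circular replicons to machine precision.
* For any M the window uses ⌊M/2⌋ offsets per side (always symmetric,
  length 2⌊M/2⌋+1).

Edge handling is not a property of the mathematics but of the replicon:
circular replicons convolve modulo the length (`wrap`); linear contigs
divide by the in-bounds kernel mass at the ends (`renormalize`), which
keeps a constant track constant there too. The default bandwidth is
M = 27 bp (σ = 4.5 bp); the alternative two-pass simple moving average
uses 40 bp then 15 bp windows.

`select_window` needs a decision rule because correlation with the raw
track is trivially maximized by no smoothing at all. The rule implemented
is: among candidate bandwidths, take the **largest M whose smoothed track
still correlates with the raw signal at r ≥ r_min** (default 0.85) — the
strongest smoothing that still tracks the data. The full (M, r) table is
returned so the trade-off is inspectable. The control comparison between
an MNase track and a deproteinized naked-DNA digest is computed on the raw
(unsmoothed) tracks by default.

## Nucleosome calling

Local maxima of the smoothed track are nucleosome midpoints (dyads), local
minima are linkers. Plateaus collapse to their center (left-of-center for
even lengths — symmetric and deterministic); on circular replicons the
scan wraps so first and last extrema alternate too. Peak magnitude is not
considered by default (`min_prominence = 0`): every maximum is a call.
A positive threshold merges a sub-threshold peak into its neighbor by
removing the peak together with its shallower flanking trough, repeated
until all remaining calls pass; this is useful at low coverage where
sampling noise creates spurious alternations.

Peak-to-peak statistics are stratified by region class. Genic regions are
the expressed transcribed span plus 40 bp upstream of the 5′ end (an
average promoter length), strand-aware, merged at the per-base level so
genic/non-genic exactly partition the replicon. A spacing contributes to a
class only when **both** flanking midpoints lie in that class; boundary
pairs are dropped rather than misassigned. On circular replicons the
wrap-around pair is included. Density is calls per kilobase.

Occupancy states rescale each segment between consecutive extrema to
[0, 1] and threshold at 2/3 (occupied) and 1/3 (depleted), with the middle
band transitional. The thresholds are this package's choice; segment-wise
min–max rescaling makes the states invariant to depth differences across
the genome, so a weakly covered region with clear structure is treated
like a deeply covered one. On linear tracks the contig ends bound the
outer segments. Flat segments degrade to "transition" with a warning.

## Dyad sequence composition

Windows of midpoint ± 30 bp (the ~60 bp tetramer protection) are cut from
the forward genome strand; `--symmetrize` adds reverse complements for
palindromic dyad statistics. Composition tables carry exact per-position
mono- and dinucleotide counts; the A/T ("W") and G/C ("S") grouped series
mirror the standard dinucleotide plots. The GC gradient compares GC at
offset 0 against the mean of the two outermost positions (robust to
single-position noise). Information content is 2 + Σ p·log₂p bits against
a uniform background, or relative entropy against the genome's base
composition.

The periodicity test removes the linear trend, sums discrete Fourier power
over frequencies with period 9–11 bp, and computes a permutation p-value
(999 permutations by default, seeded, with the observation counted so
p ≥ 1/(n+1)). Two nulls are provided:

* `periodicity_test` permutes the series positions — exact when the
  series is exchangeable (measured type-I error 0.055 at α = 0.05 on
  i.i.d. series).
* `periodicity_test_windows` permutes the **offset columns of the window
  matrix** and recomputes the dinucleotide series each time. Overlapping
  dinucleotides share a base between adjacent positions; series-level
  permutation ignores that dependence and is anti-conservative for such
  series (measured 0.12 for the W-grouped series), while column
  permutation reproduces the overlap structure under the null and is
  exact (measured 0.045). Window-level data should use the second form.

## Transcript-unit refinement

Expression: an annotation is detectably expressed when its mean RNA-seq
coverage is ≥ `c_min` (default 5×). Boundary adjustment uses a plateau
threshold t = max(3, 0.1 × median coverage within the annotation): each
end first shrinks inward while coverage < t, then extends outward while
coverage ≥ t, capped at 250 bp and stopping before the next same-strand
annotation. Neighbors merge when every base of the intervening gap is
covered ≥ t (strictly — one uncovered base blocks the merge), transitively
along operon chains. Novel units are maximal covered runs ≥ 100 bp that
overlap no refined unit; they carry strand "." and are excluded from
strand-dependent analyses. All four thresholds are explicit, documented
stand-ins for informally described heuristics and are configurable.

## Promoter architecture

Profile rows are the smoothed occupancy over anchor ± 200 bp (TSS or TTS),
reversed for minus-strand units so positive offsets point downstream of
transcription, and divided by their own mean. Row-mean normalization makes
the aggregate invariant to per-region depth scaling; z-scoring is
available. The smoothed track (not raw coverage, not the ternary states)
is the default input signal.

NDR detection takes the aggregate minimum inside a search window (default
−150..+50 relative to the anchor). When the floor is an exact tie — fully
depleted regions average to exactly zero — the center of the tied run is
reported rather than its leftmost position. Depth is
(flank mean − minimum)/flank mean using the nearest local maxima on either
side (the −1 and +1 nucleosomes); width is the contiguous span below the
half-depth level. The 5′/3′ comparison bootstraps profile rows to put
percentile confidence intervals on the depth and width differences.

Clustering uses 1 − Pearson r between rows and average linkage. The tree
is cut at the most-merged height that yields at least k clusters **whose k
largest members each have ≥ 2 rows**: a single-height "≥ k clusters, keep
the k largest" rule is fragile because one outlier row can claim a slot
while two genuine classes remain merged below the cut; requiring
non-trivial subclades descends past such outliers. The k largest subclades
are labeled 1..k by size (ties broken by first row occurrence), the
remainder 0; everything is deterministic in row order.

## The synthetic-data generator

The generator emulates the study system: a circular 200-kb genome at 65%
GC; 120 transcripts of 500–1200 bp (8 operons of 2–4 genes, gaps 20–40 bp;
intergenic gaps 260–500 bp; divergent promoter pairs ≥ 620 bp apart so
their 5′ NDR neighborhoods never overlap); exactly 75% of transcripts
expressed, decided at operon level; 10 novel units of 150–400 bp absent
from the GFF. Protected fragments are 50–60 bp at 30× mean depth with
midpoint jitter σ = 3 bp; the naked control has the same fragment count
placed uniformly.

Dyads are placed by **exact segment tiling**: between consecutive NDR
anchors, class-mean spacings (genic 68.5 ± 6 bp, non-genic 76.1 ± 8 bp)
are drawn sequentially and then rescaled — choosing the step count whose
rescale factor is closest to 1 — so they tile the segment exactly. This
keeps planted class means faithful to ~0.5 bp and avoids the heavy short
tail of anchor-adjacent gaps a naive renewal walk leaves, which would cap
caller recall around 88% for reasons unrelated to the caller.

NDRs belong to transcription units (operon-level spans, not interior gene
junctions): the 5′ zone is 120 bp centered 50 bp upstream of the TSS and
fully depleted; the 3′ zone is 70 bp centered on the TTS and retains 30%
of interior dyads, which is what makes it shallower and narrower. Each
zone gets −1/+1 anchor dyads 15 bp outside its edges. Dyad-proximal GC
ramps linearly from 0.61 at ±30 bp to 0.75 at the midpoint; since those
windows tile ~80% of the genome above the global target, linker bases are
resampled AT-shifted to hold genome-wide GC at 65%. Optional features:
10-bp periodic AA planting around dyads, and profile classes — each
expressed unit assigned k ∈ {4,5,6}, its TSS ± 300 bp filled with
phase-locked dyads at arm spacing 400/k (first dyad half a spacing from
the NDR edge so the −1/+1 positions themselves are class-specific). The
class benchmark deliberately distorts spacing statistics and is off by
default.

RNA coverage is a lognormal-level plateau (median 50×, σ = 0.5 in log
space) over each expressed operon span with ragged ± ≤ 10 bp ends;
annotations omit a 20–60 bp 5′UTR and 0–20 bp at the 3′ end, so boundary
refinement has real work to do. Fragment counts per dyad are Poisson with
rate depth × class spacing / mean fragment length, which makes
genome-average coverage equal the configured depth. All randomness flows
from one seeded generator; a fixed seed reproduces the bundle
byte-for-byte.

**What passing these benchmarks shows — and does not.** The generator's
nucleosomes are well-positioned point dyads with independent Poisson
fragments; real chromatin has fuzzy, overlapping, partially occupied
positions, sequence-dependent MNase bias, mappability gaps and replicating
(polyploid) genomes, none of which are modeled. Recovery rates here
measure the pipeline's correctness on its own declared signal model, not
expected performance on a sequencing run. Polyploidy is omitted
deliberately: it rescales depth uniformly and adds nothing testable.

## Benchmark problem sizes

The default bundle is 200 kb / ~2,700 dyads / 120 transcripts at 30×,
which gives ~1,000 spacing observations per region class and ~75 profile
rows — enough that class-mean estimates are stable to ~±1 bp across seeds.
Calibration studies use 200 null replicates (type-I error) and 20
replicates of 2,000 windows (power); determinism is checked end-to-end on
an 80-kb bundle. The full suite and the acceptance script each run in
well under a minute on one core.

## Known limitations

* Linear-contig support is generic but lightly exercised; the organism's
  replicons are circular and circularity is the default.
* `detect_ndr` requires flanking local maxima inside the widened search
  window and raises otherwise (flat or monotone aggregates); it does not
  attempt to call absence-of-NDR.
* The transcript refinement assumes strand-specific, contiguous plateau
  coverage; antisense overlap and UTR isoforms are not modeled.
* `truth_compare` uses greedy nearest matching, which is exact for the
  well-separated spacings simulated here but is not an optimal bipartite
  matching in general.
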