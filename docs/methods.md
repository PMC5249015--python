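# Methods

## Profiles

A *profile* is the non-negative read density over a genomic region, binned at
a fixed resolution (default 50 bp) and possibly carrying several tracks
(e.g. different histone marks over the same region). Coverage is computed
from BAM files by extending each fragment — paired reads use the observed
template; single-end reads are extended to a fixed fragment length from their
5' end — and counting, per bin, the fragments overlapping it by at least one
base. Profiles that are too short, too long, or too shallow are filtered out
before clustering.

## Distance: band-constrained, flip-aware DTW

Two profiles `a` (N bins) and `b` (M bins) are compared by dynamic time
warping. A warping path is a sequence of index pairs from `(0, 0)` to
`(N−1, M−1)` taking steps `(1,0)`, `(0,1)`, or `(1,1)`; its cost is the sum of
local distances along it, and the DTW distance is the minimum cost over paths.
Local distances are squared Euclidean or cosine over the per-bin track
vectors; with `normalize_heights` each track is divided by its maximum first,
so shapes are compared independent of sequencing depth.

Three modifications make the distance suitable for peak shapes:

- **Slanted band.** Paths are restricted to a corridor of half-width
  `max(k, |N−M|+1)` around the slanted diagonal `j ≈ i·M/N`, which both
  regularizes the alignment and reduces complexity to `O(k·max(N, M))`.
- **Stretch penalty.** Long vertical or horizontal runs correspond to one
  profile standing still while the other advances. With stretch penalty
  `γ ≥ 1`, the k-th consecutive non-diagonal step has its local cost
  multiplied by `γ^min(k, 8)`; a diagonal step resets the run. `γ = 1`
  recovers plain DTW. The dynamic program carries the trailing run length as
  an extra state, so optimality is preserved exactly (verified against
  exhaustive path enumeration in the tests).
- **Strand-flip awareness.** Regulatory elements occur in either orientation,
  so the distance is the minimum over aligning `b` as given and aligning its
  reversal; the chosen orientation is reported. Ties prefer the unflipped
  orientation.

## Clustering and prototypes

All pairwise flip-aware distances feed complete-linkage agglomerative
clustering; a dendrogram over n profiles always contains exactly n−1 internal
nodes and can be cut by cluster count or by height. Each internal node owns a
*prototype*: the weighted DTW average of its children. Averaging aligns the
lighter child onto the heavier one (flipping it first if the alignment
prefers that), takes the weight-weighted mean along the warping path, and
resamples to the weighted mean length, so a cluster's prototype is a
representative shape rather than a bin-wise mean of misaligned peaks.

## POI mapping and positional entropy

A point of interest (POI — a motif hit, summit, or TSS) falling in bin `i` of
a member profile is mapped through the member-to-prototype warping path: the
warped position is the (lower-median) prototype bin matched to `i`, after
reflecting `i` when the member aligned flipped. Whether warping organizes
POIs is quantified by Shannon entropy of the POI position histogram before
and after warping (raw positions are linearly rescaled to the prototype axis
so profile-length differences do not masquerade as concentration); the
reported value is the percent decrease in entropy.

## TF enrichment curves

Given a clustering and a set of binding peaks for a factor, each peak is
attributed to the cluster containing its midpoint. Per-cluster counts are
normalized by the clusters' total base-pair spans, sorted ascending, and
accumulated; the *area* between this cumulative curve and the uniform
diagonal measures concentration. A factor spread uniformly over the regions
gives area ≈ 0; a factor confined to one of K equal-sized clusters puts all
mass in the final bar and attains the maximum area `(K−1)/(2K)` (0.4 for
K = 5).

## Simulation benchmark

The benchmark draws five seed shapes on 40 bins (2 kb at 50 bp): three
bimodal and two unimodal, chosen so that the classes differ either in summit
placement by more than the alignment band or in peak width severalfold. Each
seed is expanded into corrupted copies by three independent mechanisms:

1. **Noise** — each bin is multiplied by `max(0, g)`, `g ~ N(1, √v)`, the
   same factor across tracks;
2. **Indels** — scanning left to right, each bin is hit with probability `p`
   and then deleted or duplicated with equal probability (duplicates can be
   hit again), giving expected length `N·(1 + p²/(2(1−p)))`;
3. **Flips** — the whole profile is reversed with probability `fp`.

A run clusters 500 profiles (5 seeds × 100) and scores the 5-way partition
against the true classes with the multi-class Matthews correlation
coefficient: clusters are first matched to classes by maximizing the
confusion-matrix diagonal (Hungarian algorithm), then the R_K statistic of
the matched confusion matrix is reported. The comparator pipeline zero-pads
to a common length, height-normalizes, and uses Euclidean distance with the
same linkage — identical in every respect except that it cannot warp or
flip. The benchmark configuration uses squared-Euclidean local distances,
height normalization, band half-width 6, and stretch penalty 3.5.
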