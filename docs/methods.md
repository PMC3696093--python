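# Methods

## Signal model and preprocessing

Input is a BED file of mapped ChIP-Seq tags for H3K27me3 (and optionally an
input-DNA control). Tags mapping to the same (chromosome, start, end,
strand) are collapsed to one, to limit PCR-duplication bias; a flag
(`--dedup-ignore-strand`) collapses by position only. The genome is tiled
with non-overlapping windows of `w` = 200 bp and each tag increments the
window containing its 5′ end (start on `+`, end−1 on `−`; unstranded tags
use start). No fragment-size extension or shifting is applied. All
coordinates are 0-based half-open, BED/bedGraph native.

With a control, each window is replaced by
`n_t / (max(n_c, 1) · N_t/N_c)`: the ratio of depth-normalized treatment to
control. A zero control count is replaced by one so that a coverage gap in
the control cannot manufacture an infinite ratio; the consequence is that
treatment signal over control gaps passes through unnormalized.

## The transition statistic

For window `i`, `L` and `R` are the mean window values over the `N` windows
upstream (`[i−N, i−1]`) and downstream (`[i+1, i+N]`); the focal window
belongs to neither flank. The statistic is

    T = (√L − √R) / √d,   d = min(L, R) if min(L, R) > 0 else 1/N.

Properties that motivate this form: the square-root transform makes the
variance of a Poisson mean approximately rate-free, so one threshold is
meaningful genome-wide; T is antisymmetric under coordinate mirroring, so
the two boundary orientations are treated identically; and the denominator
ranks a transition into a genuinely depleted flank above an equal contrast
sitting on elevated signal. The long default flank (`N` = 20 windows = 4 kb)
integrates over the within-domain enrichment fluctuation that defeats
island callers at domain edges. The exact functional form is isolated in
`ctr_core.t_statistic`, one line to swap.

The published equations for both the transition and refinement statistics
and the background correction are reconstructions: the source renders them
as images, so the forms used here are the simplest ones satisfying every
constraint the surrounding text states (square-root transform; the 1/N
zero-denominator guard; a ratio of depth-normalized counts with the
zero-control guard). Each is isolated behind a single function.

## Bootstrap null and tier-1 scan

The null distribution of T is estimated without distributional assumptions:
each of `n_boot` replicates (default 10⁶) draws `N` windows uniformly with
replacement from all windows genome-wide for the left flank and `N` for the
right, and computes T. The |T| threshold is the (1 − p) empirical quantile,
default p = 0.001. The null is computed once genome-wide, not per
chromosome. Because the pool contains enriched windows, the threshold rises
with the fraction of the genome inside domains; this is intrinsic to a
whole-genome bootstrap and is the reason the synthetic benchmark keeps its
enriched coverage low (below).

A window is a candidate hit when |T| ≥ threshold *and* its larger flank
mean is at least `enrich_fold` (default 1.5) times the genome-average
window value — the enrichment gate that distinguishes a real
heterochromatin edge from a sharp fluctuation between two low-signal
regions. Hit windows within `N` windows of one another merge into a single
candidate anchored at the hit with maximal |T|. Windows with fewer than `N`
windows on either side are ineligible; candidates whose whole refinement
span is ineligible are dropped with a log entry.

## Tier-2 refinement

Within ±`N` windows of a candidate anchor, each window `j` is scored with

    T′(j) = T_N(j) · |√L_n(j) − √R_n(j)|,

the long-range T-score times the short-range contrast over `n` = 3 flanking
windows. Two deliberate departures from the naive product of two T-scores:

* the short factor carries no depletion denominator. A 3-window mean of
  background counts is frequently near zero, and dividing by it lets noise
  spikes two or three windows off the true edge dominate the product; on
  the synthetic benchmark the naive product localizes within ±1 window only
  ~85% of the time, against ~99.5% for the form above (an MLE changepoint
  fit, as an information ceiling, reaches ~99%).
* the reported window maximizes the 1-2-1 locally averaged T′ profile (in
  the direction of the anchor's transition sign), not the raw profile: the
  ideal T′ peak is a two-window plateau (either window abutting the edge),
  so averaging with immediate neighbours selects the peak *region* and
  suppresses single-window noise wins. Ties break to the smallest
  coordinate.

Orientation comes from the sign of T at the reported window: positive T
(upstream flank higher) means heterochromatin upstream (`H>E`), negative
means heterochromatin downstream (`E>H`). In BED output, strand `+` encodes
heterochromatin downstream. Calls within `N` windows of each other collapse
to the strongest |T′|, one call per transition. Each call carries a
plus-one-smoothed empirical p-value, the null fraction of |T| at or above
the candidate's maximum |T|.

Boundaries closer than 4 kb to an unmappable region can be filtered
(`filter_unmappable`, strict "less than" on the distance from the call
midpoint to the nearest interval base).

## Annotation computations

A binding site is associated with a CTR when the midpoint-to-midpoint
distance to its nearest CTR is ≤ 1000 bp (inclusive; distance ties go to
the smaller-coordinate CTR). Site classification is three-way with
precedence: CTR-associated, else heterochromatic when the site midpoint
falls inside an H3K27me3 domain interval (domains are an input, from any
domain caller or from synthetic truth), else euchromatic. Composite
profiles average any windowed track in fixed bins (default 100 bp over
±5 kb) around oriented anchors; anchors with heterochromatin upstream are
coordinate-flipped first, so negative offsets always denote the euchromatic
side. Bins outside a chromosome receive no contribution from that anchor.

Poly(dA:dT) content is the count of overlapping AAAA/TTTT 4-mers per 200 bp
window sliding by 25 bp, case-insensitive, with ambiguity codes breaking
tracts; a homopolymer run of length k contributes k − 3, making the score
monotone in tract length. Values are normalized to the genome-average
window count (mean of normalized values is 1 by construction).

## Synthetic benchmark

The generator plants `K` non-overlapping enriched domains on a background
of i.i.d. Poisson windows and emits tag-level BED files (tags placed
uniformly within their window, random strand, 36 bp) plus an independent
Poisson control track and the ground-truth boundary list with orientations.
Within domains, enrichment fluctuates: one gamma multiplier (mean 1,
variance φ) is drawn per block of 10 windows and linearly interpolated
between block centres. Two design rules keep the benchmark internally
consistent:

* the multiplier is *interpolated*, never stepwise — i.i.d. per-block
  multipliers would create 2–3-fold jumps at block edges, which are genuine
  sharp transitions absent from the truth labels, and under them no
  estimator (including an MLE changepoint fit) can reach the recovery rates
  the benchmark is meant to verify;
* the first and last block of each domain are pinned to multiplier 1, so
  the planted boundary contrast is exactly the configured fold. Fluctuation
  is an interior property; the planted edges are the controlled condition.

Defaults represent the standard benchmark: two 12 Mb chromosomes, 20
domains of 8–20 kb (≈1.2% enriched coverage), background 1 tag per window,
8-fold enrichment, φ = 0.3, sharp (0 bp ramp) boundaries, domains ≥ 8 kb
apart and clear of chromosome ends. Coverage is kept near 1% so that the
whole-genome bootstrap null stays background-dominated; at several-percent
coverage the threshold inflation from enriched windows in the resampling
pool makes 8-fold edges over a 1-tag background undetectable at p = 0.001
regardless of implementation. An optional linear ramp (`boundary_sharpness`)
blurs the planted edges, and an optional region-wide copy-number multiplier
applied to both tracks exercises background correction.

What the generator does *not* emulate: mappability structure, GC or
fragment-length bias, correlated duplicate stacks, partially-penetrant or
nested domains, and real inter-domain spacing statistics. Passing the
recovery tests therefore demonstrates correctness of the statistic,
threshold and refinement machinery under the stated noise model, not
performance on any real chromatin landscape.

Recovery scoring matches calls to truth boundaries greedily, one-to-one, by
increasing distance. A planted boundary is a point on a window edge and a
call is a w-bp region, so localization error is the point-to-interval
distance: 0 for either abutting window, w for the next window out; the
default tolerance of 1 window admits the symmetric four-window set around
the edge. With no calls at all, precision is reported as 1 with an explicit
`precision_defined = False` flag.

## Numerical and procedural choices

* One seeded NumPy generator per run, threaded through bootstrap,
  subsampling and simulation; the seed is recorded in output headers and
  manifests. Same seed, same inputs → byte-identical outputs.
* The bootstrap runs in chunks of 10⁵ replicates (memory ~32 MB per chunk);
  the sorted |T| sample is kept for quantile queries and empirical
  p-values.
* Scanning uses per-chromosome cumulative sums; on integer tracks the
  streaming flank means are bit-identical to direct means (int64 sums are
  exact in float64 far beyond realistic depths).
* An all-zero track yields threshold 0 with a warning; the enrichment gate
  then suppresses calls on constant tracks.
* Degenerate inputs: empty BED files parse to empty tag lists; tags beyond
  a chromosome end clamp to the last window with a warning; tags on unknown
  chromosomes are dropped and counted in the log.
* Problem sizes in the test-suite and acceptance script (24 Mb benchmark
  genome, 10⁵–2·10⁵ bootstrap replicates instead of the 10⁶ default) are
  chosen so a full run completes in seconds while every Monte-Carlo
  comparison keeps ≥3σ margins.

## Known limitations

* The statistic assumes a single sharp transition per flank span; two real
  boundaries closer than ~2N windows merge into one candidate and only the
  stronger is reported.
* The bootstrap null conditions on the marginal window distribution but not
  on local autocorrelation; on strongly autocorrelated input (uncorrected
  copy-number structure, very broad crosslinking artefacts) the threshold
  is anti-conservative unless a control is supplied.
* Background correction divides window-by-window; it does not model
  control-specific variance, so low-coverage controls add noise to the
  corrected track rather than shrinking toward the prior.
* `empirical_p` is computed from the candidate's maximal |T| against the
  bootstrap sample and can exceed the nominal p by up to ~1/n_boot at the
  threshold boundary.
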