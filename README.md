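# ctrics

**Two-tiered detection of chromatin transitional regions (CTRs) in H3K27me3
ChIP-Seq data.**

Facultative heterochromatin — chromatin silenced by the Polycomb mark
H3K27me3 — forms broad domains whose *edges* matter: they are where
insulator proteins (dCTCF, Su(Hw), BEAF-32, GAF and their co-factors) sit
and where the spread of silencing is stopped. Island/domain callers built
for broad marks (SICER-style clustering, HMM segmentation) locate the
domains but are imprecise about the edges, because enrichment fluctuates
*inside* domains as strongly as it changes at many boundaries. `ctrics`
targets the edges directly: it finds, at ~200 bp resolution, the windows
where H3K27me3 enrichment changes fastest — chromatin transitional regions —
and annotates them with binding-site association, orientation-aware
composite profiles and poly(dA:dT) tract density.

## Method

The genome is divided into non-overlapping windows of *w* = 200 bp;
deduplicated ChIP-Seq tags (BED) are counted per window, optionally
normalized by an input-DNA control ("background correction"):

    value = n_t / ( max(n_c, 1) · N_t/N_c )

with `n_t`, `n_c` the window tag counts and `N_t`, `N_c` the library totals.

**Tier 1 — scan.** Every window *i* is scored with a long-range transition
statistic comparing the mean signal `L` over the *N* = 20 windows upstream
with the mean `R` over the *N* windows downstream:

    T = (√L − √R) / √d ,   d = min(L, R)  if min(L, R) > 0,  else 1/N

The square root stabilises count variance; the denominator rewards
transitions whose low side is genuinely depleted. Significance is assessed
against a bootstrap null: many replicates (default 10⁶) each draw *N*
windows genome-wide, with replacement, for each flank, and the |T| threshold
is the (1 − p) quantile (default p = 0.001). Windows with |T| above threshold
whose enriched flank also exceeds 1.5× the genome-average window value are
candidate transitions; nearby hits are merged.

**Tier 2 — refine.** Around each candidate, every window *j* is scored with

    T′(j) = T_N(j) · | √L_n(j) − √R_n(j) |

the long-range T-score times the short-range (*n* = 3 windows) square-root
contrast; the window on the peak of the T′ profile is reported as the CTR.
The sign of T at the reported window gives the orientation: which side of
the CTR is euchromatic and which heterochromatic.

## Worked example

Simulate a 4 Mb genome with 4 planted H3K27me3 domains (8 boundaries),
then call CTRs:

```
$ ctrics simulate --config example.yaml --seed 1 --out ex
$ ctrics call --chip ex.treat.bed --genome ex.genome.chrom.sizes \
              --nboot 200000 --pvalue 0.001 --seed 1 --out excall
INFO ctrics: call: 9 CTRs, |T| threshold 0.9720
$ cat excall.ctr.bed
track name=CTR description="chromatin transitional regions; strand + = heterochromatin downstream (E>H), - = upstream (H>E); seed=1"
chrS1   143800  144000  CTR1    222     +
chrS1   157200  157400  CTR2    231     -
chrS1   591000  591200  CTR3    578     +
chrS1   605200  605400  CTR4    146     -
chrS1   3257600 3257800 CTR5    450     +
chrS1   3275000 3275200 CTR6    251     -
chrS1   3450200 3450400 CTR7    93      +
chrS1   3772400 3772600 CTR8    1000    +
chrS1   3791800 3792000 CTR9    288     -
```

where `example.yaml` contains `chrom_lengths: [[chrS1, 4000000]]` and
`n_domains: 4`. The planted boundaries were at 143600, 157200, 591200,
605400, 3257800, 3275000, 3772600 and 3792000; all eight are recovered by a
call window abutting the true edge, with the correct orientation (`+` means
the heterochromatic side is downstream). CTR7 is a false positive — at
p = 0.001 over ~20 000 scanned windows, a small number of spurious calls is
the expected price of the genome-wide threshold. The score column is
1000·|T′|/max|T′|; `excall.null.tsv` records the bootstrap threshold and
quantiles, and every run writes a JSON manifest with parameters, input
digests and the seed.

Other subcommands: `ctrics associate` (binding sites vs CTRs by the 1 kb
midpoint rule), `ctrics profile` (composite metaplots around oriented CTRs),
`ctrics polyat` (genome-normalized poly(dA:dT) tract density from FASTA),
`ctrics saturation` (CTR counts under tag subsampling).

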