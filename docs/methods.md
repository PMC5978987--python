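# Methods

This note documents the model and the numerical choices behind `popsv`:
what each stage assumes, which parameters matter, what the synthetic data
generator does and does not emulate, and the known limitations.

## Coverage model and counting

Read depth is summarised as the number of properly mapped reads whose
leftmost aligned base falls in a fixed-size, non-overlapping genomic bin
(default 5,000 bp; `bin_size ≥ 100`). "Properly mapped" is operationalised
as: primary alignment, mapped, proper-pair flag set, not a duplicate,
MAPQ ≥ 30 (`min_mapq`). The leftmost-base rule assigns each read to exactly
one bin, so the column sum equals the number of qualifying reads.
Coordinates are 0-based half-open internally and in all BED-like output;
1-based only in VCF export.

Per-bin GC content is the G+C fraction of non-N bases; bins with more than
20% N are unusable. GC correction fits, per sample, a lowess trend of count
versus GC (span 0.3, evaluated at 100 GC-quantile knots, linear
interpolation between knots) over usable bins and rescales counts by
`median/trend`; the sample's genome-wide median is restored exactly
afterwards. Bins whose trend drops below 1% of the sample median cannot be
corrected multiplicatively and are zeroed and flagged. The correction is
per-sample, so correcting a subset of samples reproduces the corresponding
columns of a joint run.

Bin filtering drops bins whose cross-sample median is strictly below
`low_frac` (0.1) or strictly above `high_mult` (3) times the genome-wide
median, or with zeros in strictly more than `max_zero_frac` (0.1) of
samples. Ties at a threshold are retained.

## Targeted normalization

The central assumption: technical coverage bias is shared across genomic
regions with similar behaviour, so the best normalizer for a bin is a set
of other bins with a similar coverage profile across the reference panel.

For each usable bin, its reference-panel coverage vector is scaled to mean
1 and compared by Euclidean distance with a seeded random candidate pool of
`C` = 5,000 usable bins shared across all target bins (cost O(B·C)). The
bin itself plus the `K − 1` nearest candidates form its support set
(`K` = 100). Two refinements matter in practice:

- **Winsorised selection.** Before the distance computation each bin's
  scaled vector is clipped at its median ± 3 robust SD. Similarity should
  reflect shared *technical* covariation; without clipping, a reference
  sample that carries a CNV at the bin drags in support bins where that
  sample is also high, which biases that sample's own normalization factor
  toward diploid and deflates copy-number estimates.
- **Ties** are broken deterministically (stable sort on distance, then bin
  index), so a seed fully determines the profile.

The normalization factor for sample *s* at bin *b* is the median over the
support set of `ref_median_j / count_{s,j}`, skipping zero-count bins; if
more than half the support is zero the value is set missing and flagged.
The median over ~100 ratios is robust to a CNV inside the support set and
absorbs any global per-sample factor exactly. Per-bin location is the
median of the normalized reference coverage and scale is 1.4826 × MAD (SD
fallback when the MAD is 0), with one moderation step: each bin's scale is
floored at a genome-wide variance–mean trend (least-squares fit of scale²
on loc and loc²). A robust scale estimated from ~45 samples carries ~25%
sampling error, and bins whose scale is *under*-estimated generate spurious
Z tails; flooring at the trend removes that failure mode while the per-bin
MAD still captures genuinely noisy bins.

A reference panel of at least 20 samples is recommended (a warning is
issued below that); all cohort samples can serve as the panel, or controls
only when case-specific sensitivity is the priority.

Baselines for comparison: global median rescaling and classic rank-based
quantile normalization (average ranks at ties). Quantile normalization
equalises marginal distributions and removes genome-wide sample factors,
but cannot touch region × sample interactions; targeted normalization can,
because the supporting bins share the interaction. The QC module
(`qc_bias`, `qc_pca`) exposes the relevant diagnostics: per-bin
cross-sample moments against a shuffled null (each sample's values permuted
across bins) and a moment-matched Gaussian null, per-sample shares of the
genome where the sample has the highest/lowest coverage (≈ 1/n when
exchangeable), per-sample Z-normality (worst sample highlighted), and a
bin-centred PCA of samples for batch inspection.

## Testing and calling

Z-scores are `(x − loc)/scale` per usable bin; bins with zero scale or
missing values are excluded and logged. The per-sample null scale σ₀ is
fitted by half-normal quantile matching on the central 50% of |z| (grid of
quantiles 0.25–0.75, median of implied scales), so true CNVs in the tails
do not inflate the null; with fewer than 500 tested bins σ₀ falls back to 1
with a warning. p = 2Φ(−|z|/σ₀) and Benjamini–Hochberg q-values are
computed across the sample's tested bins; a bin is abnormal when
q < `fdr_threshold`.

Calling is a screen-then-confirm procedure. Bins with uncorrected
p < `screen_p` (0.01) are candidates; runs of same-direction candidates
(with up to `stitch` = 0 intervening bins allowed) are merged. The region
statistic is the Stouffer combination mean(z)·√nbins over the spanned bins,
and the region q-value is BH-adjusted *against the number of tested bins*,
because regions are selected from that many candidate locations; regions
with q_region < `fdr_threshold` are kept. The liberal screen prevents
moderate-effect events (single-copy duplications, z ≈ 7 per bin at 40×)
from fragmenting into sub-threshold pieces, while region-level confirmation
carries the FDR control. Two operating points are used in this package's
own benchmarks: the conventional 0.05 for null calibration and a
high-confidence point, q_region < 0.001, for benchmark-grade call sets;
counting noise is mildly right-skewed, so singleton candidates pass a 0.05
region threshold more often than the Gaussian model predicts, and the
stricter point buys precision at essentially no recall cost (a true 4-bin
event carries |z_region| ≳ 15).

An alternative merger, `segmenter="cbs"`, performs recursive binary
change-point segmentation of the z track with a permutation stopping rule
(α = 0.01, 100 permutations) and emits segments meeting the same
abnormality criterion.

Copy number is `2 × mean normalized coverage over the call's bins ÷ mean
normalized reference coverage over the same bins`; DEL/DUP is assigned by
the z sign alone, cn is reported, never thresholded.

## Cohort catalog and frequency annotation

Same-type calls are clustered per chromosome by single linkage at
reciprocal overlap ≥ `ro` (0.5); a cluster becomes one region spanning the
union of its members with the union of samples as carriers. Database
frequency: per database, the carrier counts of variants (any type) covering
at least `cov` (0.5) of the region are summed, capped at the database size,
and divided by it; `db_freq` is the maximum over databases, and a region is
*rare* iff db_freq < 1% (strict). The deletion/duplication comparison is a
Pearson χ² (1 df, no continuity correction) on the 2×2 rare-region table,
optionally after seeded downsampling of the control cohort. Twin
replication first removes calls whose catalog frequency exceeds 50% (so
systematic artefacts cannot inflate the metric), then counts a call as
replicated when the co-twin has a same-type call overlapping it by ≥ 1 bp.

## Burden and enrichment statistics

Control regions reuse the exact sizes of the input regions, placed
uniformly over the genome (chromosomes weighted by placeable length), with
targeted resampling until the fraction overlapping assembly gaps matches
the input within ±2%. Fold-enrichment is the ratio of ≥1-bp track-overlap
counts, observed versus the control-set mean.

The case/control burden statistic is the median over `n_sub` (100) *paired*
subsampled catalogs — each built from `sub_size` (150) randomly selected
samples, the i-th case and control subsample sharing their randomness so
identical cohorts give exactly zero — of fold(case) − fold(control). The
null permutes cohort labels across the 2·n_sub folds (`n_perm` = 10,000)
and p = (1 + #{null ≥ observed})/(n_perm + 1), one-sided for an excess in
cases (two-sided available). Known-gene enrichment draws null gene sets
preserving the gene-length composition of the hit set over 20 length
quantile strata. The private proportion is the fraction of single-carrier
catalog regions, with a reference distribution from `n_down` (1,000) seeded
downsamples of the control cohort, a 95% percentile interval and an
empirical p. The proximity analysis measures, per distance threshold, how
many individuals carry a qualifying non-coding call within that distance of
a known-gene exon (distance = gap in bp, 0 when overlapping; calls can be
restricted to a functional track), forms the case/control odds ratio with
Haldane 0.5 correction on zero cells (controls downsampled to the case
size), and compares per-call distance distributions with a two-sample KS
test (per-individual minima by flag). All empirical p-values use the +1
convention and are seed-reproducible.

## The synthetic-data generator

`simulate_coverage` draws `count ~ NegBin(mean, dispersion)` with
`mean = depth_mean · μ_b · L_s · R_{s,r(b)} · g_s(gc_b) · cn_{s,b}/2`:

| parameter | default | meaning |
|---|---|---|
| `n_bins` × `n_samples` | 2,000 × 45 | study-scale geometry (a 45-sample panel) |
| `depth_mean` | 2,000 reads/bin | ≈ 40× with 100-bp reads in 5-kb bins |
| `bin_effect_sd` | 0.2 | lognormal region effect μ_b (mappability-like) |
| `sample_bias_sd` | 0.05 | lognormal genome-wide factor L_s (rank bias) |
| `region_size`, `n_region_classes`, `region_bias_sd` | 50 bins, 6, 0.04 | contiguous blocks belong to latent classes; each sample has a lognormal factor per class (replication-timing/batch-like region × sample interaction) |
| `gc_opt_mean/sd`, `gc_width` | 0.45/0.02, 0.3 | per-sample unimodal GC response, normalized to mean 1 |
| `overdispersion` | 0.005 | NB: var = m(1+φm); ≈ 7% coverage CV at 40×, matching well-behaved WGS panels; 0 gives Poisson |
| `cnv_spikes` | — | (n_events, nbins, copy_number, carrier_freq) families, placed non-overlapping by rejection, carriers Bernoulli |

`noise="gaussian"` produces the moment-matched normal comparator used in
the coverage diagnostics. `simulate_twins` pairs the first 2·`twin_pairs`
samples and draws carriers per pair, so twins share all spiked events while
counting noise stays independent. `simulate_annotation` builds random
multi-exon gene models, a known-gene subset, assembly-gap intervals, and a
toy SV database with plantable carrier frequencies.

What the generator does *not* emulate: read-level sequence artefacts,
mappability/repeat structure (and hence the heavy-tailed z distributions of
real repeat-rich regions), sex chromosomes, multi-allelic and overlapping
CNVs, breakpoints inside bins, and LD between variants. Passing tests
therefore demonstrate the statistical machinery under the documented bias
structure, not performance on real cohorts; on real data the σ₀ fit is
expected to behave more conservatively because artefact tails widen the
centre of |z|.

## Benchmarks the package runs on itself

The acceptance suite (and `scripts/acceptance.py`) measures, at the
study-scale conditions: per-sample Z SD within [0.8, 1.25] and ≤ 0.5% of
bins inside calls at FDR 0.05 on a no-CNV cohort; recall ≥ 0.95,
precision ≥ 0.9 and mean copy-number error ≤ 0.3 for 4-bin spike-ins (2%
carrier frequency) in the high-confidence call set, with ≥ 0.6 recall for
single-bin events; exact agreement of the BH, clustering, counting,
distance and χ²/OR primitives with brute-force oracles; type-I calibration
of the permutation tests within binomial bounds and ≥ 0.8 power against a
planted exonic excess; twin replication within ±0.05 of its analytic
expectation; and byte-identical end-to-end reruns under a fixed seed.
Problem sizes in the suite (600–2,000 bins, 24–45 samples, n_perm
500–1,000) are chosen to keep the whole run on one CPU in minutes while
leaving every statistical conclusion at conventional resolution.

## Known limitations

- Copy-number estimates shrink slightly toward diploid (≈ 0.1–0.2 copies
  at study scale) because supporting bins resemble the carrier's pattern
  and reference means include carriers; winsorised selection removes most
  but not all of this.
- Variants at ≥ 50% population frequency distort the per-bin reference
  location and may be missed, as expected for a reference-panel method.
- The consecutive merger reports bin-resolution breakpoints; CBS shares
  the limitation.
- One GC trend per sample; two-dimensional GC × mappability correction is
  out of scope.
- Catalog clustering is single-linkage: long chains of partially
  overlapping calls can merge into one region.
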