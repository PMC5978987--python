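"""Genome binning, per-bin read counting, GC correction and bin filtering.

The read-depth signal is summarised as the number of properly mapped reads
starting in each fixed-size, non-overlapping genomic bin (default 5 kb).
Counts are then corrected for the sample-specific GC bias and bins with
extreme coverage are excluded from downstream testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

BIN_COLUMNS = ["chrom", "start", "end", "gc", "usable"]

#: default bin size in bp
DEFAULT_BIN_SIZE = 5_000
#: bins whose sequence is more than this fraction N get an undefined GC
MAX_N_FRACTION = 0.2
#: default minimum mapping quality for a read to be counted
DEFAULT_MIN_MAPQ = 30


@dataclass
class CoverageMatrix:
    """Bin x sample read-count matrix with bin metadata.

    Parameters
    ----------
    bins : pandas.DataFrame
        One row per bin with columns ``chrom, start, end, gc, usable``.
        Coordinates are 0-based half-open. ``gc`` may be NaN (undefined),
        in which case ``usable`` is False.
    counts : pandas.DataFrame
        Same row index as ``bins``; one column per sample.
    state : str
        One of ``raw``, ``gc_corrected``, ``normalized``.
    """

    bins: pd.DataFrame
    counts: pd.DataFrame
    state: str = "raw"
    flags: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.state not in ("raw", "gc_corrected", "normalized"):
            raise ValueError(f"unknown state {self.state!r}")
        if len(self.bins) != len(self.counts):
            raise ValueError("bins and counts have different numbers of rows")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicated sample IDs")
        if self.state == "raw":
            vals = self.counts.to_numpy()
            if (vals < 0).any():
                raise ValueError("raw counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def subset_samples(self, samples: list[str]) -> "CoverageMatrix":
        return replace(self, counts=self.counts[list(samples)].copy())


def define_bins(
    chrom_lengths: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    reference_sequence: str | None = None,
) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping fixed-size bins.

    The last bin of a chromosome may be shorter.  If a FASTA path is given,
    per-bin GC content is the G+C fraction of non-N bases; bins with more
    than ``MAX_N_FRACTION`` N bases get an undefined GC and are marked
    unusable.
    """
    if bin_size < 100:
        raise ValueError("bin_size must be >= 100 bp")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"zero-length chromosome {chrom!r}")
        starts = np.arange(0, length, bin_size)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + bin_size, length))))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    bins["gc"] = np.nan
    bins["usable"] = True

    if reference_sequence is not None:
        import pyfaidx

        fa = pyfaidx.Fasta(reference_sequence)
        for chrom in fa.keys():
            if chrom not in chrom_lengths:
                warnings.warn(f"chromosome {chrom!r} in FASTA not in chrom_lengths; skipped")
        for chrom in chrom_lengths:
            if chrom not in fa:
                continue
            seq = str(fa[chrom][:]).upper()
            mask = bins["chrom"] == chrom
            for i in bins.index[mask]:
                sub = seq[bins.at[i, "start"]: bins.at[i, "end"]]
                if not sub:
                    continue
                n_n = sub.count("N")
                if n_n / len(sub) > MAX_N_FRACTION:
                    continue  # gc stays NaN
                denom = len(sub) - n_n
                if denom == 0:
                    continue
                bins.at[i, "gc"] = (sub.count("G") + sub.count("C")) / denom
        bins.loc[bins["gc"].isna(), "usable"] = False
    return bins


def _harmonize_contig(chrom: str, bam_contigs: set[str]) -> str | None:
    """Map a bin chromosome name onto the BAM's naming (chr prefix or not)."""
    if chrom in bam_contigs:
        return chrom
    if chrom.startswith("chr") and chrom[3:] in bam_contigs:
        return chrom[3:]
    if "chr" + chrom in bam_contigs:
        return "chr" + chrom
    return None


def count_reads(
    bam_paths: list[str] | dict[str, str],
    bins: pd.DataFrame,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> CoverageMatrix:
    """Count properly mapped reads per bin per sample.

    A read is counted in the single bin containing its leftmost aligned
    base, and only if it is primary, mapped, not a duplicate, has the
    proper-pair flag set and MAPQ >= ``min_mapq``.

    ``bam_paths`` may be a list of paths (sample = BAM basename) or a
    mapping sample ID -> path.  BAMs must be coordinate-sorted and indexed.
    """
    import pysam

    if isinstance(bam_paths, dict):
        items = list(bam_paths.items())
    else:
        items = [(p.rsplit("/", 1)[-1].removesuffix(".bam"), p) for p in bam_paths]

    counts = {}
    for sample, path in items:
        bam = pysam.AlignmentFile(path)
        if not bam.has_index():
            raise FileNotFoundError(f"{path}: missing BAM index")
        bam_contigs = set(bam.references)
        col = np.zeros(len(bins), dtype=np.int64)
        missing = []
        for chrom, sub in bins.groupby("chrom", sort=False):
            contig = _harmonize_contig(str(chrom), bam_contigs)
            if contig is None:
                missing.append(str(chrom))
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            idx = sub.index.to_numpy()
            for read in bam.fetch(contig):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                    or not read.is_proper_pair
                    or read.mapping_quality < min_mapq
                ):
                    continue
                pos = read.reference_start
                j = np.searchsorted(starts, pos, side="right") - 1
                if j >= 0 and pos < ends[j]:
                    col[idx[j]] += 1
        if missing:
            raise ValueError(
                f"{path}: contigs absent after chr-prefix harmonization: {missing}"
            )
        counts[sample] = col
        bam.close()

    return CoverageMatrix(
        bins=bins.copy(),
        counts=pd.DataFrame(counts, index=bins.index),
        state="raw",
    )


def _gc_trend(gc: np.ndarray, y: np.ndarray, span: float = 0.3, n_knots: int = 100):
    """Fit a smooth count-vs-GC trend, evaluated by interpolation.

    Lowess with the given span, evaluated at GC quantile knots; returns a
    callable mapping GC values to trend values.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    knots = np.unique(np.quantile(gc, np.linspace(0, 1, n_knots)))
    fitted = lowess(y, gc, frac=span, xvals=knots)
    return lambda g: np.interp(g, knots, fitted)


MIN_BINS_FOR_GC = 200


def gc_correct(cm: CoverageMatrix, span: float = 0.3) -> CoverageMatrix:
    """Remove the per-sample GC bias from raw counts.

    For each sample a smooth trend t(gc) of count versus GC is fitted over
    usable bins; corrected counts are ``count * median / t(gc)``, rescaled
    so each sample's genome-wide median is preserved.  Bins where the trend
    collapses below 1% of the sample median are zeroed and flagged.
    """
    if cm.state != "raw":
        raise ValueError("gc_correct expects a raw CoverageMatrix")
    gc = cm.bins["gc"].to_numpy(dtype=float)
    usable = cm.bins["usable"].to_numpy(dtype=bool) & ~np.isnan(gc)
    if usable.sum() < MIN_BINS_FOR_GC:
        raise ValueError(
            f"only {int(usable.sum())} usable bins with defined GC; "
            f"need >= {MIN_BINS_FOR_GC} to fit a GC trend"
        )

    out = cm.counts.astype(float).copy()
    flags = pd.DataFrame(False, index=cm.bins.index, columns=cm.samples)
    for s in cm.samples:
        y = cm.counts[s].to_numpy(dtype=float)
        med = np.median(y[usable])
        if med <= 0:
            continue
        trend = _gc_trend(gc[usable], y[usable], span=span)
        t = np.full(len(y), med)
        t[usable] = trend(gc[usable])
        bad = t < 0.01 * med
        t[bad] = med  # placeholder; zeroed below
        corr = y * med / t
        corr[bad & usable] = 0.0
        flags.loc[bad & usable, s] = True
        # preserve the genome-wide median exactly
        new_med = np.median(corr[usable])
        if new_med > 0:
            corr *= med / new_med
        out[s] = corr
    return CoverageMatrix(bins=cm.bins.copy(), counts=out, state="gc_corrected", flags=flags)


def filter_bins(
    cm: CoverageMatrix,
    low_frac: float = 0.1,
    high_mult: float = 3.0,
    max_zero_frac: float = 0.1,
) -> tuple[CoverageMatrix, pd.DataFrame]:
    """Mark bins with extreme coverage as unusable.

    A bin is filtered when its cross-sample median is strictly below
    ``low_frac`` x the genome-wide median, strictly above ``high_mult`` x
    the genome-wide median, or when strictly more than ``max_zero_frac`` of
    samples have a zero count in it.  Ties at a threshold are retained.

    Returns the filtered matrix and a per-bin reason log
    (columns ``bin, reason``).
    """
    if cm.state not in ("raw", "gc_corrected"):
        raise ValueError("filter_bins expects raw or gc_corrected counts")
    vals = cm.counts.to_numpy(dtype=float)
    usable = cm.bins["usable"].to_numpy(dtype=bool)
    bin_med = np.median(vals, axis=1)
    genome_med = np.median(bin_med[usable])
    zero_frac = (vals == 0).mean(axis=1)

    reasons = []
    new_usable = usable.copy()
    for i in np.nonzero(usable)[0]:
        if bin_med[i] < low_frac * genome_med:
            reasons.append((i, "low"))
            new_usable[i] = False
        elif bin_med[i] > high_mult * genome_med:
            reasons.append((i, "high"))
            new_usable[i] = False
        elif zero_frac[i] > max_zero_frac:
            reasons.append((i, "zero_frac"))
            new_usable[i] = False
    if not new_usable.any():
        raise ValueError("all bins filtered out")

    bins = cm.bins.copy()
    bins["usable"] = new_usable
    log = pd.DataFrame(reasons, columns=["bin", "reason"])
    return replace(cm, bins=bins), log
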