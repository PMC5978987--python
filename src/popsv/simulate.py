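"""Synthetic bin x sample WGS coverage with realistic technical structure.

The generator emulates the bias phenomenology seen in population read-depth
data: region-specific mean effects (mappability-like lognormal bin
factors), sample-specific multiplicative bias (one sample consistently
high/low genome-wide), region x sample interactions (contiguous blocks
where particular samples run high or low, as batch or replication-timing
structure produces), per-sample GC response curves, and overdispersed
(negative-binomial) counting noise.  CNVs of known copy number are spiked
into randomly chosen carrier samples and reported as ground truth.

Counts follow

    count[s, b] ~ NegBin(mean = depth_mean * mu_b * L_s * R_{s,r(b)}
                                * g_s(gc_b) * cn[s,b]/2)

with mu_b ~ lognormal(0, bin_effect_sd), L_s ~ lognormal(0, sample_bias_sd),
R the per-sample regional factors over latent region classes r(b), and g_s
a unimodal GC response normalized to mean 1 over bins.  With
``overdispersion = 0`` the noise is Poisson; ``noise="gaussian"`` gives the
matched normal comparator used for null diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import SvDatabase
from .coverage import CoverageMatrix
from .enrichment import AnnotationSet


@dataclass
class SpikeSpec:
    """One family of spiked CNVs: ``n_events`` events of ``nbins`` bins at
    ``copy_number`` carried by each sample with prob. ``carrier_freq``."""

    n_events: int
    nbins: int
    copy_number: int
    carrier_freq: float

    def __post_init__(self) -> None:
        if not 0 < self.carrier_freq <= 1:
            raise ValueError("carrier_freq must be in (0, 1]")
        if self.copy_number == 2 or self.copy_number < 0:
            raise ValueError("copy_number must be a non-negative integer != 2")


@dataclass
class SimConfig:
    """Study conditions for the coverage simulator.

    Defaults mirror a ~40x short-read WGS cohort counted in 5 kb bins
    (about 2,000 properly mapped reads per bin) with a 45-sample panel.
    """

    n_bins: int = 2_000
    n_samples: int = 45
    bin_size: int = 5_000
    depth_mean: float = 2_000.0
    bin_effect_sd: float = 0.2
    sample_bias_sd: float = 0.05
    region_size: int = 50
    n_region_classes: int = 6
    region_bias_sd: float = 0.04
    gc_opt_mean: float = 0.45
    gc_opt_sd: float = 0.02
    gc_width: float = 0.3
    overdispersion: float = 0.005
    cnv_spikes: list[SpikeSpec] = field(default_factory=list)
    twin_pairs: int = 0
    noise: str = "negbin"
    gc: np.ndarray | None = None
    seed: int = 0


TRUTH_COLUMNS = ["sample", "chrom", "start", "end", "bin_start", "bin_end", "cn"]


def _gc_response(gc: np.ndarray, opt: float, width: float) -> np.ndarray:
    g = np.exp(-((gc - opt) ** 2) / (2 * width**2))
    return g / g.mean()


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, cfg: SimConfig) -> np.ndarray:
    if cfg.noise == "gaussian":
        sd = np.sqrt(mean * (1 + cfg.overdispersion * mean))
        return np.maximum(rng.normal(mean, sd), 0.0).round()
    if cfg.overdispersion <= 0:
        return rng.poisson(mean).astype(float)
    r = 1.0 / cfg.overdispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def _place_events(rng: np.random.Generator, cfg: SimConfig) -> list[tuple[int, int, int]]:
    """Non-overlapping (start_bin, nbins, cn) placements by rejection."""
    taken = np.zeros(cfg.n_bins, dtype=bool)
    events = []
    for spike in cfg.cnv_spikes:
        for _ in range(spike.n_events):
            for _ in range(10_000):
                s = int(rng.integers(0, cfg.n_bins - spike.nbins + 1))
                if not taken[s: s + spike.nbins].any():
                    taken[s: s + spike.nbins] = True
                    events.append((s, spike.nbins, spike.copy_number, spike.carrier_freq))
                    break
            else:
                raise ValueError("could not place all spiked events without overlap")
    return events


def simulate_coverage(cfg: SimConfig) -> tuple[CoverageMatrix, pd.DataFrame, np.ndarray]:
    """Generate a raw CoverageMatrix, the spiked-CNV truth table and per-bin GC.

    Returns ``(cm, truth, gc)``; ``cm.counts`` also exposes the per-sample
    genome-wide bias factors as ``cm.counts.attrs["sample_bias"]``.
    """
    rng = np.random.default_rng(cfg.seed)
    gc = cfg.gc if cfg.gc is not None else rng.beta(8, 10, size=cfg.n_bins)
    mu = rng.lognormal(0.0, cfg.bin_effect_sd, size=cfg.n_bins)
    L = rng.lognormal(0.0, cfg.sample_bias_sd, size=cfg.n_samples)
    opts = rng.normal(cfg.gc_opt_mean, cfg.gc_opt_sd, size=cfg.n_samples)
    # region x sample interaction: contiguous blocks of bins belong to latent
    # region classes (replication-timing / batch-like structure); each sample
    # has its own multiplicative factor per class.  Unlike the genome-wide
    # factor L_s, this bias is not removable by global or quantile
    # normalization.
    n_blocks = int(np.ceil(cfg.n_bins / max(cfg.region_size, 1)))
    block_class = rng.integers(0, cfg.n_region_classes, size=n_blocks)
    bin_class = np.repeat(block_class, cfg.region_size)[: cfg.n_bins]
    region_factors = rng.lognormal(
        0.0, cfg.region_bias_sd, size=(cfg.n_region_classes, cfg.n_samples)
    )
    R = region_factors[bin_class]  # (n_bins, n_samples)

    cn = np.full((cfg.n_bins, cfg.n_samples), 2.0)
    truth_rows = []
    events = _place_events(rng, cfg)
    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]
    if cfg.twin_pairs:
        carrier_units = cfg.twin_pairs + (cfg.n_samples - 2 * cfg.twin_pairs)
    for s0, nb, copy_number, cf in events:
        if cfg.twin_pairs:
            unit_draw = rng.random(carrier_units) < cf
            carriers = []
            for u in range(cfg.twin_pairs):
                if unit_draw[u]:
                    carriers += [2 * u, 2 * u + 1]
            for k, u in enumerate(range(cfg.twin_pairs, carrier_units)):
                if unit_draw[u]:
                    carriers.append(2 * cfg.twin_pairs + k)
        else:
            carriers = list(np.nonzero(rng.random(cfg.n_samples) < cf)[0])
        for c in carriers:
            cn[s0: s0 + nb, c] = copy_number
            truth_rows.append(
                {
                    "sample": samples[c],
                    "chrom": "chrS",
                    "start": s0 * cfg.bin_size,
                    "end": (s0 + nb) * cfg.bin_size,
                    "bin_start": s0,
                    "bin_end": s0 + nb,
                    "cn": copy_number,
                }
            )

    g = np.column_stack([_gc_response(gc, o, cfg.gc_width) for o in opts])
    mean = cfg.depth_mean * mu[:, None] * L[None, :] * R * g * (cn / 2.0)
    counts = _draw_counts(rng, mean, cfg)

    bins = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": np.arange(cfg.n_bins) * cfg.bin_size,
            "end": (np.arange(cfg.n_bins) + 1) * cfg.bin_size,
            "gc": gc,
            "usable": True,
        }
    )
    counts_df = pd.DataFrame(counts, columns=samples)
    counts_df.attrs["sample_bias"] = dict(zip(samples, L))
    cm = CoverageMatrix(bins=bins, counts=counts_df, state="raw")
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return cm, truth, gc


def simulate_twins(cfg: SimConfig) -> tuple[CoverageMatrix, pd.DataFrame, list[tuple[str, str]]]:
    """Coverage for a cohort whose first ``2 * twin_pairs`` samples form
    monozygotic pairs sharing all spiked events; noise stays independent."""
    if cfg.twin_pairs <= 0:
        raise ValueError("cfg.twin_pairs must be positive")
    if 2 * cfg.twin_pairs > cfg.n_samples:
        raise ValueError("more twins than samples")
    cm, truth, _ = simulate_coverage(cfg)
    pairs = [(f"S{2*i:03d}", f"S{2*i+1:03d}") for i in range(cfg.twin_pairs)]
    return cm, truth, pairs


def simulate_annotation(
    genome: dict[str, int],
    n_genes: int = 100,
    n_known: int = 15,
    exons_per_gene: tuple[int, int] = (2, 8),
    gene_size_range: tuple[int, int] = (5_000, 200_000),
    gap_fraction: float = 0.02,
    db_name: str = "simdb",
    db_n_samples: int = 200,
    db_variants: list[tuple[str, int, int, str, int]] | None = None,
    seed: int = 0,
) -> tuple[AnnotationSet, SvDatabase]:
    """Random gene models, a known-gene subset, assembly gaps and a toy SV
    database with configurable planted variants.

    ``db_variants`` rows are ``(chrom, start, end, type, n_carriers)``; by
    default a handful of common and rare variants are planted uniformly.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)

    genes, exons = [], []
    for i in range(n_genes):
        size = int(rng.integers(gene_size_range[0], gene_size_range[1]))
        ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
        chrom = chroms[ci]
        start = int(rng.integers(0, max(genome[chrom] - size, 1)))
        name = f"G{i:04d}"
        genes.append({"chrom": chrom, "start": start, "end": start + size, "gene": name})
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        ex_starts = np.sort(rng.integers(start, start + size - 200, size=n_ex))
        for es in ex_starts:
            ee = min(int(es) + int(rng.integers(100, 300)), start + size)
            exons.append({"chrom": chrom, "start": int(es), "end": ee, "gene": name})
    genes_df = pd.DataFrame(genes).sort_values(["chrom", "start"]).reset_index(drop=True)
    exons_df = pd.DataFrame(exons).sort_values(["chrom", "start"]).reset_index(drop=True)
    known = set(rng.choice(genes_df["gene"].to_numpy(), size=n_known, replace=False))
    lof = set(rng.choice(genes_df["gene"].to_numpy(), size=max(n_genes // 5, 1), replace=False))

    gaps = []
    for chrom in chroms:
        total_gap = int(gap_fraction * genome[chrom])
        if total_gap >= 1000:
            gs = int(rng.integers(0, genome[chrom] - total_gap))
            gaps.append({"chrom": chrom, "start": gs, "end": gs + total_gap})
    gaps_df = pd.DataFrame(gaps, columns=["chrom", "start", "end"])

    if db_variants is None:
        db_variants = []
        for _ in range(10):
            ci = int(rng.choice(len(chroms)))
            chrom = chroms[ci]
            size = int(rng.integers(5_000, 50_000))
            start = int(rng.integers(0, genome[chrom] - size))
            typ = "DEL" if rng.random() < 0.5 else "DUP"
            carriers = int(rng.integers(1, db_n_samples // 2))
            db_variants.append((chrom, start, start + size, typ, carriers))
    db = SvDatabase(
        name=db_name,
        n_samples=db_n_samples,
        variants=pd.DataFrame(
            db_variants, columns=["chrom", "start", "end", "type", "n_carriers"]
        ),
    )
    ann = AnnotationSet(
        exons=exons_df, genes=genes_df, gaps=gaps_df,
        known_genes=known, lof_intolerant=lof,
    )
    return ann, db
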