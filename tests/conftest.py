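import numpy as np
import pandas as pd
import pytest

from popsv import (
    SimConfig,
    SpikeSpec,
    build_reference,
    filter_bins,
    gc_correct,
    normalize_targeted,
    simulate_coverage,
)


@pytest.fixture(scope="session")
def small_null():
    """Null coverage (no CNVs) with all bias arms on, small enough for unit tests."""
    cfg = SimConfig(n_bins=600, n_samples=25, depth_mean=2000, seed=11)
    cm, truth, gc = simulate_coverage(cfg)
    return cfg, cm, truth, gc


@pytest.fixture(scope="session")
def small_pipeline(small_null):
    """GC-corrected, filtered, reference-profiled and normalized null data."""
    cfg, cm, _, _ = small_null
    cmg = gc_correct(cm)
    cmf, _ = filter_bins(cmg)
    rp = build_reference(cmf, cmf.samples, K=40, C=600, seed=11)
    norm = normalize_targeted(cmf, rp)
    return cmf, rp, norm


@pytest.fixture(scope="session")
def spiked_pipeline():
    """Small cohort with known heterozygous deletions and CN=3 duplications."""
    cfg = SimConfig(
        n_bins=800,
        n_samples=30,
        depth_mean=2000,
        seed=23,
        cnv_spikes=[SpikeSpec(12, 4, 1, 0.05), SpikeSpec(12, 4, 3, 0.05)],
    )
    cm, truth, _ = simulate_coverage(cfg)
    cmg = gc_correct(cm)
    cmf, _ = filter_bins(cmg)
    rp = build_reference(cmf, cmf.samples, K=60, C=800, seed=23)
    norm = normalize_targeted(cmf, rp)
    return norm, rp, truth


def make_bam(path, reads, chrom="c1", length=15000):
    """Write a coordinate-sorted, indexed BAM from read dicts.

    Each read dict: pos (0-based), plus optional flag overrides
    (duplicate, secondary, unmapped, not_proper, mapq, cigar).
    """
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": length}]}
    tmp = str(path) + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as fh:
        for i, r in enumerate(sorted(reads, key=lambda r: r["pos"])):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"r{i}"
            a.reference_id = 0
            a.reference_start = r["pos"]
            a.cigarstring = r.get("cigar", "100M")
            a.mapping_quality = r.get("mapq", 60)
            flag = 0x1 | 0x40  # paired, first in pair
            if not r.get("not_proper", False):
                flag |= 0x2
            if r.get("duplicate", False):
                flag |= 0x400
            if r.get("secondary", False):
                flag |= 0x100
            if r.get("unmapped", False):
                flag |= 0x4
            a.flag = flag
            a.query_sequence = "A" * sum(
                ln for op, ln in a.cigartuples or [] if op in (0, 1, 4)
            ) or "A" * 100
            a.next_reference_id = 0
            a.next_reference_start = min(r["pos"] + 200, length - 1)
            a.template_length = 300
            fh.write(a)
    pysam.sort("-o", str(path), tmp)
    pysam.index(str(path))
    return str(path)


def reciprocal_overlap_match(call, truth, ro=0.5):
    ov = min(call["end"], truth["end"]) - max(call["start"], truth["start"])
    if ov <= 0:
        return False
    return ov >= ro * (truth["end"] - truth["start"]) and ov >= ro * (
        call["end"] - call["start"]
    )


def recall_precision(calls: pd.DataFrame, truth: pd.DataFrame, ro=0.5):
    tp = sum(
        any(
            reciprocal_overlap_match(c, t, ro)
            for _, c in calls[calls["sample"] == t["sample"]].iterrows()
        )
        for _, t in truth.iterrows()
    )
    fp = sum(
        not any(
            reciprocal_overlap_match(c, t, ro)
            for _, t in truth[truth["sample"] == c["sample"]].iterrows()
        )
        for _, c in calls.iterrows()
    )
    recall = tp / len(truth) if len(truth) else np.nan
    precision = 1 - fp / len(calls) if len(calls) else np.nan
    return recall, precision
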