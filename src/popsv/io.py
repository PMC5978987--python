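"""Plain-text readers/writers for count matrices, profiles and call sets.

Counts TSV layout: ``chrom, start, end, gc`` followed by one column per
sample (0-based half-open coordinates).  Calls TSV is BED-compatible in its
first three columns.  Reference profiles round-trip through JSON.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .catalog import SvDatabase
from .coverage import CoverageMatrix
from .normalization import ReferenceProfile

BIN_META = ["chrom", "start", "end", "gc"]


def write_counts(cm: CoverageMatrix, path: str) -> None:
    df = pd.concat([cm.bins[BIN_META].reset_index(drop=True),
                    cm.counts.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_counts(path: str, state: str = "raw") -> CoverageMatrix:
    df = pd.read_csv(path, sep="\t")
    bins = df[BIN_META].copy()
    bins["usable"] = ~bins["gc"].isna()
    counts = df.drop(columns=BIN_META)
    if state == "raw":
        counts = counts.round().astype(np.int64)
    return CoverageMatrix(bins=bins, counts=counts, state=state)


def write_profile(rp: ReferenceProfile, path: str) -> None:
    obj = {
        "ref_samples": rp.ref_samples,
        "K": rp.K,
        "C": rp.C,
        "seed": rp.seed,
        "support": rp.support.tolist(),
        "ref_median": _nanlist(rp.ref_median),
        "loc": _nanlist(rp.loc),
        "scale": _nanlist(rp.scale),
        "ref_mean_norm": _nanlist(rp.ref_mean_norm),
        "usable": rp.usable.astype(int).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def read_profile(path: str) -> ReferenceProfile:
    with open(path) as fh:
        obj = json.load(fh)
    return ReferenceProfile(
        ref_samples=obj["ref_samples"],
        support=np.asarray(obj["support"], dtype=np.int64),
        ref_median=_nanarray(obj["ref_median"]),
        loc=_nanarray(obj["loc"]),
        scale=_nanarray(obj["scale"]),
        ref_mean_norm=_nanarray(obj["ref_mean_norm"]),
        usable=np.asarray(obj["usable"], dtype=bool),
        K=obj["K"],
        C=obj["C"],
        seed=obj["seed"],
    )


def _nanlist(a: np.ndarray) -> list:
    return [None if not np.isfinite(x) else float(x) for x in a]


def _nanarray(lst: list) -> np.ndarray:
    return np.array([np.nan if x is None else x for x in lst], dtype=float)


def write_calls(calls: pd.DataFrame, path: str) -> None:
    cols = ["chrom", "start", "end", "sample", "type", "nbins", "z_region", "q_region", "cn"]
    calls[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_calls(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(calls: pd.DataFrame, path: str, sample_order: list[str] | None = None) -> None:
    """Minimal VCF export: one record per call with SVTYPE, END and CN."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=CN,Number=1,Type=Float,Description="Copy number estimate">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Carrier sample">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for i, r in calls.reset_index(drop=True).iterrows():
        alt = "<DEL>" if r["type"] == "DEL" else "<DUP>"
        info = (
            f"SVTYPE={r['type']};END={int(r['end'])};"
            f"CN={r['cn']:.3g};SAMPLE={r['sample']}"
        )
        lines.append(
            f"{r['chrom']}\t{int(r['start']) + 1}\tcnv{i}\tN\t{alt}\t.\tPASS\t{info}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_sv_database(path: str, name: str, n_samples: int | None = None) -> SvDatabase:
    """Read a BED4+ database TSV with columns chrom,start,end,type,n_carriers
    (,n_samples)."""
    df = pd.read_csv(path, sep="\t")
    if n_samples is None:
        n_samples = int(df["n_samples"].iloc[0])
    cols = ["chrom", "start", "end", "type", "n_carriers"]
    return SvDatabase(name=name, n_samples=n_samples, variants=df[cols].copy())
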