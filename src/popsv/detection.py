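"""Per-bin testing against the reference panel and CNV call construction.

After targeted normalization every bin of a test sample is compared with
the reference panel through a Z-score, the per-sample null scale is fitted
robustly from the centre of the |Z| distribution, p-values get
Benjamini-Hochberg control, and runs of abnormal bins are merged into
deletion/duplication calls with a copy-number estimate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageMatrix
from .normalization import ReferenceProfile

#: minimum number of tested bins before the null scale is considered fittable
MIN_BINS_FOR_SIGMA0 = 500

CALL_COLUMNS = [
    "sample", "chrom", "start", "end", "type", "nbins", "z_region", "q_region", "cn",
]


def zscore_bins(cm: CoverageMatrix, rp: ReferenceProfile, sample: str) -> pd.DataFrame:
    """Z-score every usable bin of one sample: z = (x - loc) / scale.

    Bins with zero/undefined reference scale or a missing normalized value
    are excluded and logged in ``df.attrs["excluded"]``.
    """
    if cm.state != "normalized":
        raise ValueError("zscore_bins expects a normalized CoverageMatrix")
    x = cm.counts[sample].to_numpy(dtype=float)
    ok = rp.usable & (rp.scale > 0) & ~np.isnan(rp.scale) & ~np.isnan(x)
    z = np.full(len(x), np.nan)
    z[ok] = (x[ok] - rp.loc[ok]) / rp.scale[ok]
    tests = pd.DataFrame(
        {
            "bin": np.arange(len(x)),
            "chrom": cm.bins["chrom"].to_numpy(),
            "start": cm.bins["start"].to_numpy(),
            "end": cm.bins["end"].to_numpy(),
            "z": z,
        }
    )
    tests = tests[ok].reset_index(drop=True)
    tests.attrs["sample"] = sample
    tests.attrs["excluded"] = np.nonzero(rp.usable & ~ok)[0]
    return tests


def fit_sigma0(z: np.ndarray) -> float:
    """Null Z scale from the central 50% of |z| by half-normal quantile matching.

    For z ~ N(0, s), the q-quantile of |z| is s * Phi^-1((1+q)/2); matching
    a grid of central quantiles (0.25..0.75 of |z|) and taking the median of
    the implied scales keeps true CNVs in the tails from inflating the null.
    """
    z = z[~np.isnan(z)]
    qs = np.linspace(0.25, 0.75, 11)
    emp = np.quantile(np.abs(z), qs)
    theo = stats.norm.ppf((1 + qs) / 2)
    s = np.median(emp / theo)
    return float(s) if s > 0 else 1.0


def estimate_fdr(tests: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Attach p, BH-adjusted q and abnormal flags to per-bin Z-scores.

    p = 2 Phi(-|z| / sigma0) with sigma0 fitted from the sample's own Z
    distribution; a bin is abnormal when q < ``fdr_threshold``.
    """
    from statsmodels.stats.multitest import multipletests

    tests = tests.copy()
    z = tests["z"].to_numpy(dtype=float)
    if len(z) < MIN_BINS_FOR_SIGMA0:
        warnings.warn(
            f"only {len(z)} tested bins; using sigma0 = 1 instead of fitting"
        )
        sigma0 = 1.0
    else:
        sigma0 = fit_sigma0(z)
    p = 2 * stats.norm.sf(np.abs(z) / sigma0)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    abnormal = q < fdr_threshold
    tests["p"] = p
    tests["q"] = q
    tests["abnormal"] = abnormal
    tests["direction"] = np.where(
        abnormal, np.where(z < 0, "loss", "gain"), "none"
    )
    tests.attrs["sigma0"] = sigma0
    tests.attrs["fdr_threshold"] = fdr_threshold
    tests.attrs["n_tests"] = len(tests)
    return tests


def _bh_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg adjustment with an explicit test count ``m``."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(len(p)) + 1)
    q = np.empty_like(p)
    q[order] = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    return q


def _runs(idx: np.ndarray, direction: np.ndarray, positions: np.ndarray, stitch: int):
    """Group abnormal bin positions (per chromosome) into stitched runs."""
    runs = []
    cur = None
    for pos, d in zip(positions, direction):
        if cur is not None and d == cur["dir"] and pos - cur["last"] <= stitch + 1:
            cur["last"] = pos
        else:
            if cur is not None:
                runs.append(cur)
            cur = {"dir": d, "first": pos, "last": pos}
    if cur is not None:
        runs.append(cur)
    return runs


def merge_calls(
    tests: pd.DataFrame,
    stitch: int = 0,
    segmenter: str = "consecutive",
) -> pd.DataFrame:
    """Merge abnormal bins into CNV calls.

    ``consecutive``: runs of same-direction abnormal bins (up to ``stitch``
    intervening non-abnormal bins allowed inside a run) become one call.
    ``cbs``: change-point segmentation of the Z track; segments whose
    combined Z meets the abnormality criterion become calls.

    The region Z is the Stouffer combination mean(z) * sqrt(nbins) over the
    bins spanned; region q-values are recomputed from the region Z via the
    sample's sigma0 and BH across the sample's calls.
    """
    if stitch < 0:
        raise ValueError("stitch must be >= 0")
    if segmenter not in ("consecutive", "cbs"):
        raise ValueError(f"unknown segmenter {segmenter!r}")
    sigma0 = tests.attrs.get("sigma0", 1.0)
    sample = tests.attrs.get("sample", "sample")
    fdr_threshold = tests.attrs.get("fdr_threshold", 0.05)

    calls = []
    for chrom, sub in tests.groupby("chrom", sort=False):
        sub = sub.sort_values("bin").reset_index(drop=True)
        if segmenter == "consecutive":
            ab = sub[sub["abnormal"]]
            if ab.empty:
                continue
            runs = _runs(
                ab.index.to_numpy(),
                ab["direction"].to_numpy(),
                ab["bin"].to_numpy(),
                stitch,
            )
        else:
            runs = _cbs_runs(sub, sigma0, fdr_threshold)
        for run in runs:
            span = sub[(sub["bin"] >= run["first"]) & (sub["bin"] <= run["last"])]
            zbar = span["z"].mean()
            nb = len(span)
            calls.append(
                {
                    "sample": sample,
                    "chrom": chrom,
                    "start": int(span["start"].min()),
                    "end": int(span["end"].max()),
                    "type": "DEL" if zbar < 0 else "DUP",
                    "nbins": nb,
                    "z_region": zbar * np.sqrt(nb),
                    "bins": span["bin"].to_numpy(),
                }
            )
    if not calls:
        df = pd.DataFrame(columns=CALL_COLUMNS + ["bins"])
        df.attrs["sample"] = sample
        return df
    df = pd.DataFrame(calls)
    p_region = 2 * stats.norm.sf(np.abs(df["z_region"].to_numpy()) / sigma0)
    p_region = np.clip(p_region, np.nextafter(0, 1), 1.0)
    # regions are selected from ~n_tests candidate locations, so the BH
    # multiplicity for region confirmation is the number of tested bins,
    # not the handful of merged calls
    m = int(tests.attrs.get("n_tests", len(tests)))
    df["q_region"] = _bh_adjust(p_region, m)
    df["cn"] = np.nan
    df = df[CALL_COLUMNS + ["bins"]]
    df.attrs["sample"] = sample
    return df


def _cbs_runs(sub: pd.DataFrame, sigma0: float, fdr_threshold: float):
    """Binary change-point segmentation of a chromosome's Z track.

    Recursive search for the contiguous segment with the largest mean shift,
    accepted when it survives a permutation test (alpha = 0.01); accepted
    segments whose Stouffer Z reaches the per-bin abnormality criterion
    become candidate calls.
    """
    z = sub["z"].to_numpy(dtype=float)
    positions = sub["bin"].to_numpy()
    rng = np.random.default_rng(abs(hash((len(z), round(float(z.sum()), 6)))) % 2**31)
    segments = []

    def best_segment(x: np.ndarray):
        n = len(x)
        if n < 2:
            return None
        cs = np.concatenate([[0.0], np.cumsum(x)])
        total = cs[-1]
        best = (0.0, 0, n)
        for i in range(n):
            seg_sums = cs[i + 1:] - cs[i]
            lens = np.arange(1, n - i + 1)
            out_lens = n - lens
            with np.errstate(invalid="ignore", divide="ignore"):
                stat = np.abs(
                    seg_sums / lens - np.where(out_lens > 0, (total - seg_sums) / np.maximum(out_lens, 1), 0.0)
                ) * np.sqrt(lens * np.maximum(out_lens, 1) / n)
            j = int(np.nanargmax(stat))
            if stat[j] > best[0]:
                best = (float(stat[j]), i, i + j + 1)
        return best

    def recurse(lo: int, hi: int, depth: int = 0):
        x = z[lo:hi]
        if len(x) < 3 or depth > 20:
            return
        stat, i, j = best_segment(x)
        if stat <= 0:
            return
        n_perm = 100
        perm_stats = np.empty(n_perm)
        for k in range(n_perm):
            perm_stats[k] = best_segment(rng.permutation(x))[0]
        p = (1 + (perm_stats >= stat).sum()) / (n_perm + 1)
        if p > 0.01:
            return
        segments.append((lo + i, lo + j))
        recurse(lo, lo + i, depth + 1)
        recurse(lo + j, hi, depth + 1)

    recurse(0, len(z))
    crit = stats.norm.isf(fdr_threshold / 2)  # conservative per-segment criterion
    runs = []
    for lo, hi in segments:
        seg = z[lo:hi]
        if np.abs(seg.mean()) * np.sqrt(len(seg)) / sigma0 > crit:
            runs.append({"first": positions[lo], "last": positions[hi - 1],
                         "dir": "loss" if seg.mean() < 0 else "gain"})
    runs.sort(key=lambda r: r["first"])
    return runs


def estimate_cn(call: pd.Series, cm: CoverageMatrix, rp: ReferenceProfile) -> float:
    """Copy number = 2 x mean normalized coverage over the call's bins
    divided by the mean reference coverage over the same bins."""
    sample = call["sample"]
    bins = np.asarray(call["bins"])
    x = cm.counts[sample].to_numpy(dtype=float)[bins]
    ref = rp.ref_mean_norm[bins]
    denom = np.nanmean(ref)
    if not np.isfinite(denom) or denom <= 0:
        return float("nan")
    return float(2.0 * np.nanmean(x) / denom)


def call_sample(
    cm: CoverageMatrix,
    rp: ReferenceProfile,
    sample: str,
    fdr_threshold: float = 0.05,
    screen_p: float = 0.01,
    stitch: int = 0,
    segmenter: str = "consecutive",
) -> pd.DataFrame:
    """Full per-sample pipeline: Z-scores -> screen -> merge -> confirm -> CN.

    Bins with uncorrected p below ``screen_p`` are candidate abnormal bins;
    runs of same-direction candidates are merged, and a merged region is
    kept only when its region-level q — BH-adjusted against the full number
    of tested bins, since regions are selected from that many candidate
    locations — stays below ``fdr_threshold``.  The liberal screen keeps
    moderate-effect events (e.g. single-copy duplications) from fragmenting
    into sub-threshold pieces, while the region-level confirmation carries
    the FDR control.
    """
    tests = estimate_fdr(zscore_bins(cm, rp, sample), fdr_threshold)
    screened = tests.copy()
    cand = screened["p"].to_numpy() < screen_p
    screened["abnormal"] = cand
    screened["direction"] = np.where(
        cand, np.where(screened["z"].to_numpy() < 0, "loss", "gain"), "none"
    )
    screened.attrs = dict(tests.attrs)
    calls = merge_calls(screened, stitch=stitch, segmenter=segmenter)
    if not calls.empty:
        calls = calls[calls["q_region"] < fdr_threshold].reset_index(drop=True)
    if not calls.empty:
        calls["cn"] = [estimate_cn(row, cm, rp) for _, row in calls.iterrows()]
    return calls


def call_all(
    cm: CoverageMatrix,
    rp: ReferenceProfile,
    samples: list[str] | None = None,
    fdr_threshold: float = 0.05,
    screen_p: float = 0.01,
    stitch: int = 0,
    segmenter: str = "consecutive",
) -> pd.DataFrame:
    """Run the calling pipeline for every sample and concatenate calls."""
    samples = list(samples) if samples is not None else cm.samples
    parts = [
        call_sample(cm, rp, s, fdr_threshold, screen_p, stitch, segmenter)
        for s in samples
    ]
    parts = [p for p in parts if not p.empty]
    if not parts:
        return pd.DataFrame(columns=CALL_COLUMNS)
    out = pd.concat(parts, ignore_index=True)
    return out.drop(columns=["bins"])
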