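"""Targeted normalization against a reference panel, baselines and QC.

Read coverage varies across the genome and across samples in ways that
global normalization (median scaling, quantile normalization) cannot
remove: some samples are consistently the highest or lowest in large parts
of the genome, and the per-bin cross-sample variance is far from what an
exchangeable model predicts.  Targeted normalization addresses this by
normalizing each bin with a set of "supporting bins" — other bins whose
coverage profile across the reference samples is most similar — so that the
normalization factor tracks local, bin-specific technical behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageMatrix

#: default number of supporting bins per target bin
DEFAULT_K = 100
#: default size of the shared candidate pool
DEFAULT_C = 5_000
#: recommended minimum reference-panel size
MIN_REF_SAMPLES = 20

_MAD_TO_SD = 1.4826


@dataclass
class ReferenceProfile:
    """Per-bin statistics learned from the reference panel.

    Attributes
    ----------
    ref_samples : list of sample IDs in the reference panel.
    support : (n_bins, K) int array; row b lists the supporting bins of bin
        b (b itself first).  Rows of -1 for unusable bins.
    ref_median : per-bin median of GC-corrected reference coverage; the
        numerator of the normalization factor.
    loc, scale : robust location (median) and scale (1.4826 x MAD, SD
        fallback) of the *normalized* reference coverage, used for Z-scores.
    ref_mean_norm : per-bin mean of normalized reference coverage, used for
        copy-number estimation.
    """

    ref_samples: list[str]
    support: np.ndarray
    ref_median: np.ndarray
    loc: np.ndarray
    scale: np.ndarray
    ref_mean_norm: np.ndarray
    usable: np.ndarray
    K: int
    C: int
    seed: int


def build_reference(
    cm: CoverageMatrix,
    ref_samples: list[str],
    K: int = DEFAULT_K,
    C: int = DEFAULT_C,
    seed: int = 0,
) -> ReferenceProfile:
    """Learn supporting bins and per-bin reference statistics.

    For each usable bin, its coverage vector across the reference samples is
    scaled to mean 1 and compared (Euclidean distance) with a seeded random
    candidate pool of ``C`` usable bins shared by all target bins; the bin
    itself plus the ``K - 1`` closest candidates form its support set.  The
    reference samples are then normalized against themselves to obtain the
    per-bin location and scale used for Z-scores.
    """
    if cm.state != "gc_corrected":
        raise ValueError("build_reference expects GC-corrected counts")
    ref_samples = list(ref_samples)
    if len(ref_samples) < MIN_REF_SAMPLES:
        warnings.warn(
            f"{len(ref_samples)} reference samples; >= {MIN_REF_SAMPLES} recommended"
        )
    X = cm.counts[ref_samples].to_numpy(dtype=float)
    usable = cm.bins["usable"].to_numpy(dtype=bool).copy()
    row_mean = X.mean(axis=1)
    # degenerate all-zero reference vectors cannot be scaled or tested
    usable &= row_mean > 0

    usable_idx = np.nonzero(usable)[0]
    n_usable = usable_idx.size
    if K > n_usable:
        raise ValueError(f"K={K} exceeds the {n_usable} usable bins")
    C_eff = min(C, n_usable)
    if K > C_eff:
        raise ValueError(f"K={K} exceeds the candidate pool size {C_eff}")

    rng = np.random.default_rng(seed)
    pool = np.sort(rng.choice(usable_idx, size=C_eff, replace=False))

    Xs = X.copy()
    Xs[usable_idx] = X[usable_idx] / row_mean[usable_idx, None]
    # winsorize each bin's scaled vector before the similarity search: the
    # distances should reflect shared technical covariation, not which
    # reference samples happen to carry a CNV at the bin; without clipping,
    # a carrier's outlying entry drags in support bins where that sample is
    # also high, biasing its own normalization factor toward diploid
    med = np.median(Xs[usable_idx], axis=1, keepdims=True)
    rob = _MAD_TO_SD * np.median(np.abs(Xs[usable_idx] - med), axis=1, keepdims=True)
    lim = 3.0 * np.where(rob > 0, rob, np.inf)
    Xsel = Xs.copy()
    Xsel[usable_idx] = np.clip(Xs[usable_idx], med - lim, med + lim)

    n_bins = len(cm.bins)
    support = np.full((n_bins, K), -1, dtype=np.int64)
    pool_mat = Xsel[pool]  # (C, n_ref)
    pool_sq = (pool_mat**2).sum(axis=1)
    chunk = 256
    for lo in range(0, n_usable, chunk):
        idx = usable_idx[lo: lo + chunk]
        Q = Xsel[idx]
        d2 = ((Q**2).sum(axis=1)[:, None] - 2 * Q @ pool_mat.T) + pool_sq[None, :]
        np.maximum(d2, 0, out=d2)
        for r, b in enumerate(idx):
            drow = d2[r].copy()
            self_pos = np.searchsorted(pool, b)
            if self_pos < pool.size and pool[self_pos] == b:
                drow[self_pos] = np.inf  # b is prepended explicitly
            # deterministic ties: stable sort on (distance, pool index)
            order = np.lexsort((pool, drow))[: K - 1]
            support[b, 0] = b
            support[b, 1:] = pool[np.sort(order)]
    # normalize the reference panel against itself to get loc/scale
    ref_median = np.where(usable, np.median(X, axis=1), np.nan)
    profile = ReferenceProfile(
        ref_samples=ref_samples,
        support=support,
        ref_median=ref_median,
        loc=np.full(n_bins, np.nan),
        scale=np.full(n_bins, np.nan),
        ref_mean_norm=np.full(n_bins, np.nan),
        usable=usable,
        K=K,
        C=C_eff,
        seed=seed,
    )
    ref_norm = _targeted_values(X, profile)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        loc = np.nanmedian(ref_norm, axis=1)
        mad = np.nanmedian(np.abs(ref_norm - loc[:, None]), axis=1)
        scale = _MAD_TO_SD * mad
        sd = np.nanstd(ref_norm, axis=1, ddof=1)
    scale = np.where(scale == 0, sd, scale)
    # moderate the per-bin scale with the genome-wide variance-mean trend:
    # a robust scale from ~45 samples has ~25% sampling error, and bins whose
    # scale is underestimated produce spurious Z tails; flooring each bin's
    # scale at the trend value removes that failure mode while the per-bin
    # MAD still captures genuinely noisy bins.
    fin = usable & np.isfinite(scale) & np.isfinite(loc) & (loc > 0)
    if fin.sum() >= 50:
        A = np.column_stack([loc[fin], loc[fin] ** 2])
        coef, *_ = np.linalg.lstsq(A, scale[fin] ** 2, rcond=None)
        trend = np.sqrt(np.clip(A @ coef, 0.0, None))
        scale[fin] = np.maximum(scale[fin], trend)
    profile.loc[usable] = loc[usable]
    profile.scale[usable] = scale[usable]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_norm = np.nanmean(ref_norm, axis=1)
    profile.ref_mean_norm[usable] = mean_norm[usable]
    return profile


def _targeted_values(counts: np.ndarray, rp: ReferenceProfile) -> np.ndarray:
    """Apply targeted normalization factors to a (n_bins, n_samples) array.

    f(s, b) = median over the support set of ref_median_j / count_{s,j},
    zero-count supporting bins skipped; missing (NaN) when more than half of
    the support is zero for that sample.
    """
    n_bins, n_samples = counts.shape
    ratios = np.where(counts > 0, rp.ref_median[:, None] / np.where(counts > 0, counts, 1.0), np.nan)
    out = np.full((n_bins, n_samples), np.nan)
    usable_idx = np.nonzero(rp.usable)[0]
    chunk = 512
    K = rp.K
    for lo in range(0, usable_idx.size, chunk):
        idx = usable_idx[lo: lo + chunk]
        sup = rp.support[idx]  # (m, K)
        block = ratios[sup]    # (m, K, n_samples)
        n_missing = np.isnan(block).sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f = np.nanmedian(block, axis=1)
        f[n_missing > K / 2] = np.nan
        out[idx] = counts[idx] * f
    return out


def normalize_targeted(cm: CoverageMatrix, rp: ReferenceProfile) -> CoverageMatrix:
    """Normalize every sample with the reference profile's supporting bins.

    The same supporting bins chosen on the reference panel are used for
    every test sample, so a sample's own abnormality at the target bin
    cannot distort its normalization factor (the factor is a median over
    ~K other bins).
    """
    if cm.state != "gc_corrected":
        raise ValueError("normalize_targeted expects GC-corrected counts")
    if len(cm.bins) != rp.support.shape[0]:
        raise ValueError("bin sets of the matrix and profile differ")
    vals = _targeted_values(cm.counts.to_numpy(dtype=float), rp)
    counts = pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns)
    flags = counts.isna() & rp.usable[:, None]
    return CoverageMatrix(bins=cm.bins.copy(), counts=counts, state="normalized", flags=flags)


def normalize_baseline(cm: CoverageMatrix, method: str = "median") -> CoverageMatrix:
    """Global baseline normalizations the targeted scheme is compared with.

    ``median``: rescale each sample to the common (cross-sample mean of)
    genome-wide medians.  ``quantile``: classic rank-based quantile
    normalization; after it every sample has identical sorted values. Ties
    are resolved by average rank.
    """
    if cm.state != "gc_corrected":
        raise ValueError("normalize_baseline expects GC-corrected counts")
    usable = cm.bins["usable"].to_numpy(dtype=bool)
    vals = cm.counts.to_numpy(dtype=float)
    if method == "median":
        meds = np.median(vals[usable], axis=0)
        target = meds.mean()
        out = vals * (target / meds)[None, :]
    elif method == "quantile":
        order = np.argsort(vals, axis=0, kind="stable")
        ranks = pd.DataFrame(vals).rank(axis=0, method="average").to_numpy() - 1
        mean_sorted = np.take_along_axis(vals, order, axis=0).mean(axis=1)
        # average rank may be fractional at ties: interpolate the target
        out = np.empty_like(vals)
        grid = np.arange(vals.shape[0], dtype=float)
        for j in range(vals.shape[1]):
            out[:, j] = np.interp(ranks[:, j], grid, mean_sorted)
    else:
        raise ValueError(f"unknown baseline {method!r}")
    counts = pd.DataFrame(out, index=cm.counts.index, columns=cm.counts.columns)
    return CoverageMatrix(bins=cm.bins.copy(), counts=counts, state="normalized")


@dataclass
class QcReport:
    """Coverage-bias diagnostics.

    ``bin_stats`` holds the observed per-bin cross-sample mean and SD next
    to two null references: the same statistics after independently
    shuffling each bin's entries across samples, and from matched Gaussian
    draws.  ``sample_extremes`` gives, per sample, the share of bins where
    it has the highest (and lowest) coverage — ~1/n for well-behaved data.
    """

    bin_stats: pd.DataFrame
    sample_extremes: pd.DataFrame
    worst_sample: str
    normality: pd.Series


def _ks_normal(x: np.ndarray) -> float:
    from scipy import stats

    x = x[~np.isnan(x)]
    if x.size < 3 or np.std(x) == 0:
        return 0.0
    z = (x - np.mean(x)) / np.std(x)
    return float(stats.kstest(z, "norm").statistic)


def qc_bias(cm: CoverageMatrix, seed: int = 0) -> QcReport:
    """Per-bin moment diagnostics and per-sample extreme-coverage shares."""
    vals = cm.counts.to_numpy(dtype=float)
    usable = cm.bins["usable"].to_numpy(dtype=bool)
    v = vals[usable]
    v = v[~np.isnan(v).any(axis=1)]
    rng = np.random.default_rng(seed)

    mean_obs = v.mean(axis=1)
    sd_obs = v.std(axis=1, ddof=1)

    # break the bin-sample association: permute each sample's values across bins
    shuf = np.column_stack([rng.permutation(v[:, j]) for j in range(v.shape[1])])
    mean_shuf = shuf.mean(axis=1)
    sd_shuf = shuf.std(axis=1, ddof=1)

    gauss = rng.normal(v.mean(), v.std(ddof=1), size=v.shape)
    mean_gauss = gauss.mean(axis=1)
    sd_gauss = gauss.std(axis=1, ddof=1)

    bin_stats = pd.DataFrame(
        {
            "mean": mean_obs,
            "sd": sd_obs,
            "mean_shuffled": mean_shuf,
            "sd_shuffled": sd_shuf,
            "mean_gaussian": mean_gauss,
            "sd_gaussian": sd_gauss,
        }
    )

    amax = v.argmax(axis=1)
    amin = v.argmin(axis=1)
    n = v.shape[1]
    max_share = np.bincount(amax, minlength=n) / v.shape[0]
    min_share = np.bincount(amin, minlength=n) / v.shape[0]
    sample_extremes = pd.DataFrame(
        {"max_share": max_share, "min_share": min_share}, index=cm.samples
    )

    centred = (v - v.mean(axis=1, keepdims=True))
    sds = v.std(axis=1, ddof=1, keepdims=True)
    sds[sds == 0] = 1.0
    zs = centred / sds
    normality = pd.Series(
        [_ks_normal(zs[:, j]) for j in range(n)], index=cm.samples, name="ks_normality"
    )
    return QcReport(
        bin_stats=bin_stats,
        sample_extremes=sample_extremes,
        worst_sample=str(normality.idxmax()),
        normality=normality,
    )


def qc_pca(cm: CoverageMatrix, n_components: int = 5) -> pd.DataFrame:
    """Principal-component scores of samples for batch inspection.

    Bins are centred; samples are the observations.  Returns a DataFrame of
    scores (samples x components) with the explained-variance ratio stored
    in ``df.attrs["explained_variance_ratio"]``.
    """
    from sklearn.decomposition import PCA

    usable = cm.bins["usable"].to_numpy(dtype=bool)
    vals = cm.counts.to_numpy(dtype=float)[usable]
    vals = vals[~np.isnan(vals).any(axis=1)]
    X = vals.T  # samples x bins
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0, keepdims=True))
    df = pd.DataFrame(
        scores, index=cm.samples, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    df.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_
    return df
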