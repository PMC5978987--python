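"""Burden and enrichment statistics for case/control CNV catalogs.

Implements size- and gap-matched random control regions, exonic
fold-enrichment, label-permutation burden tests on subsampled catalogs,
gene-size-matched known-gene enrichment, the private-CNV proportion with
control downsampling, and the distance-to-nearest-exon analysis of
non-coding CNVs (cumulative carrier curves, odds ratios, KS test).

All empirical p-values use the (1 + #{null >= observed}) / (n + 1)
convention and are reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import build_catalog


@dataclass
class AnnotationSet:
    """Named interval tracks used by the burden analyses.

    ``exons`` and ``genes`` carry a ``gene`` column; ``lof_intolerant`` and
    ``known_genes`` are gene-ID sets; ``gaps`` are assembly
    gaps/centromeres/telomeres; ``functional`` is an optional regulatory
    track (e.g. eQTL or promoter-linked intervals).
    """

    exons: pd.DataFrame
    genes: pd.DataFrame
    gaps: pd.DataFrame
    known_genes: set[str] = field(default_factory=set)
    lof_intolerant: set[str] = field(default_factory=set)
    functional: pd.DataFrame | None = None


@dataclass
class EnrichmentResult:
    fold: float
    null_folds: np.ndarray
    p_perm: float
    n_subsamples: int
    n_perm: int


# ---------------------------------------------------------------- intervals

def _merged(track: pd.DataFrame) -> dict[str, np.ndarray]:
    """Merge a track into disjoint sorted intervals per chromosome."""
    out = {}
    for chrom, sub in track.groupby("chrom", sort=False):
        iv = sub[["start", "end"]].sort_values(["start", "end"]).to_numpy()
        merged = []
        for s, e in iv:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged)
        out[str(chrom)] = arr
    return out


def overlaps_any(query: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """Boolean array: does each query interval overlap the track by >= 1 bp."""
    tr = _merged(track)
    res = np.zeros(len(query), dtype=bool)
    for k, (_, r) in enumerate(query.iterrows()):
        iv = tr.get(str(r["chrom"]))
        if iv is None:
            continue
        j = np.searchsorted(iv[:, 0], r["end"], side="left")
        res[k] = bool(j > 0 and iv[j - 1, 1] > r["start"])
    return res


def nearest_distance(query: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """Gap in bp between each query interval and the nearest track interval.

    0 when overlapping or bookended; inf when the chromosome has no track
    intervals.
    """
    tr = _merged(track)
    out = np.full(len(query), np.inf)
    for k, (_, r) in enumerate(query.iterrows()):
        iv = tr.get(str(r["chrom"]))
        if iv is None or len(iv) == 0:
            continue
        gaps_left = r["start"] - iv[:, 1]   # track upstream of query
        gaps_right = iv[:, 0] - r["end"]    # track downstream of query
        d = np.maximum(np.maximum(gaps_left, gaps_right), 0)
        overlap = (iv[:, 0] < r["end"]) & (iv[:, 1] > r["start"])
        d[overlap] = 0
        out[k] = d.min()
    return out


# ----------------------------------------------------------- control regions

def sample_control_regions(
    regions: pd.DataFrame,
    gaps: pd.DataFrame,
    genome: dict[str, int],
    n_sets: int = 10,
    seed: int = 0,
    gap_tol: float = 0.02,
) -> list[pd.DataFrame]:
    """Random control sets matching the input sizes and gap overlap.

    Each control set reuses the exact region sizes, placed uniformly over
    the genome, with targeted resampling so the proportion of controls
    overlapping assembly gaps matches the input proportion within
    ``gap_tol``.
    """
    rng = np.random.default_rng(seed)
    sizes = (regions["end"] - regions["start"]).to_numpy()
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    target_prop = float(overlaps_any(regions, gaps).mean()) if len(gaps) else 0.0
    gap_merged = _merged(gaps) if len(gaps) else {}

    def place(size: int) -> tuple[str, int, int]:
        # chromosomes weighted by placeable length
        ok = lengths >= size
        w = np.where(ok, lengths - size + 1, 0.0)
        ci = rng.choice(len(chroms), p=w / w.sum())
        start = int(rng.integers(0, genome[chroms[ci]] - size + 1))
        return chroms[ci], start, start + size

    def hits_gap(chrom: str, start: int, end: int) -> bool:
        iv = gap_merged.get(chrom)
        if iv is None:
            return False
        j = np.searchsorted(iv[:, 0], end, side="left")
        return bool(j > 0 and iv[j - 1, 1] > start)

    sets = []
    n = len(sizes)
    for _ in range(n_sets):
        placed = [place(int(s)) for s in sizes]
        in_gap = np.array([hits_gap(*p) for p in placed])
        # targeted resampling until the gap-overlap proportion matches
        for _ in range(200 * n):
            prop = in_gap.mean()
            if abs(prop - target_prop) <= gap_tol:
                break
            want_gap = prop < target_prop
            cand = np.nonzero(in_gap != want_gap)[0]
            i = int(rng.choice(cand))
            for _ in range(1000):
                p = place(int(sizes[i]))
                if hits_gap(*p) == want_gap:
                    placed[i] = p
                    in_gap[i] = want_gap
                    break
            else:  # genome cannot produce the wanted class; give up
                break
        df = pd.DataFrame(placed, columns=["chrom", "start", "end"])
        sets.append(df)
    return sets


def fold_enrichment(
    regions: pd.DataFrame,
    track: pd.DataFrame,
    controls: list[pd.DataFrame],
) -> float:
    """(# regions overlapping the track) / (mean control-set count)."""
    obs = int(overlaps_any(regions, track).sum())
    ctrl = np.array([overlaps_any(c, track).sum() for c in controls], dtype=float)
    denom = ctrl.mean()
    if obs == 0 and denom == 0:
        raise ValueError("0/0 fold-enrichment is undefined")
    if denom == 0:
        return float("inf")
    return obs / denom


# -------------------------------------------------------------- burden tests

def burden_permutation(
    case_calls: pd.DataFrame,
    control_calls: pd.DataFrame,
    track: pd.DataFrame,
    genome: dict[str, int],
    gaps: pd.DataFrame | None = None,
    n_sub: int = 100,
    sub_size: int = 150,
    n_perm: int = 10_000,
    n_control_sets: int = 3,
    ro: float = 0.5,
    seed: int = 0,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Case-vs-control difference in track fold-enrichment.

    The statistic is the median over ``n_sub`` paired subsampled catalogs
    (each built from ``sub_size`` randomly chosen samples per cohort) of
    fold(case) - fold(control); the null permutes the cohort labels of the
    2 * n_sub catalog folds.  One-sided (excess in cases) by default.
    """
    if gaps is None:
        gaps = pd.DataFrame(columns=["chrom", "start", "end"])
    rng = np.random.default_rng(seed)
    case_samples = sorted(case_calls["sample"].unique())
    ctrl_samples = sorted(control_calls["sample"].unique())

    def subsample_fold(calls: pd.DataFrame, samples: list[str], sub_seed: int) -> float:
        r = np.random.default_rng(sub_seed)
        size = min(sub_size, len(samples))
        chosen = set(r.choice(samples, size=size, replace=False))
        cat = build_catalog(calls[calls["sample"].isin(chosen)], ro=ro, n_cohort=size)
        if cat.empty:
            return 0.0
        ctrl_sets = sample_control_regions(
            cat, gaps, genome, n_sets=n_control_sets, seed=int(r.integers(2**31))
        )
        return fold_enrichment(cat, track, ctrl_sets)

    # paired subsampling: the i-th case and control catalogs share the same
    # subsampling/control-region randomness, so identical cohorts give an
    # observed statistic of exactly zero
    sub_seeds = [int(rng.integers(2**31)) for _ in range(n_sub)]
    folds_case = np.array(
        [subsample_fold(case_calls, case_samples, s) for s in sub_seeds]
    )
    folds_ctrl = np.array(
        [subsample_fold(control_calls, ctrl_samples, s) for s in sub_seeds]
    )
    observed = float(np.median(folds_case - folds_ctrl))

    pooled = np.concatenate([folds_case, folds_ctrl])
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        null[i] = np.median(perm[:n_sub] - perm[n_sub:])
    if alternative == "greater":
        p = (1 + (null >= observed).sum()) / (n_perm + 1)
    elif alternative == "two-sided":
        p = (1 + (np.abs(null) >= abs(observed)).sum()) / (n_perm + 1)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return EnrichmentResult(
        fold=observed, null_folds=null, p_perm=float(p),
        n_subsamples=n_sub, n_perm=n_perm,
    )


def gene_hit_enrichment(
    hit_genes: set[str],
    known_genes: set[str],
    gene_sizes: pd.Series,
    n_sets: int = 10_000,
    n_strata: int = 20,
    seed: int = 0,
) -> dict:
    """Are known genes over-represented among CNV-hit genes, given gene size?

    Null gene sets are drawn to preserve the gene-length quantile-stratum
    composition of the hit set (``n_strata`` strata over all genes); the
    empirical p is the +1-corrected fraction of null sets hitting at least
    as many known genes.
    """
    rng = np.random.default_rng(seed)
    genes = gene_sizes.index.to_numpy()
    sizes = gene_sizes.to_numpy(dtype=float)
    qs = np.quantile(sizes, np.linspace(0, 1, n_strata + 1))
    strata = np.clip(np.searchsorted(qs, sizes, side="right") - 1, 0, n_strata - 1)
    stratum_of = dict(zip(genes, strata))
    known_arr = np.isin(genes, sorted(known_genes))

    hit_list = [g for g in hit_genes if g in stratum_of]
    observed = len(set(hit_list) & known_genes)
    comp = np.bincount([stratum_of[g] for g in hit_list], minlength=n_strata)
    members = [np.nonzero(strata == s)[0] for s in range(n_strata)]

    null = np.empty(n_sets, dtype=int)
    for i in range(n_sets):
        tot = 0
        for s in range(n_strata):
            k = comp[s]
            if k == 0:
                continue
            pick = rng.choice(members[s], size=min(k, members[s].size), replace=False)
            tot += int(known_arr[pick].sum())
        null[i] = tot
    p = (1 + (null >= observed).sum()) / (n_sets + 1)
    return {"observed": observed, "null": null, "p": float(p)}


def private_proportion(
    case_catalog: pd.DataFrame,
    control_calls: pd.DataFrame,
    case_n: int,
    n_down: int = 1_000,
    ro: float = 0.5,
    seed: int = 0,
) -> dict:
    """Proportion of catalog regions private to one sample, with a control
    reference distribution from repeated downsampling of the control cohort
    to the case sample size.  Also returns the fraction of regions seen in
    >= x samples for x = 1, 2, ...."""
    rng = np.random.default_rng(seed)
    prop = float((case_catalog["n_carriers"] == 1).mean())
    nmax = int(case_catalog["n_carriers"].max()) if len(case_catalog) else 1
    curve = pd.Series(
        {x: float((case_catalog["n_carriers"] >= x).mean()) for x in range(1, nmax + 1)}
    )
    ctrl_samples = sorted(control_calls["sample"].unique())
    size = min(case_n, len(ctrl_samples))
    props = np.empty(n_down)
    for i in range(n_down):
        chosen = set(rng.choice(ctrl_samples, size=size, replace=False))
        cat = build_catalog(
            control_calls[control_calls["sample"].isin(chosen)], ro=ro, n_cohort=size
        )
        props[i] = (cat["n_carriers"] == 1).mean() if len(cat) else np.nan
    props = props[~np.isnan(props)]
    ci = (float(np.quantile(props, 0.025)), float(np.quantile(props, 0.975)))
    p = (1 + (props >= prop).sum()) / (len(props) + 1)
    return {
        "proportion": prop,
        "curve": curve,
        "control_props": props,
        "ci": ci,
        "p": float(p),
    }


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """OR of a 2x2 table [[a, b], [c, d]] with Haldane correction on zeros."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def proximity_analysis(
    case_calls: pd.DataFrame,
    control_calls: pd.DataFrame,
    known_exons: pd.DataFrame,
    dist_grid: list[int],
    case_n: int | None = None,
    control_n: int | None = None,
    functional: pd.DataFrame | None = None,
    per_individual: bool = False,
    seed: int = 0,
) -> dict:
    """Distance of non-coding CNVs to the nearest known-gene exon.

    For each distance threshold d: the number of individuals per cohort
    with at least one qualifying call (optionally restricted to calls
    overlapping the ``functional`` track) within d bp of a known-gene exon,
    and the case/control odds ratio of being such an individual (Haldane
    0.5 correction when a table cell is zero).  A two-sample KS test
    compares the per-call (or per-individual minimum) distance
    distributions.  Controls are downsampled to the case cohort size.
    """
    rng = np.random.default_rng(seed)
    if case_n is None:
        case_n = case_calls["sample"].nunique()
    if control_n is None:
        control_n = control_calls["sample"].nunique()
    ctrl = control_calls
    eff_control_n = control_n
    if control_n > case_n:
        ctrl_samples = sorted(control_calls["sample"].unique())
        keep = set(rng.choice(ctrl_samples, size=min(case_n, len(ctrl_samples)), replace=False))
        ctrl = control_calls[control_calls["sample"].isin(keep)]
        eff_control_n = case_n

    def prep(calls: pd.DataFrame) -> pd.DataFrame:
        calls = calls.copy()
        if functional is not None and len(calls):
            calls = calls[overlaps_any(calls, functional)]
        if len(calls):
            calls["dist"] = nearest_distance(calls, known_exons)
        else:
            calls["dist"] = pd.Series(dtype=float)
        return calls

    case = prep(case_calls)
    ctrl = prep(ctrl)

    rows = []
    for d in dist_grid:
        n_case = case.loc[case["dist"] <= d, "sample"].nunique()
        n_ctrl = ctrl.loc[ctrl["dist"] <= d, "sample"].nunique()
        orr = _odds_ratio(n_case, case_n - n_case, n_ctrl, eff_control_n - n_ctrl)
        rows.append(
            {"distance": d, "n_case": n_case, "n_control": n_ctrl, "odds_ratio": orr}
        )
    curve = pd.DataFrame(rows)

    if per_individual:
        xc = case.groupby("sample")["dist"].min().to_numpy()
        xt = ctrl.groupby("sample")["dist"].min().to_numpy()
    else:
        xc = case["dist"].to_numpy()
        xt = ctrl["dist"].to_numpy()
    if len(xc) and len(xt):
        ks = stats.ks_2samp(xc, xt)
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat, ks_p = float("nan"), float("nan")
    return {
        "curve": curve,
        "ks_statistic": ks_stat,
        "ks_p": ks_p,
        "case_distances": xc,
        "control_distances": xt,
    }
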