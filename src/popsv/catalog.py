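"""Cohort-level CNV catalog: merging recurrent calls, database frequencies,
the rare (<1%) definition, and cohort comparison statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: a region is rare when its maximum database frequency is strictly below this
RARE_FREQ = 0.01

CATALOG_COLUMNS = ["chrom", "start", "end", "type", "carriers", "n_carriers", "cohort_freq"]


@dataclass
class SvDatabase:
    """An SV call-set used for frequency annotation.

    ``variants`` is a DataFrame with columns ``chrom, start, end, type,
    n_carriers``; carrier counts may not exceed ``n_samples``.
    """

    name: str
    n_samples: int
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.variants["n_carriers"] > self.n_samples).any():
            raise ValueError(f"{self.name}: carrier counts exceed n_samples")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def reciprocal_overlap(s1: int, e1: int, s2: int, e2: int) -> float:
    """min of the two mutual overlap fractions; 0 when disjoint."""
    ov = min(e1, e2) - max(s1, s2)
    if ov <= 0:
        return 0.0
    return min(ov / (e1 - s1), ov / (e2 - s2))


def build_catalog(
    calls: pd.DataFrame,
    ro: float = 0.5,
    n_cohort: int | None = None,
) -> pd.DataFrame:
    """Merge recurrent same-type calls into catalog regions.

    Same-type calls are clustered by single linkage on reciprocal overlap
    >= ``ro``; each cluster becomes one region spanning the union of its
    members, carrying the union of their samples.  ``cohort_freq`` is
    carriers / ``n_cohort`` (inferred from the distinct samples in
    ``calls`` when not given).
    """
    if n_cohort is None:
        n_cohort = calls["sample"].nunique()
    regions = []
    for (chrom, typ), sub in calls.groupby(["chrom", "type"], sort=False):
        sub = sub.sort_values(["start", "end"]).reset_index(drop=True)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        uf = _UnionFind(len(sub))
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                if starts[j] >= ends[i]:
                    break
                if reciprocal_overlap(starts[i], ends[i], starts[j], ends[j]) >= ro:
                    uf.union(i, j)
        groups: dict[int, list[int]] = {}
        for i in range(len(sub)):
            groups.setdefault(uf.find(i), []).append(i)
        for members in groups.values():
            carriers = sorted(set(sub.loc[members, "sample"]))
            regions.append(
                {
                    "chrom": chrom,
                    "start": int(starts[members].min()),
                    "end": int(ends[members].max()),
                    "type": typ,
                    "carriers": carriers,
                    "n_carriers": len(carriers),
                    "cohort_freq": len(carriers) / n_cohort,
                }
            )
    cat = pd.DataFrame(regions, columns=CATALOG_COLUMNS)
    cat = cat.sort_values(["chrom", "start", "end", "type"]).reset_index(drop=True)
    cat.attrs["n_cohort"] = n_cohort
    return cat


def annotate_frequency(
    regions: pd.DataFrame,
    dbs: list[SvDatabase],
    cov: float = 0.5,
) -> pd.DataFrame:
    """Annotate regions with their maximum database frequency.

    Per database: frequency = (sum of carrier counts of DB variants of any
    type covering >= ``cov`` of the region, capped at the database size)
    / n_samples.  ``db_freq`` is the maximum over databases and a region is
    ``rare`` when db_freq < 1% (strict).
    """
    regions = regions.copy()
    db_freq = np.zeros(len(regions))
    for db in dbs:
        v = db.variants
        freqs = np.zeros(len(regions))
        for k, (_, r) in enumerate(regions.iterrows()):
            length = r["end"] - r["start"]
            sub = v[v["chrom"] == r["chrom"]]
            ov = np.minimum(sub["end"].to_numpy(), r["end"]) - np.maximum(
                sub["start"].to_numpy(), r["start"]
            )
            hit = ov >= cov * length
            carriers = int(sub.loc[hit, "n_carriers"].sum())
            freqs[k] = min(carriers, db.n_samples) / db.n_samples
        db_freq = np.maximum(db_freq, freqs)
    regions["db_freq"] = db_freq
    regions["rare"] = db_freq < RARE_FREQ
    return regions


def deldup_test(
    catalog_cases: pd.DataFrame,
    catalog_controls: pd.DataFrame,
    downsample_to: int | None = None,
    control_samples: list[str] | None = None,
    seed: int = 0,
    rare_only: bool = True,
) -> dict:
    """Pearson chi-square (1 df) on the 2x2 DEL/DUP x cohort table of
    (rare) catalog regions, optionally after seeded downsampling of the
    control cohort to the case sample size."""
    def _counts(cat: pd.DataFrame) -> tuple[int, int]:
        if rare_only and "rare" in cat.columns:
            cat = cat[cat["rare"]]
        return int((cat["type"] == "DEL").sum()), int((cat["type"] == "DUP").sum())

    ctrl = catalog_controls
    if downsample_to is not None:
        if control_samples is None:
            control_samples = sorted(
                {s for cl in catalog_controls["carriers"] for s in cl}
            )
        rng = np.random.default_rng(seed)
        keep = set(rng.choice(control_samples, size=downsample_to, replace=False))
        ctrl = catalog_controls.copy()
        ctrl["carriers"] = ctrl["carriers"].apply(
            lambda cl: [s for s in cl if s in keep]
        )
        ctrl = ctrl[ctrl["carriers"].str.len() > 0]

    case_del, case_dup = _counts(catalog_cases)
    ctrl_del, ctrl_dup = _counts(ctrl)
    table = np.array([[case_del, case_dup], [ctrl_del, ctrl_dup]])
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return {"table": table, "chi2": float(chi2), "p": float(p), "dof": int(dof)}


def call_frequency_spectrum(
    calls: pd.DataFrame,
    n_cohort: int | None = None,
    strata: tuple[float, float] = (0.5, 0.95),
    ro: float = 0.5,
) -> pd.DataFrame:
    """Distribution of a typical sample's calls across cohort-frequency strata.

    Each call inherits the cohort frequency of its catalog region; per
    sample, its calls are divided into low (< strata[0]), mid and high
    (> strata[1]) frequency strata.  Returns per-sample proportions with the
    across-sample average in ``df.attrs["average"]``.
    """
    cat = build_catalog(calls, ro=ro, n_cohort=n_cohort)
    lo, hi = strata
    rows = []
    for sample, sub in calls.groupby("sample"):
        freqs = []
        for _, c in sub.iterrows():
            f = 0.0
            for _, r in cat[(cat["chrom"] == c["chrom"]) & (cat["type"] == c["type"])].iterrows():
                if sample in r["carriers"] and min(c["end"], r["end"]) > max(c["start"], r["start"]):
                    f = max(f, r["cohort_freq"])
            freqs.append(f)
        freqs = np.array(freqs)
        n = len(freqs)
        rows.append(
            {
                "sample": sample,
                "n_calls": n,
                "low": float((freqs < lo).mean()) if n else np.nan,
                "mid": float(((freqs >= lo) & (freqs <= hi)).mean()) if n else np.nan,
                "high": float((freqs > hi).mean()) if n else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["average"] = df[["low", "mid", "high"]].mean().to_dict()
    return df


def twin_replication(
    calls: pd.DataFrame,
    pairs: list[tuple[str, str]],
    max_freq: float = 0.5,
    n_cohort: int | None = None,
    ro: float = 0.5,
) -> pd.DataFrame:
    """Replication of one twin's calls in the co-twin.

    Calls whose catalog-region cohort frequency exceeds ``max_freq`` are
    removed first (systematic artefacts replicate trivially); a remaining
    call replicates when the partner has a same-type call overlapping it by
    at least 1 bp.  Returns per-sample counts and replication rate.
    """
    cat = build_catalog(calls, ro=ro, n_cohort=n_cohort)

    def region_freq(call: pd.Series) -> float:
        sub = cat[(cat["chrom"] == call["chrom"]) & (cat["type"] == call["type"])]
        f = 0.0
        for _, r in sub.iterrows():
            if call["sample"] in r["carriers"] and min(call["end"], r["end"]) > max(
                call["start"], r["start"]
            ):
                f = max(f, r["cohort_freq"])
        return f

    keep = calls[calls.apply(region_freq, axis=1) <= max_freq]
    rows = []
    for a, b in pairs:
        for me, partner in ((a, b), (b, a)):
            mine = keep[keep["sample"] == me]
            theirs = keep[keep["sample"] == partner]
            n_rep = 0
            for _, c in mine.iterrows():
                hit = theirs[
                    (theirs["chrom"] == c["chrom"])
                    & (theirs["type"] == c["type"])
                    & (theirs["start"] < c["end"])
                    & (theirs["end"] > c["start"])
                ]
                if not hit.empty:
                    n_rep += 1
            rows.append(
                {
                    "sample": me,
                    "partner": partner,
                    "n_calls": len(mine),
                    "n_replicated": n_rep,
                    "rate": n_rep / len(mine) if len(mine) else np.nan,
                }
            )
    return pd.DataFrame(rows)
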