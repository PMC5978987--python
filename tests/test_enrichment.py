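"""Matched control regions, fold-enrichment, permutation burden statistics,
gene-hit enrichment, private proportions and exon-proximity analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popsv import (
    burden_permutation,
    fold_enrichment,
    gene_hit_enrichment,
    nearest_distance,
    overlaps_any,
    private_proportion,
    proximity_analysis,
    sample_control_regions,
    simulate_annotation,
)
from popsv.enrichment import _odds_ratio

GENOME = {"c1": 2_000_000, "c2": 1_500_000}


def _iv(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _random_intervals(rng, n, genome=GENOME, max_size=30_000):
    rows = []
    chroms = list(genome)
    for _ in range(n):
        c = str(rng.choice(chroms))
        size = int(rng.integers(500, max_size))
        start = int(rng.integers(0, genome[c] - size))
        rows.append((c, start, start + size))
    return _iv(rows)


class TestIntervalPrimitives:
    def test_overlap_against_pyranges_oracle(self):
        import pyranges as pr

        rng = np.random.default_rng(0)
        for _ in range(30):
            # sort first: pyranges returns rows grouped by chromosome
            q = _random_intervals(rng, 40).sort_values(
                ["chrom", "start", "end"]).reset_index(drop=True)
            t = _random_intervals(rng, 25)
            got = overlaps_any(q, t)
            qr = pr.PyRanges(q.rename(columns={"chrom": "Chromosome", "start": "Start", "end": "End"}))
            tr = pr.PyRanges(t.rename(columns={"chrom": "Chromosome", "start": "Start", "end": "End"}))
            odf = qr.count_overlaps(tr).df.sort_values(
                ["Chromosome", "Start", "End"]).reset_index(drop=True)
            oracle = odf["NumberOverlaps"].to_numpy() > 0
            np.testing.assert_array_equal(got, oracle)

    def test_nearest_distance_against_bruteforce(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            q = _random_intervals(rng, 30)
            t = _random_intervals(rng, 20)
            got = nearest_distance(q, t)
            for k, (_, r) in enumerate(q.iterrows()):
                best = np.inf
                for _, e in t[t["chrom"] == r["chrom"]].iterrows():
                    if e["start"] < r["end"] and e["end"] > r["start"]:
                        d = 0
                    else:
                        d = max(e["start"] - r["end"], r["start"] - e["end"])
                    best = min(best, d)
                assert got[k] == best


class TestControlRegions:
    def test_sizes_preserved_exactly(self):
        regions = _iv([("c1", 0, 5_000), ("c1", 50_000, 60_000), ("c2", 0, 20_000)])
        sets = sample_control_regions(regions, _iv([]), GENOME, n_sets=5, seed=1)
        want = sorted([5_000, 10_000, 20_000])
        for s in sets:
            assert sorted((s["end"] - s["start"]).tolist()) == want

    def test_gap_overlap_matched_to_zero(self):
        rng = np.random.default_rng(2)
        regions = _random_intervals(rng, 50, max_size=10_000)
        gaps = _iv([("c1", 500_000, 600_000)])
        # force the input to have no gap overlap
        regions = regions[~overlaps_any(regions, gaps)].reset_index(drop=True)
        sets = sample_control_regions(regions, gaps, GENOME, n_sets=10, seed=3)
        for s in sets:
            assert overlaps_any(s, gaps).mean() <= 0.02 + 1e-9

    def test_gap_overlap_matched_to_positive_rate(self):
        gaps = _iv([("c1", 0, 400_000)])
        regions = _iv(
            [("c1", 100_000 + i * 30_000, 105_000 + i * 30_000) for i in range(10)]
            + [("c2", i * 40_000, i * 40_000 + 5_000) for i in range(10)]
        )
        target = overlaps_any(regions, gaps).mean()
        sets = sample_control_regions(regions, gaps, GENOME, n_sets=8, seed=4)
        for s in sets:
            assert abs(overlaps_any(s, gaps).mean() - target) <= 0.02 + 1e-9

    def test_placement_uniformity(self):
        """Mean midpoint over many control sets sits at the genome midpoint."""
        genome = {"c1": 1_000_000}
        regions = _iv([("c1", 0, 10_000)] * 4)
        sets = sample_control_regions(regions, _iv([]), genome, n_sets=250, seed=5)
        mids = np.concatenate([((s["start"] + s["end"]) / 2).to_numpy() for s in sets])
        se = 1_000_000 / np.sqrt(12) / np.sqrt(len(mids))
        assert abs(mids.mean() - 500_000) < 3 * se


class TestFoldEnrichment:
    def test_regions_equal_controls_give_unity(self):
        rng = np.random.default_rng(6)
        regions = _random_intervals(rng, 30)
        track = _random_intervals(rng, 20)
        assert fold_enrichment(regions, track, [regions.copy()]) == pytest.approx(1.0)

    def test_arithmetic(self):
        track = _iv([("c1", 0, 1_000)])
        hit = _iv([("c1", 500, 1_500)] * 8)
        miss = _iv([("c1", 10_000, 11_000)])
        controls = [
            pd.concat([hit.iloc[:4], miss.iloc[[0] * 4]], ignore_index=True),
        ]
        assert fold_enrichment(hit, track, controls) == pytest.approx(2.0)

    def test_matches_recount_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            regions = _random_intervals(rng, 25)
            track = _random_intervals(rng, 15)
            controls = [_random_intervals(rng, 25) for _ in range(3)]
            obs = overlaps_any(regions, track).sum()
            denom = np.mean([overlaps_any(c, track).sum() for c in controls])
            if obs == 0 and denom == 0:
                continue
            expect = np.inf if denom == 0 else obs / denom
            assert fold_enrichment(regions, track, controls) == pytest.approx(expect)

    def test_undefined_zero_over_zero(self):
        track = _iv([("c1", 0, 1_000)])
        far = _iv([("c2", 0, 5_000)])
        with pytest.raises(ValueError):
            fold_enrichment(far, track, [far.copy()])

    def test_invariant_to_chromosome_relabeling(self):
        rng = np.random.default_rng(8)
        regions = _random_intervals(rng, 20)
        track = _random_intervals(rng, 10)
        controls = [_random_intervals(rng, 20)]
        f1 = fold_enrichment(regions, track, controls)
        relabel = {"c1": "chrA", "c2": "chrB"}
        f2 = fold_enrichment(
            regions.assign(chrom=regions["chrom"].map(relabel)),
            track.assign(chrom=track["chrom"].map(relabel)),
            [c.assign(chrom=c["chrom"].map(relabel)) for c in controls],
        )
        assert f1 == pytest.approx(f2)


def _cohort_calls(rng, samples, n_per_sample, genome=GENOME, exonic_bias=None,
                  exons=None):
    rows = []
    for s in samples:
        for _ in range(n_per_sample):
            if exonic_bias is not None and rng.random() < exonic_bias:
                e = exons.iloc[int(rng.integers(len(exons)))]
                start = max(0, int(e["start"]) - int(rng.integers(0, 2_000)))
                rows.append((s, e["chrom"], start, start + int(rng.integers(3_000, 8_000)), "DEL"))
            else:
                c = str(rng.choice(list(genome)))
                size = int(rng.integers(3_000, 8_000))
                start = int(rng.integers(0, genome[c] - size))
                rows.append((s, c, start, start + size, "DEL"))
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "type"])


class TestBurdenPermutation:
    def test_identical_catalogs_null(self):
        rng = np.random.default_rng(9)
        ann, _ = simulate_annotation(GENOME, n_genes=40, seed=9)
        samples = [f"x{i}" for i in range(12)]
        calls = _cohort_calls(rng, samples, 4)
        res = burden_permutation(
            calls, calls.copy(), ann.exons, GENOME, gaps=ann.gaps,
            n_sub=8, sub_size=12, n_perm=200, seed=9,
        )
        assert res.fold == pytest.approx(0.0)
        assert res.p_perm > 0.5

    def test_planted_excess_detected(self):
        rng = np.random.default_rng(10)
        ann, _ = simulate_annotation(GENOME, n_genes=40, seed=10)
        case = _cohort_calls(rng, [f"p{i}" for i in range(25)], 5,
                             exonic_bias=0.7, exons=ann.exons)
        ctrl = _cohort_calls(rng, [f"q{i}" for i in range(25)], 5)
        res = burden_permutation(
            case, ctrl, ann.exons, GENOME, gaps=ann.gaps,
            n_sub=10, sub_size=15, n_perm=500, seed=10,
        )
        assert res.fold > 0
        assert res.p_perm < 0.05

    def test_p_value_bounds_and_reproducibility(self):
        rng = np.random.default_rng(11)
        ann, _ = simulate_annotation(GENOME, n_genes=30, seed=11)
        calls = _cohort_calls(rng, [f"x{i}" for i in range(10)], 3)
        other = _cohort_calls(rng, [f"y{i}" for i in range(10)], 3)
        kw = dict(n_sub=6, sub_size=8, n_perm=99, seed=12)
        r1 = burden_permutation(calls, other, ann.exons, GENOME, **kw)
        r2 = burden_permutation(calls, other, ann.exons, GENOME, **kw)
        assert r1.p_perm == r2.p_perm
        assert 1 / 100 <= r1.p_perm <= 1.0


class TestGeneHitEnrichment:
    def _sizes(self, rng, n=200):
        return pd.Series(
            rng.integers(5_000, 200_000, size=n),
            index=[f"G{i:04d}" for i in range(n)],
        )

    def test_all_genes_known_gives_p_one(self):
        rng = np.random.default_rng(13)
        sizes = self._sizes(rng)
        known = set(sizes.index)
        res = gene_hit_enrichment(set(sizes.index[:20]), known, sizes, n_sets=200, seed=13)
        assert res["p"] == pytest.approx(1.0)

    def test_perfect_hit_of_rare_known_set_at_floor(self):
        rng = np.random.default_rng(14)
        sizes = self._sizes(rng)
        known = set(sizes.index[:5])
        res = gene_hit_enrichment(known, known, sizes, n_sets=500, seed=14)
        assert res["p"] <= 5 / 501  # at or near the +1 floor

    def test_size_matched_null_calibration(self):
        """Uniform-within-strata hit sets give roughly uniform p-values."""
        rng = np.random.default_rng(15)
        sizes = self._sizes(rng, n=300)
        known = set(rng.choice(sizes.index, size=30, replace=False))
        ps = []
        for seed in range(40):
            hits = set(np.random.default_rng(seed).choice(sizes.index, size=25, replace=False))
            ps.append(gene_hit_enrichment(hits, known, sizes, n_sets=300, seed=seed)["p"])
        frac = np.mean([p < 0.1 for p in ps])
        lo, hi = stats.binom.ppf([0.025, 0.975], 40, 0.1) / 40
        assert lo <= frac <= hi


class TestPrivateProportion:
    def _catalog(self, carrier_counts):
        return pd.DataFrame(
            {
                "chrom": "c1",
                "start": np.arange(len(carrier_counts)) * 10_000,
                "end": np.arange(len(carrier_counts)) * 10_000 + 5_000,
                "type": "DEL",
                "carriers": [[f"s{j}" for j in range(k)] for k in carrier_counts],
                "n_carriers": carrier_counts,
            }
        )

    def test_all_private(self):
        rng = np.random.default_rng(16)
        ctrl = _cohort_calls(rng, [f"y{i}" for i in range(8)], 2)
        res = private_proportion(self._catalog([1, 1, 1]), ctrl, case_n=5, n_down=20, seed=16)
        assert res["proportion"] == pytest.approx(1.0)

    def test_toy_proportion(self):
        rng = np.random.default_rng(17)
        ctrl = _cohort_calls(rng, [f"y{i}" for i in range(8)], 2)
        res = private_proportion(self._catalog([1, 1, 2, 3]), ctrl, case_n=5, n_down=20, seed=17)
        assert res["proportion"] == pytest.approx(0.5)
        assert res["curve"][1] == pytest.approx(1.0)
        assert res["curve"][2] == pytest.approx(0.5)
        assert res["curve"][3] == pytest.approx(0.25)

    def test_ci_and_p_reproducible(self):
        rng = np.random.default_rng(18)
        ctrl = _cohort_calls(rng, [f"y{i}" for i in range(10)], 3)
        r1 = private_proportion(self._catalog([1, 2]), ctrl, case_n=6, n_down=50, seed=19)
        r2 = private_proportion(self._catalog([1, 2]), ctrl, case_n=6, n_down=50, seed=19)
        assert r1["ci"] == r2["ci"] and r1["p"] == r2["p"]


class TestProximity:
    def test_odds_ratio_closed_form(self):
        assert _odds_ratio(40, 160, 20, 180) == pytest.approx(2.25)

    def test_haldane_correction_on_zero_cell(self):
        assert _odds_ratio(4, 196, 0, 200) == pytest.approx(
            (4.5 * 200.5) / (196.5 * 0.5)
        )

    def test_identical_cohorts_or_one(self):
        rng = np.random.default_rng(20)
        exons = _random_intervals(rng, 10)
        calls = _cohort_calls(rng, [f"x{i}" for i in range(10)], 3)
        res = proximity_analysis(
            calls, calls.copy(), exons, dist_grid=[5_000, 50_000, 500_000], seed=20
        )
        assert np.allclose(res["curve"]["odds_ratio"], 1.0)
        assert res["ks_p"] > 0.99

    def test_distance_enrichment_detected(self):
        """Case calls planted near known exons give OR > 1 at short range
        and a small KS p."""
        rng = np.random.default_rng(21)
        exons = _random_intervals(rng, 12)
        near_rows = []
        for i in range(15):
            e = exons.iloc[int(rng.integers(len(exons)))]
            start = int(e["end"]) + int(rng.integers(500, 4_000))
            near_rows.append((f"p{i}", e["chrom"], start, start + 2_000, "DEL"))
        case = pd.DataFrame(near_rows, columns=["sample", "chrom", "start", "end", "type"])
        ctrl = _cohort_calls(rng, [f"q{i}" for i in range(15)], 1)
        res = proximity_analysis(case, ctrl, exons, dist_grid=[5_000], seed=21)
        assert res["curve"]["odds_ratio"].iloc[0] > 1
        assert res["ks_p"] < 0.05

    def test_functional_restriction_filters_calls(self):
        rng = np.random.default_rng(22)
        exons = _iv([("c1", 100_000, 101_000)])
        func = _iv([("c1", 150_000, 160_000)])
        case = pd.DataFrame(
            [("p0", "c1", 155_000, 158_000, "DEL"),   # in functional track
             ("p1", "c1", 300_000, 305_000, "DEL")],  # not
            columns=["sample", "chrom", "start", "end", "type"],
        )
        ctrl = case.copy()
        ctrl["sample"] = ["q0", "q1"]
        res = proximity_analysis(
            case, ctrl, exons, dist_grid=[100_000], functional=func, seed=22
        )
        assert res["curve"]["n_case"].iloc[0] == 1
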