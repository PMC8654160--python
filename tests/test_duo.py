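"""Fisher combination, duo optimization, regions, and post-hoc filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from duosgs.duo import (
    DuoRegion,
    annotate_regions,
    duo_profile,
    extract_regions,
    fisher_combine,
    intersect_segments,
    optimize_duo,
    posthoc_filter,
)
from duosgs.sgs_core import OptimalProfile, SharedSegment, optimize_profile

from test_sgs_core import seg


def profile_from_p(p, pedigree_id="P"):
    return OptimalProfile(
        pedigree_id=pedigree_id,
        p=np.asarray(p, float),
        seg_index=np.full(len(p), -1, dtype=np.int64),
        segments=[],
    )


class TestFisherCombine:
    # published duo p-values for published single-pedigree pairs
    PUBLISHED = [
        (2.80e-5, 1.14e-5, 7.30e-9),    # 18q21.33
        (4.30e-4, 6.00e-6, 5.36e-8),    # 5q21.3
        (2.90e-5, 6.70e-5, 4.09e-8),    # 7q11.23
        (6.70e-5, 1.89e-4, 2.43e-7),    # 2p16.1
        (3.60e-5, 3.87e-4, 2.66e-7),    # 13q13.3
        (1.62e-3, 3.80e-5, 1.08e-6),    # 1q42.2
    ]

    @pytest.mark.parametrize("p1,p2,expected", PUBLISHED)
    def test_published_pairs_three_sig_figs(self, p1, p2, expected):
        got = fisher_combine(p1, p2)
        assert got == pytest.approx(expected, rel=5e-3)

    def test_unit_inputs(self):
        assert fisher_combine(1.0, 1.0) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine(0.0, 0.5)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.floats(1e-12, 1.0), st.floats(1e-12, 1.0), st.floats(1e-12, 1.0)
    )
    def test_symmetry_monotonicity_and_chi2_identity(self, p1, p2, p3):
        a = fisher_combine(p1, p2)
        assert a == pytest.approx(fisher_combine(p2, p1))
        # closed form equals an independent chi-square survival evaluation
        X = -2.0 * (np.log(p1) + np.log(p2))
        assert a == pytest.approx(stats.chi2.sf(X, 4), rel=1e-12, abs=1e-300)
        # monotone non-decreasing in each argument
        lo, hi = sorted((p2, p3))
        assert fisher_combine(p1, lo) <= fisher_combine(p1, hi) + 1e-15


class TestDuoProfile:
    def test_partner_all_ones(self):
        fixed = profile_from_p([0.5, 1e-3, 1.0])
        partner = profile_from_p([1.0, 1.0, 1.0])
        got = duo_profile(fixed, partner)
        exp = [fisher_combine(p, 1.0) for p in fixed.p]
        np.testing.assert_allclose(got, exp)

    def test_both_ones(self):
        got = duo_profile(profile_from_p([1.0] * 4), profile_from_p([1.0] * 4))
        np.testing.assert_allclose(got, 1.0)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="grids"):
            duo_profile(profile_from_p([1.0]), profile_from_p([1.0, 1.0]))

    def test_random_profiles_match_positionwise_oracle(self):
        rng = np.random.default_rng(2)
        a = profile_from_p(rng.uniform(1e-6, 1, 200))
        b = profile_from_p(rng.uniform(1e-6, 1, 200))
        got = duo_profile(a, b)
        for i in range(200):
            q = a.p[i] * b.p[i]
            assert got[i] == pytest.approx(q * (1 - np.log(q)))


class TestOptimizeDuo:
    def test_two_pedigrees_equals_duo_profile(self):
        profs = {
            "A": profile_from_p([0.5, 1e-4, 1.0], "A"),
            "B": profile_from_p([0.1, 1e-2, 1.0], "B"),
        }
        duo = optimize_duo("A", profs)
        np.testing.assert_allclose(
            duo.combined_p, duo_profile(profs["A"], profs["B"])
        )
        assert duo.partner_ids == ["B"]

    def test_dominating_partner_wins_everywhere(self):
        profs = {
            "A": profile_from_p([0.5, 0.2, 0.9], "A"),
            "B": profile_from_p([1e-4, 1e-5, 1e-3], "B"),
            "C": profile_from_p([0.9, 0.8, 0.7], "C"),
        }
        duo = optimize_duo("A", profs)
        assert all(duo.winning_partner(i) == "B" for i in range(3))

    def test_single_pedigree_rejected(self):
        with pytest.raises(ValueError):
            optimize_duo("A", {"A": profile_from_p([1.0])})

    def test_matches_exhaustive_partner_scan(self):
        rng = np.random.default_rng(3)
        profs = {
            pid: profile_from_p(rng.uniform(1e-6, 1, 150), pid)
            for pid in "ABCD"
        }
        duo = optimize_duo("B", profs)
        others = [p for p in "ACD"]
        stack = np.stack([duo_profile(profs["B"], profs[p]) for p in others])
        np.testing.assert_allclose(duo.combined_p, stack.min(axis=0))
        for i in range(150):
            assert duo.winning_partner(i) == others[int(np.argmin(stack[:, i]))]
        # optimized result is <= every single-partner combination
        for p in others:
            assert np.all(
                duo.combined_p <= duo_profile(profs["B"], profs[p]) + 1e-18
            )


class TestIntersectSegments:
    def test_basic_overlap(self):
        assert intersect_segments(("1", 1, 10), ("1", 5, 20)) == ("1", 5, 10)

    def test_disjoint_empty(self):
        assert intersect_segments(("1", 1, 4), ("1", 5, 9)) is None

    def test_chromosome_mismatch(self):
        with pytest.raises(ValueError):
            intersect_segments(("1", 1, 4), ("2", 1, 4))

    def test_published_18q_intersection(self):
        got = intersect_segments(
            ("18", 57_945_602, 59_167_836), ("18", 58_208_260, 59_059_262)
        )
        assert got == ("18", 58_208_260, 59_059_262)

    def test_idempotent_on_identical(self):
        assert intersect_segments(("3", 5, 9), ("3", 5, 9)) == ("3", 5, 9)


def _two_profiles_with_segments(n=60):
    fa = seg(10, 30, 1e-4, subset=("a1", "a2"), ped="A")
    fb = seg(15, 40, 2e-4, subset=("b1", "b2", "b3"), ped="B")
    pa = optimize_profile([fa], n, "A")
    pb = optimize_profile([fb], n, "B")
    return {"A": pa, "B": pb}, fa, fb


def snps_frame(n=60):
    return pd.DataFrame(
        {"chrom": ["1"] * n, "snp_id": [f"m{i}" for i in range(n)],
         "cm": np.arange(n, dtype=float), "bp": 1000 * (1 + np.arange(n))}
    )


class TestExtractRegions:
    def test_none_below_threshold(self):
        profs, *_ = _two_profiles_with_segments()
        duo = optimize_duo("A", profs)
        assert extract_regions(duo, 1e-12, profs, snps_frame()) == []

    def test_region_reports_both_segments_and_intersection(self):
        profs, fa, fb = _two_profiles_with_segments()
        duo = optimize_duo("A", profs)
        regions = extract_regions(duo, 1e-4, profs, snps_frame())
        assert len(regions) == 1
        r = regions[0]
        assert r.fixed_segment.subset == fa.subset
        assert r.partner_segment.subset == fb.subset
        assert (r.overlap_start, r.overlap_end) == (
            max(fa.start_bp, fb.start_bp), min(fa.end_bp, fb.end_bp)
        )

    def test_interior_below_threshold_flanks_above(self):
        profs, fa, fb = _two_profiles_with_segments()
        duo = optimize_duo("A", profs)
        thr = 1e-4
        for r in extract_regions(duo, thr, profs, snps_frame()):
            bp = snps_frame()["bp"].to_numpy()
            inside = (bp >= r.start_bp) & (bp <= r.end_bp)
            assert np.all(duo.combined_p[inside] <= thr)
            edges = np.flatnonzero(inside)
            if edges[0] > 0:
                assert duo.combined_p[edges[0] - 1] > thr
            if edges[-1] < len(bp) - 1:
                assert duo.combined_p[edges[-1] + 1] > thr


def region(fixed="A", partner="B", chrom="1", start=100, end=200, p=1e-6,
           fsub=("a1", "a2"), psub=("b1", "b2")):
    fseg = SharedSegment(fixed, fsub, chrom, 0, 1, start, end, 1e-3)
    pseg = SharedSegment(partner, psub, chrom, 0, 1, start, end, 1e-3)
    return DuoRegion(
        locus=f"{chrom}:{start}-{end}", fixed_id=fixed, partner_id=partner,
        chrom=chrom, start_bp=start, end_bp=end, combined_p=p,
        fixed_segment=fseg, partner_segment=pseg,
        overlap_start=start, overlap_end=end,
    )


class TestPosthocFilter:
    def test_duplicate_pair_keeps_most_significant(self):
        a = region(fixed="A", partner="B", p=1e-8)
        b = region(fixed="B", partner="A", p=1e-8)
        # identical p: thresholds decide ("most significant" is p relative
        # to the fixed pedigree's own significant threshold)
        out = posthoc_filter([a, b], thresholds={"A": 1e-7, "B": 1e-6})
        assert out == [b]

    def test_overlap_individual_removed(self):
        shared = region(fsub=("x", "a2"), psub=("x", "b2"))
        clean = region(start=5000, end=6000)
        out = posthoc_filter([shared, clean])
        assert out == [clean]

    def test_centromere_spanning_removed(self):
        cen = pd.DataFrame({"chrom": ["1"], "start": [150], "end": [160]})
        spanning = region(start=100, end=200)
        clear = region(start=300, end=400)
        out = posthoc_filter([spanning, clear], centromeres=cen)
        assert out == [clear]

    def test_interval_overlap_oracle(self):
        rng = np.random.default_rng(4)
        cen = pd.DataFrame({"chrom": ["1"], "start": [5000], "end": [6000]})
        regions = []
        for _ in range(40):
            s = int(rng.integers(0, 10_000))
            e = s + int(rng.integers(1, 2000))
            regions.append(region(start=s, end=e, p=float(rng.uniform(1e-9, 1e-5))))
        # distinct pairs so only the centromere filter acts
        for i, r in enumerate(regions):
            r.partner_id = f"B{i}"
        out = posthoc_filter(regions, centromeres=cen)
        survivors = {(r.start_bp, r.end_bp) for r in out}
        for r in regions:
            overlaps = r.start_bp <= 6000 and r.end_bp >= 5000
            assert ((r.start_bp, r.end_bp) in survivors) == (not overlaps)


class TestAnnotateRegions:
    def test_empty_gene_table(self):
        r = region()
        out = annotate_regions([r], pd.DataFrame(columns=["chrom", "start", "end", "name"]))
        assert out[0].genes == []

    def test_published_18q_gene(self):
        r = region(chrom="18", start=58_208_260, end=59_059_262)
        genes = pd.DataFrame(
            {"chrom": ["18"], "start": [59_000_815], "end": [59_223_006],
             "name": ["CDH20"]}
        )
        assert annotate_regions([r], genes)[0].genes == ["CDH20"]

    def test_matches_quadratic_scan(self):
        rng = np.random.default_rng(5)
        regions = [
            region(start=int(s), end=int(s) + 500, p=1e-6)
            for s in rng.integers(0, 50_000, 15)
        ]
        for i, r in enumerate(regions):
            r.partner_id = f"B{i}"
        genes = pd.DataFrame(
            {
                "chrom": ["1"] * 30,
                "start": rng.integers(0, 50_000, 30),
            }
        ).assign(end=lambda d: d.start + 300, name=[f"g{i}" for i in range(30)])
        out = annotate_regions(regions, genes)
        for r in out:
            expected = sorted(
                row["name"]
                for _, row in genes.iterrows()
                if row.start <= r.overlap_end and row.end >= r.overlap_start
            )
            assert sorted(r.genes) == expected
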