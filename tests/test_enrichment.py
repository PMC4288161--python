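import math

import numpy as np
import pytest

from modmotif.config import PipelineConfig
from modmotif.enrichment import (background_fraction, build_region_types,
                                 enrichment_profile, intersect_bp,
                                 merge_intervals, points_in_set,
                                 subtract_intervals)
# aliased so pytest does not collect the library function as a test
from modmotif.enrichment import test_enrichment as enrich_test
from modmotif.io import GeneModel, GenomicRegion, InputError


def binom_tail_oracle(k, n, p):
    return sum(math.comb(n, i) * p ** i * (1 - p) ** (n - i)
               for i in range(k, n + 1))


class TestIntervalOps:
    def test_merge_overlapping_and_adjacent(self):
        got = merge_intervals([(5, 10), (0, 3), (9, 12), (3, 4)])
        assert got.tolist() == [[0, 4], [5, 12]]

    def test_subtract_punches_holes(self):
        a = merge_intervals([(0, 100)])
        b = merge_intervals([(10, 20), (50, 60)])
        assert subtract_intervals(a, b).tolist() == [[0, 10], [20, 50],
                                                     [60, 100]]

    def test_intersect_bp_counts_overlap(self):
        a = merge_intervals([(0, 10), (20, 30)])
        b = merge_intervals([(5, 25)])
        assert intersect_bp(a, b) == 10

    def test_points_in_set_half_open(self):
        ivset = {"chr1": merge_intervals([(10, 20)])}
        inside = points_in_set(["chr1"] * 3 + ["chr2"], [10, 19, 20, 15],
                               ivset)
        assert inside.tolist() == [True, True, False, False]


TOY_GENES = [
    GeneModel("g1", "chr1", "+", 10_000, 15_000,
              exons=[(10_000, 10_400), (11_000, 11_300), (14_000, 15_000)],
              five_utrs=[(10_000, 10_200)], three_utrs=[(14_500, 15_000)]),
    GeneModel("g2", "chr1", "-", 40_000, 46_000,
              exons=[(40_000, 40_800), (42_000, 42_300), (45_500, 46_000)],
              five_utrs=[(45_700, 46_000)], three_utrs=[(40_000, 40_300)]),
]
TOY_CHROMS = {"chr1": 200_000}


class TestRegionTypes:
    cfg = PipelineConfig()

    def test_sixteen_primary_types(self):
        rmap = build_region_types(TOY_GENES, TOY_CHROMS, self.cfg,
                                  include_pure=False)
        assert len(rmap) == 16

    def test_strand_aware_proximal_windows(self):
        rmap = build_region_types(TOY_GENES, TOY_CHROMS, self.cfg)
        assert rmap["proximal_tss"]["chr1"].tolist() == [[7_500, 10_000],
                                                         [46_000, 48_500]]
        assert rmap["proximal_tts"]["chr1"].tolist() == [[15_000, 17_500],
                                                         [37_500, 40_000]]

    def test_pure_variants_are_subsets(self):
        rmap = build_region_types(TOY_GENES, TOY_CHROMS, self.cfg)
        for name in ("proximal_tss", "proximal_tts"):
            pure = rmap[f"pure_{name}"]
            for chrom, arr in pure.items():
                primary = rmap[name][chrom]
                for s, e in arr:
                    assert intersect_bp(primary,
                                        merge_intervals([(s, e)])) == e - s

    def test_types_internally_disjoint(self):
        rmap = build_region_types(TOY_GENES, TOY_CHROMS, self.cfg)
        for ivset in rmap.values():
            for arr in ivset.values():
                assert np.all(arr[:, 0] < arr[:, 1])
                assert np.all(arr[1:, 0] > arr[:-1, 1] - 1)


class TestBackgroundFraction:
    def test_full_cover_is_one(self):
        dhs = [GenomicRegion("chr1", 100, 300, "a")]
        assert background_fraction({"chr1": merge_intervals([(0, 1000)])},
                                   dhs) == 1.0

    def test_disjoint_is_zero(self):
        dhs = [GenomicRegion("chr1", 100, 300, "a")]
        assert background_fraction({"chr1": merge_intervals([(500, 900)])},
                                   dhs) == 0.0

    def test_partial_overlap_ratio(self):
        dhs = [GenomicRegion("chr1", 0, 500, "a"),
               GenomicRegion("chr1", 600, 1100, "b")]
        ivset = {"chr1": merge_intervals([(400, 500), (600, 700)])}
        assert background_fraction(ivset, dhs) == pytest.approx(0.2)

    def test_zero_dhs_bp_rejected(self):
        with pytest.raises(InputError):
            background_fraction({"chr1": merge_intervals([(0, 10)])}, [])


class TestEnrichmentTest:
    cfg = PipelineConfig()
    ivset = {"chr1": merge_intervals([(0, 1000)])}

    def sites(self, n_in, n_out):
        inside = [("chr1", 10 * i, 10 * i + 8) for i in range(n_in)]
        outside = [("chr1", 2000 + 10 * i, 2008 + 10 * i)
                   for i in range(n_out)]
        return inside + outside

    def test_hand_case_ten_sites(self):
        res = enrich_test(self.sites(5, 5), self.ivset, 0.2, 1, self.cfg)
        assert res.k_in == 5
        assert res.pvalue == pytest.approx(binom_tail_oracle(5, 10, 0.2),
                                           abs=1e-12)
        assert res.pvalue == pytest.approx(0.0327935, abs=1e-7)

    def test_saturated_background_never_enriched(self):
        res = enrich_test(self.sites(10, 0), self.ivset, 1.0, 1, self.cfg)
        assert res.pvalue == 1.0
        assert not res.enriched

    def test_zero_hits_pvalue_one(self):
        res = enrich_test(self.sites(0, 10), self.ivset, 0.2, 1, self.cfg)
        assert res.pvalue == 1.0

    def test_zero_background_with_hits_is_degenerate(self):
        res = enrich_test(self.sites(3, 0), self.ivset, 0.0, 1, self.cfg)
        assert res.pvalue == 0.0
        assert res.degenerate

    def test_matches_direct_summation_on_random_cases(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 50))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.01, 0.99))
            sites = self.sites(k, n - k)
            res = enrich_test(sites, self.ivset, p, 1, self.cfg)
            want = 1.0 if k == 0 else binom_tail_oracle(k, n, p)
            assert res.pvalue == pytest.approx(want, abs=1e-12)


class TestEnrichmentProfile:
    cfg = PipelineConfig()

    def test_planted_proximal_motif_enriched_only_there(self):
        rmap = build_region_types(TOY_GENES, TOY_CHROMS, self.cfg,
                                  include_pure=False)
        rng = np.random.default_rng(6)
        # DHS panel spanning promoter and far-distal territory
        dhs = [GenomicRegion("chr1", 7_500 + 100 * i, 7_600 + 100 * i, f"p{i}")
               for i in range(25)]
        dhs += [GenomicRegion("chr1", 120_000 + 100 * i, 120_100 + 100 * i,
                              f"d{i}") for i in range(75)]
        tss_sites = [("chr1", int(x), int(x) + 8)
                     for x in rng.integers(7_500, 9_900, 60)]
        scattered = [("chr1", int(r.start) + 20, int(r.start) + 28)
                     for r in rng.choice(dhs, size=60, replace=False)]
        prof = enrichment_profile({"tss_motif": tss_sites,
                                   "scattered": scattered}, rmap, dhs,
                                  self.cfg)
        tss_rows = prof[prof.motif_id == "tss_motif"].set_index("region_type")
        assert tss_rows.loc["proximal_tss"].enriched
        distal_names = [n for n in rmap if n.startswith("distal")]
        assert not tss_rows.loc[distal_names].enriched.any()
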