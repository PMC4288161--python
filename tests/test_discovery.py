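import math

import numpy as np
import pytest

from modmotif import seqs
from modmotif.config import PipelineConfig
from modmotif.discovery import (MotifModule,
                                brute_force_modules, discover_modules,
                                lexically_blocked_pairs, module_pvalue,
                                occurrence_sets, pattern_sites, run_discovery)
from modmotif import synthetic
from tests.conftest import dataset_from_sequences


def binom_tail_oracle(support, n, q):
    """Independent direct summation of the upper binomial tail."""
    return sum(math.comb(n, i) * q ** i * (1 - q) ** (n - i)
               for i in range(support, n + 1))


class TestModulePvalue:
    def test_hand_case_sets_six_and_five_over_ten(self):
        sets = [set(range(6)), set(range(1, 6))]  # sizes 6, 5; intersection 5
        p = module_pvalue(sets, 10)
        assert p == pytest.approx(binom_tail_oracle(5, 10, 0.30), abs=1e-12)
        assert p == pytest.approx(0.1502683326, abs=1e-9)

    def test_zero_support_gives_one(self):
        assert module_pvalue([{1, 2}, {3, 4}], 10) == 1.0

    def test_empty_member_set_gives_one(self):
        assert module_pvalue([set(), {1, 2}], 10) == 1.0

    def test_saturated_null_gives_one(self):
        full = set(range(10))
        assert module_pvalue([full, full], 10) == 1.0

    def test_matches_oracle_on_random_cases(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 50))
            a = set(rng.choice(n, size=int(rng.integers(1, n)), replace=False))
            b = set(rng.choice(n, size=int(rng.integers(1, n)), replace=False))
            q = len(a) * len(b) / n ** 2
            support = len(a & b)
            expected = 1.0 if support == 0 else binom_tail_oracle(support, n, q)
            assert module_pvalue([a, b], n) == pytest.approx(expected,
                                                             abs=1e-12)


class TestOccurrenceSets:
    def test_planted_regions_recovered(self):
        pat = "ACGTTGCA"
        sequences = ["T" * 30 for _ in range(6)]
        for i in (1, 3, 5):
            sequences[i] = "TTTT" + pat + "T" * 18
        ds = dataset_from_sequences(sequences)
        occ = occurrence_sets([pat], ds)
        assert occ[pat] == {f"test:r{i}" for i in (1, 3, 5)}

    def test_reverse_complement_occurrence_counts(self):
        pat = "ACGTTGCA"
        ds = dataset_from_sequences(["G" * 10 + seqs.revcomp(pat) + "G" * 10])
        occ = occurrence_sets([pat], ds)
        assert occ[pat] == {"test:r0"}

    def test_absent_pattern_gives_empty_set(self):
        ds = dataset_from_sequences(["A" * 40])
        assert occurrence_sets(["ACGTTGCA"], ds)["ACGTTGCA"] == set()


def random_occurrence_instance(rng, n_patterns, n_regions, heavy=False):
    """Random per-pattern region sets over disjoint-looking 8-mers."""
    pats = []
    while len(pats) < n_patterns:
        p = "".join(rng.choice(list("ACGT"), size=8))
        pats.append(p)
    pats = list(dict.fromkeys(pats))
    occ = {}
    for p in pats:
        dense = 0.6 if heavy else float(rng.uniform(0.05, 0.5))
        size = max(1, int(dense * n_regions))
        occ[p] = set(int(x) for x in
                     rng.choice(n_regions, size=size, replace=False))
    return occ


class TestDiscoverModules:
    def test_strong_planted_pair_is_significant(self, rng):
        cfg = PipelineConfig()
        n = 1000
        shared = set(range(400))
        a = shared | set(range(400, 450))
        b = shared | set(range(450, 500))
        occ = {"AAAACCCC": a, "GGTGGTGG": b}
        mods = discover_modules(occ, cfg, n_regions=n)
        assert len(mods) == 1
        (m,) = mods
        assert m.motif_ids == frozenset(occ)
        assert m.support == 400
        q = (450 / n) ** 2
        assert m.pvalue == pytest.approx(binom_tail_oracle(400, n, q),
                                         rel=1e-9)

    def test_pruned_search_equals_exhaustive_enumeration(self, rng):
        cfg = PipelineConfig()
        for trial in range(10):
            occ = random_occurrence_instance(
                rng, n_patterns=int(rng.integers(4, 10)),
                n_regions=int(rng.integers(20, 50)), heavy=trial % 2 == 0)
            fast = discover_modules(occ, cfg, n_regions=50)
            slow = brute_force_modules(occ, cfg, n_regions=50)
            assert [(m.motif_ids, m.support) for m in fast] == \
                   [(m.motif_ids, m.support) for m in slow]
            for f, s in zip(fast, slow):
                assert f.pvalue == pytest.approx(s.pvalue, abs=1e-12)
                assert f.corrected_pvalue == pytest.approx(s.corrected_pvalue,
                                                           abs=1e-12)

    def test_supports_match_recomputed_intersections(self, rng):
        cfg = PipelineConfig()
        occ = random_occurrence_instance(rng, 8, 40, heavy=True)
        for m in discover_modules(occ, cfg, n_regions=40):
            inter = set.intersection(*(occ[p] for p in m.motif_ids))
            assert m.support == len(inter)

    def test_anti_monotone_supports_among_reported(self, rng):
        cfg = PipelineConfig(module_alpha=0.5)
        occ = random_occurrence_instance(rng, 8, 30, heavy=True)
        mods = {m.motif_ids: m.support
                for m in discover_modules(occ, cfg, n_regions=30)}
        for a, sa in mods.items():
            for b, sb in mods.items():
                if a < b:
                    assert sa >= sb

    def test_output_invariant_to_region_relabeling(self, rng):
        cfg = PipelineConfig()
        occ = random_occurrence_instance(rng, 6, 30, heavy=True)
        perm = rng.permutation(30)
        remapped = {p: {int(perm[i]) for i in s} for p, s in occ.items()}
        a = discover_modules(occ, cfg, n_regions=30)
        b = discover_modules(remapped, cfg, n_regions=30)
        assert [(m.motif_ids, m.support, m.pvalue) for m in a] == \
               [(m.motif_ids, m.support, m.pvalue) for m in b]

    def test_lexically_entangled_pairs_never_tested(self):
        cfg = PipelineConfig()
        # two patterns sharing a 6-mer co-occur perfectly
        a, b = "ACGTTGCA", "GTTGCAGG"
        occ = {a: set(range(20)), b: set(range(20))}
        assert discover_modules(occ, cfg, n_regions=40) == []
        assert lexically_blocked_pairs([a, b], 6) == {(0, 1)}


class TestMotifModuleType:
    def test_corrected_pvalue_cannot_undershoot(self):
        with pytest.raises(ValueError):
            MotifModule(frozenset({"A", "B"}), 3, 0.5, 0.4)


class TestRunDiscovery:
    def test_empty_dataset_discovers_nothing(self):
        ds = dataset_from_sequences(["N" * 50])
        state = run_discovery(ds, PipelineConfig())
        assert state.discovered_motifs == []
        assert state.discovered_modules == []

    def test_motif_cap_bounds_discovery(self):
        cfg = PipelineConfig(motif_cap=4)
        g = synthetic.make_genome(1_700_000, seed=21)
        mot = {f"M{i}": synthetic.make_informative_motif(8, (21, i))
               for i in range(8)}
        mods = [((f"M{2 * i}", f"M{2 * i + 1}"), 0.25) for i in range(4)]
        spec = {"motifs": mot,
                "datasets": [{"id": "d", "type_label": "t", "modules": mods}]}
        dsets, _ = synthetic.plant_datasets(g, [], spec, 1000, 800, 0.05,
                                            seed=22)
        state = run_discovery(dsets[0], cfg)
        assert len(state.discovered_motifs) >= 4
        assert len(state.discovered_motifs) <= 4 + cfg.module_max_size - 1

    def test_state_invariant_at_exit(self):
        ds = dataset_from_sequences(
            ["".join(np.random.default_rng(7).choice(list("ACGT"), size=100))
             for _ in range(10)])
        cfg = PipelineConfig()
        state = run_discovery(ds, cfg)
        assert (state.rounds_without_new <= cfg.stop_rounds_r
                or len(state.discovered_motifs) >= cfg.motif_cap)


class TestPatternSites:
    def test_sites_cover_both_strands(self):
        pat = "ACGTTGCA"
        s1 = "T" * 5 + pat + "T" * 10
        s2 = "G" * 3 + seqs.revcomp(pat) + "G" * 12
        ds = dataset_from_sequences([s1, s2])
        sites = pattern_sites(ds, pat)
        assert (0, 5, "+") in sites
        assert (1, 3, "-") in sites
        assert len(sites) == 2
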