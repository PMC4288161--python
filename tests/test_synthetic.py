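import numpy as np
import pytest

from modmotif import seqs, synthetic


class TestMakeGenome:
    def test_gc_fraction_concentrates(self):
        g = synthetic.make_genome(1_000_000, gc=0.5, seed=1)
        s = g.sequences["chr1"]
        gc = (s.count("G") + s.count("C")) / len(s)
        assert abs(gc - 0.5) < 0.01

    def test_same_seed_reproduces_sequence(self):
        a = synthetic.make_genome(20_000, seed=3)
        b = synthetic.make_genome(20_000, seed=3)
        assert a.sequences == b.sequences
        assert np.array_equal(a.transition, b.transition)

    @pytest.mark.parametrize("kwargs", [
        {"gc": 0.0}, {"gc": 1.0}, {"length": 500}])
    def test_preconditions(self, kwargs):
        args = {"length": 20_000, "gc": 0.4, "seed": 0}
        args.update(kwargs)
        with pytest.raises(ValueError):
            synthetic.make_genome(args["length"], gc=args["gc"],
                                  seed=args["seed"])

    def test_transition_rows_are_stochastic_with_exact_gc(self):
        g = synthetic.make_genome(20_000, gc=0.4, seed=2)
        assert np.allclose(g.transition.sum(axis=1), 1.0)
        assert np.allclose(g.transition[:, [1, 2]].sum(axis=1), 0.4)


class TestMakeAnnotation:
    def test_genes_have_utrs_and_two_introns(self):
        g = synthetic.make_genome(100_000, seed=4)
        genes = synthetic.make_annotation(g, 2, seed=5)
        assert len(genes) == 2
        for gene in genes:
            assert gene.five_utrs and gene.three_utrs
            assert len(gene.introns()) >= 2
            assert gene.first_intron() is not None
        # non-nested, non-overlapping spans
        (a, b) = sorted(genes, key=lambda x: x.start)
        assert a.end <= b.start

    def test_zero_genes_gives_empty_annotation(self):
        g = synthetic.make_genome(50_000, seed=6)
        assert synthetic.make_annotation(g, 0, seed=7) == []

    def test_capacity_error_when_genome_too_small(self):
        g = synthetic.make_genome(12_000, seed=8)
        with pytest.raises(ValueError, match="too small"):
            synthetic.make_annotation(g, 10, seed=9)


class TestRandomMotif:
    def test_rows_sum_to_one_within_tolerance(self):
        for i in range(50):
            m = synthetic.make_random_motif(8, (0, i))
            assert np.all(m >= 0) and np.all(m <= 1)
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_width_and_determinism(self):
        a = synthetic.make_random_motif(8, 1)
        b = synthetic.make_random_motif(8, 1)
        c = synthetic.make_random_motif(8, 2)
        assert a.shape == (8, 4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


def two_motif_spec(seed, prob):
    mot = {"A": synthetic.make_informative_motif(8, (seed, 1)),
           "B": synthetic.make_informative_motif(8, (seed, 2))}
    return {"motifs": mot,
            "datasets": [{"id": "d1", "type_label": "t",
                          "modules": [(("A", "B"), prob)]}]}


class TestPlantDatasets:
    def test_planted_region_count_matches_binomial(self):
        g = synthetic.make_genome(900_000, seed=10)
        (_ds,), truth = synthetic.plant_datasets(
            g, [], two_motif_spec(10, 0.5), 1000, 800, 0.0, seed=11)
        planted_regions = {rid for rid, _m, _o, _s in truth.site_log}
        assert abs(len(planted_regions) - 500) <= 50

    def test_zero_probability_plants_nothing(self):
        g = synthetic.make_genome(200_000, seed=12)
        _, truth = synthetic.plant_datasets(
            g, [], two_motif_spec(12, 0.0), 200, 800, 0.0, seed=13)
        assert truth.site_log == []

    def test_mask_fraction_of_background(self):
        g = synthetic.make_genome(900_000, seed=14)
        (ds,), truth = synthetic.plant_datasets(
            g, [], two_motif_spec(14, 0.2), 1000, 800, 0.1, seed=15)
        site_bp = sum(truth.motifs[m].shape[0]
                      for _r, m, _o, _s in truth.site_log)
        total = sum(len(s) for s in ds.sequences)
        n_count = sum(s.count("N") for s in ds.sequences)
        frac = n_count / (total - site_bp)
        assert abs(frac - 0.1) < 0.02

    def test_site_log_rescans_to_sampled_strings(self):
        g = synthetic.make_genome(200_000, seed=16)
        (ds,), truth = synthetic.plant_datasets(
            g, [], two_motif_spec(16, 0.5), 100, 800, 0.1, seed=17)
        assert truth.site_log
        idx = {r.id: i for i, r in enumerate(ds.regions)}
        for (rid, mid, off, strand), site in zip(truth.site_log,
                                                 truth.site_strings):
            w = truth.motifs[mid].shape[0]
            found = ds.sequences[idx[rid]][off:off + w]
            if strand == "-":
                found = seqs.revcomp(found)
            assert found == site
            assert "N" not in found

    def test_module_too_wide_for_region_rejected(self):
        g = synthetic.make_genome(200_000, seed=18)
        wide = {"W": synthetic.make_informative_motif(150, (18, 1)),
                "V": synthetic.make_informative_motif(150, (18, 2))}
        spec = {"motifs": wide,
                "datasets": [{"id": "d", "type_label": "t",
                              "modules": [(("W", "V"), 0.5)]}]}
        with pytest.raises(ValueError, match="cannot host"):
            synthetic.plant_datasets(g, [], spec, 10, 200, 0.0, seed=19)

    def test_determinism(self):
        g = synthetic.make_genome(200_000, seed=20)
        a, ta = synthetic.plant_datasets(g, [], two_motif_spec(20, 0.3),
                                         50, 800, 0.05, seed=21)
        b, tb = synthetic.plant_datasets(g, [], two_motif_spec(20, 0.3),
                                         50, 800, 0.05, seed=21)
        assert a[0].sequences == b[0].sequences
        assert ta.site_log == tb.site_log


class TestTypedCollection:
    def test_balanced_labels_and_shared_profile(self):
        dsets, truth = synthetic.make_typed_collection(
            5, 10, 2, 1, seed=1, n_regions=20, region_len=400)
        assert len(dsets) == 50
        labels = [d.type_label for d in dsets]
        assert all(labels.count(f"type{t + 1}") == 10 for t in range(5))
        for profile in truth.type_profiles.values():
            assert {"shared1", "shared2"} <= set(profile)

    def test_no_specific_motifs_gives_identical_truth(self):
        _, truth = synthetic.make_typed_collection(
            3, 2, 2, 0, seed=2, n_regions=20, region_len=400)
        profiles = list(truth.type_profiles.values())
        assert all(p == profiles[0] for p in profiles)

    def test_single_type_rejected(self):
        with pytest.raises(ValueError):
            synthetic.make_typed_collection(1, 2, 1, 1, seed=3)


class TestInteractions:
    def test_module_pair_closure(self):
        truth = synthetic.PlantedTruth(
            motifs={m: synthetic.make_random_motif(8, i)
                    for i, m in enumerate("ABCD")},
            modules=[(frozenset("ABC"), 0.2)])
        pairs = synthetic.make_interactions(truth, noise_pairs=0)
        assert pairs == [("A", "B"), ("A", "C"), ("B", "C")]

    def test_noise_pairs_added_outside_modules(self):
        truth = synthetic.PlantedTruth(
            motifs={m: synthetic.make_random_motif(8, i)
                    for i, m in enumerate("ABCDE")},
            modules=[(frozenset("AB"), 0.2)])
        pairs = synthetic.make_interactions(truth, noise_pairs=2, seed=4)
        assert ("A", "B") in pairs
        assert len(pairs) == 3
        assert len(set(pairs)) == 3
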