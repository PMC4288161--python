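import numpy as np
import pytest

from modmotif import synthetic
from modmotif.config import PipelineConfig
from modmotif.validation import (StratificationError, auc_score,
                                 classify_types, coverage,
                                 interaction_coverage, map_motif_to_tf,
                                 motif_presence_matrix, random_baseline)


def informative_set(n, seed):
    return [synthetic.make_informative_motif(8, (seed, i)) for i in range(n)]


class TestCoverage:
    def test_self_coverage_is_complete(self, engine, cfg):
        motifs = informative_set(10, 50)
        rep = coverage(motifs, motifs, engine, cfg)
        assert rep.pct_covered == 100.0
        assert rep.pct_predicted_known == 100.0
        assert rep.n_covered == rep.n_collection == 10

    def test_monotone_in_predicted_set(self, engine, cfg):
        collection = informative_set(12, 51)
        preds = [synthetic.perturb_motif(m, (52, i), 0.1)
                 for i, m in enumerate(collection)]
        small = coverage(preds[:4], collection, engine, cfg)
        large = coverage(preds, collection, engine, cfg)
        assert large.pct_covered >= small.pct_covered

    def test_empty_collection_flagged(self, engine, cfg):
        rep = coverage(informative_set(3, 53), [], engine, cfg)
        assert rep.flagged and rep.n_collection == 0

    def test_random_baseline_below_true_coverage(self, engine, cfg):
        collection = informative_set(12, 54)
        preds = [synthetic.perturb_motif(m, (55, i), 0.1)
                 for i, m in enumerate(collection)]
        true_cov = coverage(preds, collection, engine, cfg).pct_covered
        base = random_baseline(collection, len(preds), [8] * len(preds),
                               reps=3, seed=56, engine=engine, config=cfg)
        assert true_cov >= 90.0
        assert base < true_cov - 50.0

    def test_random_baseline_reproducible(self, engine, cfg):
        collection = informative_set(6, 57)
        a = random_baseline(collection, 6, [8] * 6, 2, 58, engine, cfg)
        b = random_baseline(collection, 6, [8] * 6, 2, 58, engine, cfg)
        assert a == b


class TestMotifToTf:
    def test_exact_reference_match_maps_to_its_tf(self, engine, cfg):
        ref_motifs = informative_set(5, 60)
        reference = [(m, f"TF{i}") for i, m in enumerate(ref_motifs)]
        assert map_motif_to_tf(ref_motifs[3], reference, engine, cfg) == "TF3"

    def test_dissimilar_motif_unmapped(self, engine, cfg):
        reference = [(synthetic.make_random_motif(8, 61), "TFX")]
        probe = synthetic.make_random_motif(8, 62)
        assert map_motif_to_tf(probe, reference, engine, cfg) is None

    def test_ties_break_lexicographically(self, engine, cfg):
        m = synthetic.make_informative_motif(8, 63)
        reference = [(m.copy(), "TFB"), (m.copy(), "TFA")]
        assert map_motif_to_tf(m, reference, engine, cfg) == "TFA"


class TestInteractionCoverage:
    def test_truth_modules_fully_discovered(self):
        modules = [frozenset({"a", "b"}), frozenset({"b", "c", "d"})]
        mapping = {m: m.upper() for m in "abcd"}
        known = [("A", "B"), ("B", "C"), ("B", "D"), ("C", "D")]
        rep = interaction_coverage(modules, mapping, known)
        assert rep.pct_known_discovered == 100.0
        assert rep.n_known_universe == 4

    def test_empty_modules_flagged(self):
        rep = interaction_coverage([], {"a": "A"}, [("A", "B")])
        assert rep.flagged
        assert np.isnan(rep.pct_predicted_supported)

    def test_noise_only_interactions_unsupported(self):
        modules = [frozenset({"a", "b"})]
        mapping = {"a": "A", "b": "B", "c": "C", "d": "D"}
        rep = interaction_coverage(modules, mapping, [("C", "D")])
        assert rep.pct_known_discovered == 0.0
        assert rep.pct_predicted_supported == 0.0

    def test_invariant_to_pair_order_and_duplication(self):
        modules = [frozenset({"a", "b"})]
        mapping = {"a": "A", "b": "B"}
        a = interaction_coverage(modules, mapping, [("A", "B")])
        b = interaction_coverage(modules, mapping,
                                 [("B", "A"), ("A", "B"), ("B", "A")])
        assert (a.pct_known_discovered, a.pct_predicted_supported) == \
               (b.pct_known_discovered, b.pct_predicted_supported)

    def test_unmapped_motifs_skipped(self):
        modules = [frozenset({"a", "zz"})]
        mapping = {"a": "A", "zz": None, "b": "B"}
        rep = interaction_coverage(modules, mapping, [("A", "B")])
        assert rep.n_predicted_pairs == 0


class TestClassification:
    def separable_features(self, n_classes=5, per_class=10, noise=0.0,
                           seed=0):
        rng = np.random.default_rng(seed)
        labels = []
        rows = []
        for c in range(n_classes):
            for _ in range(per_class):
                row = np.zeros(n_classes)
                row[c] = 1.0
                rows.append(row + noise * rng.normal(size=n_classes))
                labels.append(f"class{c}")
        return np.array(rows), labels

    def test_separable_features_classify_perfectly(self, cfg):
        X, y = self.separable_features()
        rep = classify_types(X, y, cfg)
        assert rep.accuracy == 1.0
        assert all(v == 1.0 for v in rep.per_class_auc.values())
        assert rep.weighted_auc == 1.0

    def test_confusion_rows_sum_to_class_counts(self, cfg):
        X, y = self.separable_features(noise=0.8, seed=1)
        rep = classify_types(X, y, cfg)
        assert rep.confusion.sum(axis=1).tolist() == [10] * 5

    def test_weighted_auc_identity(self, cfg):
        X, y = self.separable_features(noise=0.8, seed=2)
        rep = classify_types(X, y, cfg)
        sizes = {c: y.count(c) for c in set(y)}
        manual = sum(sizes[c] / len(y) * rep.per_class_auc[c]
                     for c in rep.per_class_auc)
        assert rep.weighted_auc == pytest.approx(manual, abs=1e-12)

    def test_small_classes_excluded(self, cfg):
        X, y = self.separable_features()
        X = np.vstack([X, np.ones((3, 5))])
        y = y + ["tiny"] * 3
        rep = classify_types(X, y, cfg)
        assert "tiny" not in rep.classes
        assert rep.n_datasets == 50

    def test_class_smaller_than_folds_raises(self):
        cfg = PipelineConfig(min_class_size=8, cv_folds=10)
        X, y = self.separable_features(n_classes=2, per_class=9)
        with pytest.raises(StratificationError):
            classify_types(X, y, cfg)

    def test_deterministic_given_seed(self, cfg):
        X, y = self.separable_features(noise=0.8, seed=3)
        a = classify_types(X, y, cfg)
        b = classify_types(X, y, cfg)
        assert a.accuracy == b.accuracy
        assert a.fold_accuracies == b.fold_accuracies


class TestAuc:
    def test_four_point_hand_case(self):
        # scores (0.9,+),(0.8,-),(0.7,+),(0.1,-): 3 of 4 pairs concordant
        assert auc_score([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == 0.75

    def test_perfect_ranking(self):
        assert auc_score([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0


class TestPresenceFeatures:
    def test_planted_motifs_detected_absent_motifs_not(self):
        dsets, truth = synthetic.make_typed_collection(
            2, 2, 1, 2, seed=70, n_regions=150, region_len=600,
            planting_prob=0.3)
        cons = {m: truth.consensus(m) for m in truth.motifs}
        feat, labels = motif_presence_matrix(dsets, cons)
        assert labels == [d.type_label for d in dsets]
        for i, ds in enumerate(dsets):
            profile = truth.type_profiles[ds.type_label]
            on = {m for m in feat.columns if feat.iloc[i][m] == 1}
            detected_planted = len(on & set(profile)) / len(profile)
            assert detected_planted >= 0.5
            off_profile = on - set(profile)
            assert len(off_profile) <= 1
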