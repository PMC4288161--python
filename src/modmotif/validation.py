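"""Downstream validation: known-motif coverage, TF-interaction coverage of
motif modules, and cell/tissue-type classification from motif features.

Coverage asks what fraction of a reference motif collection is similar to
at least one predicted motif (and vice versa), with a random-motif
baseline matched in number and widths.  Interaction coverage maps motifs
to TFs by best similarity against a labeled reference and compares the TF
pairs co-occurring in predicted modules with a known-interaction list.
Classification trains a linear maximum-margin (SVM) model on per-dataset
motif presence features under stratified cross validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from modmotif.config import PipelineConfig
from modmotif import seqs
from modmotif.io import SequenceDataset
from modmotif.patterns import KmerCounts, MarkovBackground
from modmotif.similarity import (SimilarityEngine, make_random_motif,
                                 similar_matrix)


# ---------------------------------------------------------------------------
# coverage


@dataclass
class CoverageReport:
    collection_name: str
    n_collection: int
    n_covered: int
    pct_covered: float          # % of the collection similar to >=1 prediction
    pct_predicted_known: float  # % of predictions similar to >=1 collection motif
    random_baseline_mean_pct: float | None = None
    flagged: bool = False       # empty collection / undefined percentages


def coverage(predicted, collection, engine: SimilarityEngine,
             config: PipelineConfig | None = None,
             name: str = "collection") -> CoverageReport:
    cfg = config or engine.config
    if len(collection) == 0:
        return CoverageReport(name, 0, 0, float("nan"), float("nan"),
                              flagged=True)
    comp = engine.compare_matrix(list(collection), list(predicted))
    sim = similar_matrix(comp.evalue_corr, comp.evalue_allr, cfg)
    covered = sim.any(axis=1)
    known = sim.any(axis=0)
    return CoverageReport(
        name, len(collection), int(covered.sum()),
        100.0 * covered.mean(),
        100.0 * known.mean() if len(predicted) else float("nan"),
        flagged=len(predicted) == 0)


def random_baseline(collection, n_random: int, widths, reps: int, seed,
                    engine: SimilarityEngine,
                    config: PipelineConfig | None = None) -> float:
    """Mean % of the collection covered by random motifs matched in number
    and width to the predictions, over ``reps`` replicates."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    widths = list(widths)
    pcts = []
    for rep in range(reps):
        randoms = [make_random_motif(w, (seed, rep, i))
                   for i, w in enumerate(widths[:n_random])]
        rep_cov = coverage(randoms, collection, engine, config,
                           name=f"random_rep{rep}")
        pcts.append(rep_cov.pct_covered)
    return float(np.mean(pcts))


# ---------------------------------------------------------------------------
# motif -> TF mapping and interaction coverage


def map_motif_to_tf(motif, reference, engine: SimilarityEngine,
                    config: PipelineConfig | None = None) -> str | None:
    """TF of the most similar reference motif, or None if nothing is
    similar.  Ties: lower ALLR E-value, then lower correlation E-value,
    then lexicographic TF id."""
    mapping = map_motifs_to_tfs([motif], reference, engine, config)
    return mapping[0]


def map_motifs_to_tfs(motifs, reference, engine: SimilarityEngine,
                      config: PipelineConfig | None = None):
    cfg = config or engine.config
    if not reference:
        raise ValueError("reference collection is empty")
    ref_motifs = [r[0] for r in reference]
    ref_tfs = [r[1] for r in reference]
    comp = engine.compare_matrix(list(motifs), ref_motifs)
    sim = similar_matrix(comp.evalue_corr, comp.evalue_allr, cfg)
    out = []
    for i in range(len(motifs)):
        best = None
        for j in np.nonzero(sim[i])[0]:
            key = (comp.evalue_allr[i, j], comp.evalue_corr[i, j], ref_tfs[j])
            if best is None or key < best[0]:
                best = (key, ref_tfs[j])
        out.append(best[1] if best else None)
    return out


@dataclass
class InteractionReport:
    n_known_universe: int
    n_predicted_pairs: int
    n_overlap: int
    pct_known_discovered: float
    pct_predicted_supported: float
    flagged: bool = False


def interaction_coverage(modules, motif_to_tf: dict, known_pairs) -> InteractionReport:
    """Compare TF pairs co-occurring in modules with known interactions.

    ``motif_to_tf`` maps motif ids to TF ids (unmapped motifs skipped).
    Both percentages are computed on the universe of known pairs whose TFs
    both appear in the mapping image.  Input pair order/duplication is
    irrelevant.
    """
    predicted: set[tuple] = set()
    for mod in modules:
        ids = mod.motif_ids if hasattr(mod, "motif_ids") else mod
        tfs = sorted({motif_to_tf[m] for m in ids
                      if motif_to_tf.get(m) is not None})
        for i in range(len(tfs)):
            for j in range(i + 1, len(tfs)):
                predicted.add((tfs[i], tfs[j]))
    mapped_tfs = {t for t in motif_to_tf.values() if t is not None}
    known = {tuple(sorted(p)) for p in known_pairs}
    universe = {p for p in known if p[0] in mapped_tfs and p[1] in mapped_tfs}
    overlap = universe & predicted
    flagged = not universe or not predicted
    pct_known = 100.0 * len(overlap) / len(universe) if universe else float("nan")
    pct_supported = (100.0 * len(overlap) / len(predicted)
                     if predicted else float("nan"))
    return InteractionReport(len(universe), len(predicted), len(overlap),
                             pct_known, pct_supported, flagged)


# ---------------------------------------------------------------------------
# classification


@dataclass
class ClassificationReport:
    accuracy: float
    fold_accuracies: list[float]
    confusion: pd.DataFrame
    per_class_auc: dict[str, float]
    weighted_auc: float
    classes: list[str] = field(default_factory=list)
    n_datasets: int = 0


class StratificationError(ValueError):
    """A kept class is smaller than the fold count."""


def auc_score(labels, scores) -> float:
    """Rank-sum (ROC) AUC for binary labels."""
    return float(roc_auc_score(np.asarray(labels, dtype=int), scores))


def classify_types(features, labels, config: PipelineConfig) -> ClassificationReport:
    """Linear SVM (one-vs-rest) under stratified k-fold cross validation.

    Classes with fewer than ``min_class_size`` datasets are excluded before
    anything else.  Reports overall and per-fold accuracy, the confusion
    matrix, per-class one-vs-rest AUC from out-of-fold decision scores, and
    the class-size-weighted AUC.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    counts = pd.Series(y).value_counts()
    kept = sorted(counts[counts >= config.min_class_size].index)
    mask = np.isin(y, kept)
    X, y = X[mask], y[mask]
    if len(kept) < 2:
        raise StratificationError("need at least two classes after exclusion")
    if pd.Series(y).value_counts().min() < config.cv_folds:
        raise StratificationError(
            "a class is smaller than the number of folds")
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.random_seed)
    classes = np.array(kept)
    n = len(y)
    pred = np.empty(n, dtype=y.dtype)
    scores = np.zeros((n, len(classes)))
    fold_acc = []
    for train, test in skf.split(X, y):
        clf = SVC(kernel="linear", C=1.0,
                  decision_function_shape="ovr")
        clf.fit(X[train], y[train])
        p = clf.predict(X[test])
        pred[test] = p
        dec = clf.decision_function(X[test])
        if dec.ndim == 1:   # binary: expand to two-column ovr scores
            two = np.stack([-dec, dec], axis=1)
            cols = {c: k for k, c in enumerate(clf.classes_)}
            for k, c in enumerate(classes):
                scores[test, k] = two[:, cols[c]]
        else:
            cols = {c: k for k, c in enumerate(clf.classes_)}
            for k, c in enumerate(classes):
                scores[test, k] = dec[:, cols[c]]
        fold_acc.append(float(np.mean(p == y[test])))
    accuracy = float(np.mean(pred == y))
    conf = pd.DataFrame(
        confusion_matrix(y, pred, labels=classes),
        index=classes, columns=classes)
    per_class = {}
    weights = {}
    for k, c in enumerate(classes):
        binary = (y == c).astype(int)
        per_class[str(c)] = float(roc_auc_score(binary, scores[:, k]))
        weights[str(c)] = binary.sum() / n
    weighted = float(sum(weights[c] * per_class[c] for c in per_class))
    return ClassificationReport(accuracy, fold_acc, conf, per_class, weighted,
                                classes=[str(c) for c in classes],
                                n_datasets=n)


# ---------------------------------------------------------------------------
# motif presence features


def motif_presence_matrix(datasets: list[SequenceDataset],
                          consensus_patterns: dict[str, str],
                          alpha: float = 1e-4):
    """Binary presence of each motif (by consensus word) in each dataset.

    A motif counts as present when its consensus word (either strand)
    occurs in significantly more windows than expected under the dataset's
    own order-2 Markov background (one-sided exact binomial over windows at
    level ``alpha``).  Returns (DataFrame datasets x motifs, labels list).
    """
    motif_ids = sorted(consensus_patterns)
    rows = []
    labels = []
    for ds in datasets:
        k_widths = {len(p) for p in consensus_patterns.values()}
        bg = MarkovBackground(order=2).fit(ds.sequences)
        row = {}
        for k in sorted(k_widths):
            counts = KmerCounts(ds, k)
            codes = np.array([seqs.encode_kmer(seqs.canonical_pattern(
                consensus_patterns[m])) for m in motif_ids
                if len(consensus_patterns[m]) == k], dtype=np.int64)
            ids_k = [m for m in motif_ids if len(consensus_patterns[m]) == k]
            expected = bg.expected_counts(codes, k, counts.n_windows)
            p_window = np.clip(expected / max(counts.n_windows, 1),
                               1e-15, 1 - 1e-15)
            for mid, code, pw in zip(ids_k, codes, p_window):
                pos = np.searchsorted(counts.codes, code)
                obs = int(counts.counts[pos]) if (
                    pos < counts.codes.size and counts.codes[pos] == code) else 0
                pval = float(sps.binom.sf(obs - 1, counts.n_windows,
                                          float(pw))) if obs else 1.0
                row[mid] = int(pval < alpha)
        rows.append(row)
        labels.append(ds.type_label)
    frame = pd.DataFrame(rows, index=[ds.id for ds in datasets])
    frame = frame.reindex(columns=motif_ids).fillna(0).astype(int)
    return frame, labels
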