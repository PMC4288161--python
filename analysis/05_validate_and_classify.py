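#!/usr/bin/env python
"""Validate predictions against planted truth and classify dataset types.

Three checks mirror the downstream analyses the pipeline supports:
coverage of a reference motif collection (here the planted PWMs) by the
discovered-and-refined motifs, compared against a size- and width-matched
random-motif baseline (10 replicates); coverage of known TF-TF
interactions (the planted within-module pairs) by TF pairs co-occurring in
predicted modules; and linear-SVM classification of dataset cell types
from per-dataset motif presence features under stratified 10-fold cross
validation.  Writes coverage/interaction/classification tables under
results/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from modmotif import synthetic
from modmotif.benchmarks import (planted_module_benchmark,
                                 typed_classification_benchmark)
from modmotif.config import PipelineConfig
from modmotif.discovery import pattern_sites, run_discovery
from modmotif.refine import build_pwm, refine_motifs, update_modules
from modmotif.similarity import SimilarityEngine
from modmotif.validation import (classify_types, coverage,
                                 interaction_coverage, map_motifs_to_tfs,
                                 motif_presence_matrix, random_baseline)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
RESULTS = Path("results")


def main():
    RESULTS.mkdir(exist_ok=True)
    cfg = PipelineConfig(random_seed=SEED)
    engine = SimilarityEngine(cfg, seed=SEED)

    # --- rebuild the planted-benchmark predictions (deterministic)
    dataset, truth = planted_module_benchmark(SEED)
    state = run_discovery(dataset, cfg)
    raw = [build_pwm(pattern_sites(dataset, pat), dataset.sequences,
                     len(pat), cfg.refine_pseudocount, motif_id=pat,
                     source_dataset=dataset.id)
           for pat in state.discovered_motifs]
    adjusted = refine_motifs(raw, dataset.sequences, cfg)
    modules, merged, _ = update_modules(
        state.discovered_modules, state.discovered_motifs, adjusted,
        dataset.n_regions, cfg)

    collection = [truth.motifs[m] for m in sorted(truth.motifs)]
    cov = coverage(merged, collection, engine, cfg, name="planted_truth")
    base = random_baseline(collection, len(merged),
                           [m.width for m in merged], reps=10,
                           seed=(SEED, 42), engine=engine, config=cfg)
    print(f"coverage: {cov.pct_covered:.1f}% of the {cov.n_collection} "
          f"planted motifs matched by {len(merged)} predictions "
          f"({cov.pct_predicted_known:.1f}% of predictions known); "
          f"random baseline {base:.1f}% over 10 replicates")

    reference = [(truth.motifs[m], f"TF_{m}") for m in sorted(truth.motifs)]
    tf_of = dict(zip([m.id for m in merged],
                     map_motifs_to_tfs(merged, reference, engine, cfg)))
    known = [(f"TF_{a}", f"TF_{b}")
             for a, b in synthetic.make_interactions(truth, noise_pairs=0)]
    inter = interaction_coverage(modules, tf_of, known)
    print(f"interactions: {inter.pct_known_discovered:.1f}% of "
          f"{inter.n_known_universe} known pairs discovered; "
          f"{inter.pct_predicted_supported:.1f}% of "
          f"{inter.n_predicted_pairs} predicted pairs supported")

    pd.DataFrame([{**cov.__dict__, "random_baseline_mean_pct": base},
                  ]).to_csv(RESULTS / "coverage.tsv", sep="\t", index=False)
    pd.DataFrame([inter.__dict__]).to_csv(RESULTS / "interactions.tsv",
                                          sep="\t", index=False)

    # --- cell-type classification on the typed collection
    datasets, typed_truth = typed_classification_benchmark(SEED)
    cons = {m: typed_truth.consensus(m) for m in typed_truth.motifs}
    feats, labels = motif_presence_matrix(datasets, cons)
    report = classify_types(feats.values, labels, cfg)
    print(f"classification: accuracy {100 * report.accuracy:.1f}% over "
          f"{report.n_datasets} datasets ({len(report.classes)} types); "
          f"fold accuracies {min(report.fold_accuracies):.2f}.."
          f"{max(report.fold_accuracies):.2f}; "
          f"weighted AUC {report.weighted_auc:.3f}")
    report.confusion.to_csv(RESULTS / "classification_confusion.tsv",
                            sep="\t")
    (RESULTS / "classification_report.json").write_text(json.dumps({
        "accuracy": report.accuracy,
        "fold_accuracies": report.fold_accuracies,
        "per_class_auc": report.per_class_auc,
        "weighted_auc": report.weighted_auc,
        "classes": report.classes,
        "n_datasets": report.n_datasets,
    }, indent=2) + "\n")


if __name__ == "__main__":
    main()
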