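"""Standard synthetic benchmarks: the study conditions in one place.

These constructors fix the scenario parameters (region counts, lengths,
planting rates, family sizes) used by the analysis drivers and the
acceptance script, so every entry point measures the same conditions.
All are pure functions of the seed.
"""

from __future__ import annotations

from modmotif import synthetic
from modmotif.refine import Motif


def planted_module_benchmark(seed: int):
    """One DHS-like dataset: 2000 regions x 800 bp, six informative motifs
    planted as three two-motif modules in 15% of regions, 10% masking.

    Returns (dataset, truth)."""
    genome = synthetic.make_genome(3_500_000, seed=(seed, 10))
    motifs = {f"M{i}": synthetic.make_informative_motif(8, (seed, 7, i))
              for i in range(6)}
    modules = [(("M0", "M1"), 0.15), (("M2", "M3"), 0.15),
               (("M4", "M5"), 0.15)]
    spec = {"motifs": motifs,
            "datasets": [{"id": "planted", "type_label": "planted",
                          "modules": modules}]}
    (dataset,), truth = synthetic.plant_datasets(
        genome, [], spec, n_regions=2000, region_len=800,
        mask_fraction=0.1, seed=(seed, 11))
    return dataset, truth


def null_benchmark(seed: int, n_datasets: int = 20, n_regions: int = 500):
    """Pure-background datasets (no planted structure), one per genome."""
    for i in range(n_datasets):
        genome = synthetic.make_genome(900_000, seed=(seed, 100, i))
        spec = {"motifs": {},
                "datasets": [{"id": f"null{i}", "type_label": "null",
                              "modules": []}]}
        (dataset,), _ = synthetic.plant_datasets(
            genome, [], spec, n_regions=n_regions, region_len=800,
            mask_fraction=0.1, seed=(seed, 101, i))
        yield dataset


def family_clustering_benchmark(seed: int, n_families: int = 10,
                                n_copies: int = 20, n_datasets: int = 10,
                                eps: float = 0.12):
    """Perturbed copies of planted motif families spread over datasets.

    Returns (datasets_with_motifs, family-of-motif map)."""
    datasets = {f"ds{d + 1}": [] for d in range(n_datasets)}
    family_of = {}
    for f in range(n_families):
        _, copies = synthetic.make_motif_family(8, n_copies, (seed, f),
                                                eps=eps)
        for c, mat in enumerate(copies):
            d = (f + c) % n_datasets
            mid = f"f{f}c{c}"
            datasets[f"ds{d + 1}"].append(
                Motif(mid, mat, source_dataset=f"ds{d + 1}"))
            family_of[mid] = f
    return sorted(datasets.items()), family_of


def typed_classification_benchmark(seed: int, n_types: int = 5,
                                   datasets_per_type: int = 10):
    """Labeled multi-type collection: 2 shared + 3 type-specific motifs per
    type, 200 regions x 800 bp per dataset at 15% planting."""
    return synthetic.make_typed_collection(
        n_types, datasets_per_type, shared_motifs=2,
        specific_motifs_per_type=3, seed=seed)
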