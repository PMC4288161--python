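# modmotif

Co-occurrence based discovery of DNA motifs and motif modules in
open-chromatin (DNase I hypersensitive site, DHS) sequence collections,
with cross-dataset non-redundant motif clustering, genomic-region
enrichment, and cell-type classification from motif features.

## The problem

A DHS is a short stretch of open chromatin (hundreds of bp) where
regulatory proteins bind.  Transcription factors (TFs) rarely act alone:
a cis-regulatory module is bound by several TFs whose binding sites
co-occur within the same short region.  This package exploits that
structure for *de novo* motif discovery: instead of asking which words are
over-represented one at a time, it asks which **sets** of candidate words
co-occur in significantly many regions.

The core statistic: given candidate patterns with observed region
frequencies `p_i = |R_i| / n` (where `R_i` is the set of regions containing
pattern *i* on either strand), a candidate module `S` with support
`k = |∩_{i∈S} R_i|` is scored by the exact upper binomial tail

    P(X ≥ k),   X ~ Binomial(n, q),   q = ∏_{i∈S} p_i,

i.e. the probability of seeing that much co-occurrence if members occurred
independently at their observed rates.  Modules of 2–6 patterns are
enumerated level-wise over the itemset lattice (support is anti-monotone),
Bonferroni-corrected over the sets examined, and kept at corrected
p < 0.01.  Patterns appearing in any significant module become motifs; the
search iterates over the top-2000 ranked 8-mers until no new motif appears
in *r* consecutive rounds (or 2000 motifs are found).  Discovered words are
then refined into position weight matrices (PWMs) from their sites, length-
adjusted by flanking information content, clustered across datasets into
non-redundant motifs under a two-threshold similarity rule, tested for
enrichment in 16 gene-anchored genomic region types with an exact binomial
test, and used as binary features to classify dataset cell/tissue types
with a linear SVM under stratified 10-fold cross validation.

Everything runs on synthetic data with planted ground truth generated by
`modmotif.synthetic`: Markov-background genomes, gene annotations,
DHS-like datasets carrying co-occurring sites of planted PWMs, typed
dataset collections, and known-interaction lists.

## Worked example

```python
from modmotif.benchmarks import planted_module_benchmark
from modmotif.config import PipelineConfig
from modmotif.discovery import run_discovery

cfg = PipelineConfig()
dataset, truth = planted_module_benchmark(seed=1)   # 2000 regions x 800 bp
state = run_discovery(dataset, cfg)
print(len(state.discovered_motifs), len(state.discovered_modules))
```

The benchmark plants six informative PWMs as three two-motif modules in
15% of regions.  Running the analysis drivers (each takes the seed as an
optional argument):

```bash
python analysis/01_simulate_benchmarks.py 1
python analysis/02_discover_modules.py 1
python analysis/03_refine_and_cluster.py 1
python analysis/04_region_enrichment.py 1
python analysis/05_validate_and_classify.py 1
```

prints, for seed 1:

```
planted dataset: 9 motifs, 5 modules in 3 rounds
  consensus patterns recovered: 6/6 ['M0', 'M1', 'M2', 'M3', 'M4', 'M5']
  module member sets recovered: 3/3 [('M0', 'M1'), ('M2', 'M3'), ('M4', 'M5')]
null control: 1/20 datasets produced any module
clustering: 200 motifs -> 10 non-redundant clusters (descending order), 10 (ascending order)
coverage: 100.0% of the 6 planted motifs matched by 9 predictions (...); random baseline 0.0%
classification: accuracy 98.0% over 50 datasets (5 types); weighted AUC 1.000
```

Reading: all six planted consensus words and all three module member sets
are recovered (the three extra motifs are shifted variants of planted
words); pure-background datasets produce essentially no modules, so the
significance machinery controls false discovery; 200 perturbed copies of
10 motif families collapse to exactly 10 non-redundant clusters regardless
of dataset processing order; and type-specific motif profiles classify the
50 labeled datasets almost perfectly.  Tables land in `results/`, large
regenerable data in `scratch/`.

## Layout

- `src/modmotif/` — the library: `config`, `synthetic`, `io`, `patterns`,
  `discovery`, `refine`, `similarity`, `cluster`, `enrichment`,
  `validation`, `benchmarks`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit/property tests plus `test_acceptance.py` (end-to-end
  contracts).
- `docs/methods.md` — models, parameters, and design decisions.
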