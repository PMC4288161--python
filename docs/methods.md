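# Methods

## Overview

The pipeline discovers DNA motifs in a DHS dataset through the motif
modules they form, then post-processes the per-dataset discoveries into a
cross-dataset non-redundant motif catalog with location and classification
analyses.  This note records the models, the tunable parameters with their
defaults, the synthetic data the package is validated on, and the places
where the design was genuinely open and a choice had to be made.

## Region preprocessing

DHS regions shorter than `region_target_len` (800 bp) are extended evenly
from both ends to exactly that length — cis-regulatory modules are
typically longer than a raw DHS call — and regions longer than
`region_max_len` (5000 bp) are discarded.  An odd deficit puts its extra
base on the right end; at a chromosome boundary the shortfall moves to the
other side, so output length is exact whenever the chromosome allows.
Coordinates are 0-based half-open throughout; GTF is converted at the
boundary.  Lowercase (soft-masked) genome bases and explicit mask
intervals become `N`, which poisons every k-mer window covering them.

## Pattern ranking

All 8-mers (`kmer_width`) are counted over N-free windows, with a pattern
and its reverse complement merged under the lexicographically smaller key;
each window contributes one count to the canonical key of its forward
string, so counts total the number of clean windows.  Patterns are ranked
by the Poisson z-score `(observed − expected)/√expected` against an
order-2 Markov chain fitted on the dataset's own masked sequences
(transition pseudocount 1, so expectations are strictly positive).  The
ranking statistic and background of the original per-dataset discovery
engine are not published; this z-score is the declared stand-in, isolated
behind one function, and no equivalence is claimed.

The top `top_patterns` (2000) ranked patterns become candidates after a
de-overlap pass: a candidate sharing a word of `candidate_overlap_min` (7)
bases with a higher-ranked candidate (either orientation) is dropped,
because shifted variants of one underlying word are the same signal.

## Motif modules

A module is a set of `module_min_size`..`module_max_size` (2..6)
candidates whose sites co-occur in many regions.  With observed marginal
region frequencies `p_i` and support `k` (size of the exact intersection
of the members' region sets), the p-value is the exact binomial tail
`P(X ≥ k | n, q)` with `q = ∏ p_i`.  Conventions: empty member set or zero
support give p = 1.

The lattice is searched level-wise with a support floor
(`module_min_support` = 5): a set is *examined* when all its
next-smaller subsets meet the floor, and *retained* when it meets the
floor itself.  Because support is anti-monotone, the retained family is
exactly `{S : support(S) ≥ floor}` — a pure function of the support
table — so an exhaustive enumeration reproduces the pruned search output
verbatim (tested).  The Bonferroni denominator is the number of examined
sets: counting only the floor-survivors would shrink the correction after
a data-driven selection and break family-wise error control on
pure-background data.  Modules with corrected p < `module_alpha` (0.01)
are reported.

Two additional guards keep the independence null honest:

* **Lexical blocking** (`module_pair_min_overlap` = 6): two patterns
  sharing a ≥6-base word (either orientation) co-occur through occurrences
  of a longer shared word — e.g. two 8-mers overlapping by 6 both fire on
  every occurrence of their common 10-mer — which the product-of-marginals
  null cannot describe.  Such pairs are never tested together (and by
  anti-monotonicity no superset containing them is).  Without this guard,
  background datasets produce shift-chain "modules" whose support is
  driven entirely by a single repeated word.
* The per-round candidate de-overlap above, which removes the same
  redundancy at the single-pattern level.

The discovery loop ranks the not-yet-discovered patterns, mines modules,
and adds member patterns of significant modules as motifs; it stops at
`motif_cap` (2000) motifs (checked while adding, so overshoot is below
`module_max_size`) or after `stop_rounds_r` (3) consecutive rounds without
a new motif.  *r* is a free parameter of the protocol; 3 is this package's
default and it is config-exposed.  Pattern scores are fixed for a dataset,
so a round that adds nothing would replay verbatim; the loop detects this
and completes the count immediately rather than re-running identical
rounds.

## Motif refinement

Each discovered word becomes a PWM from all its exact-match sites
(additive pseudocount `refine_pseudocount` = 0.25 per base).  Length
adjustment appends a flanking column while the bases adjacent to all sites
carry at least `ic_min` (0.5) bits of information (2 + Σ p log2 p), taking
the higher-information side first (ties extend right), then trims terminal
columns below the threshold, within `motif_min_width`..`motif_max_width`
(6..16).  A side where any site touches its sequence boundary is frozen.
The procedure is idempotent and preserves row-stochasticity.  Adjusted
motifs with identical site intervals merge under the earlier id; module
membership is re-expressed over merged ids, supports recomputed from the
adjusted site lists, and modules falling below the minimum size dropped.
The original supplementary procedure for length adjustment is not public;
thresholds here are declared stand-ins and config-exposed.

## Motif similarity and E-values

Motif pairs are compared by the best ungapped alignment over both
orientations with overlap ≥ min(6, shorter width) under two per-column
metrics: Pearson correlation of the probability 4-vectors (zero-variance
columns score 0), and a symmetrized average log-likelihood ratio (ALLR)
against a flat background.  Using two metrics mirrors the published
two-tool AND-rule: the correlation metric is insensitive to length
artifacts, the ALLR metric to low-information matches.  Two motifs are
*similar* iff

    (E_corr < 0.5 and E_allr < 1e-4)  or  (E_corr < 1 and E_allr < 1e-5).

E-values are calibrated against a random-motif null (each PWM row is four
iid uniforms normalized to sum 1).  Two calibrations exist:

* the empirical tail `E = n·(1 + #{null ≥ s}) / (1 + |null|)`, used where
  an empirical null is the right tool (it is bounded below by
  `1/(1+|null|)`);
* the engine's **column-sum Gaussian tail**: per-column null moments
  (μ0, σ0) are estimated once from random column pairs, and an alignment
  of overlap `w` scoring `S` per column gets
  `p = Φ̄((wS − wμ0)/(σ0√w))`.  This extrapolates smoothly past any
  feasible empirical null, which the clustering anchor threshold (1e-8)
  requires — a finite empirical null can never certify E < 1e-8.  The
  absolute E-value scale is a calibrated stand-in for published comparison
  tools, not a numerical reproduction; thresholds keep their published
  semantics and are config-exposed.

## Non-redundant clustering

Datasets are processed in descending order of predicted-motif count
(ascending is available as the robustness variant).  Motifs of the first
dataset seed singleton clusters.  A later motif joins the first cluster
where (i) it is similar to ≥1 member at `cluster_e_anchor` (1e-8, ALLR
E-value) and (ii) it is similar at `cluster_e_member` (1e-5) to all
members when the cluster has fewer than `cluster_small_size` (4) members,
or to ≥ `cluster_frac` (90%) of them otherwise.  Per dataset, unplaced
motifs pool; mutually similar pooled motifs form new clusters greedily
(seeded by the pooled motif with the most pooled similars), the rest
become singletons.  Each cluster is represented by the member similar to
the most other members (ties to the earliest added).  Clusters whose
representatives are similar are pooled and re-partitioned by
average-linkage hierarchical clustering on `1 − (corr score + 1)/2`,
cutting the dendrogram top-down at the largest subtrees whose members all
satisfy the same membership rules, iterated to a fixed point (≤10
rounds).  "First qualifying cluster" assignment, the greedy pool grouping,
and the re-use of the membership rules as the cut criterion are this
package's choices where the published description is underdetermined; all
are deterministic and order-auditable.

## Genomic region types and enrichment

Sixteen primary types from a gene annotation: proximal TSS and proximal
TTS (`proximal_window` = 2.5 kb, strand-aware: upstream of a minus-strand
gene lies to its right), 5′/3′ UTRs, first introns (transcription order)
and other introns, and 5′/3′ distal territories at cutoffs
`distal_cutoffs` = {2.5, 5, 10, 20, 100} kb — a 5′ >x position lies more
than x bp from the gene's start on its 5′ side and at least x bp from
every other gene (a gene's own padded span never overlaps its candidate
interval, so subtracting all padded spans is equivalent and is what the
implementation does).  "Pure" variants subtract the opposing type.

A motif's enrichment in a type is the exact binomial tail
`P(X ≥ k | n_sites, p_bg)` where `p_bg` is the fraction of DHS base pairs
the type overlaps and a site counts by its midpoint (the any-overlap
variant was considered; midpoint is unambiguous for sites shorter than
regions).  Bonferroni denominator: motifs × types per dataset; enriched
iff corrected p < `enrich_alpha` (0.01).  Trials are sites, not base
pairs — the natural binomial reading.

## Validation and classification

*Coverage*: a collection motif is covered iff similar to ≥1 predicted
motif; the baseline repeats the comparison with random motifs matched in
number and width, 10 replicates, and reports the mean percentage.
*Interaction coverage*: each motif maps to the TF of its most similar
reference motif (ALLR E-value, then correlation E-value, then
lexicographic TF id; unmapped motifs are skipped); predicted TF pairs are
all unordered pairs co-occurring in ≥1 module; both percentages are
computed on the universe of known pairs whose TFs appear in the mapping
image.  *Classification*: binary presence of each motif per dataset (a
count-based variant of the presence statistic is the natural extension),
linear-kernel SVM (the minimal faithful reading of an SMO-trained
maximum-margin model), one-vs-rest, stratified 10-fold cross validation
with a fixed seed, after excluding types with fewer than `min_class_size`
(8) datasets; reported: accuracy, per-fold range, confusion matrix,
per-class one-vs-rest AUC from out-of-fold decision scores, and
class-size-weighted AUC.

Motif presence for the synthetic benchmarks is detected from data: a
motif's consensus word is present in a dataset when its window count
exceeds the expectation under the dataset's own order-2 Markov background
(exact binomial, α = 1e-4).

## The synthetic data

The generator emulates the statistical structure the analysis assumes:
order-2 Markov background genomes whose transition rows all carry the
target GC content exactly (the C/G and A/T splits vary by context, and the
rows are recorded in the generator's output so the ranking null is
testable against the truth); gene models with UTRs and ≥2 introns; DHS
datasets of short regions in which a planted module places one site per
member PWM at non-overlapping offsets on random strands in a Bernoulli
fraction of regions; background-only N-masking in geometric stretches
(planted sites are never masked); typed collections sharing common motifs
plus type-specific ones; and interaction lists as the within-module pair
closure plus noise.  Planted motifs default to one dominant base per
position at probability ~0.9 (≈1.4 bits/column), a strong but realistic
TF motif.  Every operation is a pure function of (inputs, seed).

What it does **not** model: DNase cut bias or footprint shape, overlapping
or clustered binding sites, motif degeneracy beyond independent PWM
columns, sequence composition heterogeneity along the genome, gapped
motifs, and the scale of real compendia (hundreds of datasets, ~170k
regions each).  Passing tests therefore demonstrate the statistical
machinery — significance control, recovery under the assumed generative
model, deterministic procedures — not performance on real DNase-seq data.

## Benchmark problem sizes

Chosen to exercise each claim at desk scale: planted recovery uses one
dataset of 2000 × 800 bp regions with six motifs in three modules at 15%
planting; the null control uses twenty independent 500-region background
datasets; clustering uses 10 families × 20 perturbed copies (mixing
coefficient 0.12) over 10 datasets; classification uses 5 types × 10
datasets of 200 regions with 2 shared + 3 specific motifs; enrichment uses
an 8-gene annotation on a 500 kb genome with a 200-region DHS panel.

## Numerical choices and degenerate inputs

Exact binomial tails come from the regularized incomplete beta function
(`scipy.stats.binom.sf`) and match direct summation to 1e-12 on small
cases.  Ties everywhere are broken deterministically (lexicographic
patterns, smaller offsets, forward orientation, earliest-added members).
Degenerate cases have stated conventions: empty occurrence sets give
p-value 1; saturated nulls (q ≥ 1, p_bg ≥ 1) give p-value 1; p_bg = 0 with
hits is flagged degenerate with p-value 0; uniform columns score 0 under
the correlation metric; probability floors (1e-6 in ALLR logs, 1e-300 in
tail p-values) avoid log-of-zero and underflow.

## Known limitations

The ranking statistic, module significance model, length-adjustment
thresholds, similarity E-value scale, and hierarchical cut criterion all
stand in for unpublished components of the original tooling; each is
isolated behind one function and config-exposed, and none is claimed to
reproduce the original numerically.  Discovery sites are exact word
matches (no mismatches, no gaps); degeneracy enters only through PWM
refinement.  Interaction "support" on synthetic data over-counts motifs
mapped to the same TF only once, so spurious shifted-variant modules can
dilute the supported percentage.  The Gaussian column-sum tail is
anti-conservative for highly informative motif pairs (its null is random
columns), which the clustering rules absorb via the membership
requirement; a full convolution of the per-column null would be the
next refinement.
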