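"""Motif-module discovery: co-occurrence mining over candidate patterns.

A motif module is a set of 2..module_max_size candidate patterns whose
exact-match sites co-occur in significantly many regions.  Under the null
the member patterns occur independently, each with its observed marginal
region frequency p_i; the co-occurrence probability is q = prod p_i and the
module p-value is the exact upper binomial tail P(X >= support | n, q).

The search enumerates the itemset lattice level-wise with a support floor
(``module_min_support``): a set is examined when all its subsets of the
previous level meet the floor, and retained when it meets the floor itself.
Support is anti-monotone, so the retained family is exactly
{S : support(S) >= floor} and an exhaustive enumeration reproduces the
pruned search verbatim.  The Bonferroni denominator is the number of
examined sets, i.e. every set whose support the search computed, which
keeps family-wise error control honest under the data-driven pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

from modmotif import seqs
from modmotif.config import PipelineConfig
from modmotif.io import SequenceDataset
from modmotif.patterns import KmerCounts, MarkovBackground, dedup_overlapping_codes


@dataclass(frozen=True)
class MotifModule:
    motif_ids: frozenset
    support: int
    pvalue: float
    corrected_pvalue: float

    def __post_init__(self):
        if self.corrected_pvalue < self.pvalue - 1e-15:
            raise ValueError("corrected p-value below raw p-value")


@dataclass
class DiscoveryState:
    discovered_motifs: list[str] = field(default_factory=list)
    discovered_modules: list[MotifModule] = field(default_factory=list)
    rounds_without_new: int = 0
    round_index: int = 0


# ---------------------------------------------------------------------------
# p-value


def module_pvalue(region_sets, n_regions: int) -> float:
    """Exact binomial upper-tail co-occurrence p-value.

    ``region_sets``: one set of region ids per member motif.  The support is
    the size of their intersection.  Any empty member set gives p-value 1 by
    convention, as does zero support.
    """
    if n_regions <= 0:
        raise ValueError("n_regions must be positive")
    region_sets = [set(s) for s in region_sets]
    if any(len(s) == 0 for s in region_sets):
        return 1.0
    support = len(set.intersection(*region_sets))
    sizes = [len(s) for s in region_sets]
    return _tail_pvalue(support, n_regions, sizes)


def _tail_pvalue(support: int, n_regions: int, sizes) -> float:
    if support <= 0:
        return 1.0
    q = 1.0
    for s in sizes:
        q *= s / n_regions
    if q >= 1.0:
        return 1.0
    return float(sps.binom.sf(support - 1, n_regions, q))


# ---------------------------------------------------------------------------
# occurrence sets


def occurrence_sets(candidates, dataset: SequenceDataset) -> dict[str, set]:
    """Region-id sets per pattern: a region counts if the pattern or its
    reverse complement occurs in its sequence."""
    if not candidates:
        return {}
    k = len(next(iter(candidates)))
    counts = KmerCounts(dataset, k)
    ids = dataset.region_ids
    out: dict[str, set] = {}
    for pattern in candidates:
        if len(pattern) != k:
            raise ValueError("candidates must share one width")
        canon = seqs.encode_kmer(seqs.canonical_pattern(pattern))
        out[pattern] = {ids[i] for i in counts.region_indices(canon)}
    return out


# ---------------------------------------------------------------------------
# lattice search


@dataclass
class SearchStats:
    n_examined: int = 0
    n_retained: int = 0


def lexically_blocked_pairs(patterns: list[str],
                            min_overlap: int) -> set[tuple[int, int]]:
    """Index pairs of patterns sharing a word of >= min_overlap bases in
    either orientation.

    Such pairs co-occur through occurrences of a longer shared word, which
    violates the marginal-independence null of the module test, so they are
    never tested together.
    """
    if not patterns or min_overlap > len(patterns[0]):
        return set()
    word_index: dict[str, list[int]] = {}
    for i, p in enumerate(patterns):
        subs = set()
        for s in (p, seqs.revcomp(p)):
            for j in range(len(s) - min_overlap + 1):
                subs.add(s[j:j + min_overlap])
        for w in subs:
            word_index.setdefault(w, []).append(i)
    blocked: set[tuple[int, int]] = set()
    for idxs in word_index.values():
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                blocked.add((idxs[a], idxs[b]))
    return blocked


def _search_matrix(matrix: np.ndarray, config: PipelineConfig,
                   blocked: set[tuple[int, int]] = frozenset()):
    """Level-wise search over a boolean (patterns x regions) matrix.

    Returns (retained sets as dict tuple->support, stats).
    """
    n_pat, n_regions = matrix.shape
    floor = config.module_min_support
    stats = SearchStats()
    retained: dict[tuple, int] = {}
    if n_pat < 2 or n_regions == 0:
        return retained, stats

    packed = np.packbits(matrix, axis=1)
    s2 = (matrix.astype(np.float32) @ matrix.astype(np.float32).T)
    stats.n_examined += n_pat * (n_pat - 1) // 2 - len(blocked)
    iu, ju = np.triu_indices(n_pat, k=1)
    sup = s2[iu, ju].astype(np.int64)
    keep = sup >= floor
    if blocked:
        allowed = np.ones((n_pat, n_pat), dtype=bool)
        for a, b in blocked:
            allowed[a, b] = allowed[b, a] = False
        keep &= allowed[iu, ju]
    level: dict[tuple, tuple[int, np.ndarray]] = {}
    for i, j, s in zip(iu[keep], ju[keep], sup[keep]):
        key = (int(i), int(j))
        level[key] = (int(s), packed[i] & packed[j])
        retained[key] = int(s)

    size = 2
    while level and size < config.module_max_size:
        # apriori join on shared prefix, then full subset check
        groups: dict[tuple, list[tuple]] = {}
        for key in level:
            groups.setdefault(key[:-1], []).append(key)
        nxt: dict[tuple, tuple[int, np.ndarray]] = {}
        retained_keys = set(level)
        for prefix, keys in groups.items():
            keys.sort()
            for a_idx in range(len(keys)):
                for b_idx in range(a_idx + 1, len(keys)):
                    a, b = keys[a_idx], keys[b_idx]
                    cand = a + (b[-1],)
                    if any(sub not in retained_keys
                           for sub in combinations(cand, size)
                           if sub != a and sub != b):
                        continue
                    stats.n_examined += 1
                    row = level[a][1] & level[b][1]
                    s = int(np.bitwise_count(row).sum())
                    if s >= floor:
                        nxt[cand] = (s, row)
                        retained[cand] = s
        level = nxt
        size += 1
    stats.n_retained = len(retained)
    return retained, stats


def discover_modules(occ_sets: dict, config: PipelineConfig,
                     n_regions: int | None = None,
                     return_stats: bool = False):
    """Significant motif modules from per-pattern region sets.

    ``occ_sets`` maps pattern -> set of region ids (as from
    :func:`occurrence_sets`).  ``n_regions`` defaults to the number of
    distinct region ids observed; pass it explicitly when some regions
    contain no candidate at all.
    """
    patterns = sorted(occ_sets)
    all_regions = sorted(set().union(*occ_sets.values()) if occ_sets else set())
    if n_regions is None:
        n_regions = len(all_regions)
    region_index = {r: i for i, r in enumerate(all_regions)}
    matrix = np.zeros((len(patterns), n_regions), dtype=bool)
    for i, p in enumerate(patterns):
        for r in occ_sets[p]:
            matrix[i, region_index[r]] = True
    modules, stats = _modules_from_matrix(matrix, patterns, config)
    return (modules, stats) if return_stats else modules


def _modules_from_matrix(matrix: np.ndarray, patterns: list[str],
                         config: PipelineConfig):
    n_regions = matrix.shape[1]
    blocked = lexically_blocked_pairs(patterns, config.module_pair_min_overlap)
    retained, stats = _search_matrix(matrix, config, blocked)
    counts = matrix.sum(axis=1)
    modules = []
    denom = max(stats.n_examined, 1)
    for key in sorted(retained):
        if len(key) < config.module_min_size:
            continue
        support = retained[key]
        p = _tail_pvalue(support, n_regions, [int(counts[i]) for i in key])
        corrected = min(1.0, p * denom)
        if corrected < config.module_alpha:
            modules.append(MotifModule(
                motif_ids=frozenset(patterns[i] for i in key),
                support=support, pvalue=p, corrected_pvalue=corrected))
    modules.sort(key=lambda m: (m.corrected_pvalue, m.pvalue,
                                len(m.motif_ids), sorted(m.motif_ids)))
    return modules, stats


def brute_force_modules(occ_sets: dict, config: PipelineConfig,
                        n_regions: int | None = None) -> list[MotifModule]:
    """Exhaustive reference enumeration (small inputs only).

    Examines every subset whose next-smaller subsets all meet the support
    floor, mirroring the pruned search's examined family; used as an
    independent oracle in tests.
    """
    patterns = sorted(occ_sets)
    sets = {p: set(occ_sets[p]) for p in patterns}
    if n_regions is None:
        n_regions = len(set().union(*sets.values()) if sets else set())
    blocked_idx = lexically_blocked_pairs(patterns,
                                          config.module_pair_min_overlap)
    blocked = {frozenset((patterns[a], patterns[b])) for a, b in blocked_idx}
    floor = config.module_min_support
    support: dict[tuple, int] = {}
    examined = 0
    results = []
    for size in range(2, config.module_max_size + 1):
        for combo in combinations(patterns, size):
            if size == 2 and frozenset(combo) in blocked:
                continue
            if size > 2 and any(sub not in support
                                for sub in combinations(combo, size - 1)):
                continue
            examined += 1
            inter = set.intersection(*(sets[p] for p in combo))
            s = len(inter)
            if s >= floor:
                support[combo] = s
                results.append((combo, s))
    modules = []
    for combo, s in results:
        if len(combo) < config.module_min_size:
            continue
        p = _tail_pvalue(s, n_regions, [len(sets[q]) for q in combo])
        corrected = min(1.0, p * max(examined, 1))
        if corrected < config.module_alpha:
            modules.append(MotifModule(frozenset(combo), s, p, corrected))
    modules.sort(key=lambda m: (m.corrected_pvalue, m.pvalue,
                                len(m.motif_ids), sorted(m.motif_ids)))
    return modules


# ---------------------------------------------------------------------------
# iterative discovery loop


def run_discovery(dataset: SequenceDataset, config: PipelineConfig,
                  background: MarkovBackground | None = None) -> DiscoveryState:
    """Iteratively rank candidates and mine modules until convergence.

    Each round ranks the not-yet-discovered patterns, takes the top
    ``top_patterns`` (de-overlapped against candidates and discovered
    motifs), mines significant modules, and adds their member patterns as
    discovered motifs.  Stops at ``motif_cap`` motifs or after
    ``stop_rounds_r`` consecutive rounds without a new motif.  Pattern
    scores are fixed for a dataset, so a round that adds nothing would
    repeat verbatim; the loop detects this and ends the count early.
    """
    k = config.kmer_width
    state = DiscoveryState()
    counts = KmerCounts(dataset, k)
    if counts.n_windows == 0:
        return state
    if background is None:
        background = MarkovBackground(order=2).fit(dataset.sequences)
    expected = background.expected_counts(counts.codes, k, counts.n_windows)
    scores = (counts.counts - expected) / np.sqrt(expected)
    rank_order = np.lexsort((counts.codes, -scores))
    ranked_codes = counts.codes[rank_order]

    discovered_codes: set[int] = set()
    prev_candidates: tuple | None = None
    while True:
        available = np.array(
            [c for c in ranked_codes if int(c) not in discovered_codes],
            dtype=np.int64)
        candidates = available[:config.top_patterns]
        if config.candidate_overlap_dedup:
            seed = np.array(sorted(discovered_codes), dtype=np.int64)
            merged = np.concatenate([seed, candidates])
            kept = dedup_overlapping_codes(merged, k, config.candidate_overlap_min)
            kept_set = set(int(c) for c in kept) - discovered_codes
            candidates = np.array(
                [c for c in candidates if int(c) in kept_set], dtype=np.int64)
        cand_key = tuple(int(c) for c in candidates)
        state.round_index += 1
        if candidates.size < config.module_min_size:
            state.rounds_without_new = config.stop_rounds_r
            break
        matrix = counts.occurrence_matrix(candidates)
        patterns = [seqs.decode_kmer(int(c), k) for c in candidates]
        modules, _ = _modules_from_matrix(matrix, patterns, config)
        known_sets = {m.motif_ids for m in state.discovered_modules}
        new_motifs = []
        for mod in modules:
            if len(state.discovered_motifs) >= config.motif_cap:
                break   # cap reached mid-round; overshoot < module_max_size
            if mod.motif_ids not in known_sets:
                state.discovered_modules.append(mod)
                known_sets.add(mod.motif_ids)
            for pat in sorted(mod.motif_ids):
                code = seqs.encode_kmer(pat)
                if code not in discovered_codes:
                    discovered_codes.add(code)
                    state.discovered_motifs.append(pat)
                    new_motifs.append(pat)
        if new_motifs:
            state.rounds_without_new = 0
        else:
            state.rounds_without_new += 1
            # nothing new means the next round's candidate list is identical
            # and would replay deterministically; end the count early
            if prev_candidates is None or cand_key == prev_candidates:
                state.rounds_without_new = config.stop_rounds_r
        prev_candidates = cand_key
        if len(state.discovered_motifs) >= config.motif_cap:
            break
        if state.rounds_without_new >= config.stop_rounds_r:
            break
    return state


def pattern_sites(dataset: SequenceDataset, pattern: str):
    """All exact occurrences of a canonical pattern (or its reverse
    complement) as (region_index, offset, strand) triples."""
    k = len(pattern)
    fwd = seqs.encode_kmer(pattern)
    rc = seqs.encode_kmer(seqs.revcomp(pattern))
    sites = []
    for idx, seq in enumerate(dataset.sequences):
        codes = seqs.encode(seq)
        n = codes.size - k + 1
        if n <= 0:
            continue
        invalid = (codes == 255).astype(np.int32)
        cum = np.concatenate(([0], np.cumsum(invalid)))
        bad = (cum[k:] - cum[:-k]) > 0
        safe = np.where(codes == 255, 0, codes).astype(np.int64)
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        vals = np.lib.stride_tricks.sliding_window_view(safe, k) @ powers
        ok = ~bad
        for pos in np.nonzero(ok & (vals == fwd))[0]:
            sites.append((idx, int(pos), "+"))
        if rc != fwd:
            for pos in np.nonzero(ok & (vals == rc))[0]:
                sites.append((idx, int(pos), "-"))
    sites.sort()
    return sites
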