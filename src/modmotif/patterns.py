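"""k-mer pattern counting and ranking against a Markov background.

A pattern and its reverse complement are merged under the lexicographically
smaller key (binding is strand-symmetric); each N-free window contributes
one count to the canonical key of its forward string, so total counts add
up to the number of N-free windows.  Patterns are ranked by a Poisson
z-score, (observed - expected) / sqrt(expected), with expected counts from
an order-2 Markov chain fitted on the dataset's own masked sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from modmotif import seqs
from modmotif.io import SequenceDataset


class ModelError(ValueError):
    """Background model cannot supply a valid expectation."""


@dataclass
class KmerStats:
    pattern: str
    observed_count: int
    expected_count: float = 0.0
    score: float = 0.0
    region_set: frozenset = frozenset()


class KmerStatsMap(dict):
    """pattern -> KmerStats, remembering the window total behind the counts."""

    def __init__(self, *args, n_windows: int = 0, n_regions: int = 0, **kw):
        super().__init__(*args, **kw)
        self.n_windows = n_windows
        self.n_regions = n_regions


class KmerCounts:
    """Array-backed canonical k-mer counts and per-region presence.

    The heavy per-window work is done once here; both the public
    ``count_kmers`` view and the discovery loop read from it.
    """

    def __init__(self, dataset: SequenceDataset, k: int):
        if k < 4:
            raise ValueError("k must be >= 4")
        self.k = k
        self.n_regions = dataset.n_regions
        self.region_ids = dataset.region_ids
        all_codes = []
        pres_codes = []
        pres_regions = []
        n_windows = 0
        for idx, seq in enumerate(dataset.sequences):
            codes = seqs.window_codes(seqs.encode(seq), k)
            if codes.size == 0:
                continue
            canon = seqs.canonical_codes(codes, k)
            n_windows += canon.size
            all_codes.append(canon)
            uniq = np.unique(canon)
            pres_codes.append(uniq)
            pres_regions.append(np.full(uniq.size, idx, dtype=np.int64))
        self.n_windows = n_windows
        if n_windows == 0:
            self.codes = np.empty(0, dtype=np.int64)
            self.counts = np.empty(0, dtype=np.int64)
            self._pres_codes = np.empty(0, dtype=np.int64)
            self._pres_regions = np.empty(0, dtype=np.int64)
            self.presence_counts = np.empty(0, dtype=np.int64)
            return
        concat = np.concatenate(all_codes)
        self.codes, self.counts = np.unique(concat, return_counts=True)
        pc = np.concatenate(pres_codes)
        pr = np.concatenate(pres_regions)
        order = np.argsort(pc, kind="stable")
        self._pres_codes = pc[order]
        self._pres_regions = pr[order]
        # regions containing >= 1 match, per unique code
        idx = np.searchsorted(self._pres_codes, self.codes)
        bounds = np.append(idx, self._pres_codes.size)
        self.presence_counts = np.diff(bounds)

    def region_indices(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._pres_codes, code, side="left")
        hi = np.searchsorted(self._pres_codes, code, side="right")
        return self._pres_regions[lo:hi]

    def occurrence_matrix(self, codes: np.ndarray) -> np.ndarray:
        """Boolean (n_patterns x n_regions) presence matrix."""
        mat = np.zeros((len(codes), self.n_regions), dtype=bool)
        for i, c in enumerate(codes):
            mat[i, self.region_indices(int(c))] = True
        return mat


class MarkovBackground:
    """Order-m Markov chain over ACGT fitted on masked sequences.

    Transition probabilities carry an additive pseudocount of 1, so the
    expectation of any observable pattern is strictly positive.
    """

    def __init__(self, order: int = 2):
        if not (0 <= order <= 3):
            raise ValueError("order must be in 0..3")
        self.order = order
        self.transition: np.ndarray | None = None   # (4^m, 4)
        self.context_prob: np.ndarray | None = None  # (4^m,)

    def fit(self, sequences) -> "MarkovBackground":
        m = self.order
        n_ctx = 4 ** m
        trans_counts = np.zeros((n_ctx, 4), dtype=np.int64)
        ctx_counts = np.zeros(n_ctx, dtype=np.int64)
        for seq in sequences:
            codes = seqs.window_codes(seqs.encode(seq), m + 1)
            if codes.size:
                ctx = codes >> 2
                base = codes & 3
                np.add.at(trans_counts, (ctx, base), 1)
            if m > 0:
                mg = seqs.window_codes(seqs.encode(seq), m)
                if mg.size:
                    ctx_counts += np.bincount(mg, minlength=n_ctx)
            else:
                ctx_counts[0] += max(len(seq) - 1, 0)
        self.transition = (trans_counts + 1) / (
            trans_counts.sum(axis=1, keepdims=True) + 4)
        self.context_prob = (ctx_counts + 1) / (ctx_counts.sum() + n_ctx)
        return self

    @classmethod
    def from_transition(cls, transition: np.ndarray,
                        context_prob: np.ndarray | None = None) -> "MarkovBackground":
        """Wrap explicitly given parameters (e.g. a generator's truth)."""
        transition = np.asarray(transition, dtype=float)
        n_ctx = transition.shape[0]
        order = int(round(np.log(n_ctx) / np.log(4)))
        bg = cls(order)
        bg.transition = transition
        if context_prob is None:
            # stationary-ish start: uniform over contexts
            context_prob = np.full(n_ctx, 1.0 / n_ctx)
        bg.context_prob = np.asarray(context_prob, dtype=float)
        return bg

    def pattern_prob(self, codes: np.ndarray, k: int) -> np.ndarray:
        """P(pattern) for packed codes under the chain (vectorized)."""
        if self.transition is None:
            raise ModelError("background model not fitted")
        m = self.order
        if k < m:
            raise ModelError("pattern shorter than model order")
        codes = np.asarray(codes, dtype=np.int64)
        digits = [(codes >> (2 * (k - 1 - i))) & 3 for i in range(k)]
        ctx = np.zeros(codes.shape, dtype=np.int64)
        for i in range(m):
            ctx = (ctx << 2) | digits[i]
        p = self.context_prob[ctx] if m > 0 else np.ones(codes.shape, dtype=float)
        ctx_mask = 4 ** m - 1
        for i in range(m, k):
            p = p * self.transition[ctx, digits[i]]
            ctx = ((ctx << 2) | digits[i]) & ctx_mask
        return p

    def expected_counts(self, canon_codes: np.ndarray, k: int,
                        n_windows: int) -> np.ndarray:
        """Expected canonical-key counts over ``n_windows`` windows."""
        canon_codes = np.asarray(canon_codes, dtype=np.int64)
        p_fwd = self.pattern_prob(canon_codes, k)
        rc = seqs.rc_codes(canon_codes, k)
        p_rc = self.pattern_prob(rc, k)
        palindrome = rc == canon_codes
        total = np.where(palindrome, p_fwd, p_fwd + p_rc)
        return n_windows * total


# ---------------------------------------------------------------------------
# public operations


def count_kmers(dataset: SequenceDataset, k: int) -> KmerStatsMap:
    """Canonical k-mer statistics for one dataset's masked sequences."""
    counts = KmerCounts(dataset, k)
    out = KmerStatsMap(n_windows=counts.n_windows, n_regions=counts.n_regions)
    ids = counts.region_ids
    for code, cnt in zip(counts.codes, counts.counts):
        pattern = seqs.decode_kmer(int(code), k)
        rset = frozenset(ids[i] for i in counts.region_indices(int(code)))
        out[pattern] = KmerStats(pattern, int(cnt), region_set=rset)
    return out


def rank_patterns(stats: KmerStatsMap, background: MarkovBackground,
                  exclude=()) -> list[KmerStats]:
    """Rank canonical patterns by Poisson z-score, descending.

    Ties break lexicographically; ``exclude`` patterns are omitted.
    """
    exclude = {seqs.canonical_pattern(p) for p in exclude}
    patterns = sorted(p for p in stats if p not in exclude)
    if not patterns:
        return []
    k = len(patterns[0])
    codes = np.array([seqs.encode_kmer(p) for p in patterns], dtype=np.int64)
    expected = background.expected_counts(codes, k, stats.n_windows)
    if np.any(expected <= 0):
        bad = patterns[int(np.argmax(expected <= 0))]
        raise ModelError(f"non-positive expectation for observed pattern {bad}")
    observed = np.array([stats[p].observed_count for p in patterns], dtype=float)
    scores = (observed - expected) / np.sqrt(expected)
    order = np.lexsort((np.arange(len(patterns)), -scores))
    ranked = []
    for i in order:
        st = stats[patterns[i]]
        st.expected_count = float(expected[i])
        st.score = float(scores[i])
        ranked.append(st)
    return ranked


def top_candidates(ranked: list, m: int) -> list:
    """First ``m`` patterns of a ranked list (order preserved)."""
    if m < 0:
        raise ValueError("m must be >= 0")
    return list(ranked[:m])


def _substring_codes(code: int, k: int, length: int) -> list[int]:
    mask = 4 ** length - 1
    return [(code >> (2 * s)) & mask for s in range(k - length + 1)]


def dedup_overlapping_codes(codes: np.ndarray, k: int, min_overlap: int) -> np.ndarray:
    """Greedy rank-order de-overlap of candidate pattern codes.

    A candidate is dropped when it shares a word of length ``min_overlap``
    (in either orientation) with an already kept candidate, i.e. when some
    ungapped alignment matches on >= min_overlap positions.  Shifted
    variants of one underlying word co-occur through shared longer words,
    which would violate the independence null of the module test.
    """
    if min_overlap >= k:
        return np.asarray(codes, dtype=np.int64)
    kept = []
    seen: set[int] = set()
    for c in np.asarray(codes, dtype=np.int64):
        c = int(c)
        rc = int(seqs.rc_codes(np.array([c]), k)[0])
        subs = set(_substring_codes(c, k, min_overlap))
        subs.update(_substring_codes(rc, k, min_overlap))
        if subs & seen:
            continue
        kept.append(c)
        seen |= subs
    return np.array(kept, dtype=np.int64)


def dedup_overlapping(patterns: list[str], min_overlap: int = 7) -> list[str]:
    """String-level wrapper of :func:`dedup_overlapping_codes`."""
    if not patterns:
        return []
    k = len(patterns[0])
    codes = np.array([seqs.encode_kmer(p) for p in patterns], dtype=np.int64)
    kept = dedup_overlapping_codes(codes, k, min_overlap)
    kept_set = set(int(c) for c in kept)
    return [p for p, c in zip(patterns, codes) if int(c) in kept_set]
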