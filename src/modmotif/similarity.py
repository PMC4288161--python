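"""PWM comparison with two column metrics and calibrated E-values.

Two motifs are compared by the best ungapped alignment (both orientations,
overlap at least min(6, shorter width)) under two per-column metrics:

* Pearson correlation of the 4-vectors (guards against length artifacts;
  plays the role of the first comparison tool in the two-threshold rule);
* average log-likelihood ratio (ALLR) against a flat background (guards
  against low-information matches; plays the second tool's role).

E-values come from a random-motif null (rows are four iid uniforms
normalized to sum 1).  Two calibrations are provided: the empirical tail
``evalue`` (bounded below by 1/(1+|null|)), and the engine's column-sum
Gaussian tail, which extrapolates far beyond the sampled null so that
strong matches reach the very small E-values the clustering thresholds
(down to 1e-8) require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from modmotif.config import PipelineConfig

_LOG_BG = np.log2(0.25)
_EPS = 1e-6


@dataclass
class PairwiseComparison:
    """Pairwise comparison matrices between two motif lists."""

    score_corr: np.ndarray
    score_allr: np.ndarray
    evalue_corr: np.ndarray
    evalue_allr: np.ndarray


@dataclass
class SimilarityResult:
    score_corr: float
    score_allr: float
    evalue_corr: float
    evalue_allr: float
    offset: int
    orientation: str   # 'forward' | 'reverse'


def make_random_motif(width: int, seed) -> np.ndarray:
    """Random PWM: each row is four iid uniform(0,1) draws divided by
    their sum, so every row sums to exactly 1."""
    if width < 1:
        raise ValueError("width must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    u = rng.random((width, 4))
    return u / u.sum(axis=1, keepdims=True)


def _as_matrix(motif) -> np.ndarray:
    mat = motif.matrix if hasattr(motif, "matrix") else motif
    return np.asarray(mat, dtype=float)


def _revcomp_matrix(mat: np.ndarray) -> np.ndarray:
    return mat[::-1, ::-1]


def _corr_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation per column pair; zero-variance columns score 0."""
    ac = a - a.mean(axis=-1, keepdims=True)
    bc = b - b.mean(axis=-1, keepdims=True)
    num = (ac * bc).sum(axis=-1)
    den = np.sqrt((ac * ac).sum(axis=-1) * (bc * bc).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return r


def _allr_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Symmetrized average log-likelihood ratio vs a flat background."""
    la = np.log2(np.maximum(a, _EPS)) - _LOG_BG
    lb = np.log2(np.maximum(b, _EPS)) - _LOG_BG
    return 0.5 * ((a * lb).sum(axis=-1) + (b * la).sum(axis=-1))


_COLUMN_METRICS = {"corr": _corr_columns, "allr": _allr_columns}


def _offsets(wa: int, wb: int):
    minov = min(6, wa, wb)
    return range(-(wb - minov), wa - minov + 1), minov


def align_score(a, b, metric: str = "corr"):
    """Best mean per-column score over all ungapped alignments.

    Returns (score, offset, orientation); b is also tried
    reverse-complemented.  Ties resolve to the forward orientation and the
    smaller offset.  Offset is the position of b's first column relative
    to a's first column.
    """
    fn = _COLUMN_METRICS[metric]
    A = _as_matrix(a)
    B = _as_matrix(b)
    wa, wb = A.shape[0], B.shape[0]
    if wa < 4 or wb < 4:
        raise ValueError("motif widths must be >= 4")
    offsets, _ = _offsets(wa, wb)
    best = (-np.inf, 0, "forward")
    for orientation, mat in (("forward", B), ("reverse", _revcomp_matrix(B))):
        for off in offsets:
            lo = max(0, off)
            hi = min(wa, off + wb)
            cols = fn(A[lo:hi], mat[lo - off:hi - off])
            score = float(cols.mean())
            if score > best[0] + 1e-12:
                best = (score, off, orientation)
    return best


def _batch_best(A: np.ndarray, B: np.ndarray, metric: str):
    """Best alignment score and its overlap for stacked pairs.

    A: (n, wa, 4), B: (n, wb, 4).  Returns (scores, overlaps)."""
    fn = _COLUMN_METRICS[metric]
    wa, wb = A.shape[1], B.shape[1]
    offsets, _ = _offsets(wa, wb)
    n = A.shape[0]
    best = np.full(n, -np.inf)
    best_ov = np.full(n, min(wa, wb), dtype=np.int64)
    for Bmat in (B, B[:, ::-1, ::-1]):
        for off in offsets:
            lo = max(0, off)
            hi = min(wa, off + wb)
            cols = fn(A[:, lo:hi], Bmat[:, lo - off:hi - off])
            score = cols.mean(axis=-1)
            better = score > best + 1e-12
            best = np.where(better, score, best)
            best_ov = np.where(better, hi - lo, best_ov)
    return best, best_ov


def calibrate_null(width_a: int, width_b: int, n_samples: int, seed,
                   metric: str = "corr") -> np.ndarray:
    """Sorted empirical null of align_score over random-motif pairs."""
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000")
    rng = np.random.default_rng(seed)
    ua = rng.random((n_samples, width_a, 4))
    ub = rng.random((n_samples, width_b, 4))
    A = ua / ua.sum(axis=-1, keepdims=True)
    B = ub / ub.sum(axis=-1, keepdims=True)
    scores, _ = _batch_best(A, B, metric)
    return np.sort(scores)


def evalue(score: float, null: np.ndarray, n_comparisons: int = 1) -> float:
    """Empirical-tail E-value: n * (1 + #null >= score) / (1 + |null|)."""
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    n_ge = null.size - np.searchsorted(np.sort(null), score, side="left")
    return n_comparisons * (1 + int(n_ge)) / (1 + null.size)


class SimilarityEngine:
    """Caches null calibrations and applies the two-threshold rule.

    The engine's E-values use a column-sum Gaussian tail: per-column null
    moments (mu0, sigma0) are estimated once from random column pairs, and
    an alignment of overlap w scoring S (mean per column) gets
    p = Phi_bar((w*S - w*mu0) / (sigma0 * sqrt(w))), E = n_comparisons * p.
    This extrapolates smoothly past the empirical null range, which the
    clustering thresholds (1e-8) require; absolute scales are a calibrated
    stand-in for published comparison tools, not a reproduction.
    """

    def __init__(self, config: PipelineConfig | None = None,
                 seed: int | None = None):
        self.config = config or PipelineConfig()
        self.seed = self.config.random_seed if seed is None else seed
        self._null_cache: dict[tuple, np.ndarray] = {}
        rng = np.random.default_rng((self.seed, 0x5151))
        n = self.config.column_null_samples
        ua = rng.random((n, 4))
        ub = rng.random((n, 4))
        a = ua / ua.sum(axis=1, keepdims=True)
        b = ub / ub.sum(axis=1, keepdims=True)
        self.column_moments = {}
        for metric, fn in _COLUMN_METRICS.items():
            vals = fn(a, b)
            self.column_moments[metric] = (float(vals.mean()),
                                           float(vals.std(ddof=1)))

    # -- empirical null (spec'd evalue path) --------------------------------
    def null(self, width_a: int, width_b: int, metric: str) -> np.ndarray:
        key = (min(width_a, width_b), max(width_a, width_b), metric)
        if key not in self._null_cache:
            metric_id = sorted(_COLUMN_METRICS).index(metric)
            self._null_cache[key] = calibrate_null(
                key[0], key[1], self.config.null_samples,
                (self.seed, key[0], key[1], metric_id), metric)
        return self._null_cache[key]

    # -- Gaussian column-sum tail ------------------------------------------
    def tail_pvalue(self, score, overlap, metric: str):
        mu, sigma = self.column_moments[metric]
        score = np.asarray(score, dtype=float)
        ov = np.asarray(overlap, dtype=float)
        z = (score * ov - ov * mu) / (sigma * np.sqrt(ov))
        return np.clip(sps.norm.sf(z), 1e-300, 1.0)

    def compare(self, a, b, n_comparisons: int = 1) -> SimilarityResult:
        s_corr, off_c, ori_c = align_score(a, b, "corr")
        s_allr, off_a, ori_a = align_score(a, b, "allr")
        A = _as_matrix(a)
        B = _as_matrix(b)

        def ov_of(off):
            return min(A.shape[0], off + B.shape[0]) - max(0, off)

        e_corr = float(self.tail_pvalue(s_corr, ov_of(off_c), "corr")) \
            * n_comparisons
        e_allr = float(self.tail_pvalue(s_allr, ov_of(off_a), "allr")) \
            * n_comparisons
        return SimilarityResult(s_corr, s_allr, e_corr, e_allr, off_a, ori_a)

    def compare_matrix(self, motifs_a, motifs_b=None,
                       chunk: int = 200_000) -> "PairwiseComparison":
        """Pairwise score and E-value matrices between motif lists.

        Symmetric when ``motifs_b`` is None (compares a list to itself).
        """
        mats_a = [_as_matrix(m) for m in motifs_a]
        symmetric = motifs_b is None
        mats_b = mats_a if symmetric else [_as_matrix(m) for m in motifs_b]
        na, nb = len(mats_a), len(mats_b)
        E = {m: np.ones((na, nb)) for m in _COLUMN_METRICS}
        S = {m: np.zeros((na, nb)) for m in _COLUMN_METRICS}
        pairs = []
        for i in range(na):
            j0 = i + 1 if symmetric else 0
            for j in range(j0, nb):
                pairs.append((i, j))
        # group by width pair so each batch is rectangular
        groups: dict[tuple, list[tuple]] = {}
        for i, j in pairs:
            groups.setdefault((mats_a[i].shape[0], mats_b[j].shape[0]),
                              []).append((i, j))
        for (wa, wb), idx in groups.items():
            for start in range(0, len(idx), chunk):
                sub = idx[start:start + chunk]
                A = np.stack([mats_a[i] for i, _ in sub])
                B = np.stack([mats_b[j] for _, j in sub])
                for metric in _COLUMN_METRICS:
                    scores, ovs = _batch_best(A, B, metric)
                    pv = self.tail_pvalue(scores, ovs, metric)
                    for (i, j), p, s in zip(sub, pv, scores):
                        E[metric][i, j] = p
                        S[metric][i, j] = s
                        if symmetric:
                            E[metric][j, i] = p
                            S[metric][j, i] = s
        if symmetric:
            for metric in _COLUMN_METRICS:
                np.fill_diagonal(E[metric], 0.0)
                np.fill_diagonal(S[metric], 1.0 if metric == "corr" else 2.0)
        return PairwiseComparison(S["corr"], S["allr"], E["corr"], E["allr"])


def is_similar(a, b, engine: SimilarityEngine,
               config: PipelineConfig | None = None):
    """The two-threshold similarity rule.

    Similar iff (E_corr < e1_strict and E_allr < e2_strict) or
    (E_corr < e1_loose and E_allr < e2_loose)."""
    cfg = config or engine.config
    res = engine.compare(a, b)
    verdict = _rule(res.evalue_corr, res.evalue_allr, cfg)
    return verdict, res


def _rule(e_corr, e_allr, cfg: PipelineConfig):
    return bool((e_corr < cfg.sim_e1_strict and e_allr < cfg.sim_e2_strict)
                or (e_corr < cfg.sim_e1_loose and e_allr < cfg.sim_e2_loose))


def similar_matrix(E_corr: np.ndarray, E_allr: np.ndarray,
                   cfg: PipelineConfig) -> np.ndarray:
    """Vectorized two-threshold rule over E-value matrices."""
    return ((E_corr < cfg.sim_e1_strict) & (E_allr < cfg.sim_e2_strict)) | \
           ((E_corr < cfg.sim_e1_loose) & (E_allr < cfg.sim_e2_loose))
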