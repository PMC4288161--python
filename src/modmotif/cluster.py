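"""Sequential non-redundant clustering of motifs across datasets.

Datasets are processed in descending order of predicted-motif count.  Every
motif of the first dataset seeds a cluster.  Each later motif joins the
first existing cluster it qualifies for: it must be highly similar to at
least one member (the anchor rule, E < cluster_e_anchor on the second
metric) and similar (E < cluster_e_member) to all members of a small
cluster or to at least cluster_frac of a larger one.  Motifs qualifying
nowhere are pooled per dataset; mutually similar pooled motifs form new
clusters greedily (seeded by the motif with the most pooled similars), the
rest become singletons.  Each cluster is represented by the member similar
to the most other members, and clusters with similar representatives are
iteratively re-partitioned by average-linkage hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from modmotif.config import PipelineConfig
from modmotif.refine import Motif
from modmotif.similarity import SimilarityEngine


@dataclass
class MotifCluster:
    members: list[tuple[Motif, str]]            # (motif, dataset id), added order
    representative: str | None = None           # member motif id
    indices: list[int] = field(default_factory=list)   # context positions

    def __len__(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m, _ in self.members]


@dataclass
class _Context:
    motifs: list[Motif]
    dataset_ids: list[str]
    member_sim: np.ndarray     # E_allr < cluster_e_member
    anchor_sim: np.ndarray     # E_allr < cluster_e_anchor
    score_corr: np.ndarray


def _build_context(entries, engine: SimilarityEngine,
                   config: PipelineConfig) -> _Context:
    motifs = [m for m, _ in entries]
    dataset_ids = [d for _, d in entries]
    comp = engine.compare_matrix(motifs)
    member_sim = comp.evalue_allr < config.cluster_e_member
    anchor_sim = comp.evalue_allr < config.cluster_e_anchor
    np.fill_diagonal(member_sim, False)
    np.fill_diagonal(anchor_sim, False)
    return _Context(motifs, dataset_ids, member_sim, anchor_sim,
                    comp.score_corr)


def _passes_rules(anchor_any: bool, n_similar: int, n_members: int,
                  config: PipelineConfig) -> bool:
    if n_members == 0 or not anchor_any:
        return False
    if n_members < config.cluster_small_size:
        return n_similar == n_members
    return n_similar / n_members >= config.cluster_frac


def _qualifies(ctx: _Context, x: int, members: list[int],
               config: PipelineConfig) -> bool:
    anchor = bool(ctx.anchor_sim[x, members].any())
    n_sim = int(ctx.member_sim[x, members].sum())
    return _passes_rules(anchor, n_sim, len(members), config)


def similar_to_cluster(x: Motif, cluster: MotifCluster,
                       engine: SimilarityEngine,
                       config: PipelineConfig) -> bool:
    """Anchor + membership rule for one motif against one cluster."""
    members = [m for m, _ in cluster.members]
    if not members:
        return False
    evs = [engine.compare(x, m).evalue_allr for m in members]
    anchor = any(e < config.cluster_e_anchor for e in evs)
    n_sim = sum(e < config.cluster_e_member for e in evs)
    return _passes_rules(anchor, n_sim, len(members), config)


def _greedy_pool_groups(pool: list[int], ctx: _Context) -> list[list[int]]:
    """Group mutually similar pooled motifs; greedy max-degree seeding."""
    groups = []
    remaining = list(pool)
    while remaining:
        degrees = [int(ctx.member_sim[p, remaining].sum()) for p in remaining]
        best = int(np.argmax(degrees))
        if degrees[best] == 0:
            break
        seed = remaining[best]
        members = [seed] + [q for q in remaining
                            if q != seed and ctx.member_sim[seed, q]]
        groups.append(members)
        remaining = [q for q in remaining if q not in members]
    groups.extend([[q] for q in remaining])
    return groups


def _materialize(ctx: _Context, idx_clusters: list[list[int]],
                 config: PipelineConfig) -> list[MotifCluster]:
    out = []
    for idxs in idx_clusters:
        members = [(ctx.motifs[i], ctx.dataset_ids[i]) for i in idxs]
        cl = MotifCluster(members=members, indices=list(idxs))
        cl.representative = ctx.motifs[_representative_index(ctx, idxs)].id
        out.append(cl)
    return out


def _representative_index(ctx: _Context, idxs: list[int]) -> int:
    best, best_count = idxs[0], -1
    for i in idxs:
        others = [j for j in idxs if j != i]
        count = int(ctx.member_sim[i, others].sum()) if others else 0
        if count > best_count:
            best, best_count = i, count
    return best


def choose_representative(cluster: MotifCluster, engine: SimilarityEngine,
                          config: PipelineConfig) -> str:
    """Member similar to the most other members; ties to earliest added."""
    motifs = [m for m, _ in cluster.members]
    if not motifs:
        raise ValueError("empty cluster")
    if len(motifs) == 1:
        return motifs[0].id
    comp = engine.compare_matrix(motifs)
    sim = comp.evalue_allr < config.cluster_e_member
    np.fill_diagonal(sim, False)
    counts = sim.sum(axis=1)
    return motifs[int(np.argmax(counts))].id


def cluster_all(datasets_with_motifs, engine: SimilarityEngine,
                config: PipelineConfig, order: str = "descending",
                refine: bool = True) -> list[MotifCluster]:
    """Full sequential clustering of per-dataset motif lists.

    ``datasets_with_motifs``: list of (dataset_id, [Motif, ...]).
    ``order``: 'descending' (default protocol) or 'ascending' motif-count
    processing order (the robustness variant).
    """
    if not datasets_with_motifs:
        raise ValueError("need at least one dataset")
    sign = -1 if order == "descending" else 1
    ordered = sorted(datasets_with_motifs,
                     key=lambda dm: (sign * len(dm[1]), dm[0]))
    entries = []
    starts = []
    for did, motifs in ordered:
        starts.append(len(entries))
        entries.extend((m, did) for m in motifs)
    ctx = _build_context(entries, engine, config)

    idx_clusters: list[list[int]] = []
    first_count = len(ordered[0][1])
    for i in range(first_count):
        idx_clusters.append([i])
    pos = first_count
    for did, motifs in ordered[1:]:
        pool = []
        for _ in motifs:
            x = pos
            pos += 1
            placed = False
            for cl in idx_clusters:
                if _qualifies(ctx, x, cl, config):
                    cl.append(x)
                    placed = True
                    break
            if not placed:
                pool.append(x)
        for group in _greedy_pool_groups(pool, ctx):
            idx_clusters.append(group)
    if refine:
        idx_clusters = _refine(ctx, idx_clusters, config)
    return _materialize(ctx, idx_clusters, config)


# ---------------------------------------------------------------------------
# refinement


def _valid_cluster(ctx: _Context, idxs: list[int],
                   config: PipelineConfig) -> bool:
    if len(idxs) <= 1:
        return True
    for x in idxs:
        others = [j for j in idxs if j != x]
        if not _qualifies(ctx, x, others, config):
            return False
    return True


def _cut_tree(ctx: _Context, pooled: list[int], config: PipelineConfig):
    """Average-linkage clustering of pooled motifs, cut so that every
    resulting cluster satisfies the membership rules for all members."""
    if len(pooled) == 1:
        return [list(pooled)]
    # distance from the correlation-metric alignment score, mapped to [0, 1]
    sub = ctx.score_corr[np.ix_(pooled, pooled)]
    D = 1.0 - (sub + 1.0) / 2.0
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    root = to_tree(Z)

    def collect(node):
        leaves = [pooled[i] for i in node.pre_order()]
        if _valid_cluster(ctx, leaves, config):
            return [leaves]
        return collect(node.get_left()) + collect(node.get_right())

    return collect(root)


def _refine(ctx: _Context, idx_clusters: list[list[int]],
            config: PipelineConfig, max_iter: int = 10) -> list[list[int]]:
    clusters = [list(c) for c in idx_clusters]
    for _ in range(max_iter):
        reps = [_representative_index(ctx, c) for c in clusters]
        n = len(clusters)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        any_similar = False
        for i in range(n):
            for j in range(i + 1, n):
                if ctx.member_sim[reps[i], reps[j]]:
                    any_similar = True
                    pi, pj = find(i), find(j)
                    if pi != pj:
                        parent[max(pi, pj)] = min(pi, pj)
        if not any_similar:
            break
        components: dict[int, list[int]] = {}
        for i in range(n):
            components.setdefault(find(i), []).append(i)
        new_clusters: list[list[int]] = []
        changed = False
        for root in sorted(components):
            group = components[root]
            if len(group) == 1:
                new_clusters.append(clusters[group[0]])
                continue
            pooled = [i for g in group for i in clusters[g]]
            pieces = _cut_tree(ctx, pooled, config)
            old = {frozenset(clusters[g]) for g in group}
            if {frozenset(p) for p in pieces} != old:
                changed = True
            new_clusters.extend(pieces)
        clusters = new_clusters
        if not changed:
            break
    return clusters


def refine_clusters(clusters: list[MotifCluster], engine: SimilarityEngine,
                    config: PipelineConfig) -> list[MotifCluster]:
    """Standalone refinement of materialized clusters."""
    entries = [(m, d) for cl in clusters for (m, d) in cl.members]
    ctx = _build_context(entries, engine, config)
    offsets = []
    pos = 0
    for cl in clusters:
        offsets.append(list(range(pos, pos + len(cl.members))))
        pos += len(cl.members)
    refined = _refine(ctx, offsets, config)
    return _materialize(ctx, refined, config)
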