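"""Synthetic genomes, annotations and DHS datasets with planted truth.

The generator is the statistical stand-in for a large collection of
DNase-seq open-chromatin datasets: many short regions (hundreds of bp)
drawn from an order-2 Markov background, a minority of regions carrying
co-occurring binding sites of 2-6 planted PWMs (motif modules), masked
('N') background stretches emulating repeat/exon masking, and multiple
datasets grouped into types sharing type-specific motif profiles.  Planted
sites are never masked and never overlap each other, so recovery rates
against the logged truth are interpretable.  Every operation is a pure
function of its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from modmotif import seqs
from modmotif.config import PipelineConfig
from modmotif.io import GeneModel, GenomicRegion, SequenceDataset
from modmotif.similarity import make_random_motif

__all__ = [
    "GenomeResult", "PlantedTruth", "make_genome", "make_annotation",
    "make_random_motif", "make_informative_motif", "perturb_motif",
    "make_motif_family", "plant_datasets", "make_typed_collection",
    "make_interactions",
]


@dataclass
class GenomeResult:
    sequences: dict[str, str]
    lengths: dict[str, int]
    transition: np.ndarray       # (4^order, 4) row-stochastic
    order: int
    gc: float

    def __getitem__(self, chrom):
        return self.sequences[chrom]


@dataclass
class PlantedTruth:
    motifs: dict[str, np.ndarray] = field(default_factory=dict)
    modules: list[tuple[frozenset, float]] = field(default_factory=list)
    site_log: list[tuple[str, str, int, str]] = field(default_factory=list)
    site_strings: list[str] = field(default_factory=list)  # parallel to site_log
    type_profiles: dict[str, frozenset] = field(default_factory=dict)

    def consensus(self, motif_id: str) -> str:
        mat = self.motifs[motif_id]
        return "".join(seqs.BASES[i] for i in mat.argmax(axis=1))


# ---------------------------------------------------------------------------
# genome and annotation


def make_genome(length: int, gc: float = 0.41, markov_order: int = 2,
                seed=0, chrom_name: str = "chr1") -> GenomeResult:
    """Order-m Markov background genome with exact per-position GC.

    Every transition row assigns total probability ``gc`` to {C, G} (the
    split between C and G, and between A and T, varies by context), so the
    empirical GC fraction concentrates tightly around ``gc``.
    """
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must lie strictly between 0 and 1")
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    if not (0 <= markov_order <= 3):
        raise ValueError("markov_order must be in 0..3")
    rng = np.random.default_rng((seed, 0xC0DE))
    n_ctx = 4 ** markov_order
    u = rng.uniform(0.35, 0.65, size=n_ctx)
    v = rng.uniform(0.35, 0.65, size=n_ctx)
    rows = np.stack([(1 - gc) * v, gc * u, gc * (1 - u),
                     (1 - gc) * (1 - v)], axis=1)  # A C G T
    cum = np.cumsum(rows, axis=1)
    cum[:, -1] = 1.0
    cum_list = [tuple(r[:3]) for r in cum]
    unifs = rng.random(length)
    mask = n_ctx - 1
    ctx = 0
    out = bytearray(length)
    bases = b"ACGT"
    for i in range(length):
        row = cum_list[ctx]
        x = unifs[i]
        if x < row[0]:
            b = 0
        elif x < row[1]:
            b = 1
        elif x < row[2]:
            b = 2
        else:
            b = 3
        out[i] = bases[b]
        ctx = ((ctx << 2) | b) & mask
    seq = out.decode("ascii")
    return GenomeResult({chrom_name: seq}, {chrom_name: length},
                        rows, markov_order, gc)


def make_annotation(genome, n_genes: int, seed=0) -> list[GeneModel]:
    """Random non-overlapping gene models with UTRs and >= 2 introns each."""
    lengths = genome.lengths if isinstance(genome, GenomeResult) else dict(genome)
    rng = np.random.default_rng((seed, 0xA110))
    genes: list[GeneModel] = []
    if n_genes == 0:
        return genes
    chroms = sorted(lengths)
    per_chrom = {c: [] for c in chroms}
    for i in range(n_genes):
        per_chrom[chroms[i % len(chroms)]].append(i)
    for chrom in chroms:
        idxs = per_chrom[chrom]
        if not idxs:
            continue
        clen = lengths[chrom]
        cursor = int(rng.integers(1000, 3000))
        for i in idxs:
            n_ex = int(rng.integers(3, 6))
            ex_lens = rng.integers(150, 400, size=n_ex)
            in_lens = rng.integers(300, 1500, size=n_ex - 1)
            span = int(ex_lens.sum() + in_lens.sum())
            gap = int(rng.integers(2000, 6000))
            start = cursor + gap
            end = start + span
            if end + 1000 > clen:
                raise ValueError(
                    f"genome too small for {n_genes} genes on {chrom}")
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = start
            for j in range(n_ex):
                exons.append((pos, pos + int(ex_lens[j])))
                pos += int(ex_lens[j])
                if j < n_ex - 1:
                    pos += int(in_lens[j])
            first_ex = exons[0]
            last_ex = exons[-1]
            u5 = max(40, int(0.5 * (first_ex[1] - first_ex[0])))
            u3 = max(40, int(0.5 * (last_ex[1] - last_ex[0])))
            if strand == "+":
                five = [(first_ex[0], first_ex[0] + u5)]
                three = [(last_ex[1] - u3, last_ex[1])]
            else:
                five = [(last_ex[1] - u5, last_ex[1])]
                three = [(first_ex[0], first_ex[0] + u3)]
            genes.append(GeneModel(f"gene{i + 1}", chrom, strand, start, end,
                                   exons=exons, five_utrs=five,
                                   three_utrs=three))
            cursor = end
    return genes


# ---------------------------------------------------------------------------
# motifs


def make_informative_motif(width: int, seed, dominance: float = 0.9) -> np.ndarray:
    """High-information PWM: one dominant base per position."""
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    mat = np.empty((width, 4))
    for i in range(width):
        d = float(np.clip(dominance + rng.normal(0, 0.02), 0.7, 0.98))
        row = np.full(4, (1 - d) / 3)
        row[rng.integers(4)] = d
        mat[i] = row
    return mat


def perturb_motif(matrix: np.ndarray, seed, eps: float = 0.12) -> np.ndarray:
    """Mix each row with a Dirichlet draw; small eps = near-copy."""
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    noise = rng.dirichlet(np.ones(4), size=matrix.shape[0])
    out = (1 - eps) * matrix + eps * noise
    return out / out.sum(axis=1, keepdims=True)


def make_motif_family(width: int, n_copies: int, seed,
                      dominance: float = 0.9, eps: float = 0.12):
    """A base informative motif plus perturbed copies."""
    rng = np.random.default_rng((seed, 0xFA41))
    base = make_informative_motif(width, rng, dominance)
    copies = [perturb_motif(base, rng, eps) for _ in range(n_copies)]
    return base, copies


def _sample_site(matrix: np.ndarray, rng) -> str:
    cum = np.cumsum(matrix, axis=1)
    u = rng.random(matrix.shape[0])
    codes = (u[:, None] > cum).sum(axis=1)
    return "".join(seqs.BASES[c] for c in codes)


# ---------------------------------------------------------------------------
# planted datasets


def plant_datasets(genome: GenomeResult, annotation, truth_spec: dict,
                   n_regions: int, region_len: int, mask_fraction: float,
                   seed=0, region_pool=None,
                   config: PipelineConfig | None = None):
    """Generate DHS-like datasets with planted motif-module sites.

    ``truth_spec``::

        {"motifs": {motif_id: PWM, ...},
         "datasets": [{"id": ..., "type_label": ...,
                       "modules": [((motif ids...), probability), ...]},
                      ...]}

    For each region selected for a module, one site per member motif is
    sampled from its PWM and placed at a non-overlapping offset on a random
    strand.  ``mask_fraction`` of background base pairs (never site bases)
    are set to 'N' in geometric stretches.  Returns (datasets, truth).
    """
    cfg = config or PipelineConfig()
    if not (200 <= region_len <= cfg.region_max_len):
        raise ValueError("region_len out of range [200, region_max_len]")
    if not (0.0 <= mask_fraction < 1.0):
        raise ValueError("mask_fraction must be in [0, 1)")
    motifs = {k: np.asarray(v, dtype=float) for k, v in
              truth_spec["motifs"].items()}
    for ds in truth_spec["datasets"]:
        for ids, prob in ds["modules"]:
            if not (0.0 <= prob <= 1.0):
                raise ValueError("planting probability must be in [0, 1]")
            total = sum(motifs[i].shape[0] for i in ids)
            if total > region_len:
                raise ValueError(
                    f"region length {region_len} cannot host module {ids}")
    truth = PlantedTruth(motifs=motifs)
    module_set: set[tuple] = set()
    datasets = []
    if region_pool is None:
        region_pool = [(c, 0, genome.lengths[c]) for c in sorted(genome.lengths)]
    starts_all = []
    for chrom, s, e in region_pool:
        grid = np.arange(s, e - region_len + 1, region_len, dtype=np.int64)
        starts_all.extend((chrom, int(g)) for g in grid)
    if len(starts_all) < n_regions:
        raise ValueError("region pool too small for requested regions")

    for ds_index, ds_spec in enumerate(truth_spec["datasets"]):
        rng = np.random.default_rng((seed, 0xD5, ds_index))
        chosen = sorted(
            (starts_all[i] for i in
             rng.choice(len(starts_all), size=n_regions, replace=False)),
            key=lambda cs: (cs[0], cs[1]))
        regions = []
        sequences = []
        profile_ids: set[str] = set()
        for ridx, (chrom, start) in enumerate(chosen):
            rid = f"{ds_spec['id']}:r{ridx:05d}"
            regions.append(GenomicRegion(chrom, start, start + region_len, rid))
            seq = bytearray(
                genome.sequences[chrom][start:start + region_len].upper(),
                "ascii")
            occupied: list[tuple[int, int]] = []
            for ids, prob in ds_spec["modules"]:
                key = (frozenset(ids), float(prob))
                if key not in module_set:
                    module_set.add(key)
                    truth.modules.append((frozenset(ids), float(prob)))
                profile_ids.update(ids)
                if rng.random() >= prob:
                    continue
                for mid in ids:
                    w = motifs[mid].shape[0]
                    placed = False
                    for _try in range(200):
                        off = int(rng.integers(0, region_len - w + 1))
                        if all(off + w <= s0 or off >= e0
                               for s0, e0 in occupied):
                            placed = True
                            break
                    if not placed:
                        raise ValueError(
                            f"cannot place site of {mid} in region {rid}")
                    occupied.append((off, off + w))
                    site = _sample_site(motifs[mid], rng)
                    strand = "+" if rng.random() < 0.5 else "-"
                    written = site if strand == "+" else seqs.revcomp(site)
                    seq[off:off + w] = written.encode("ascii")
                    truth.site_log.append((rid, mid, off, strand))
                    truth.site_strings.append(site)
            # mask background stretches
            if mask_fraction > 0:
                is_bg = np.ones(region_len, dtype=bool)
                for s0, e0 in occupied:
                    is_bg[s0:e0] = False
                n_bg = int(is_bg.sum())
                target = int(round(mask_fraction * n_bg))
                masked = np.zeros(region_len, dtype=bool)
                n_masked = 0
                guard = 0
                while n_masked < target and guard < 10_000:
                    guard += 1
                    st = int(rng.integers(0, region_len))
                    run = 1 + int(rng.geometric(1 / 30))
                    # trim the stretch so the target is hit exactly
                    for pos in range(st, min(st + run, region_len)):
                        if n_masked >= target:
                            break
                        if is_bg[pos] and not masked[pos]:
                            n_masked += 1
                        masked[pos] = True
                apply = masked & is_bg
                for pos in np.nonzero(apply)[0]:
                    seq[pos] = ord("N")
            sequences.append(seq.decode("ascii"))
        datasets.append(SequenceDataset(ds_spec["id"],
                                        ds_spec.get("type_label", ""),
                                        regions, sequences))
        label = ds_spec.get("type_label", "")
        prev = set(truth.type_profiles.get(label, frozenset()))
        truth.type_profiles[label] = frozenset(prev | profile_ids)
    return datasets, truth


# ---------------------------------------------------------------------------
# typed collections and interactions


def _chunk_modules(profile: list[str], prob: float):
    """Deterministically group a motif profile into modules of size 2-3."""
    modules = []
    i = 0
    sizes = [2, 3]
    s_idx = 0
    while i < len(profile):
        size = sizes[s_idx % 2]
        s_idx += 1
        chunk = profile[i:i + size]
        if len(chunk) == 1:
            # singletons cannot form a module; fold into the previous one
            if modules:
                prev_ids, p = modules[-1]
                modules[-1] = (tuple(prev_ids) + tuple(chunk), p)
            i += 1
            continue
        modules.append((tuple(chunk), prob))
        i += size
    return modules


def make_typed_collection(n_types: int, datasets_per_type: int,
                          shared_motifs: int, specific_motifs_per_type: int,
                          seed=0, n_regions: int = 200, region_len: int = 800,
                          planting_prob: float = 0.15,
                          mask_fraction: float = 0.05,
                          motif_width: int = 8,
                          genome: GenomeResult | None = None):
    """Labeled multi-type dataset collection with type-specific profiles.

    Every dataset of a type plants all shared motifs plus its type's
    specific motifs, grouped into modules of 2-3 motifs.
    """
    if n_types < 2:
        raise ValueError("need at least two types")
    rng = np.random.default_rng((seed, 0x7E9))
    motifs: dict[str, np.ndarray] = {}
    for i in range(shared_motifs):
        motifs[f"shared{i + 1}"] = make_informative_motif(motif_width, rng)
    type_labels = [f"type{t + 1}" for t in range(n_types)]
    profiles = {}
    for t, label in enumerate(type_labels):
        spec = []
        for j in range(specific_motifs_per_type):
            mid = f"{label}_m{j + 1}"
            motifs[mid] = make_informative_motif(motif_width, rng)
            spec.append(mid)
        profiles[label] = [f"shared{i + 1}" for i in range(shared_motifs)] + spec
    if genome is None:
        min_len = max(10_000, 2 * n_regions * region_len)
        genome = make_genome(min_len, seed=(seed, 0x9E0))
    ds_specs = []
    for label in type_labels:
        for d in range(datasets_per_type):
            ds_specs.append({
                "id": f"{label}_d{d + 1}",
                "type_label": label,
                "modules": _chunk_modules(profiles[label], planting_prob),
            })
    datasets, truth = plant_datasets(
        genome, [], {"motifs": motifs, "datasets": ds_specs},
        n_regions, region_len, mask_fraction, seed=(seed, 0x117))
    return datasets, truth


def make_interactions(truth: PlantedTruth, noise_pairs: int = 0, seed=0):
    """Known-interaction stand-in: all within-module motif pairs, plus
    random non-module noise pairs; symmetric and deduplicated."""
    rng = np.random.default_rng((seed, 0x1AC))
    pairs: set[tuple[str, str]] = set()
    for ids, _prob in truth.modules:
        members = sorted(ids)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.add((members[i], members[j]))
    module_pairs = set(pairs)
    all_ids = sorted(truth.motifs)
    candidates = [(a, b) for i, a in enumerate(all_ids)
                  for b in all_ids[i + 1:]
                  if (a, b) not in module_pairs]
    n_noise = min(noise_pairs, len(candidates))
    if n_noise:
        idx = rng.choice(len(candidates), size=n_noise, replace=False)
        pairs.update(candidates[i] for i in idx)
    return sorted(pairs)
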