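"""Genomic region types and binomial TFBS enrichment.

Sixteen primary region types are built from a gene annotation: proximal
TSS and TTS windows (2.5 kb, strand-aware), 5'/3' UTRs, first and other
introns, and 5'/3' distal territories at five cutoffs (a 5' >x distal
position lies more than x bp from the gene's start, on its 5' side, and at
least x bp from every other gene).  "Pure" variants subtract the opposing
type.  A motif's enrichment in a type is the exact upper binomial tail of
its site count in the type, with success probability the fraction of DHS
base pairs overlapped by the type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from modmotif.config import PipelineConfig
from modmotif.io import GeneModel, GenomicRegion, InputError

IntervalSet = dict  # chrom -> (n, 2) int array, merged and sorted


# ---------------------------------------------------------------------------
# interval arithmetic (sorted, merged, half-open)


def merge_intervals(intervals) -> np.ndarray:
    ivs = [(int(s), int(e)) for s, e in intervals if e > s]
    if not ivs:
        return np.empty((0, 2), dtype=np.int64)
    ivs.sort()
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def subtract_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a \\ b for merged arrays."""
    if a.size == 0 or b.size == 0:
        return a.copy()
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        jj = j
        while jj < len(b) and b[jj][0] < e:
            bs, be = b[jj]
            if bs > cur:
                out.append((cur, min(bs, e)))
            cur = max(cur, be)
            if cur >= e:
                break
            jj += 1
        if cur < e:
            out.append((cur, e))
    return merge_intervals(out)


def intersect_bp(a: np.ndarray, b: np.ndarray) -> int:
    """Total overlapping base pairs between two merged arrays."""
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return int(total)


def total_bp(ivset: IntervalSet) -> int:
    return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in ivset.values()))


def points_in_set(chroms, positions, ivset: IntervalSet) -> np.ndarray:
    """Boolean membership of (chrom, position) points in an interval set."""
    out = np.zeros(len(positions), dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for idx, c in enumerate(chroms):
        by_chrom.setdefault(c, []).append(idx)
    for c, idxs in by_chrom.items():
        arr = ivset.get(c)
        if arr is None or arr.size == 0:
            continue
        flat = arr.ravel()
        pos = np.asarray([positions[i] for i in idxs])
        inside = (np.searchsorted(flat, pos, side="right") % 2) == 1
        out[np.asarray(idxs)] = inside
    return out


# ---------------------------------------------------------------------------
# region types


def _clamped(s: int, e: int, clen: int):
    return max(0, s), min(e, clen)


def build_region_types(genes: list[GeneModel],
                       chrom_lengths: dict[str, int],
                       config: PipelineConfig,
                       include_pure: bool = True) -> dict[str, IntervalSet]:
    """The 16 primary region types (and pure variants) as interval sets."""
    w = config.proximal_window
    raw: dict[str, dict[str, list]] = {}

    def add(name, chrom, s, e):
        clen = chrom_lengths[chrom]
        s, e = _clamped(s, e, clen)
        if e > s:
            raw.setdefault(name, {}).setdefault(chrom, []).append((s, e))

    padded: dict[str, list] = {}
    for g in genes:
        if g.chrom not in chrom_lengths:
            raise InputError(f"gene {g.id} on unknown chromosome {g.chrom!r}")
        if g.strand == "+":
            add("proximal_tss", g.chrom, g.start - w, g.start)
            add("proximal_tts", g.chrom, g.end, g.end + w)
        else:
            add("proximal_tss", g.chrom, g.end, g.end + w)
            add("proximal_tts", g.chrom, g.start - w, g.start)
        for s, e in g.five_utrs:
            add("five_utr", g.chrom, s, e)
        for s, e in g.three_utrs:
            add("three_utr", g.chrom, s, e)
        first = g.first_intron()
        for iv in g.introns():
            name = "first_intron" if iv == first else "other_intron"
            add(name, g.chrom, *iv)
    for x in config.distal_cutoffs:
        for g in genes:
            clen = chrom_lengths[g.chrom]
            if g.strand == "+":
                add(f"distal5_{x}", g.chrom, 0, g.start - x)
                add(f"distal3_{x}", g.chrom, g.end + x, clen)
            else:
                add(f"distal5_{x}", g.chrom, g.end + x, clen)
                add(f"distal3_{x}", g.chrom, 0, g.start - x)
    out: dict[str, IntervalSet] = {}
    base_names = ["proximal_tss", "proximal_tts", "five_utr", "three_utr",
                  "first_intron", "other_intron"]
    base_names += [f"distal5_{x}" for x in config.distal_cutoffs]
    base_names += [f"distal3_{x}" for x in config.distal_cutoffs]
    for name in base_names:
        ivs = raw.get(name, {})
        out[name] = {c: merge_intervals(v) for c, v in ivs.items()}
    # distal territories must keep distance x from every *other* gene; a
    # gene's own padded span never overlaps its candidate interval, so
    # subtracting all padded spans is equivalent
    for x in config.distal_cutoffs:
        pads: dict[str, list] = {}
        for g in genes:
            pads.setdefault(g.chrom, []).append((g.start - x, g.end + x))
        padset = {c: merge_intervals(v) for c, v in pads.items()}
        for side in ("distal5", "distal3"):
            name = f"{side}_{x}"
            out[name] = {c: subtract_intervals(arr, padset.get(
                c, np.empty((0, 2), dtype=np.int64)))
                for c, arr in out[name].items()}
    if include_pure:
        out["pure_proximal_tss"] = _setminus(out["proximal_tss"],
                                             out["proximal_tts"])
        out["pure_proximal_tts"] = _setminus(out["proximal_tts"],
                                             out["proximal_tss"])
        for x in config.distal_cutoffs:
            out[f"pure_distal5_{x}"] = _setminus(out[f"distal5_{x}"],
                                                 out[f"distal3_{x}"])
            out[f"pure_distal3_{x}"] = _setminus(out[f"distal3_{x}"],
                                                 out[f"distal5_{x}"])
    return out


def _setminus(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    out = {}
    for c, arr in a.items():
        res = subtract_intervals(arr, b.get(c, np.empty((0, 2),
                                                        dtype=np.int64)))
        if res.size:
            out[c] = res
    return out


# ---------------------------------------------------------------------------
# enrichment tests


@dataclass
class EnrichmentResult:
    motif_id: str
    region_type: str
    n_sites: int
    k_in: int
    p_bg: float
    pvalue: float
    corrected_pvalue: float
    enriched: bool
    degenerate: bool = False


def background_fraction(region_type: IntervalSet,
                        dhs_regions: list[GenomicRegion]) -> float:
    """Fraction of DHS base pairs overlapped by the region type."""
    by_chrom: dict[str, list] = {}
    for r in dhs_regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    dhs = {c: merge_intervals(v) for c, v in by_chrom.items()}
    total = total_bp(dhs)
    if total == 0:
        raise InputError("DHS regions cover zero base pairs")
    overlap = sum(intersect_bp(arr, region_type.get(
        c, np.empty((0, 2), dtype=np.int64))) for c, arr in dhs.items())
    return overlap / total


def test_enrichment(sites, region_type: IntervalSet, p_bg: float,
                    n_tests: int, config: PipelineConfig,
                    motif_id: str = "", type_name: str = "") -> EnrichmentResult:
    """Exact binomial upper-tail enrichment of sites in a region type.

    ``sites``: (chrom, start, end) genomic intervals; a site counts as
    inside when its midpoint lies in the type.
    """
    n_sites = len(sites)
    if n_sites < 1:
        raise InputError("need at least one site")
    chroms = [s[0] for s in sites]
    mids = [(s[1] + s[2]) // 2 for s in sites]
    k_in = int(points_in_set(chroms, mids, region_type).sum())
    degenerate = False
    if p_bg <= 0.0:
        pvalue = 0.0 if k_in > 0 else 1.0
        degenerate = k_in > 0
    elif k_in == 0:
        pvalue = 1.0
    else:
        pvalue = float(sps.binom.sf(k_in - 1, n_sites, min(p_bg, 1.0)))
    corrected = min(1.0, pvalue * n_tests)
    return EnrichmentResult(motif_id, type_name, n_sites, k_in, float(p_bg),
                            pvalue, corrected,
                            enriched=corrected < config.enrich_alpha,
                            degenerate=degenerate)


def enrichment_profile(motif_sites: dict[str, list],
                       region_map: dict[str, IntervalSet],
                       dhs_regions: list[GenomicRegion],
                       config: PipelineConfig) -> pd.DataFrame:
    """All motif x region-type enrichment tests for one dataset.

    Bonferroni denominator: (#motifs x #types).  Returns a tidy frame with
    one row per test.
    """
    n_tests = len(motif_sites) * len(region_map)
    p_bgs = {name: background_fraction(ivset, dhs_regions)
             for name, ivset in region_map.items()}
    rows = []
    for motif_id in sorted(motif_sites):
        sites = motif_sites[motif_id]
        for name in region_map:
            res = test_enrichment(sites, region_map[name], p_bgs[name],
                                  n_tests, config, motif_id, name)
            rows.append(res.__dict__)
    return pd.DataFrame(rows)


def region_types_to_bed(region_map: dict[str, IntervalSet], out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, ivset in region_map.items():
        with open(out / f"{name}.bed", "w") as fh:
            for chrom in sorted(ivset):
                for s, e in ivset[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t+\n")
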