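"""PWM construction and data-driven motif length adjustment.

Discovered patterns are fixed-width words; real binding sites often extend
beyond them.  Each motif's PWM is built from its aligned exact-match sites
(with an additive pseudocount), then flanking columns are appended while
the nucleotides adjacent to all sites carry enough information
(``ic_min`` bits), and weak terminal columns are trimmed, within hard
width bounds.  Site coordinates are kept consistent throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from modmotif import seqs
from modmotif.config import PipelineConfig
from modmotif.discovery import MotifModule
from modmotif.io import InputError


@dataclass
class Motif:
    """A PWM with its supporting sites.

    ``sites`` are (region_index, offset, strand) with offsets on the
    forward strand of the region sequence; minus-strand sites are
    reverse-complemented before counting.
    """

    id: str
    matrix: np.ndarray
    sites: list[tuple[int, int, str]] = field(default_factory=list)
    source_dataset: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"motif {self.id}: matrix must be width x 4")
        rowsums = self.matrix.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError(f"motif {self.id}: rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(seqs.BASES[i] for i in self.matrix.argmax(axis=1))


def _site_string(sequences, region: int, offset: int, strand: str,
                 width: int) -> str | None:
    seq = sequences[region]
    if offset < 0 or offset + width > len(seq):
        return None
    s = seq[offset:offset + width]
    return s if strand == "+" else seqs.revcomp(s)


def build_pwm(sites, sequences, width: int, pseudocount: float = 0.25,
              motif_id: str = "", source_dataset: str = "") -> Motif:
    """Column-frequency PWM from aligned sites with additive pseudocount."""
    if not sites:
        raise InputError("cannot build a PWM from zero sites")
    counts = np.zeros((width, 4), dtype=float)
    for region, offset, strand in sites:
        s = _site_string(sequences, region, offset, strand, width)
        if s is None:
            raise InputError(
                f"site ({region}, {offset}, {strand}) off sequence end")
        codes = seqs.encode(s)
        if np.any(codes == 255):
            raise InputError(f"site ({region}, {offset}, {strand}) contains N")
        counts[np.arange(width), codes] += 1
    counts += pseudocount
    matrix = counts / counts.sum(axis=1, keepdims=True)
    return Motif(motif_id, matrix, list(sites), source_dataset)


def column_information(column) -> float:
    """Information content in bits: 2 + sum p log2 p (0 log 0 := 0)."""
    col = np.asarray(column, dtype=float)
    nz = col[col > 0]
    return float(2.0 + np.sum(nz * np.log2(nz)))


def _flank_column(motif: Motif, sequences, side: str,
                  pseudocount: float) -> np.ndarray | None:
    """Distribution of the base adjacent to all sites on one motif side.

    Returns None when any site lacks the flanking base (that side frozen).
    """
    counts = np.zeros(4, dtype=float)
    for region, offset, strand in motif.sites:
        # the motif-orientation left flank of a minus-strand site lies at
        # the right end of its forward-strand interval
        if (side == "left") == (strand == "+"):
            pos = offset - 1
        else:
            pos = offset + motif.width
        seq = sequences[region]
        if pos < 0 or pos >= len(seq):
            return None
        base = seq[pos] if strand == "+" else seqs.revcomp(seq[pos])
        code = seqs.encode(base)[0]
        if code == 255:
            return None
        counts[code] += 1
    counts += pseudocount
    return counts / counts.sum()


def _grow_sites(sites, side: str):
    """Site list after appending one column on the given motif side.

    The forward-strand interval grows leftward exactly when the motif-side
    and the site strand agree (motif-left of a plus site, motif-right of a
    minus site)."""
    out = []
    for region, offset, strand in sites:
        if (side == "left") == (strand == "+"):
            out.append((region, offset - 1, strand))
        else:
            out.append((region, offset, strand))
    return out


def adjust_length(motif: Motif, sequences, config: PipelineConfig) -> Motif:
    """Extend the motif over informative flanks, then trim weak ends.

    Extension appends the flanking column with the higher information
    content while it reaches ``ic_min`` bits (ties extend right); trimming
    removes terminal columns below ``ic_min``.  Idempotent: a second pass
    leaves the motif unchanged.
    """
    ic_min = config.ic_min
    pc = config.refine_pseudocount
    current = motif
    # --- extension
    while current.width < config.motif_max_width:
        left = _flank_column(current, sequences, "left", pc)
        right = _flank_column(current, sequences, "right", pc)
        ic_left = column_information(left) if left is not None else -1.0
        ic_right = column_information(right) if right is not None else -1.0
        if max(ic_left, ic_right) < ic_min:
            break
        side = "right" if ic_right >= ic_left else "left"
        new_sites = _grow_sites(current.sites, side)
        current = build_pwm(new_sites, sequences, current.width + 1, pc,
                            current.id, current.source_dataset)
    # --- trimming
    while current.width > config.motif_min_width:
        ic_first = column_information(current.matrix[0])
        ic_last = column_information(current.matrix[-1])
        if ic_first < ic_min:
            side = "left"
        elif ic_last < ic_min:
            side = "right"
        else:
            break
        current = _trim_motif(current, sequences, side, pc)
    return current


def _trim_motif(motif: Motif, sequences, side: str, pc: float) -> Motif:
    new_sites = []
    for region, offset, strand in motif.sites:
        motif_left = (side == "left") == (strand == "+")
        if motif_left:
            new_sites.append((region, offset + 1, strand))
        else:
            new_sites.append((region, offset, strand))
    return build_pwm(new_sites, sequences, motif.width - 1, pc,
                     motif.id, motif.source_dataset)


def refine_motifs(state_motifs: list[Motif], sequences,
                  config: PipelineConfig) -> list[Motif]:
    """Adjust every motif's length; order preserved."""
    return [adjust_length(m, sequences, config) for m in state_motifs]


def update_modules(modules: list[MotifModule], motifs_before: list[str],
                   motifs_after: list[Motif], n_regions: int,
                   config: PipelineConfig):
    """Re-express modules over adjusted motifs.

    Adjusted motifs with identical site intervals are merged (first id
    wins); module supports are recomputed from the adjusted site lists and
    modules falling below ``module_min_size`` are dropped.  Returns
    (modules', merged motif list, id remapping).
    """
    remap: dict[str, str] = {}
    merged: list[Motif] = []
    seen_interval_sets: dict[frozenset, str] = {}
    for old_id, motif in zip(motifs_before, motifs_after):
        intervals = frozenset(
            (r, o, o + motif.width) for (r, o, _s) in motif.sites)
        if intervals in seen_interval_sets:
            remap[old_id] = seen_interval_sets[intervals]
        else:
            keep_id = motif.id or old_id
            seen_interval_sets[intervals] = keep_id
            remap[old_id] = keep_id
            merged.append(motif)
    region_sets = {
        m.id: frozenset(r for (r, _o, _s) in m.sites) for m in merged}
    out = []
    seen_members: set[frozenset] = set()
    for mod in modules:
        members = frozenset(remap.get(i, i) for i in mod.motif_ids)
        if len(members) < config.module_min_size or members in seen_members:
            continue
        seen_members.add(members)
        support = len(frozenset.intersection(
            *(region_sets[i] for i in members)))
        out.append(MotifModule(members, support, mod.pvalue,
                               mod.corrected_pvalue))
    return out, merged, remap
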