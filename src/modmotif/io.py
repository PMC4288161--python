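"""Region / sequence / motif / module input-output.

Coordinates are 0-based half-open (BED convention) everywhere in memory;
GTF's 1-based closed intervals are converted at the boundary.  Region
preprocessing follows the protocol for DHS collections: regions shorter
than the target length are extended evenly from both ends to exactly that
length, regions longer than the maximum are discarded, and repeat/exon
masked bases (lowercase or explicit mask intervals) become 'N'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np

from modmotif.config import PipelineConfig


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class ParseError(InputError):
    """Malformed record in a text format; message carries the line number."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GenomicRegion:
    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise InputError(
                f"invalid region {self.id!r}: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class SequenceDataset:
    """One DHS dataset: preprocessed regions plus their masked sequences."""

    id: str
    type_label: str
    regions: list[GenomicRegion]
    sequences: list[str]

    def __post_init__(self):
        if len(self.regions) != len(self.sequences):
            raise InputError("regions and sequences differ in length")
        for r, s in zip(self.regions, self.sequences):
            if len(s) != len(r):
                raise InputError(
                    f"sequence length {len(s)} != region length {len(r)}"
                    f" for {r.id!r}")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def region_ids(self) -> list[str]:
        return [r.id for r in self.regions]


@dataclass
class GeneModel:
    """A gene with strand-aware structure (UTRs, exons, derived introns)."""

    id: str
    chrom: str
    strand: str          # '+' or '-'
    start: int           # genomic span, half-open
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)       # genomic order
    five_utrs: list[tuple[int, int]] = field(default_factory=list)
    three_utrs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise InputError(f"gene {self.id}: bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise InputError(f"gene {self.id}: bad span")

    @property
    def tss(self) -> int:
        """Transcription start coordinate (rightmost base for minus strand)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        ex = sorted(self.exons)
        for (s1, e1), (s2, _) in zip(ex, ex[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    def first_intron(self) -> tuple[int, int] | None:
        """The intron adjacent to the first exon in transcription order."""
        intr = self.introns()
        if not intr:
            return None
        return intr[0] if self.strand == "+" else intr[-1]


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_regions(
    regions: Sequence[GenomicRegion],
    chrom_lengths: Mapping[str, int],
    config: PipelineConfig,
) -> list[GenomicRegion]:
    """Extend short regions evenly to the target length; drop overlong ones.

    An odd extension deficit puts the extra base on the right end.  Clamping
    at a chromosome boundary moves the shortfall to the other side when
    possible, so output regions are exactly ``region_target_len`` long
    whenever the chromosome allows it.  Idempotent on its own output.
    """
    target = config.region_target_len
    out: list[GenomicRegion] = []
    for r in regions:
        if r.chrom not in chrom_lengths:
            raise InputError(f"region {r.id!r} on unknown chromosome {r.chrom!r}")
        clen = chrom_lengths[r.chrom]
        if r.end > clen:
            raise InputError(f"region {r.id!r} exceeds chromosome {r.chrom!r}")
        length = len(r)
        if length > config.region_max_len:
            continue
        if length >= target:
            out.append(r)
            continue
        deficit = target - length
        start = r.start - deficit // 2
        end = r.end + (deficit - deficit // 2)
        if start < 0:
            end = min(clen, end - start)
            start = 0
        if end > clen:
            start = max(0, start - (end - clen))
            end = clen
        out.append(GenomicRegion(r.chrom, start, end, r.id))
    return out


def extract_sequences(
    genome,
    regions: Sequence[GenomicRegion],
    mask_intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    dataset_id: str = "",
    type_label: str = "",
) -> SequenceDataset:
    """Slice region sequences out of a genome, applying masking.

    ``genome`` is a mapping chrom -> sequence string or a ``pyfaidx.Fasta``.
    Soft-masked (lowercase) bases and bases inside ``mask_intervals`` become
    'N'; everything else is uppercased.
    """
    mask_intervals = mask_intervals or {}
    seqs = []
    for r in regions:
        chrom_seq = genome[r.chrom]
        raw = str(chrom_seq[r.start:r.end])
        if len(raw) != len(r):
            raise InputError(f"region {r.id!r} exceeds chromosome {r.chrom!r}")
        arr = np.frombuffer(raw.encode("ascii"), dtype=np.uint8).copy()
        lower = (arr >= ord("a")) & (arr <= ord("z"))
        arr[lower] = ord("N")
        for (ms, me) in mask_intervals.get(r.chrom, ()):
            lo = max(ms, r.start) - r.start
            hi = min(me, r.end) - r.start
            if lo < hi:
                arr[lo:hi] = ord("N")
        seq = arr.tobytes().decode("ascii").upper()
        seqs.append(seq)
    return SequenceDataset(dataset_id, type_label, list(regions), seqs)


# ---------------------------------------------------------------------------
# BED


def read_regions_bed(path: Union[str, Path]) -> list[GenomicRegion]:
    regions = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: expected >=3 BED columns")
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad coordinates") from exc
        name = fields[3] if len(fields) > 3 else f"region{lineno}"
        regions.append(GenomicRegion(chrom, start, end, name))
    return regions


def write_regions_bed(regions: Sequence[GenomicRegion], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\t0\t+\n")


def write_sites_bed(sites, path: Union[str, Path]) -> None:
    """Sites: iterable of (chrom, start, end, motif_id, score, strand)."""
    with open(path, "w") as fh:
        for chrom, start, end, motif_id, score, strand in sites:
            fh.write(f"{chrom}\t{start}\t{end}\t{motif_id}\t{score:g}\t{strand}\n")


def read_sites_bed(path: Union[str, Path]) -> list[tuple]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise ParseError(f"line {lineno}: expected 6 BED columns")
        try:
            out.append((f[0], int(f[1]), int(f[2]), f[3], float(f[4]), f[5]))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad site record") from exc
    return out


# ---------------------------------------------------------------------------
# MEME minimal motif format


def write_meme(motifs, path: Union[str, Path], background=None) -> None:
    """Write PWMs in MEME minimal format.

    ``motifs``: iterable of objects with ``id`` and ``matrix`` (w x 4,
    row-stochastic) attributes, or (id, matrix) pairs.
    """
    bg = background if background is not None else [0.25] * 4
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", "",
             "Background letter frequencies",
             "A {:.5f} C {:.5f} G {:.5f} T {:.5f}".format(*bg), ""]
    for m in motifs:
        mid, mat = (m.id, m.matrix) if hasattr(m, "matrix") else m
        mat = np.asarray(mat, dtype=float)
        lines.append(f"MOTIF {mid}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {mat.shape[0]} "
            f"nsites= 20 E= 0")
        for row in mat:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_meme(path: Union[str, Path]) -> list[tuple[str, np.ndarray]]:
    """Read MEME minimal motifs as (id, matrix) pairs."""
    out: list[tuple[str, np.ndarray]] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"line {i + 1}: MOTIF record without an id")
            mid = parts[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                    "letter-probability matrix"):
                if lines[i].strip().startswith("MOTIF"):
                    raise ParseError(f"line {i + 1}: motif {mid!r} has no matrix")
                i += 1
            if i >= len(lines):
                raise ParseError(f"line {i}: motif {mid!r} has no matrix")
            header = lines[i].strip()
            width = None
            toks = header.replace("=", " = ").split()
            for j, tok in enumerate(toks):
                if tok == "w" and j + 2 < len(toks):
                    width = int(toks[j + 2])
            if width is None:
                raise ParseError(f"line {i + 1}: matrix header lacks width")
            rows = []
            for j in range(width):
                i += 1
                try:
                    row = [float(v) for v in lines[i].split()]
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"line {i + 1}: bad matrix row") from exc
                if len(row) != 4:
                    raise ParseError(f"line {i + 1}: expected 4 columns")
                rows.append(row)
            out.append((mid, np.array(rows, dtype=float)))
        i += 1
    return out


# ---------------------------------------------------------------------------
# modules TSV


def write_modules_tsv(modules, path: Union[str, Path]) -> None:
    """TSV: module id, comma-separated motif ids, support, p-values."""
    with open(path, "w") as fh:
        fh.write("module_id\tmotif_ids\tsupport\tpvalue\tcorrected_pvalue\n")
        for i, mod in enumerate(modules):
            ids = ",".join(sorted(mod.motif_ids))
            fh.write(f"module{i + 1}\t{ids}\t{mod.support}\t"
                     f"{mod.pvalue:.6g}\t{mod.corrected_pvalue:.6g}\n")


def read_modules_tsv(path: Union[str, Path]) -> list[dict]:
    out = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) != 5:
            raise ParseError(f"line {lineno}: expected 5 columns")
        try:
            out.append({
                "module_id": f[0],
                "motif_ids": frozenset(f[1].split(",")),
                "support": int(f[2]),
                "pvalue": float(f[3]),
                "corrected_pvalue": float(f[4]),
            })
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad module record") from exc
    return out


# ---------------------------------------------------------------------------
# FASTA / GTF


def write_fasta(seqs: Mapping[str, str], path: Union[str, Path], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Plain FASTA into a dict (small genomes; use pyfaidx for large ones)."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        elif name is not None:
            chunks.append(line.strip())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def open_fasta(path: Union[str, Path]):
    """Random-access FASTA handle (pyfaidx), usable with extract_sequences."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=False)


_GTF_FEATURES = {"five_prime_utr": "five_utrs", "three_prime_utr": "three_utrs"}


def write_gtf(genes: Sequence[GeneModel], path: Union[str, Path]) -> None:
    """1-based closed GTF with gene / exon / UTR features."""
    with open(path, "w") as fh:
        for g in genes:
            attr = f'gene_id "{g.id}";'

            def row(feature, s, e):
                fh.write(f"{g.chrom}\tmodmotif\t{feature}\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\t{attr}\n")

            row("gene", g.start, g.end)
            for s, e in g.exons:
                row("exon", s, e)
            for s, e in g.five_utrs:
                row("five_prime_utr", s, e)
            for s, e in g.three_utrs:
                row("three_prime_utr", s, e)


def read_gtf(path: Union[str, Path]) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise ParseError(f"line {lineno}: expected 9 GTF columns")
        chrom, _, feature, start, end, _, strand, _, attrs = f
        try:
            s, e = int(start) - 1, int(end)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad coordinates") from exc
        gid = None
        for token in attrs.split(";"):
            token = token.strip()
            if token.startswith("gene_id"):
                gid = token.split(None, 1)[1].strip('" ')
        if gid is None:
            raise ParseError(f"line {lineno}: missing gene_id attribute")
        if feature == "gene":
            genes[gid] = GeneModel(gid, chrom, strand, s, e)
            order.append(gid)
        else:
            if gid not in genes:
                genes[gid] = GeneModel(gid, chrom, strand, s, e)
                order.append(gid)
            g = genes[gid]
            if feature == "exon":
                g.exons.append((s, e))
            elif feature in _GTF_FEATURES:
                getattr(g, _GTF_FEATURES[feature]).append((s, e))
    for g in genes.values():
        g.exons.sort()
        g.five_utrs.sort()
        g.three_utrs.sort()
    return [genes[gid] for gid in order]
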