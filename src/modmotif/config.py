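"""Pipeline configuration: one home for every tunable constant.

The defaults encode the published analysis protocol: 800 bp target region
length, 5000 bp discard cutoff, top-2000 8-mer candidates per round, a cap
of 2000 motifs per dataset, the two-threshold motif-similarity rule, the
non-redundant clustering thresholds, 0.01 Bonferroni-corrected significance
for modules and region enrichment, 2.5 kb proximal windows and the five
distal cutoffs, and the classification protocol (types with <= 7 datasets
excluded, 10-fold cross validation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union


class ConfigError(ValueError):
    """Raised for malformed configuration files or invariant violations."""


@dataclass
class PipelineConfig:
    # pattern ranking / discovery loop
    kmer_width: int = 8
    top_patterns: int = 2000
    motif_cap: int = 2000
    stop_rounds_r: int = 3          # consecutive no-new-motif rounds before stopping
    # region preprocessing
    region_target_len: int = 800
    region_max_len: int = 5000
    # motif modules
    module_min_size: int = 2
    module_max_size: int = 6
    module_alpha: float = 0.01      # Bonferroni-corrected significance level
    module_min_support: int = 5     # lattice-search support floor
    # candidate de-overlap (shifted near-duplicate 8-mers share occurrences,
    # which breaks the independence null of the module test)
    candidate_overlap_dedup: bool = True
    candidate_overlap_min: int = 7
    # patterns sharing a word of at least this length (either orientation)
    # are lexically entangled and never tested together as a module
    module_pair_min_overlap: int = 6
    # motif refinement
    refine_pseudocount: float = 0.25
    ic_min: float = 0.5             # bits; flank extension / trimming threshold
    motif_min_width: int = 6
    motif_max_width: int = 16
    # similarity rule (first metric plays the TOMTOM role, second the STAMP role)
    sim_e1_strict: float = 0.5
    sim_e2_strict: float = 1e-4
    sim_e1_loose: float = 1.0
    sim_e2_loose: float = 1e-5
    # non-redundant clustering
    cluster_e_anchor: float = 1e-8
    cluster_e_member: float = 1e-5
    cluster_small_size: int = 4     # "all members" rule applies when |A| < this
    cluster_frac: float = 0.90
    # similarity-null calibration
    null_samples: int = 5000
    column_null_samples: int = 100_000
    # genomic-region enrichment
    enrich_alpha: float = 0.01
    distal_cutoffs: tuple[int, ...] = (2500, 5000, 10000, 20000, 100000)
    proximal_window: int = 2500
    # classification
    min_class_size: int = 8         # types with fewer datasets are excluded
    cv_folds: int = 10
    # randomness
    random_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive_ints = [
            "kmer_width", "top_patterns", "motif_cap", "stop_rounds_r",
            "region_target_len", "region_max_len", "module_max_size",
            "module_min_support", "candidate_overlap_min",
            "module_pair_min_overlap", "motif_min_width",
            "motif_max_width", "cluster_small_size", "null_samples",
            "column_null_samples", "proximal_window", "min_class_size",
            "cv_folds",
        ]
        for name in positive_ints:
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.module_min_size < 2:
            raise ConfigError("module_min_size must be >= 2")
        if self.module_max_size < self.module_min_size:
            raise ConfigError("module_max_size must be >= module_min_size")
        for name in ("sim_e1_strict", "sim_e2_strict", "sim_e1_loose",
                     "sim_e2_loose", "cluster_e_anchor", "cluster_e_member"):
            if float(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not (0.0 < self.cluster_frac <= 1.0):
            raise ConfigError("cluster_frac must be in (0, 1]")
        for name in ("module_alpha", "enrich_alpha"):
            if not (0.0 < float(getattr(self, name)) < 1.0):
                raise ConfigError(f"{name} must be in (0, 1)")
        if any(int(c) <= 0 for c in self.distal_cutoffs):
            raise ConfigError("distal_cutoffs must be strictly positive")
        if self.motif_max_width < self.motif_min_width:
            raise ConfigError("motif_max_width must be >= motif_min_width")
        if self.ic_min < 0:
            raise ConfigError("ic_min must be non-negative")
        if self.refine_pseudocount < 0:
            raise ConfigError("refine_pseudocount must be non-negative")


_FIELDS = {f.name: f for f in dataclasses.fields(PipelineConfig)}


def _parse_value(key: str, raw: str):
    f = _FIELDS[key]
    raw = raw.strip()
    if f.type in ("int", int):
        try:
            return int(raw)
        except ValueError as exc:
            raise ConfigError(f"invalid integer for {key}: {raw!r}") from exc
    if f.type in ("float", float):
        try:
            return float(raw)
        except ValueError as exc:
            raise ConfigError(f"invalid number for {key}: {raw!r}") from exc
    if f.type in ("bool", bool):
        low = raw.lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
        raise ConfigError(f"invalid boolean for {key}: {raw!r}")
    # tuple of ints (distal_cutoffs)
    try:
        return tuple(int(tok) for tok in raw.replace(",", " ").split())
    except ValueError as exc:
        raise ConfigError(f"invalid integer list for {key}: {raw!r}") from exc


def load_config(path: Union[str, Path, None] = None, **overrides) -> PipelineConfig:
    """Build a configuration from defaults, an optional flat key=value file,
    and keyword overrides (applied last).

    Unknown keys are rejected; invariant violations raise :class:`ConfigError`
    naming the offending key.
    """
    values: dict = {}
    if path:
        text = Path(path).read_text()
        for lineno, line in enumerate(text.splitlines(), start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if "=" not in stripped:
                raise ConfigError(
                    f"line {lineno}: expected key=value, got {stripped!r}")
            key, _, raw = stripped.partition("=")
            key = key.strip()
            if key not in _FIELDS:
                raise ConfigError(f"line {lineno}: unknown key {key!r}")
            values[key] = _parse_value(key, raw)
    for key, val in overrides.items():
        if key not in _FIELDS:
            raise ConfigError(f"unknown key {key!r}")
        values[key] = val
    return PipelineConfig(**values)


def serialize_config(config: PipelineConfig) -> str:
    """Flat key=value text; ``load_config`` of the result round-trips."""
    lines = []
    for f in dataclasses.fields(PipelineConfig):
        val = getattr(config, f.name)
        if isinstance(val, tuple):
            val = ",".join(str(v) for v in val)
        lines.append(f"{f.name}={val}")
    return "\n".join(lines) + "\n"
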