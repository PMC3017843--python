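"""Run configuration for all pipeline stages.

A run is controlled by one flat YAML document whose keys mirror the
dataclass fields below (nested under ``mining:``, ``genotyping:`` and
``diversity:``).  Command-line flags override file values; the resolved
configuration is echoed to the log so every run is reproducible from its
log alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "MiningConfig",
    "GenotypingConfig",
    "DiversityConfig",
    "RunConfig",
    "load_config",
]

#: minimum whole repeat units required to call an SSR, per motif length.
#: Chosen so the shortest reportable di- to tetranucleotide tract is 12 nt
#: (the class II lower bound) and mononucleotide tracts start at 9 bases.
DEFAULT_MIN_REPEATS = {1: 9, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds for perfect/compound microsatellite detection."""

    min_repeats_by_motif_len: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    max_repeats: int = 100          # repeat count cap used in reporting
    max_interruption_nt: int = 100  # max spacer inside a compound SSR
    class1_min_len_nt: int = 20     # class I: tract >= 20 nt
    class2_min_len_nt: int = 12     # class II: 12 nt <= tract < 20 nt

    def __post_init__(self) -> None:
        if set(self.min_repeats_by_motif_len) != {1, 2, 3, 4, 5, 6}:
            raise ValueError("min_repeats_by_motif_len must cover motif lengths 1..6")
        if any(v < 1 for v in self.min_repeats_by_motif_len.values()):
            raise ValueError("minimum repeat counts must be positive")
        if self.max_repeats < 1 or self.max_interruption_nt < 0:
            raise ValueError("max_repeats must be >= 1 and max_interruption_nt >= 0")
        if not 0 < self.class2_min_len_nt < self.class1_min_len_nt:
            raise ValueError("need 0 < class2_min_len_nt < class1_min_len_nt")


@dataclass(frozen=True)
class GenotypingConfig:
    """Peak-filter and locus-binning thresholds for fragment analysis."""

    min_peak_height: float = 1500.0  # fluorescence units
    min_peak_quality: float = 6.0
    locus_gap_nt: int = 100          # size gap (bp) that separates loci

    def __post_init__(self) -> None:
        if self.min_peak_height <= 0 or self.min_peak_quality <= 0:
            raise ValueError("peak thresholds must be positive")
        if self.locus_gap_nt <= 0:
            raise ValueError("locus_gap_nt must be positive")


@dataclass(frozen=True)
class DiversityConfig:
    """Bootstrap settings for the UPGMA consensus tree."""

    n_bootstrap: int = 1000
    consensus_threshold: float = 0.50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0.5 <= self.consensus_threshold < 1.0:
            raise ValueError("consensus_threshold must lie in [0.5, 1)")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass(frozen=True)
class RunConfig:
    mining: MiningConfig = field(default_factory=MiningConfig)
    genotyping: GenotypingConfig = field(default_factory=GenotypingConfig)
    diversity: DiversityConfig = field(default_factory=DiversityConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def load_config(path: str | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file plus keyword overrides.

    Overrides use dotted keys relative to the section dataclasses, e.g.
    ``load_config("run.yaml", diversity={"n_bootstrap": 200})``.
    """
    doc: dict = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"config file {path!r} must contain a mapping")
    for key, val in overrides.items():
        if isinstance(val, dict):
            doc.setdefault(key, {}).update(val)
        else:
            doc[key] = val

    mining_kw = dict(doc.get("mining", {}))
    if "min_repeats_by_motif_len" in mining_kw:
        mining_kw["min_repeats_by_motif_len"] = {
            int(k): int(v) for k, v in mining_kw["min_repeats_by_motif_len"].items()
        }
    cfg = RunConfig(
        mining=MiningConfig(**mining_kw),
        genotyping=GenotypingConfig(**doc.get("genotyping", {})),
        diversity=DiversityConfig(**doc.get("diversity", {})),
        seed=int(doc.get("seed", 0)),
    )
    # the diversity stage inherits the global seed unless set explicitly
    if "seed" not in doc.get("diversity", {}):
        cfg = replace(cfg, diversity=replace(cfg.diversity, seed=cfg.seed))
    return cfg
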