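"""Fragment-analysis genotype processing.

Raw capillary-electrophoresis peak tables are filtered on peak height
(>= 1500 fluorescence units) and quality (>= 6.0), sizes are rounded to
integer bp, and the amplicons of each primer are binned into loci
wherever allele sizes jump by at least 100 bp (single-linkage on sorted
sizes).  Per locus the module derives allele frequencies, heterozygote
calls (a sample showing >= 2 distinct sizes; dosage is unresolved in
polyploids), a stepwise/mixed allele-size-distribution class, a P/M
polymorphism call per sample group and the polymorphic information
content PIC = 1 - sum(p_j^2).

Allele frequencies treat each distinct allele occurrence per sample as
one observation, the usual convention for polyploid fragment data where
allele dosage is unknown; per-sample presence weighting is available as
an alternative.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import GenotypingConfig

__all__ = [
    "GenotypeMatrix",
    "LocusStats",
    "filter_peaks",
    "bin_loci",
    "assign_loci",
    "build_genotype_matrix",
    "classify_distribution",
    "call_heterozygosity",
    "allele_frequencies",
    "pic",
    "polymorphism_call",
    "locus_stats",
]

STEPWISE = "stepwise"
MIXED = "mixed"
UNDETERMINED = "undetermined"


def filter_peaks(peaks: pd.DataFrame, cfg: GenotypingConfig | None = None) -> pd.DataFrame:
    """Retain exactly the peaks meeting both thresholds; round sizes to
    integer bp.  Idempotent."""
    cfg = cfg or GenotypingConfig()
    kept = peaks[
        (peaks["height"] >= cfg.min_peak_height)
        & (peaks["quality"] >= cfg.min_peak_quality)
    ].copy()
    kept["size_bp"] = kept["size_bp"].round().astype(int)
    return kept.reset_index(drop=True)


def bin_loci(sizes: Iterable[int], cfg: GenotypingConfig | None = None) -> dict[int, str]:
    """Assign each distinct allele size to a locus label.

    Sizes are sorted and a new locus starts at every gap >= the locus
    cutoff (100 bp); loci are labelled a, b, c, ... by ascending size.
    Depends only on the multiset of sizes.
    """
    cfg = cfg or GenotypingConfig()
    distinct = sorted(set(int(s) for s in sizes))
    labels: dict[int, str] = {}
    locus = 0
    for i, s in enumerate(distinct):
        if i > 0 and s - distinct[i - 1] >= cfg.locus_gap_nt:
            locus += 1
        labels[s] = string.ascii_lowercase[locus]
    return labels


def assign_loci(peaks: pd.DataFrame, cfg: GenotypingConfig | None = None) -> pd.DataFrame:
    """Add a ``locus`` column to a filtered peak table, binning per primer."""
    cfg = cfg or GenotypingConfig()
    out = peaks.copy()
    out["locus"] = ""
    for primer, grp in peaks.groupby("primer_id"):
        labels = bin_loci(grp["size_bp"], cfg)
        out.loc[grp.index, "locus"] = grp["size_bp"].map(labels)
    return out


@dataclass(frozen=True)
class GenotypeMatrix:
    """Per-(locus, sample) allele-size sets.

    ``entries[(primer_id, locus_label)][sample_id]`` is the frozenset of
    integer allele sizes observed for that sample; samples with no
    retained peak at a locus are simply absent (missing data).
    """

    entries: Mapping[tuple[str, str], Mapping[str, frozenset[int]]]
    motif_len: Mapping[tuple[str, str], int] = field(default_factory=dict)

    @property
    def loci(self) -> list[tuple[str, str]]:
        return sorted(self.entries)

    @property
    def samples(self) -> list[str]:
        return sorted({s for by in self.entries.values() for s in by})

    def alleles(self, locus: tuple[str, str]) -> list[int]:
        return sorted({a for s in self.entries[locus].values() for a in s})


def build_genotype_matrix(
    peaks: pd.DataFrame,
    markers: pd.DataFrame | None = None,
    cfg: GenotypingConfig | None = None,
) -> GenotypeMatrix:
    """Filter, bin and collect peaks into a genotype matrix.

    ``markers`` (primer_id, motif_len) attaches the repeat-unit length
    of each marker to every locus it amplifies.
    """
    cfg = cfg or GenotypingConfig()
    binned = assign_loci(filter_peaks(peaks, cfg), cfg)
    entries: dict[tuple[str, str], dict[str, frozenset[int]]] = {}
    for (primer, locus, sample), grp in binned.groupby(
        ["primer_id", "locus", "sample_id"]
    ):
        entries.setdefault((primer, locus), {})[sample] = frozenset(
            int(s) for s in grp["size_bp"]
        )
    motif_len: dict[tuple[str, str], int] = {}
    if markers is not None:
        per_primer = dict(zip(markers["primer_id"], markers["motif_len"].astype(int)))
        for key in entries:
            if key[0] in per_primer:
                motif_len[key] = per_primer[key[0]]
    return GenotypeMatrix(entries=entries, motif_len=motif_len)


def classify_distribution(allele_sizes: Iterable[int], motif_len: int) -> str:
    """Stepwise iff every pairwise size difference is an exact multiple
    of the repeat-unit length (all sizes congruent mod motif_len);
    otherwise mixed.  A single allele is undetermined."""
    if motif_len < 1:
        raise ValueError("motif_len must be >= 1")
    sizes = sorted(set(int(s) for s in allele_sizes))
    if not sizes:
        raise ValueError("need at least one allele size")
    if len(sizes) == 1:
        return UNDETERMINED
    residues = {s % motif_len for s in sizes}
    return STEPWISE if len(residues) == 1 else MIXED


def call_heterozygosity(
    matrix: GenotypeMatrix,
) -> tuple[dict[tuple[tuple[str, str], str], bool], dict[tuple[str, str], int]]:
    """Per-(locus, sample) heterozygote flags and per-locus counts.

    A sample is heterozygous at a locus iff it shows >= 2 distinct
    allele sizes there.
    """
    flags: dict[tuple[tuple[str, str], str], bool] = {}
    counts: dict[tuple[str, str], int] = {}
    for locus, by_sample in matrix.entries.items():
        n = 0
        for sample, alleles in by_sample.items():
            het = len(alleles) >= 2
            flags[(locus, sample)] = het
            n += het
        counts[locus] = n
    return flags, counts


def allele_frequencies(
    matrix: GenotypeMatrix,
    locus: tuple[str, str],
    weighting: str = "occurrence",
) -> dict[int, float]:
    """Allele frequencies at one locus.

    ``occurrence`` counts each distinct allele per sample once;
    ``presence`` weights each sample's alleles to sum to 1 so every
    genotyped sample contributes equally.  Missing samples are excluded.
    """
    by_sample = matrix.entries[locus]
    weights: dict[int, float] = {}
    for alleles in by_sample.values():
        if not alleles:
            continue
        w = 1.0 if weighting == "occurrence" else 1.0 / len(alleles)
        for a in alleles:
            weights[a] = weights.get(a, 0.0) + w
    total = sum(weights.values())
    if total == 0:
        raise ValueError(f"no alleles observed at locus {locus}")
    return {a: w / total for a, w in sorted(weights.items())}


def pic(allele_freqs: Sequence[float] | Mapping[int, float]) -> float:
    """Polymorphic information content, PIC = 1 - sum(p_j^2).

    Frequencies must be non-negative and sum to 1 (tolerance 1e-9).
    A monomorphic locus gives 0; k equifrequent alleles give 1 - 1/k.
    """
    p = np.asarray(
        list(allele_freqs.values()) if isinstance(allele_freqs, Mapping) else allele_freqs,
        dtype=float,
    )
    if (p < 0).any():
        raise ValueError("allele frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies sum to {p.sum()!r}, not 1")
    return float(1.0 - np.sum(p**2))


def polymorphism_call(
    matrix: GenotypeMatrix, sample_groups: Mapping[str, Sequence[str]]
) -> dict[tuple[str, str], dict[str, str | None]]:
    """P/M call per locus per sample group.

    P iff more than one distinct allele is observed across the group's
    genotyped samples at the locus, else M; ``None`` when no sample of
    the group amplified there.
    """
    for name, members in sample_groups.items():
        if not members:
            raise ValueError(f"sample group {name!r} is empty")
    calls: dict[tuple[str, str], dict[str, str | None]] = {}
    for locus, by_sample in matrix.entries.items():
        per_group: dict[str, str | None] = {}
        for name, members in sample_groups.items():
            observed: set[int] = set()
            genotyped = False
            for s in members:
                if s in by_sample:
                    genotyped = True
                    observed |= by_sample[s]
            per_group[name] = None if not genotyped else ("P" if len(observed) > 1 else "M")
        calls[locus] = per_group
    return calls


@dataclass(frozen=True)
class LocusStats:
    """Summary of one marker locus across the panel."""

    primer_id: str
    locus: str
    n_alleles: int
    size_min: int
    size_max: int
    allele_freqs: tuple[float, ...]
    distribution_class: str
    n_heterozygous_samples: int
    polymorphic: dict[str, str | None]
    pic: float

    def __post_init__(self) -> None:
        if abs(sum(self.allele_freqs) - 1.0) > 1e-9:
            raise ValueError("allele frequencies must sum to 1")
        if self.n_alleles == 1 and self.pic != 0.0:
            raise ValueError("a monomorphic locus must have PIC 0")


def locus_stats(
    matrix: GenotypeMatrix,
    sample_groups: Mapping[str, Sequence[str]] | None = None,
    weighting: str = "occurrence",
) -> list[LocusStats]:
    """Full per-locus statistics table for a genotype matrix."""
    sample_groups = sample_groups or {"all": matrix.samples}
    _, het_counts = call_heterozygosity(matrix)
    calls = polymorphism_call(matrix, sample_groups)
    out = []
    for locus in matrix.loci:
        alleles = matrix.alleles(locus)
        freqs = allele_frequencies(matrix, locus, weighting)
        mlen = matrix.motif_len.get(locus)
        dist = (
            classify_distribution(alleles, mlen) if mlen else UNDETERMINED
        )
        out.append(
            LocusStats(
                primer_id=locus[0],
                locus=locus[1],
                n_alleles=len(alleles),
                size_min=alleles[0],
                size_max=alleles[-1],
                allele_freqs=tuple(freqs[a] for a in alleles),
                distribution_class=dist,
                n_heterozygous_samples=het_counts[locus],
                polymorphic=calls[locus],
                pic=pic(freqs),
            )
        )
    return out


def locus_stats_frame(stats: list[LocusStats]) -> pd.DataFrame:
    """LocusStats as a flat table (one P/M column per sample group)."""
    rows = []
    for s in stats:
        row = {
            "primer_id": s.primer_id,
            "locus": s.locus,
            "n_alleles": s.n_alleles,
            "size_range": f"{s.size_min}-{s.size_max}" if s.n_alleles > 1 else str(s.size_min),
            "distribution_class": s.distribution_class,
            "n_heterozygous_samples": s.n_heterozygous_samples,
            "pic": round(s.pic, 4),
        }
        for g, call in s.polymorphic.items():
            row[f"PM_{g}"] = call if call is not None else "NA"
        rows.append(row)
    return pd.DataFrame(rows)
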