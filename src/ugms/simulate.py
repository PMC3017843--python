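"""Synthetic inputs with known ground truth.

Three generators stand in for data the pipeline would normally receive
from sequencing and capillary electrophoresis:

* :func:`simulate_corpus` - a unigene-like corpus with planted mono- to
  hexanucleotide repeats at known coordinates, per-sequence gene models
  and a truth manifest;
* :func:`simulate_panel` - fragment-analysis peak tables for a panel
  with group structure, stepwise or mixed allele series, configurable
  heterozygosity, missing data and sub-threshold noise peaks;
* :func:`simulate_homolog_table` - cross-taxon repeat-count tables with
  chosen per-taxon divergence rates.

Background sequence is produced by rejection: any candidate sequence
containing an unplanned run that meets the detection minima is redrawn,
so on noise-free specs the manifest is the complete, exact truth.
All generators are deterministic functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .config import MiningConfig
from .genic import GeneModel
from .io import SequenceRecord

__all__ = [
    "PlantedRepeat",
    "CorpusSpec",
    "LocusSpec",
    "PanelSpec",
    "simulate_corpus",
    "simulate_panel",
    "simulate_homolog_table",
    "load_preset",
]

_BASES = np.array(list("ACGT"))


# --------------------------------------------------------------------------
# corpus


@dataclass(frozen=True)
class PlantedRepeat:
    """One repeat tract (optionally with a compound partner) to plant."""

    motif: str
    n_repeats: int
    location: str = "CDS"  # CDS | UTR5 | UTR3
    partner_motif: str | None = None
    partner_repeats: int = 0
    gap: int = 0  # spacer between the tract and its partner, nt

    def block_len(self) -> int:
        n = len(self.motif) * self.n_repeats
        if self.partner_motif is not None:
            n += self.gap + len(self.partner_motif) * self.partner_repeats
        return n


@dataclass(frozen=True)
class CorpusSpec:
    """Shape of the synthetic corpus.

    Defaults mimic a small transcript set: sequences of 0.4-1.5 kb with
    even base composition, one gene model each (5'UTR / CDS / 3'UTR at
    roughly 20/60/20% of the length) and the listed repeats planted
    round-robin across sequences.
    """

    n_sequences: int = 24
    min_len: int = 400
    max_len: int = 1500
    gc: float = 0.5
    planted: tuple[PlantedRepeat, ...] = ()
    seed: int = 0
    mining: MiningConfig = field(default_factory=MiningConfig)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _is_primitive(unit: str) -> bool:
    m = len(unit)
    return not any(
        m % d == 0 and unit == unit[:d] * (m // d) for d in range(1, m)
    )


def _scan_runs(seq: str, cfg: MiningConfig) -> set[tuple[int, int]]:
    """Plain maximal-run scanner used only for rejection sampling.

    Returns 0-based (start, end) whole-unit intervals of every maximal
    tandem run of a primitive 1-6 nt motif meeting the configured
    minimum unit count.  Written independently of the mining module on
    purpose: the generator must not certify its output with the code it
    exists to test.
    """
    n = len(seq)
    hits: set[tuple[int, int]] = set()
    for m in range(1, 7):
        min_rep = cfg.min_repeats_by_motif_len[m]
        i = 0
        while i + m <= n:
            unit = seq[i : i + m]
            if "N" in unit or not _is_primitive(unit):
                i += 1
                continue
            j = i + m
            while j + m <= n and seq[j : j + m] == unit:
                j += m
            reps = (j - i) // m
            if reps >= min_rep:
                hits.add((i, i + reps * m - 1))
                i = j
            else:
                i += 1
    return hits


def _background(rng: np.random.Generator, n: int, gc: float, cfg: MiningConfig) -> str:
    """Repeat-free background: redraw until no run meets the minima."""
    if n <= 0:
        return ""
    for _ in range(500):
        s = _random_dna(rng, n, gc)
        if not _scan_runs(s, cfg):
            return s
    raise RuntimeError("could not draw repeat-free background; loosen the spec")


def _length_class(span: int, cfg: MiningConfig) -> str:
    if span >= cfg.class1_min_len_nt:
        return "class_I"
    if span >= cfg.class2_min_len_nt:
        return "class_II"
    return "below_class_II"


MANIFEST_COLUMNS = [
    "seq_id",
    "start",
    "end",
    "motif",
    "n_repeats",
    "total_len_nt",
    "length_class",
    "location",
    "compound_id",
    "gap",
]


def _plant_rows(
    sid: str, p: PlantedRepeat, start1: int, cfg: MiningConfig, compound_serial: int
) -> list[dict]:
    """Manifest rows for one plant: one row, or two rows sharing a
    compound id when the plant has a partner tract."""
    span1 = len(p.motif) * p.n_repeats
    cid = f"{sid}.c{compound_serial}" if p.partner_motif else ""
    rows = [
        {
            "seq_id": sid,
            "start": start1,
            "end": start1 + span1 - 1,
            "motif": p.motif,
            "n_repeats": p.n_repeats,
            "total_len_nt": span1,
            "length_class": _length_class(span1, cfg),
            "location": p.location,
            "compound_id": cid,
            "gap": p.gap if p.partner_motif else 0,
        }
    ]
    if p.partner_motif is not None:
        span2 = len(p.partner_motif) * p.partner_repeats
        s2 = start1 + span1 + p.gap
        rows.append(
            {
                "seq_id": sid,
                "start": s2,
                "end": s2 + span2 - 1,
                "motif": p.partner_motif,
                "n_repeats": p.partner_repeats,
                "total_len_nt": span2,
                "length_class": _length_class(span2, cfg),
                "location": p.location,
                "compound_id": cid,
                "gap": p.gap,
            }
        )
    return rows


def simulate_corpus(
    spec: CorpusSpec,
) -> tuple[list[SequenceRecord], dict[str, GeneModel], pd.DataFrame]:
    """Generate (sequences, gene models, truth manifest).

    The manifest has one row per planted tract with exact 1-based
    coordinates, motif, repeat count, expected length class and genic
    location; partnered tracts share a compound id.  A spec whose
    planted blocks cannot fit their target region raises ``ValueError``.
    """
    rng = np.random.default_rng(spec.seed)
    cfg = spec.mining
    plants_by_seq: dict[int, list[PlantedRepeat]] = {}
    for k, plant in enumerate(spec.planted):
        plants_by_seq.setdefault(k % spec.n_sequences, []).append(plant)

    sequences: list[SequenceRecord] = []
    models: dict[str, GeneModel] = {}
    manifest_rows: list[dict] = []
    compound_serial = 0
    for i in range(spec.n_sequences):
        sid = f"UG{i + 1:05d}"
        plants = plants_by_seq.get(i, [])
        total_planted = sum(p.block_len() for p in plants)
        length = int(rng.integers(spec.min_len, spec.max_len + 1))
        # gene model: UTR5 ~20%, CDS ~60% (multiple of 3), UTR3 the rest
        utr5 = max(30, int(round(length * 0.2)))
        cds = max(30, int(round(length * 0.6)))
        cds -= cds % 3
        utr3 = max(30, length - utr5 - cds)
        regions = {"UTR5": utr5, "CDS": cds, "UTR3": utr3}
        region_start = {"UTR5": 1, "CDS": utr5 + 1, "UTR3": utr5 + cds + 1}
        for reg in regions:
            need = sum(p.block_len() for p in plants if p.location == reg)
            n_blocks = sum(1 for p in plants if p.location == reg)
            if need and regions[reg] < need + 10 * (n_blocks + 1):
                raise ValueError(
                    f"planted repeats do not fit the {reg} of {sid}; "
                    f"increase min_len ({need} nt needed in {regions[reg]} nt)"
                )

        for _attempt in range(50):
            region_seq: dict[str, str] = {}
            attempt_rows: list[dict] = []
            serial = compound_serial
            for reg in ("UTR5", "CDS", "UTR3"):
                reg_plants = [p for p in plants if p.location == reg]
                reg_len = regions[reg]
                blocks = []
                for p in reg_plants:
                    block = p.motif * p.n_repeats
                    if p.partner_motif is not None:
                        block += _background(rng, p.gap, spec.gc, cfg)
                        block += p.partner_motif * p.partner_repeats
                    blocks.append((p, block))
                spare = reg_len - sum(len(b) for _, b in blocks)
                k = len(blocks)
                # background piece lengths: >= 10 nt each so tracts never abut
                extra = spare - 10 * (k + 1)
                parts = (
                    rng.multinomial(extra, [1.0 / (k + 1)] * (k + 1)) + 10
                    if k
                    else np.array([spare])
                )
                pieces = []
                offset = 0
                for (p, block), bg_len in zip(blocks, parts[:-1]):
                    pieces.append(_background(rng, int(bg_len), spec.gc, cfg))
                    offset += int(bg_len)
                    start1 = region_start[reg] + offset
                    attempt_rows.extend(_plant_rows(sid, p, start1, cfg, serial))
                    if p.partner_motif is not None:
                        serial += 1
                    pieces.append(block)
                    offset += len(block)
                pieces.append(_background(rng, int(parts[-1]), spec.gc, cfg))
                region_seq[reg] = "".join(pieces)
            full = region_seq["UTR5"] + region_seq["CDS"] + region_seq["UTR3"]
            planted_iv = {(r["start"] - 1, r["end"] - 1) for r in attempt_rows}
            if _scan_runs(full, cfg) == planted_iv:
                compound_serial = serial
                break
        else:
            raise RuntimeError(f"could not assemble {sid} without stray runs")

        sequences.append(SequenceRecord(id=sid, sequence=full))
        models[sid] = GeneModel(seq_id=sid, cds_start=utr5 + 1, cds_end=utr5 + cds)
        manifest_rows.extend(attempt_rows)

    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    return sequences, models, manifest


# --------------------------------------------------------------------------
# fragment-analysis panel


@dataclass(frozen=True)
class LocusSpec:
    """One marker locus of the simulated panel.

    ``mode='stepwise'`` draws every allele as ``base_size + k*motif_len``;
    ``mode='mixed'`` additionally shifts one allele by ``indel_offset``
    (a flanking insertion/deletion whose size is not a multiple of the
    repeat unit).  A ``diagnostic`` locus gives each sample group a
    disjoint allele subset, so groups separate in the diversity stage.
    """

    primer_id: str
    motif_len: int
    base_size: int
    n_alleles: int = 4
    mode: str = "stepwise"  # stepwise | mixed
    indel_offset: int = 1
    diagnostic: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("stepwise", "mixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "mixed" and self.indel_offset % self.motif_len == 0:
            raise ValueError("a mixed locus needs an offset not divisible by motif_len")
        if self.n_alleles < 1 or self.motif_len < 1 or self.base_size <= 0:
            raise ValueError("invalid locus spec")
        if self.mode == "mixed" and self.n_alleles < 2:
            raise ValueError("a mixed locus needs at least 2 alleles")


@dataclass(frozen=True)
class PanelSpec:
    """Panel layout: groups x samples genotyped over ``loci``."""

    loci: tuple[LocusSpec, ...]
    n_groups: int = 3
    samples_per_group: int = 4
    heterozygosity: float = 0.3  # probability a sample shows 2 alleles
    missing_rate: float = 0.0    # probability a sample x primer drops out
    n_noise_peaks: int = 0       # sub-threshold peaks sprinkled over the table
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("panel needs at least one locus")
        if not 0 <= self.heterozygosity <= 1 or not 0 <= self.missing_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")


def _allele_pool(spec: LocusSpec, n_groups: int) -> list[list[int]]:
    """Allele sizes per group. Diagnostic loci get disjoint per-group
    series; otherwise all groups share one pool."""
    per_group = []
    for g in range(n_groups if spec.diagnostic else 1):
        offset = g * spec.n_alleles
        sizes = [
            spec.base_size + (offset + k) * spec.motif_len
            for k in range(spec.n_alleles)
        ]
        if spec.mode == "mixed":
            sizes[-1] += spec.indel_offset
        per_group.append(sizes)
    if not spec.diagnostic:
        per_group = per_group * n_groups
    return per_group


def simulate_panel(spec: PanelSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (peak table, marker table, truth).

    ``truth`` maps: ``group_of`` sample -> group label; ``mode_of``
    primer -> distribution mode; ``alleles`` (primer, sample) -> tuple of
    true allele sizes.  Noise peaks all fail the >= 1500 height /
    >= 6.0 quality filter, so a noise-free spec round-trips exactly.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [
        f"G{g + 1}S{s + 1}"
        for g in range(spec.n_groups)
        for s in range(spec.samples_per_group)
    ]
    group_of = {
        f"G{g + 1}S{s + 1}": f"G{g + 1}"
        for g in range(spec.n_groups)
        for s in range(spec.samples_per_group)
    }
    rows = []
    alleles_truth: dict[tuple[str, str], tuple[int, ...]] = {}
    n_samples = spec.n_groups * spec.samples_per_group
    for locus in spec.loci:
        pools = _allele_pool(locus, spec.n_groups)
        # a random permutation of sample slots guarantees every pool allele
        # is observed somewhere without aligning allele choice across groups
        perm = rng.permutation(n_samples)
        for g in range(spec.n_groups):
            pool = pools[g]
            for s in range(spec.samples_per_group):
                sample = f"G{g + 1}S{s + 1}"
                if rng.random() < spec.missing_rate:
                    continue
                idx = s if locus.diagnostic else int(perm[g * spec.samples_per_group + s])
                chosen = [pool[idx % len(pool)]]
                if len(pool) >= 2 and rng.random() < spec.heterozygosity:
                    others = [a for a in pool if a != chosen[0]]
                    chosen.append(int(others[int(rng.integers(len(others)))]))
                chosen = sorted(chosen)
                alleles_truth[(locus.primer_id, sample)] = tuple(
                    sorted(set(alleles_truth.get((locus.primer_id, sample), ())) | set(chosen))
                )
                for size in chosen:
                    rows.append(
                        {
                            "sample_id": sample,
                            "primer_id": locus.primer_id,
                            "size_bp": float(size),
                            "height": float(rng.integers(2000, 8000)),
                            "quality": float(np.round(rng.uniform(6.5, 9.5), 2)),
                        }
                    )
    primer_ids = sorted({l.primer_id for l in spec.loci})
    for _ in range(spec.n_noise_peaks):
        bad_height = rng.random() < 0.5
        rows.append(
            {
                "sample_id": samples[int(rng.integers(len(samples)))],
                "primer_id": primer_ids[int(rng.integers(len(primer_ids)))],
                "size_bp": float(rng.integers(60, 500)),
                "height": float(rng.integers(50, 1500)) if bad_height else float(rng.integers(2000, 8000)),
                "quality": float(np.round(rng.uniform(6.5, 9.5), 2)) if bad_height else float(np.round(rng.uniform(0.5, 5.9), 2)),
            }
        )
    peaks = pd.DataFrame(rows, columns=["sample_id", "primer_id", "size_bp", "height", "quality"])
    markers = pd.DataFrame(
        sorted(
            {(l.primer_id, l.motif_len) for l in spec.loci},
        ),
        columns=["primer_id", "motif_len"],
    )
    mode_of = {}
    for l in spec.loci:
        mode_of.setdefault(l.primer_id, {})[l.base_size] = l.mode
    truth = {
        "group_of": group_of,
        "groups": {
            g: [s for s in samples if group_of[s] == g]
            for g in sorted(set(group_of.values()))
        },
        "mode_of": mode_of,
        "alleles": alleles_truth,
    }
    return peaks, markers, truth


# --------------------------------------------------------------------------
# homolog repeat-count table


def simulate_homolog_table(
    n_loci: int,
    taxa: Sequence[str],
    rates: Mapping[str, float],
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Cross-taxon repeat-count table with planted divergence rates.

    The first taxon is the reference; every other taxon differs from it
    at each locus independently with its probability in ``rates`` (a
    differing locus shifts the unit count by a nonzero amount).  The
    observed reference-vs-taxon polymorphism percentage therefore
    converges on ``100 * rate`` as ``n_loci`` grows.
    """
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    for t in taxa[1:]:
        if not 0.0 <= rates.get(t, 0.0) <= 1.0:
            raise ValueError(f"rate for {t!r} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ref = taxa[0]
    ref_counts = rng.integers(5, 31, size=n_loci)
    rows = []
    truth = {}
    for li in range(n_loci):
        locus = f"L{li + 1:05d}"
        rows.append({"locus": locus, "taxon": ref, "repeat_count": int(ref_counts[li])})
        for t in taxa[1:]:
            c = int(ref_counts[li])
            if rng.random() < rates.get(t, 0.0):
                delta = int(rng.integers(1, 6)) * (1 if rng.random() < 0.5 else -1)
                c = max(3, c + delta)
                if c == ref_counts[li]:  # clamping collision: force a change
                    c += 1
            rows.append({"locus": locus, "taxon": t, "repeat_count": c})
    truth = {t: float(rates.get(t, 0.0)) for t in taxa[1:]}
    return pd.DataFrame(rows, columns=["locus", "taxon", "repeat_count"]), truth


# --------------------------------------------------------------------------
# presets


def load_preset(name: str) -> CorpusSpec | PanelSpec | dict:
    """Load a shipped preset ("corpus-small", "panel-3group",
    "homolog-cereal") into the matching spec object (the homolog preset
    returns keyword arguments for :func:`simulate_homolog_table`)."""
    path = resources.files("ugms.presets").joinpath(f"{name}.yaml")
    try:
        doc = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise ValueError(f"unknown preset {name!r}") from None
    kind = doc.pop("kind")
    if kind == "corpus":
        planted = tuple(PlantedRepeat(**p) for p in doc.pop("planted", []))
        return CorpusSpec(planted=planted, **doc)
    if kind == "panel":
        loci = tuple(LocusSpec(**l) for l in doc.pop("loci"))
        return PanelSpec(loci=loci, **doc)
    if kind == "homolog":
        return doc
    raise ValueError(f"unknown preset kind {kind!r}")
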