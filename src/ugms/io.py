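"""Readers and writers for every external format the pipeline touches.

All tables are tab-delimited with a fixed, documented header row.  All
coordinates in files are 1-based and inclusive on the forward strand of
the transcript.  Writers are deterministic: rows are sorted by sequence
id, then start coordinate (or the natural key of the table).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "SSR_COLUMNS",
    "write_ssr_table",
    "read_ssr_table",
    "write_compound_table",
    "write_summary",
    "read_gene_models",
    "write_gene_models",
    "read_peak_table",
    "read_marker_table",
    "read_homolog_table",
    "write_homolog_table",
    "read_sample_groups",
    "write_genotype_matrix",
    "read_genotype_matrix",
]

_VALID_CHARS = set("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A transcript/unigene sequence: uppercase DNA over {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; characters outside {A,C,G,T,N} and
    duplicate ids are rejected; an empty file is an error.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# --------------------------------------------------------------------------
# SSR report tables

SSR_COLUMNS = [
    "seq_id",
    "start",
    "end",
    "motif",
    "canonical_motif",
    "n_repeats",
    "total_len_nt",
    "length_class",
    "role",
]

COMPOUND_COLUMNS = [
    "seq_id",
    "compound_id",
    "start",
    "end",
    "n_members",
    "interrupting",
    "gaps_nt",
    "members",
]


def write_ssr_table(records: Sequence, path: str | Path) -> None:
    """Write SSR records (header always present; rows sorted by
    (seq_id, start))."""
    rows = [
        {
            "seq_id": r.seq_id,
            "start": r.start,
            "end": r.end,
            "motif": r.motif,
            "canonical_motif": r.canonical_motif,
            "n_repeats": r.n_repeats_reported,
            "total_len_nt": r.total_len_nt,
            "length_class": r.length_class,
            "role": r.role,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=SSR_COLUMNS)
    if len(df):
        df = df.sort_values(["seq_id", "start"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


def read_ssr_table(path: str | Path) -> list:
    from .mining import SSRRecord  # deferred to avoid import cycle

    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str})
    missing = set(SSR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SSR table {path} missing columns {sorted(missing)}")
    return [
        SSRRecord(
            seq_id=row.seq_id,
            start=int(row.start),
            end=int(row.end),
            motif=row.motif,
            canonical_motif=row.canonical_motif,
            n_repeats=int(row.n_repeats),
            total_len_nt=int(row.total_len_nt),
            length_class=row.length_class,
            role=row.role,
        )
        for row in df.itertuples()
    ]


def write_compound_table(compounds: Sequence, path: str | Path) -> None:
    rows = []
    for c in sorted(compounds, key=lambda c: (c.seq_id, c.start)):
        rows.append(
            {
                "seq_id": c.seq_id,
                "compound_id": f"{c.seq_id}:{c.start}-{c.end}",
                "start": c.start,
                "end": c.end,
                "n_members": len(c.members),
                "interrupting": c.interrupting,
                "gaps_nt": ";".join(str(g) for g in c.gaps_nt),
                "members": ";".join(str(m) for m in c.members),
            }
        )
    pd.DataFrame(rows, columns=COMPOUND_COLUMNS).to_csv(path, sep="\t", index=False)


def write_summary(counts, path: str | Path) -> None:
    """Key/value corpus summary: raw tallies followed by derived ratios
    (densities to one decimal kb, percentages to one decimal)."""
    lines = []
    for k, v in vars(counts).items():
        lines.append(f"{k}\t{v}")
    for k, v in counts.derived().items():
        lines.append(f"{k}\tNA" if v is None else f"{k}\t{v:.1f}")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# gene models, peaks, markers, homolog tables, groups


def read_gene_models(path: str | Path) -> dict[str, tuple[int, int]]:
    """Gene-structure table: seq_id, cds_start, cds_end (1-based incl.)."""
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str})
    for col in ("seq_id", "cds_start", "cds_end"):
        if col not in df.columns:
            raise ValueError(f"gene model table {path} missing column {col!r}")
    models: dict[str, tuple[int, int]] = {}
    for row in df.itertuples():
        if row.seq_id in models:
            raise ValueError(f"duplicate gene model for {row.seq_id!r}")
        models[row.seq_id] = (int(row.cds_start), int(row.cds_end))
    return models


def write_gene_models(models: Mapping[str, tuple[int, int]], path: str | Path) -> None:
    df = pd.DataFrame(
        [(sid, s, e) for sid, (s, e) in sorted(models.items())],
        columns=["seq_id", "cds_start", "cds_end"],
    )
    df.to_csv(path, sep="\t", index=False)


PEAK_COLUMNS = ["sample_id", "primer_id", "size_bp", "height", "quality"]


def read_peak_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "primer_id": str})
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table {path} missing columns {sorted(missing)}")
    if (df["size_bp"] <= 0).any():
        raise ValueError("peak sizes must be positive")
    return df[PEAK_COLUMNS].copy()


def read_marker_table(path: str | Path) -> pd.DataFrame:
    """Marker metadata: primer_id, motif, motif_len."""
    df = pd.read_csv(path, sep="\t", dtype={"primer_id": str, "motif": str})
    missing = {"primer_id", "motif_len"} - set(df.columns)
    if missing:
        raise ValueError(f"marker table {path} missing columns {sorted(missing)}")
    return df


def read_homolog_table(path: str | Path) -> pd.DataFrame:
    """Long-format homologous-locus repeat counts: locus, taxon, repeat_count."""
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "taxon": str})
    missing = {"locus", "taxon", "repeat_count"} - set(df.columns)
    if missing:
        raise ValueError(f"homolog table {path} missing columns {sorted(missing)}")
    if (df["repeat_count"] <= 0).any():
        raise ValueError("repeat counts must be positive")
    return df


def write_homolog_table(df: pd.DataFrame, path: str | Path) -> None:
    df.sort_values(["locus", "taxon"], kind="stable").to_csv(path, sep="\t", index=False)


def read_sample_groups(path: str | Path) -> dict[str, list[str]]:
    """Sample grouping table: sample_id, group -> {group: [samples]}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"group table {path} missing columns {sorted(missing)}")
    groups: dict[str, list[str]] = {}
    for row in df.itertuples():
        groups.setdefault(row.group, []).append(row.sample_id)
    return groups


GENOTYPE_COLUMNS = ["primer_id", "locus", "sample_id", "alleles"]


def write_genotype_matrix(matrix, path: str | Path) -> None:
    """Long-format genotype matrix; allele sizes semicolon-joined,
    ascending; one row per (locus, sample) with amplification."""
    rows = []
    for (primer, locus), by_sample in sorted(matrix.entries.items()):
        for sample in sorted(by_sample):
            alleles = ";".join(str(a) for a in sorted(by_sample[sample]))
            rows.append((primer, locus, sample, alleles))
    pd.DataFrame(rows, columns=GENOTYPE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genotype_matrix(path: str | Path):
    from .genotyping import GenotypeMatrix  # deferred to avoid import cycle

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(GENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"genotype matrix {path} missing columns {sorted(missing)}")
    entries: dict[tuple[str, str], dict[str, frozenset[int]]] = {}
    for row in df.itertuples():
        sizes = frozenset(int(x) for x in row.alleles.split(";"))
        entries.setdefault((row.primer_id, row.locus), {})[row.sample_id] = sizes
    return GenotypeMatrix(entries=entries)
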