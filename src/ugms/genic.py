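"""Genic-context annotation of SSRs: CDS / 5'UTR / 3'UTR location and the
amino acid encoded by trinucleotide repeats inside coding regions.

Gene structure is an input (a per-transcript CDS interval on the forward
strand); transcripts without a model are labelled ``unannotated`` rather
than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .io import SequenceRecord
from .mining import SSRRecord

__all__ = ["GeneModel", "GenicAnnotation", "locate_ssr", "encoded_amino_acid", "annotate_ssrs"]

CDS = "CDS"
UTR5 = "UTR5"
UTR3 = "UTR3"
UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class GeneModel:
    """Coding region of a transcript, 1-based inclusive, forward strand."""

    seq_id: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.cds_start <= self.cds_end:
            raise ValueError("need 1 <= cds_start <= cds_end")
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")


@dataclass(frozen=True)
class GenicAnnotation:
    ssr: SSRRecord
    location: str                    # CDS | UTR5 | UTR3 | unannotated
    encoded_aa: str | None = None    # one-letter code, tri-motif CDS repeats only
    phase: int | None = None         # offset of SSR start within its codon

    def __post_init__(self) -> None:
        if self.encoded_aa is not None and (
            self.location != CDS or len(self.ssr.motif) != 3
        ):
            raise ValueError("encoded_aa only valid for trinucleotide CDS repeats")


def _overlap(a1: int, a2: int, b1: int, b2: int) -> int:
    return max(0, min(a2, b2) - max(a1, b1) + 1)


def locate_ssr(ssr: SSRRecord, model: GeneModel | None, seq_len: int | None = None) -> str:
    """Assign an SSR to UTR5/CDS/UTR3 by majority overlap (ties -> CDS)."""
    if model is None:
        return UNANNOTATED
    if ssr.seq_id != model.seq_id:
        raise ValueError("SSR and gene model refer to different sequences")
    if ssr.start < 1 or (seq_len is not None and ssr.end > seq_len):
        raise ValueError("SSR coordinates outside sequence bounds")
    if seq_len is not None and model.cds_end > seq_len:
        raise ValueError("gene model outside sequence bounds")
    in_utr5 = _overlap(ssr.start, ssr.end, 1, model.cds_start - 1)
    in_cds = _overlap(ssr.start, ssr.end, model.cds_start, model.cds_end)
    in_utr3 = 0
    if seq_len is not None:
        in_utr3 = _overlap(ssr.start, ssr.end, model.cds_end + 1, seq_len)
    elif ssr.end > model.cds_end:
        in_utr3 = ssr.end - max(ssr.start, model.cds_end + 1) + 1
    # majority overlap, ties in favour of the coding region
    if in_cds >= max(in_utr5, in_utr3):
        if in_cds == 0:
            return UTR5 if in_utr5 >= in_utr3 else UTR3
        return CDS
    return UTR5 if in_utr5 >= in_utr3 else UTR3


def encoded_amino_acid(
    ssr: SSRRecord, model: GeneModel, sequence: SequenceRecord
) -> tuple[str, int]:
    """Amino acid encoded by a trinucleotide repeat read in CDS frame.

    Returns ``(aa, phase)`` where ``phase = (start - cds_start) mod 3``
    and ``aa`` is the translation of the first complete codon lying
    within the repeat tract.  A tract at phase 1 or 2 therefore encodes
    the in-frame cyclic rotation of its motif.
    """
    if len(ssr.motif) != 3:
        raise ValueError("encoded_amino_acid requires a trinucleotide motif")
    if ssr.start < model.cds_start or ssr.end > model.cds_end:
        raise ValueError("SSR is not wholly inside the CDS")
    phase = (ssr.start - model.cds_start) % 3
    codon_start = ssr.start if phase == 0 else ssr.start + (3 - phase)
    if codon_start + 2 > ssr.end:
        raise ValueError("repeat tract too short to contain a complete codon")
    codon = sequence.sequence[codon_start - 1 : codon_start + 2]
    return str(Seq(codon).translate()), phase


def annotate_ssrs(
    ssrs: list[SSRRecord],
    models: dict[str, GeneModel],
    sequences: dict[str, SequenceRecord] | None = None,
) -> list[GenicAnnotation]:
    """Location (and, where possible, encoded amino acid) for every SSR."""
    out = []
    for ssr in ssrs:
        model = models.get(ssr.seq_id)
        seq = sequences.get(ssr.seq_id) if sequences else None
        loc = locate_ssr(ssr, model, seq_len=len(seq) if seq else None)
        aa = phase = None
        if (
            loc == CDS
            and len(ssr.motif) == 3
            and seq is not None
            and model is not None
            and ssr.start >= model.cds_start
            and ssr.end <= model.cds_end
        ):
            aa, phase = encoded_amino_acid(ssr, model, seq)
        out.append(GenicAnnotation(ssr=ssr, location=loc, encoded_aa=aa, phase=phase))
    return out
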