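"""Perfect and compound microsatellite (SSR) detection in transcript sequences.

A *perfect* SSR is a maximal uninterrupted tandem array of a primitive
1-6 nt motif with at least a configurable number of whole repeat units.
Two or more runs separated by at most ``max_interruption_nt`` nucleotides
form a *compound* SSR (non-interrupting when adjacent, interrupting when
spaced).  Tracts of >= 20 nt are class I (long, hypervariable); tracts of
12-19 nt are class II (potentially variable).

Motifs are reported both as read and as a canonical representative so
that a repeat and its complement strand / frame shifts (AG, GA, TC, CT)
count as one motif class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .config import MiningConfig
from .io import SequenceRecord

__all__ = [
    "SSRRecord",
    "CompoundSSR",
    "CorpusCounts",
    "canonical_motif",
    "is_primitive",
    "classify_length",
    "find_perfect_ssrs",
    "merge_compound",
    "summarize_corpus",
]

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

CLASS_I = "class_I"
CLASS_II = "class_II"
BELOW_CLASS_II = "below_class_II"


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True iff ``motif`` is not a whole-number power of a shorter motif."""
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Canonical representative of a motif's equivalence class.

    Two motifs are equivalent when one is a cyclic rotation of the other
    or of its reverse complement (an SSR read on the opposite strand or
    in a shifted frame is the same repeat).  The representative is the
    lexicographically smallest member, so the map is idempotent.
    """
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 1-6, got {motif!r}")
    if set(motif) - _DNA:
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rc = reverse_complement(motif)
    m = len(motif)
    candidates = [motif[i:] + motif[:i] for i in range(m)]
    candidates += [rc[i:] + rc[:i] for i in range(m)]
    return min(candidates)


def classify_length(total_len_nt: int, cfg: MiningConfig | None = None) -> str:
    """Length class of a tract: >=20 nt class I, 12-19 nt class II."""
    cfg = cfg or MiningConfig()
    if total_len_nt < 1:
        raise ValueError("total_len_nt must be >= 1")
    if total_len_nt >= cfg.class1_min_len_nt:
        return CLASS_I
    if total_len_nt >= cfg.class2_min_len_nt:
        return CLASS_II
    return BELOW_CLASS_II


@dataclass(frozen=True)
class SSRRecord:
    """One detected perfect repeat run (1-based inclusive coordinates)."""

    seq_id: str
    start: int
    end: int
    motif: str
    canonical_motif: str
    n_repeats: int
    total_len_nt: int
    length_class: str
    role: str = "standalone"  # standalone | compound_member

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.total_len_nt:
            raise ValueError("coordinates inconsistent with total_len_nt")
        if self.total_len_nt != self.n_repeats * len(self.motif):
            raise ValueError("total_len_nt must equal n_repeats * motif length")

    @property
    def n_repeats_reported(self) -> int:
        """Repeat count capped at 100 units for reporting/classification."""
        return min(self.n_repeats, 100)

    @property
    def motif_len(self) -> int:
        return len(self.motif)

    def __str__(self) -> str:  # e.g. "(CT)17"
        return f"({self.motif}){self.n_repeats_reported}"


@dataclass(frozen=True)
class CompoundSSR:
    """Two or more repeat runs separated by short spacers."""

    seq_id: str
    members: tuple[SSRRecord, ...]
    gaps_nt: tuple[int, ...]
    interrupting: bool

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a compound SSR needs at least 2 member runs")
        if len(self.gaps_nt) != len(self.members) - 1:
            raise ValueError("need one gap per adjacent member pair")
        if self.interrupting != any(g > 0 for g in self.gaps_nt):
            raise ValueError("interrupting flag inconsistent with gaps")

    @property
    def start(self) -> int:
        return self.members[0].start

    @property
    def end(self) -> int:
        return self.members[-1].end

    @property
    def is_class1(self) -> bool:
        return any(m.length_class == CLASS_I for m in self.members)


def _candidate_runs(seq: str, cfg: MiningConfig) -> list[tuple[int, int, str, int]]:
    """All maximal perfect runs meeting the per-motif-length minima.

    Returns ``(start0, span_nt, motif, n_repeats)`` tuples with 0-based
    starts.  Only whole repeat units count toward the span; a trailing
    partial unit never extends a run.  N (or any non-ACGT symbol) never
    matches a motif position, so ambiguity codes terminate runs.
    """
    n = len(seq)
    out: list[tuple[int, int, str, int]] = []
    for m in range(1, 7):
        min_rep = cfg.min_repeats_by_motif_len[m]
        k = m
        while k < n:
            if seq[k] == seq[k - m] and seq[k] in _DNA:
                a = k
                while k < n and seq[k] == seq[k - m] and seq[k] in _DNA:
                    k += 1
                b = k - 1          # [a, b] = positions matching m back
                start = a - m
                motif = seq[start : start + m]
                if not (set(motif) - _DNA) and is_primitive(motif):
                    length = b - start + 1
                    reps = length // m
                    if reps >= min_rep:
                        out.append((start, reps * m, motif, reps))
            else:
                k += 1
    return out


def _resolve_overlaps(
    cands: list[tuple[int, int, str, int]]
) -> list[tuple[int, int, str, int]]:
    """One repeat call per locus: keep the longest tract, ties going to
    the shorter motif, then to the leftmost start."""
    order = sorted(cands, key=lambda c: (-c[1], len(c[2]), c[0]))
    taken: list[tuple[int, int]] = []
    kept = []
    for c in order:
        s, span = c[0], c[1]
        e = s + span - 1
        if all(e < ts or s > te for ts, te in taken):
            kept.append(c)
            taken.append((s, e))
    return sorted(kept, key=lambda c: c[0])


def find_perfect_ssrs(seq: SequenceRecord, cfg: MiningConfig | None = None) -> list[SSRRecord]:
    """Detect all perfect SSRs in one sequence, sorted by start position."""
    cfg = cfg or MiningConfig()
    records = []
    for start0, span, motif, reps in _resolve_overlaps(_candidate_runs(seq.sequence, cfg)):
        records.append(
            SSRRecord(
                seq_id=seq.id,
                start=start0 + 1,
                end=start0 + span,
                motif=motif,
                canonical_motif=canonical_motif(motif),
                n_repeats=reps,
                total_len_nt=span,
                length_class=classify_length(span, cfg),
            )
        )
    return records


def merge_compound(
    ssrs: Sequence[SSRRecord], cfg: MiningConfig | None = None
) -> tuple[list[CompoundSSR], list[SSRRecord]]:
    """Chain runs separated by <= ``max_interruption_nt`` into compounds.

    ``ssrs`` must come from a single sequence, sorted by start.  Runs
    farther apart than the cutoff remain standalone perfect SSRs.  The
    interrupting flag keys on spacer presence, not motif change: members
    with identical motifs separated by a spacer still form an
    interrupting compound.
    """
    cfg = cfg or MiningConfig()
    if not ssrs:
        return [], []
    chains: list[list[SSRRecord]] = [[ssrs[0]]]
    for rec in ssrs[1:]:
        if rec.seq_id != chains[-1][-1].seq_id:
            raise ValueError("merge_compound expects SSRs from one sequence")
        gap = rec.start - chains[-1][-1].end - 1
        if gap <= cfg.max_interruption_nt:
            chains[-1].append(rec)
        else:
            chains.append([rec])
    compounds: list[CompoundSSR] = []
    standalone: list[SSRRecord] = []
    for chain in chains:
        if len(chain) == 1:
            standalone.append(chain[0])
            continue
        members = tuple(replace(r, role="compound_member") for r in chain)
        gaps = tuple(
            b.start - a.end - 1 for a, b in zip(members, members[1:])
        )
        compounds.append(
            CompoundSSR(
                seq_id=members[0].seq_id,
                members=members,
                gaps_nt=gaps,
                interrupting=any(g > 0 for g in gaps),
            )
        )
    return compounds, standalone


# --------------------------------------------------------------------------
# corpus summary


@dataclass(frozen=True)
class CorpusCounts:
    """Raw corpus tallies from which all summary ratios derive.

    ``n_perfect_excl_mono`` counts every perfect run of motif length >= 2
    (compound members included); ``n_perfect_standalone_excl_mono`` is the
    count excluding compound members, reported alongside because either
    convention is defensible for a corpus summary.
    """

    n_sequences: int
    total_bp: int
    n_mono: int = 0
    n_di: int = 0
    n_tri: int = 0
    n_tetra: int = 0
    n_penta: int = 0
    n_hexa: int = 0
    n_perfect_incl_mono: int = 0
    n_perfect_excl_mono: int = 0
    n_perfect_standalone_excl_mono: int = 0
    n_class1: int = 0
    n_compound: int = 0
    n_compound_interrupting: int = 0
    n_compound_noninterrupting: int = 0
    n_seq_with_ssr_incl_mono: int = 0
    n_seq_with_ssr_excl_mono: int = 0
    n_multi_ssr_sequences: int = 0

    def derived(self) -> dict[str, float | None]:
        """Densities (kb per SSR) and percentages, with the denominators
        conventional for this kind of summary table:

        * motif-length fractions (di..hexa) and the class I fraction are
          over ``n_perfect_excl_mono``;
        * the mononucleotide fraction and all sequence-level fractions
          are over ``n_sequences``;
        * the multi-SSR fraction is over ``n_seq_with_ssr_excl_mono``;
        * the interrupting/non-interrupting split is over ``n_compound``.

        Undefined ratios (zero denominator) are returned as ``None``.
        """

        def ratio(num: int, den: int) -> float | None:
            return None if den == 0 else 100.0 * num / den

        def kb_per(den: int) -> float | None:
            return None if den == 0 else self.total_bp / den / 1000.0

        return {
            "density_kb_per_ssr": kb_per(self.n_perfect_excl_mono),
            "density_kb_per_class1": kb_per(self.n_class1),
            "density_kb_per_compound": kb_per(self.n_compound),
            "pct_mono": ratio(self.n_mono, self.n_sequences),
            "pct_di": ratio(self.n_di, self.n_perfect_excl_mono),
            "pct_tri": ratio(self.n_tri, self.n_perfect_excl_mono),
            "pct_tetra": ratio(self.n_tetra, self.n_perfect_excl_mono),
            "pct_penta": ratio(self.n_penta, self.n_perfect_excl_mono),
            "pct_hexa": ratio(self.n_hexa, self.n_perfect_excl_mono),
            "pct_class1": ratio(self.n_class1, self.n_perfect_excl_mono),
            "pct_perfect_incl_mono": ratio(self.n_perfect_incl_mono, self.n_sequences),
            "pct_perfect_excl_mono": ratio(self.n_perfect_excl_mono, self.n_sequences),
            "pct_seq_with_ssr_incl_mono": ratio(
                self.n_seq_with_ssr_incl_mono, self.n_sequences
            ),
            "pct_seq_with_ssr_excl_mono": ratio(
                self.n_seq_with_ssr_excl_mono, self.n_sequences
            ),
            "pct_multi_ssr": ratio(
                self.n_multi_ssr_sequences, self.n_seq_with_ssr_excl_mono
            ),
            "pct_compound_interrupting": ratio(
                self.n_compound_interrupting, self.n_compound
            ),
            "pct_compound_noninterrupting": ratio(
                self.n_compound_noninterrupting, self.n_compound
            ),
        }


def summarize_corpus(
    ssrs_by_seq: Mapping[str, Sequence[SSRRecord]],
    compounds_by_seq: Mapping[str, Sequence[CompoundSSR]],
    seq_lengths: Mapping[str, int],
    cfg: MiningConfig | None = None,
) -> CorpusCounts:
    """Tally corpus-level SSR statistics.

    ``ssrs_by_seq`` holds every perfect run per sequence (including
    compound members); ``compounds_by_seq`` the merged compounds.
    """
    cfg = cfg or MiningConfig()
    by_len = {1: 0, 2: 0, 3: 0, 4: 0, 5: 0, 6: 0}
    n_class1 = 0
    n_standalone_excl_mono = 0
    seq_with_incl = seq_with_excl = multi = 0
    compound_member_keys = {
        (m.seq_id, m.start, m.end)
        for comps in compounds_by_seq.values()
        for c in comps
        for m in c.members
    }
    for sid, recs in ssrs_by_seq.items():
        non_mono = [r for r in recs if r.motif_len >= 2]
        if recs:
            seq_with_incl += 1
        if non_mono:
            seq_with_excl += 1
        if len(non_mono) > 1:
            multi += 1
        for r in recs:
            by_len[r.motif_len] += 1
            if r.motif_len >= 2:
                if r.length_class == CLASS_I:
                    n_class1 += 1
                if (r.seq_id, r.start, r.end) not in compound_member_keys:
                    n_standalone_excl_mono += 1
    all_compounds = [c for comps in compounds_by_seq.values() for c in comps]
    n_int = sum(1 for c in all_compounds if c.interrupting)
    return CorpusCounts(
        n_sequences=len(seq_lengths),
        total_bp=sum(seq_lengths.values()),
        n_mono=by_len[1],
        n_di=by_len[2],
        n_tri=by_len[3],
        n_tetra=by_len[4],
        n_penta=by_len[5],
        n_hexa=by_len[6],
        n_perfect_incl_mono=sum(by_len.values()),
        n_perfect_excl_mono=sum(v for k, v in by_len.items() if k >= 2),
        n_perfect_standalone_excl_mono=n_standalone_excl_mono,
        n_class1=n_class1,
        n_compound=len(all_compounds),
        n_compound_interrupting=n_int,
        n_compound_noninterrupting=len(all_compounds) - n_int,
        n_seq_with_ssr_incl_mono=seq_with_incl,
        n_seq_with_ssr_excl_mono=seq_with_excl,
        n_multi_ssr_sequences=multi,
    )
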