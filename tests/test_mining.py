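"""SSR detection, motif canonicalisation, length classes, compounds."""

import numpy as np
import pytest
from itertools import product

from helpers import brute_force_ssrs, random_dna

from ugms.config import MiningConfig
from ugms.io import SequenceRecord
from ugms.mining import (
    BELOW_CLASS_II,
    CLASS_I,
    CLASS_II,
    CorpusCounts,
    canonical_motif,
    classify_length,
    find_perfect_ssrs,
    is_primitive,
    merge_compound,
    reverse_complement,
    summarize_corpus,
)

CFG = MiningConfig()


class TestCanonicalMotif:
    @pytest.mark.parametrize(
        "motif,expected",
        [
            ("GA", "AG"),  # complement/rotation family AG/GA/TC/CT
            ("TC", "AG"),
            ("CT", "AG"),
            ("AG", "AG"),
            ("A", "A"),
            ("T", "A"),
            ("CAG", "AGC"),  # min over {CAG,AGC,GCA} u rot(rc) {CTG,TGC,GCT}
        ],
    )
    def test_examples(self, motif, expected):
        assert canonical_motif(motif) == expected

    def test_rejects_non_primitive_and_bad_alphabet(self):
        with pytest.raises(ValueError):
            canonical_motif("ATAT")
        with pytest.raises(ValueError):
            canonical_motif("AN")

    def test_exhaustive_class_closure(self):
        """Canonicalisation partitions all primitive motifs of length <= 6
        into classes closed under rotation and reverse complement."""
        for m in range(1, 7):
            for tup in product("ACGT", repeat=m):
                motif = "".join(tup)
                if not is_primitive(motif):
                    continue
                canon = canonical_motif(motif)
                rc = reverse_complement(motif)
                for k in range(m):
                    assert canonical_motif(motif[k:] + motif[:k]) == canon
                    assert canonical_motif(rc[k:] + rc[:k]) == canon
                assert canonical_motif(canon) == canon  # idempotent


class TestClassifyLength:
    @pytest.mark.parametrize(
        "nt,expected",
        [
            (36, CLASS_I),   # e.g. a dinucleotide repeated 18 times
            (16, CLASS_II),  # e.g. a dinucleotide repeated 8 times
            (20, CLASS_I),   # boundary: 20 nt is class I
            (19, CLASS_II),
            (12, CLASS_II),
            (11, BELOW_CLASS_II),
            (1, BELOW_CLASS_II),
        ],
    )
    def test_thresholds(self, nt, expected):
        assert classify_length(nt) == expected

    def test_monotone(self):
        order = {BELOW_CLASS_II: 0, CLASS_II: 1, CLASS_I: 2}
        ranks = [order[classify_length(nt)] for nt in range(1, 60)]
        assert ranks == sorted(ranks)


class TestFindPerfectSSRs:
    def test_dinucleotide_run_with_flanks(self):
        seq = SequenceRecord("u1", "GGGAA" + "CT" * 17 + "AGGGA")
        (rec,) = find_perfect_ssrs(seq, CFG)
        assert (rec.start, rec.end) == (6, 39)
        assert rec.motif == "CT" and rec.canonical_motif == "AG"
        assert rec.n_repeats == 17 and rec.total_len_nt == 34
        assert rec.length_class == CLASS_I

    def test_below_threshold_not_reported(self):
        seq = SequenceRecord("u1", "GGC" + "AT" * 5 + "CGG")
        assert find_perfect_ssrs(seq, CFG) == []

    def test_long_mononucleotide_run(self):
        seq = SequenceRecord("u1", "GACGC" + "T" * 69 + "CAGAC")
        (rec,) = find_perfect_ssrs(seq, CFG)
        assert rec.motif == "T" and rec.n_repeats == 69
        assert rec.total_len_nt == 69 and rec.length_class == CLASS_I

    def test_n_breaks_runs(self):
        seq = SequenceRecord("u1", "G" + "AT" * 4 + "N" + "AT" * 4 + "G")
        assert find_perfect_ssrs(seq, CFG) == []

    def test_non_primitive_reported_as_shorter_motif(self):
        seq = SequenceRecord("u1", "GCC" + "ATAT" * 7 + "GCC")
        (rec,) = find_perfect_ssrs(seq, CFG)
        assert rec.motif == "AT" and rec.n_repeats == 14

    def test_repeat_count_capped_at_100_in_report(self):
        seq = SequenceRecord("u1", "G" + "A" * 130 + "C")
        (rec,) = find_perfect_ssrs(seq, CFG)
        assert rec.n_repeats == 130          # true run length retained
        assert rec.n_repeats_reported == 100  # capped for reporting

    def test_matches_brute_force_on_random_sequences(self):
        """Detector equals exhaustive (start, motif length, count)
        enumeration on random sequences, some with planted repeats."""
        rng = np.random.default_rng(2024)
        plants = ["AT" * 8, "GCA" * 6, "A" * 12, "AGGA" * 4, "CT" * 30]
        for trial in range(150):
            s = random_dna(rng, 300)
            if trial % 3 == 0:
                pos = int(rng.integers(0, 250))
                tract = plants[trial % len(plants)]
                s = s[:pos] + tract + s[pos:]
            expected = brute_force_ssrs(s, CFG.min_repeats_by_motif_len)
            got = [
                (r.start - 1, r.end - 1, r.motif, r.n_repeats)
                for r in find_perfect_ssrs(SequenceRecord("u", s), CFG)
            ]
            assert got == expected, f"trial {trial}: {s}"


class TestMergeCompound:
    def _two_runs(self, gap):
        from ugms.mining import SSRRecord

        a = SSRRecord("u", 6, 21, "AT", "AT", 8, 16, CLASS_II)
        start_b = 21 + gap + 1
        b = SSRRecord("u", start_b, start_b + 17, "GCA", "AGC", 6, 18, CLASS_II)
        return [a, b]

    @pytest.mark.parametrize(
        "gap,n_compound,interrupting",
        [(0, 1, False), (40, 1, True), (99, 1, True), (100, 1, True)],
    )
    def test_merge_within_cutoff(self, gap, n_compound, interrupting):
        compounds, standalone = merge_compound(self._two_runs(gap), CFG)
        assert len(compounds) == n_compound and standalone == []
        assert compounds[0].interrupting is interrupting
        assert compounds[0].gaps_nt == (gap,)
        assert all(m.role == "compound_member" for m in compounds[0].members)

    def test_beyond_cutoff_stays_standalone(self):
        compounds, standalone = merge_compound(self._two_runs(101), CFG)
        assert compounds == [] and len(standalone) == 2

    def test_same_motif_with_spacer_is_interrupting_compound(self):
        from ugms.mining import SSRRecord

        a = SSRRecord("u", 1, 16, "AT", "AT", 8, 16, CLASS_II)
        b = SSRRecord("u", 30, 45, "AT", "AT", 8, 16, CLASS_II)
        (comp,), rest = merge_compound([a, b], CFG)
        assert comp.interrupting and rest == []


class TestSummarizeCorpus:
    def test_small_corpus_counts(self):
        seqs = {
            "u1": SequenceRecord("u1", "GACGTCAG" + "CT" * 17 + "GACCATGA"),
            "u2": SequenceRecord("u2", "GACGTCAG" + "A" * 12 + "CCGTGACT"),
            "u3": SequenceRecord("u3", "TAGG" + "GC" * 30 + "ATCC"),
        }
        ssrs, comps = {}, {}
        for sid, rec in seqs.items():
            found = find_perfect_ssrs(rec, CFG)
            c, s = merge_compound(found, CFG)
            ssrs[sid] = s + [m for cc in c for m in cc.members]
            comps[sid] = c
        counts = summarize_corpus(ssrs, comps, {k: len(v) for k, v in seqs.items()}, CFG)
        assert counts.n_sequences == 3
        assert counts.n_mono == 1 and counts.n_di == 2
        assert counts.n_perfect_excl_mono == 2
        assert counts.n_seq_with_ssr_excl_mono == 2
        assert counts.n_seq_with_ssr_incl_mono == 3

    def test_zero_denominators_are_none_not_zero(self):
        counts = CorpusCounts(n_sequences=5, total_bp=1000)
        derived = counts.derived()
        assert derived["density_kb_per_ssr"] is None
        assert derived["pct_class1"] is None
        assert derived["pct_multi_ssr"] is None
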