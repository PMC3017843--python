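"""Independent oracles used by the test suite.

These deliberately re-derive results by the slowest, most transparent
route available (exhaustive enumeration, direct formula evaluation) and
never call the code paths they are used to check.
"""

from __future__ import annotations

import numpy as np

DNA = set("ACGT")


def _primitive(unit: str) -> bool:
    m = len(unit)
    return not any(m % d == 0 and unit == unit[:d] * (m // d) for d in range(1, m))


def brute_force_ssrs(seq: str, min_repeats: dict[int, int]) -> list[tuple[int, int, str, int]]:
    """Enumerate every (start, motif length, repeat count) triple.

    Returns (start0, end0, motif, n_repeats) for each maximal run of a
    primitive motif meeting the per-motif-length minimum, after applying
    the one-call-per-locus rule (longest span wins, ties to the shorter
    motif, then to the leftmost start).
    """
    n = len(seq)
    cands = []
    for m in range(1, 7):
        need = min_repeats[m]
        for i in range(n - m + 1):
            unit = seq[i : i + m]
            if set(unit) - DNA or not _primitive(unit):
                continue
            c = 1
            while seq[i + c * m : i + (c + 1) * m] == unit:
                c += 1
            if c < need:
                continue
            # maximal: the periodic run must not extend one position left
            if i > 0 and i + m - 1 < n and seq[i - 1] == seq[i + m - 1]:
                continue
            cands.append((i, i + c * m - 1, unit, c))
    # overlap resolution, re-derived independently
    cands.sort(key=lambda t: (-(t[1] - t[0] + 1), len(t[2]), t[0]))
    chosen: list[tuple[int, int, str, int]] = []
    for cand in cands:
        if all(cand[1] < s or cand[0] > e for s, e, _u, _c in chosen):
            chosen.append(cand)
    return sorted(chosen)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def pic_direct(freqs) -> float:
    """PIC by direct summation, no vectorisation."""
    total = 0.0
    for p in freqs:
        total += p * p
    return 1.0 - total
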