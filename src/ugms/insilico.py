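"""In-silico repeat-length polymorphism across taxa.

Given repeat-unit counts at homologous SSR loci (locus x taxon), a locus
is polymorphic for a pair of taxa when its counts differ; the pairwise
polymorphism percentage is taken over the loci present in both taxa.
Homology is an input (matched locus ids), not computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["PairwisePolymorphism", "pairwise_polymorphism", "polymorphism_matrix"]


@dataclass(frozen=True)
class PairwisePolymorphism:
    taxon_a: str
    taxon_b: str
    n_compared: int          # loci with counts in both taxa
    n_polymorphic: int       # of those, loci with differing counts
    percent: float | None    # 100 * n_polymorphic / n_compared, 1 decimal

    def __post_init__(self) -> None:
        if self.percent is not None and not 0.0 <= self.percent <= 100.0:
            raise ValueError("percent must lie in [0, 100]")


def pairwise_polymorphism(table: pd.DataFrame) -> list[PairwisePolymorphism]:
    """One record per unordered taxon pair.

    ``table`` is long-format with columns locus, taxon, repeat_count.
    Loci absent in either taxon of a pair are excluded from that pair's
    denominator; a pair sharing no locus gets ``percent=None``.
    """
    wide = table.pivot_table(
        index="locus", columns="taxon", values="repeat_count", aggfunc="first"
    )
    taxa = sorted(wide.columns)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    out = []
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            both = wide[[a, b]].dropna()
            n = len(both)
            npoly = int((both[a] != both[b]).sum())
            pct = round(100.0 * npoly / n, 1) if n else None
            out.append(PairwisePolymorphism(a, b, n, npoly, pct))
    return out


def polymorphism_matrix(records: list[PairwisePolymorphism]) -> pd.DataFrame:
    """Symmetric taxon x taxon percentage matrix (diagonal 0)."""
    taxa = sorted({r.taxon_a for r in records} | {r.taxon_b for r in records})
    mat = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for r in records:
        val = float("nan") if r.percent is None else r.percent
        mat.loc[r.taxon_a, r.taxon_b] = val
        mat.loc[r.taxon_b, r.taxon_a] = val
    return mat
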