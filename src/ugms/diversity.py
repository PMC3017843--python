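"""Marker-based genetic diversity: Nei-Li similarity, UPGMA clustering
and bootstrap majority-rule consensus trees.

Genotype profiles are scored as allele presence/absence over
(locus, allele size) rows.  The Nei-Li (1979) coefficient is used in its
Dice form S = 2*n11 / (2*n11 + n10 + n01), the standard reading for
band-sharing data; distance is d = 1 - S.  UPGMA produces an ultrametric
rooted tree; confidence is attached by resampling whole marker loci with
replacement (alleles of one locus are not independent), rebuilding the
tree per replicate and reporting clade occurrence percentages, plus a
majority-rule (> 50%) consensus tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DiversityConfig
from .genotyping import GenotypeMatrix

__all__ = [
    "Node",
    "AlleleIncidence",
    "incidence_from_matrix",
    "nei_li_similarity",
    "similarity_matrix",
    "distance_matrix",
    "upgma",
    "cophenetic_matrix",
    "clades",
    "bootstrap_consensus",
    "to_newick",
]


# --------------------------------------------------------------------------
# incidence matrix


@dataclass(frozen=True)
class AlleleIncidence:
    """0/1 allele presence over (locus, allele size) rows x genotypes."""

    rows: tuple[tuple[tuple[str, str], int], ...]  # ((primer, locus), size)
    samples: tuple[str, ...]
    data: np.ndarray  # shape (n_rows, n_samples), dtype int8

    @property
    def loci(self) -> list[tuple[str, str]]:
        seen: dict[tuple[str, str], None] = {}
        for (locus, _size) in self.rows:
            seen.setdefault(locus, None)
        return list(seen)

    def locus_row_indices(self) -> dict[tuple[str, str], np.ndarray]:
        idx: dict[tuple[str, str], list[int]] = {}
        for i, (locus, _size) in enumerate(self.rows):
            idx.setdefault(locus, []).append(i)
        return {k: np.asarray(v) for k, v in idx.items()}


def incidence_from_matrix(matrix: GenotypeMatrix) -> AlleleIncidence:
    samples = tuple(matrix.samples)
    rows: list[tuple[tuple[str, str], int]] = []
    data: list[list[int]] = []
    for locus in matrix.loci:
        by_sample = matrix.entries[locus]
        for size in matrix.alleles(locus):
            rows.append((locus, size))
            data.append([int(size in by_sample.get(s, frozenset())) for s in samples])
    arr = np.asarray(data, dtype=np.int8)
    keep = arr.any(axis=1)
    return AlleleIncidence(
        rows=tuple(r for r, k in zip(rows, keep) if k),
        samples=samples,
        data=arr[keep],
    )


# --------------------------------------------------------------------------
# similarity / distance


def nei_li_similarity(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Dice/Nei-Li band-sharing similarity of two 0/1 profiles."""
    a = np.asarray(profile_a, dtype=bool)
    b = np.asarray(profile_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("profiles must cover the same rows")
    n11 = int((a & b).sum())
    n10 = int((a & ~b).sum())
    n01 = int((~a & b).sum())
    denom = 2 * n11 + n10 + n01
    if denom == 0:
        raise ValueError("Nei-Li similarity undefined for two empty profiles")
    return 2.0 * n11 / denom


def similarity_matrix(inc: AlleleIncidence) -> pd.DataFrame:
    n = len(inc.samples)
    if n < 2:
        raise ValueError("need at least 2 genotypes")
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = nei_li_similarity(inc.data[:, i], inc.data[:, j])
    return pd.DataFrame(S, index=inc.samples, columns=inc.samples)


def distance_matrix(inc: AlleleIncidence) -> pd.DataFrame:
    """d = 1 - S; zero diagonal, symmetric."""
    return 1.0 - similarity_matrix(inc)


# --------------------------------------------------------------------------
# UPGMA


@dataclass
class Node:
    """Rooted tree node; ``height`` is the UPGMA merge height (leaves 0)."""

    name: str | None = None
    children: tuple["Node", ...] = ()
    height: float = 0.0
    support: int | None = None  # percentage, internal nodes only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def upgma(dist: pd.DataFrame) -> Node:
    """Standard UPGMA (average linkage) with deterministic tie-breaking.

    The closest pair is merged repeatedly; inter-cluster distance is the
    arithmetic mean of member pairwise distances; merge height is d/2.
    Ties are broken by the lowest pair of original label indices, so the
    tree is a pure function of the matrix.
    """
    labels = list(dist.index)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    D = dist.to_numpy(dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    # active clusters: min original index -> (size, Node)
    clusters: dict[int, tuple[int, Node]] = {
        i: (1, Node(name=labels[i])) for i in range(n)
    }
    d: dict[tuple[int, int], float] = {
        (i, j): D[i, j] for i in range(n) for j in range(i + 1, n)
    }
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = min(
            ((d[(i, j)], i, j) for ki, i in enumerate(keys) for j in keys[ki + 1 :]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        dij, i, j = best
        ni, node_i = clusters[i]
        nj, node_j = clusters[j]
        merged = Node(children=(node_i, node_j), height=dij / 2.0)
        for k in keys:
            if k in (i, j):
                continue
            a, b = min(i, k), max(i, k)
            c, e = min(j, k), max(j, k)
            dik, djk = d[(a, b)], d[(c, e)]
            d[(min(i, k), max(i, k))] = (ni * dik + nj * djk) / (ni + nj)
        del clusters[j]
        clusters[i] = (ni + nj, merged)
    (_, root), = clusters.values()
    return root


def cophenetic_matrix(tree: Node) -> pd.DataFrame:
    """Pairwise cophenetic distances (2 x height of the lowest common
    ancestor) implied by an UPGMA tree."""
    names = tree.leaves()
    mat = pd.DataFrame(0.0, index=names, columns=names)

    def visit(node: Node) -> list[str]:
        if node.is_leaf:
            return [node.name]
        groups = [visit(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        mat.loc[a, b] = mat.loc[b, a] = 2.0 * node.height
        return [x for g in groups for x in g]

    visit(tree)
    return mat


def clades(tree: Node) -> set[frozenset[str]]:
    """Non-trivial clades (internal nodes below the root) as leaf sets."""
    out: set[frozenset[str]] = set()
    total = len(tree.leaves())

    def visit(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        s = frozenset().union(*(visit(c) for c in node.children))
        if 1 < len(s) < total:
            out.add(s)
        return s

    visit(tree)
    return out


# --------------------------------------------------------------------------
# bootstrap


def _tree_from_incidence(inc: AlleleIncidence, data: np.ndarray) -> Node:
    n = len(inc.samples)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = 1.0 - nei_li_similarity(data[:, i], data[:, j])
    return upgma(pd.DataFrame(D, index=inc.samples, columns=inc.samples))


def _annotate(node: Node, support: dict[frozenset[str], int], total: int) -> None:
    if node.is_leaf:
        return
    s = frozenset(node.leaves())
    if 1 < len(s) < total:
        node.support = support.get(s, 0)
    for c in node.children:
        _annotate(c, support, total)


def _consensus_tree(
    kept: list[tuple[frozenset[str], int]], leaf_names: list[str]
) -> Node:
    """Build a rooted tree from a nestable clade set (majority clades of
    rooted trees are always mutually compatible)."""
    items: list[tuple[frozenset[str], int | None]] = [
        (frozenset([n]), None) for n in leaf_names
    ]
    items += [(c, s) for c, s in kept]
    full = frozenset(leaf_names)

    def build(members: frozenset[str], support: int | None) -> Node:
        inner = [
            (c, s) for c, s in items if c < members
        ]
        # keep only maximal sub-clades
        maximal = [
            (c, s)
            for c, s in inner
            if not any(c < other for other, _ in inner)
        ]
        if not maximal:
            return Node(name=next(iter(members)), support=None)
        children = tuple(
            build(c, s) for c, s in sorted(maximal, key=lambda t: sorted(t[0]))
        )
        return Node(children=children, support=support)

    return build(full, None)


def bootstrap_consensus(
    matrix_or_incidence, cfg: DiversityConfig | None = None
) -> tuple[Node, Node, dict[frozenset[str], int]]:
    """Locus-resampled bootstrap of the UPGMA tree.

    Returns ``(tree, consensus, supports)``: the point-estimate UPGMA
    tree with clade supports (percent of replicates containing each
    clade), the majority-rule (> threshold) consensus tree, and the full
    clade -> support map.  Fixed seed gives identical output.
    """
    cfg = cfg or DiversityConfig()
    inc = (
        matrix_or_incidence
        if isinstance(matrix_or_incidence, AlleleIncidence)
        else incidence_from_matrix(matrix_or_incidence)
    )
    if len(inc.samples) < 3:
        raise ValueError("need at least 3 genotypes to bootstrap")
    locus_idx = inc.locus_row_indices()
    loci = list(locus_idx)
    if len(loci) < 2:
        raise ValueError("need at least 2 loci to bootstrap")
    rng = np.random.default_rng(cfg.seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(cfg.n_bootstrap):
        chosen = rng.integers(0, len(loci), size=len(loci))
        rows = np.concatenate([locus_idx[loci[k]] for k in chosen])
        rep_tree = _tree_from_incidence(inc, inc.data[rows])
        for c in clades(rep_tree):
            counts[c] = counts.get(c, 0) + 1
    supports = {
        c: int(round(100.0 * k / cfg.n_bootstrap)) for c, k in counts.items()
    }
    tree = _tree_from_incidence(inc, inc.data)
    _annotate(tree, supports, len(inc.samples))
    kept = [
        (c, supports[c])
        for c, k in counts.items()
        if k / cfg.n_bootstrap > cfg.consensus_threshold
    ]
    consensus = _consensus_tree(kept, list(inc.samples))
    return tree, consensus, supports


# --------------------------------------------------------------------------
# Newick output


def to_newick(tree: Node, branch_lengths: bool = True) -> str:
    """Newick string with bootstrap supports as internal-node labels.

    For UPGMA trees branch lengths are differences of merge heights, so
    the rendered tree is ultrametric; consensus trees are emitted
    without branch lengths.
    """

    def fmt(node: Node, parent_height: float | None) -> str:
        if node.is_leaf:
            label = node.name.replace(" ", "_")
            if branch_lengths and parent_height is not None:
                return f"{label}:{parent_height - node.height:.6g}"
            return label
        inner = ",".join(fmt(c, node.height if branch_lengths else None) for c in node.children)
        label = "" if node.support is None else str(node.support)
        if branch_lengths and parent_height is not None:
            return f"({inner}){label}:{parent_height - node.height:.6g}"
        return f"({inner}){label}"

    return fmt(tree, None) + ";"
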