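"""Orthology statistics and the UPGMA orthophylogram.

Given per-species-pair ortholog groups, this module tallies the count
matrix (how many of species A's family members have an ortholog in B,
and how many groups the pair shares), the average ortholog group size
(a proxy for in-paralog abundance: a value of 1.7 means each gene has
on average 0.7 in-paralogs), and the orthology distance

    dAB = (proteins_A - proteins_A_orthologous_to_B) / proteins_A,

the fraction of A's family lacking any ortholog in B.  The symmetrized
distance (dAB + dBA) / 2 feeds a classical (size-weighted) UPGMA
agglomeration whose rooted ultrametric tree is the *orthophylogram*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd


GroupLike = Union["OrthologGroupLike", Mapping[str, Iterable[str]]]


def _group_members(group: GroupLike, species: str) -> set[str]:
    members = getattr(group, "members", None)
    if callable(members):
        return {g for g, _ in members(species)}
    return set(group[species])


@dataclass
class OrthologCountMatrix:
    """Per-species totals and per-pair ortholog counts.

    ``n_orthologous[(A, B)]`` is the number of A genes appearing in any
    group with B (not symmetric: duplication frequencies differ between
    lineages); ``n_groups`` is shared by the unordered pair.
    """

    species: list[str]
    totals: dict[str, int]
    n_orthologous: dict[tuple[str, str], int] = field(default_factory=dict)
    n_groups: dict[frozenset, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b), n in self.n_orthologous.items():
            if not 0 <= n <= self.totals[a]:
                raise ValueError(
                    f"n_orthologous({a},{b})={n} outside [0, total {self.totals[a]}]"
                )

    def groups_between(self, a: str, b: str) -> int:
        return self.n_groups.get(frozenset((a, b)), 0)

    def to_frame(self) -> pd.DataFrame:
        """Table-1-shaped frame with slash-separated ``orth/groups`` cells."""
        data = {}
        for a in self.species:
            row = {}
            for b in self.species:
                if a == b:
                    row[b] = "-"
                else:
                    row[b] = f"{self.n_orthologous.get((a, b), 0)}/{self.groups_between(a, b)}"
            row["total_genes"] = self.totals[a]
            try:
                row["avg_group_size"] = round(average_group_size(self, a), 3)
            except ValueError:
                row["avg_group_size"] = float("nan")
            data[a] = row
        return pd.DataFrame.from_dict(data, orient="index")


def count_matrix(
    groups_by_pair: Mapping[tuple[str, str], Sequence[GroupLike]],
    totals: Mapping[str, int],
) -> OrthologCountMatrix:
    """Tally ortholog counts from per-pair group lists.

    Raises if a gene appears in two groups of the same species pair.
    """
    species = sorted(totals)
    matrix = OrthologCountMatrix(species=species, totals=dict(totals))
    for (a, b), groups in groups_by_pair.items():
        seen_a: set[str] = set()
        seen_b: set[str] = set()
        for group in groups:
            ga = _group_members(group, a)
            gb = _group_members(group, b)
            if ga & seen_a or gb & seen_b:
                dup = (ga & seen_a) | (gb & seen_b)
                raise ValueError(f"gene(s) {sorted(dup)} listed in two groups of pair ({a},{b})")
            seen_a |= ga
            seen_b |= gb
        matrix.n_orthologous[(a, b)] = len(seen_a)
        matrix.n_orthologous[(b, a)] = len(seen_b)
        matrix.n_groups[frozenset((a, b))] = len(groups)
    return matrix


def average_group_size(matrix: OrthologCountMatrix, species: str) -> float:
    """Mean of ``n_orthologous(A, B) / n_groups(A, B)`` over partners of A.

    Partners sharing zero groups are excluded; if no partner has any
    group the statistic is undefined and a :class:`ValueError` is raised.
    """
    ratios = []
    for other in matrix.species:
        if other == species:
            continue
        n_groups = matrix.groups_between(species, other)
        if n_groups == 0:
            continue
        ratios.append(matrix.n_orthologous.get((species, other), 0) / n_groups)
    if not ratios:
        raise ValueError(f"no partner of {species!r} has any ortholog group")
    return float(np.mean(ratios))


def orthology_distance(total_a: int, n_orthologous_a_to_b: int) -> float:
    """``dAB = (total_A - n_orthologous_A_to_B) / total_A``."""
    if total_a <= 0:
        raise ValueError("total_A must be positive")
    if not 0 <= n_orthologous_a_to_b <= total_a:
        raise ValueError("n_orthologous must lie in [0, total_A]")
    return (total_a - n_orthologous_a_to_b) / total_a


def distance_matrices(
    matrix: OrthologCountMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Asymmetric dAB matrix and its symmetrization (dAB + dBA) / 2.

    A pair with zero surviving groups gets distance 1.0 (the formula's
    limit as the ortholog count goes to zero).
    """
    sp = matrix.species
    asym = pd.DataFrame(0.0, index=sp, columns=sp)
    for a in sp:
        for b in sp:
            if a == b:
                continue
            n = matrix.n_orthologous.get((a, b), 0)
            asym.loc[a, b] = orthology_distance(matrix.totals[a], n)
    sym = (asym + asym.T) / 2.0
    return asym, sym


@dataclass
class Clade:
    """Node of a rooted ultrametric tree; leaves have height 0."""

    height: float
    name: Optional[str] = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def min_leaf(self) -> str:
        if self.is_leaf:
            return self.name or ""
        return min(c.min_leaf for c in self.children)

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name or ""]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick_body(self) -> str:
        if self.is_leaf:
            return self.name or ""
        parts = []
        for c in sorted(self.children, key=lambda c: c.min_leaf):
            bl = self.height - c.height
            parts.append(f"{c.newick_body()}:{bl:.6g}")
        return "(" + ",".join(parts) + ")"


@dataclass
class UpgmaTree:
    """Rooted ultrametric species tree built from symmetrized distances."""

    root: Clade

    def newick(self) -> str:
        return self.root.newick_body() + ";"

    def leaf_labels(self) -> list[str]:
        return sorted(self.root.leaves())

    def topology(self) -> frozenset:
        """Label-set nesting structure, invariant to rotation and order."""

        def rec(clade: Clade):
            if clade.is_leaf:
                return clade.name
            return frozenset(rec(c) for c in clade.children)

        return rec(self.root)

    def leaf_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}

        def rec(clade: Clade, top: float) -> None:
            if clade.is_leaf:
                depths[clade.name or ""] = top
            for c in clade.children:
                rec(c, top)

        rec(self.root, self.root.height)
        return depths

    def is_ultrametric(self, tol: float = 1e-12) -> bool:
        depths = list(self.leaf_depths().values())
        return max(depths) - min(depths) <= tol


def upgma(distances: pd.DataFrame, tol: float = 1e-9) -> UpgmaTree:
    """Classical (size-weighted) UPGMA agglomeration.

    ``distances`` must be a square, symmetric, zero-diagonal,
    non-negative labelled matrix over at least two taxa.  At each step
    the closest pair of clusters merges at height d/2; cluster-to-rest
    distances are updated with size-weighted arithmetic means.  Ties are
    broken by the lexicographically smallest leaf label of the clusters
    involved, so the result is independent of input taxon order.
    """
    labels = list(distances.index)
    if len(labels) < 2:
        raise ValueError("UPGMA needs at least two taxa")
    if list(distances.columns) != labels:
        raise ValueError("distance matrix index and columns must match")
    arr = distances.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=tol):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=tol):
        raise ValueError("distance matrix must have a zero diagonal")
    if (arr < -tol).any():
        raise ValueError("distances must be non-negative")

    clusters: dict[str, tuple[Clade, int]] = {
        lab: (Clade(height=0.0, name=lab), 1) for lab in labels
    }
    dist: dict[frozenset, float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            dist[frozenset((a, b))] = float(distances.loc[a, b])

    while len(clusters) > 1:
        # closest pair; ties by sorted (min_leaf_i, min_leaf_j)
        best_key = min(
            dist,
            key=lambda k: (dist[k], *sorted(clusters[lab][0].min_leaf for lab in k)),
        )
        a, b = sorted(best_key, key=lambda lab: clusters[lab][0].min_leaf)
        d = dist.pop(best_key)
        clade_a, size_a = clusters.pop(a)
        clade_b, size_b = clusters.pop(b)
        merged = Clade(height=d / 2.0, children=[clade_a, clade_b])
        new_label = merged.min_leaf
        for other in list(clusters):
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((new_label, other))] = (size_a * da + size_b * db) / (
                size_a + size_b
            )
        clusters[new_label] = (merged, size_a + size_b)

    (root, _size) = next(iter(clusters.values()))
    return UpgmaTree(root=root)
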