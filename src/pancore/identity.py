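"""Average-identity matrix, Gower distance and agglomerative clade trees."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .orthologs import ClusterSet, SimilarityGraph


@dataclass
class Dendrogram:
    """Binary merge tree from agglomerative clustering.

    ``merges`` lists (left_members, right_members, height) in merge
    order; the merged group is the concatenation left + right.
    """

    leaves: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    linkage: str

    def __post_init__(self):
        heights = [m[2] for m in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    def to_newick(self) -> str:
        height_of = {(leaf,): 0.0 for leaf in self.leaves}
        newick = {(leaf,): leaf for leaf in self.leaves}
        for left, right, height in self.merges:
            bl = (height - height_of[left]) / 2.0
            br = (height - height_of[right]) / 2.0
            newick[left + right] = (
                f"({newick[left]}:{bl:.8g},{newick[right]}:{br:.8g})")
            height_of[left + right] = height
        root = (self.merges[-1][0] + self.merges[-1][1]) if self.merges \
            else (self.leaves[0],)
        return newick[root] + ";"

    def leaf_order(self) -> list[str]:
        if not self.merges:
            return list(self.leaves)
        return list(self.merges[-1][0] + self.merges[-1][1])


def average_identity_matrix(clusters: ClusterSet, hits: SimilarityGraph,
                            genome_ids: list[str] | None = None) -> pd.DataFrame:
    """Mean percent identity over co-clustered gene pairs per genome pair.

    Genome pairs sharing no cluster (or no stored hit) are imputed with
    the matrix minimum, with a warning, preserving least-similar
    semantics.  Diagonal is exactly 100.
    """
    if genome_ids is None:
        genome_ids = sorted(set(clusters.genome_of.values()))
    idx = {g: i for i, g in enumerate(genome_ids)}
    n = len(genome_ids)
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=int)
    for cluster in clusters:
        members = cluster.members
        for i, ga in enumerate(members):
            for gb in members[i + 1:]:
                va, vb = clusters.genome_of[ga], clusters.genome_of[gb]
                if va == vb or va not in idx or vb not in idx:
                    continue
                hit = hits.hit_for(ga, gb)
                if hit is None:
                    continue
                a, b = idx[va], idx[vb]
                total[a, b] += hit.identity
                total[b, a] += hit.identity
                count[a, b] += 1
                count[b, a] += 1
    with np.errstate(invalid="ignore"):
        mat = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    np.fill_diagonal(mat, 100.0)
    if np.isnan(mat).any():
        finite_min = np.nanmin(mat)
        warnings.warn("genome pairs with no shared cluster imputed with "
                      f"matrix minimum {finite_min:.2f}")
        mat = np.where(np.isnan(mat), finite_min, mat)
    return pd.DataFrame(mat, index=genome_ids, columns=genome_ids)


def gower_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean range-normalized absolute difference between matrix rows.

    Zero-range columns contribute 0 to the average.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 rows")
    X = matrix.values.astype(float)
    ranges = X.max(axis=0) - X.min(axis=0)
    safe = np.where(ranges > 0, ranges, 1.0)
    diffs = np.abs(X[:, None, :] - X[None, :, :]) / safe
    diffs[:, :, ranges == 0] = 0.0
    D = diffs.mean(axis=2)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


_LINKAGES = ("single", "complete", "average")


def hierarchical_cluster(dist: pd.DataFrame, linkage: str = "average"
                         ) -> Dendrogram:
    """Deterministic agglomeration; ties broken by lexicographic pair."""
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    D = dist.values.astype(float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    names = [str(x) for x in dist.index]
    if len(set(names)) != len(names):
        raise ValueError("duplicate labels")

    active: dict[str, tuple[str, ...]] = {n: (n,) for n in names}
    pos = {n: i for i, n in enumerate(names)}
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d[(min(a, b), max(a, b))] = float(D[pos[a], pos[b]])

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    while len(active) > 1:
        best = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), height = best
        sa, sb = active.pop(a), active.pop(b)
        name = min(a, b)
        for other in active:
            key_a = (min(a, other), max(a, other))
            key_b = (min(b, other), max(b, other))
            da, db = d.pop(key_a), d.pop(key_b)
            if linkage == "single":
                new = min(da, db)
            elif linkage == "complete":
                new = max(da, db)
            else:
                new = (len(sa) * da + len(sb) * db) / (len(sa) + len(sb))
            d[(min(name, other), max(name, other))] = new
        d.pop((min(a, b), max(a, b)))
        active[name] = sa + sb
        merges.append((sa, sb, height))
    return Dendrogram(leaves=names, merges=merges, linkage=linkage)


def extract_clades(dendro: Dendrogram, k: int) -> dict[str, str]:
    """Cut the dendrogram into exactly k groups (undo the last k-1 merges)."""
    n = len(dendro.leaves)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    groups: dict[tuple[str, ...], tuple[str, ...]] = {
        (leaf,): (leaf,) for leaf in dendro.leaves}
    for left, right, _ in dendro.merges[: n - k]:
        merged = groups.pop(left) + groups.pop(right)
        groups[left + right] = merged
    labels = {}
    ordered = sorted(groups.values(), key=min)
    for i, group in enumerate(ordered, 1):
        for leaf in group:
            labels[leaf] = f"clade{i}"
    return labels


def write_matrix(df: pd.DataFrame, path, index_label: str = "genome") -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index_label=index_label)
    return path


def read_matrix(path, index_label: str = "genome") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_label)
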