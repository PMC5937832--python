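"""Presence matrix, partitioning, rarefaction and presence-pattern screens.

Occupancy counts a genome once regardless of paralog copy number; copy
counts are kept in the matrix for the expansion analysis.  Partition
classes follow the standard occupancy bands: core = all genomes,
softcore >= ceil(0.95 * n), cloud <= 2 genomes, shell = everything in
between; softcore + shell + cloud always sums to the pan size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .orthologs import ClusterSet
from .seqs import GenomeSet

CLASSES = ("core", "softcore", "shell", "cloud")


@dataclass
class PresenceMatrix:
    """clusters x genomes copy-count matrix."""

    counts: pd.DataFrame  # index=cluster ids, columns=genome ids, int

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("copy counts must be non-negative")
        if (self.counts.sum(axis=1) == 0).any():
            raise ValueError("every cluster must appear in >= 1 genome")

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genomes(self) -> int:
        return self.counts.shape[1]

    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    def occupancy(self) -> pd.Series:
        return self.presence().sum(axis=1)

    def subset_genomes(self, genome_ids) -> "PresenceMatrix":
        sub = self.counts[list(genome_ids)]
        return PresenceMatrix(sub[sub.sum(axis=1) > 0])


@dataclass
class PartitionReport:
    cluster_class: pd.Series  # cluster id -> class
    n_genomes: int
    softcore_min: int

    @property
    def sizes(self) -> dict[str, int]:
        counts = self.cluster_class.value_counts()
        sizes = {cls: int(counts.get(cls, 0)) for cls in CLASSES}
        # core clusters are also softcore by definition
        sizes["softcore"] += sizes["core"]
        sizes["pan"] = len(self.cluster_class)
        return sizes

    def clusters_of(self, cls: str) -> set[str]:
        wanted = set(self.cluster_class[self.cluster_class == cls].index)
        if cls == "softcore":
            wanted |= set(self.cluster_class[self.cluster_class == "core"].index)
        return wanted


@dataclass
class RarefactionCurve:
    permutation: int
    order: list[str]
    pan: list[int]
    core: list[int]
    seed: int


def quality_filter(gene_counts: dict[str, int], k_sigma: float = 2.0
                   ) -> tuple[list[str], list[str]]:
    """Exclude genomes whose gene count falls outside mean +/- k*sigma.

    Single pass over all input genomes with the population (divide-by-n)
    standard deviation; with fewer than 3 genomes everything is kept.
    """
    if not gene_counts:
        raise ValueError("need at least one genome")
    ids = list(gene_counts)
    counts = np.array([gene_counts[g] for g in ids], dtype=float)
    if len(ids) < 3:
        warnings.warn("fewer than 3 genomes; +/- sigma filter not applied")
        return ids, []
    mean, sigma = counts.mean(), counts.std()  # population sigma
    lo, hi = mean - k_sigma * sigma, mean + k_sigma * sigma
    kept = [g for g, c in zip(ids, counts) if lo <= c <= hi]
    excluded = [g for g, c in zip(ids, counts) if not lo <= c <= hi]
    return kept, excluded


def build_presence_matrix(clusters: ClusterSet, genomes: GenomeSet
                          ) -> PresenceMatrix:
    """Copy counts per (cluster, genome); singleton clusters included."""
    genome_ids = genomes.genome_ids
    known = set(genomes.genes_by_id())
    col_index = {g: i for i, g in enumerate(genome_ids)}
    data = np.zeros((len(clusters), len(genome_ids)), dtype=int)
    cluster_ids = []
    for row, cluster in enumerate(clusters):
        cluster_ids.append(cluster.id)
        for gene in cluster.members:
            if gene not in known:
                raise ValueError(f"gene {gene} in cluster {cluster.id} "
                                 "absent from the genome set")
            data[row, col_index[clusters.genome_of[gene]]] += 1
    return PresenceMatrix(pd.DataFrame(data, index=cluster_ids,
                                       columns=genome_ids))


def partition_pangenome(matrix: PresenceMatrix) -> PartitionReport:
    """Classify clusters as core / softcore / shell / cloud by occupancy."""
    n = matrix.n_genomes
    if n < 3:
        raise ValueError("partitioning needs >= 3 genomes")
    softcore_min = math.ceil(0.95 * n)
    occ = matrix.occupancy()

    def classify(o: int) -> str:
        if o == n:
            return "core"
        if o >= softcore_min:
            return "softcore"
        if o <= 2:
            return "cloud"
        return "shell"

    classes = occ.map(classify)
    classes.name = "class"
    return PartitionReport(classes, n_genomes=n, softcore_min=softcore_min)


def rarefaction_curves(matrix: PresenceMatrix, n_permutations: int,
                       seed: int) -> list[RarefactionCurve]:
    """Pan/core sizes along randomized genome addition orders."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    presence = matrix.presence().values  # clusters x genomes
    genome_ids = matrix.genome_ids
    curves = []
    for p in range(n_permutations):
        perm = rng.permutation(len(genome_ids))
        cols = presence[:, perm]
        any_so_far = np.logical_or.accumulate(cols, axis=1)
        all_so_far = np.logical_and.accumulate(cols, axis=1)
        curves.append(RarefactionCurve(
            permutation=p,
            order=[genome_ids[i] for i in perm],
            pan=any_so_far.sum(axis=0).astype(int).tolist(),
            core=all_so_far.sum(axis=0).astype(int).tolist(),
            seed=seed,
        ))
    return curves


def classify_openness(curves: list[RarefactionCurve],
                      tail_window: int | None = None,
                      closed_slope: float = 5.0) -> tuple[str, float]:
    """Open vs closed call from the mean marginal pan gain in the tail."""
    if not curves:
        raise ValueError("no curves")
    n = len(curves[0].pan)
    if tail_window is None:
        tail_window = max(5, n // 5)
    tail_window = min(tail_window, n - 1)
    if tail_window < 1:
        raise ValueError("too few genomes for a tail window")
    slopes = [(c.pan[-1] - c.pan[-1 - tail_window]) / tail_window for c in curves]
    slope = float(np.mean(slopes))
    return ("closed" if slope <= closed_slope else "open"), slope


def clade_specific_genes(matrix: PresenceMatrix, clade_a, clade_b
                         ) -> tuple[list[str], list[str]]:
    """Clusters private to clade A, and copy-number expansions in A vs B.

    Specific: >= 1 copy in every A genome and 0 copies in every B genome.
    Expansion: present in every A genome with min copies over A strictly
    above the max over B.
    """
    a, b = list(clade_a), list(clade_b)
    if not a or not b:
        raise ValueError("clades must be non-empty")
    if set(a) & set(b):
        raise ValueError("clades overlap")
    counts = matrix.counts
    missing = (set(a) | set(b)) - set(counts.columns)
    if missing:
        raise ValueError(f"genomes not in matrix: {sorted(missing)}")
    in_all_a = (counts[a] > 0).all(axis=1)
    absent_b = (counts[b] == 0).all(axis=1)
    specific = counts.index[in_all_a & absent_b].tolist()
    expanded = counts.index[in_all_a &
                            (counts[a].min(axis=1) > counts[b].max(axis=1))]
    return specific, expanded.tolist()


def hgt_screen(matrix: PresenceMatrix, clades: dict[str, str],
               low: float = 0.30, high: float = 0.70) -> pd.DataFrame:
    """Clusters whose presence fraction is inside [low, high] in EVERY clade.

    Returns a DataFrame of candidates (rows) with one per-clade fraction
    column.
    """
    by_clade: dict[str, list[str]] = {}
    for genome in matrix.genome_ids:
        if genome not in clades:
            raise ValueError(f"genome {genome} missing a clade label")
        by_clade.setdefault(clades[genome], []).append(genome)
    if len(by_clade) < 2:
        raise ValueError("need >= 2 clades")
    for clade, members in by_clade.items():
        if len(members) < 2:
            raise ValueError(f"clade {clade} has fewer than 2 genomes")
    presence = matrix.presence()
    fractions = pd.DataFrame({
        clade: presence[members].sum(axis=1) / len(members)
        for clade, members in sorted(by_clade.items())
    })
    mask = ((fractions >= low) & (fractions <= high)).all(axis=1)
    return fractions[mask]


# ---------------------------------------------------------------- TSV I/O

def write_matrix_tsv(matrix: PresenceMatrix, path) -> Path:
    path = Path(path)
    matrix.counts.to_csv(path, sep="\t", index_label="cluster")
    return path


def read_matrix_tsv(path) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="cluster")
    return PresenceMatrix(df.astype(int))


def write_partition_tsv(report: PartitionReport, path) -> Path:
    path = Path(path)
    df = report.cluster_class.to_frame()
    df.to_csv(path, sep="\t", index_label="cluster")
    return path


def write_rarefaction_tsv(curves: list[RarefactionCurve], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("permutation\tstep\tpan\tcore\n")
        for curve in curves:
            for step, (pan, core) in enumerate(zip(curve.pan, curve.core), 1):
                fh.write(f"{curve.permutation}\t{step}\t{pan}\t{core}\n")
    return path
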