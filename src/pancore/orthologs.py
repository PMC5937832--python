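"""Protein similarity graph and Markov clustering of ortholog families.

Stands in for a blastp + OMCL stage: genes are compared by local
alignment (BLOSUM62, affine gaps 11/1), hits are converted to
Karlin-Altschul E-values and gated on E-value and bidirectional
coverage, and the resulting weighted graph is clustered with plain MCL
(expansion / inflation / prune until convergence).

An exact all-vs-all Smith-Waterman is quadratic in the gene count, so
candidate pairs are pre-screened with a shared amino-acid k-mer filter
(the same role word seeding plays in BLAST); unrelated random proteins
essentially never share two 5-mers.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqs import GenomeSet

# published gapped BLOSUM62 constants; configurable via estimate_evalue args
KA_LAMBDA = 0.267
KA_K = 0.041

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
AA_ALPHABET = set(_BLOSUM62.alphabet)


class MCLConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: str
    score: float
    identity: float       # percent, over aligned columns
    query_cov: float      # aligned span / query length
    subject_cov: float
    e_value: float


@dataclass
class SimilarityGraph:
    """Undirected gene graph; edge weights are -log10 E-values."""

    graph: nx.Graph
    genome_of: dict[str, str]
    hits: dict[tuple[str, str], SimilarityHit] = field(default_factory=dict)

    def hit_for(self, a: str, b: str) -> SimilarityHit | None:
        return self.hits.get((min(a, b), max(a, b)))


@dataclass(frozen=True)
class OrthologCluster:
    id: str
    members: tuple[str, ...]


@dataclass
class ClusterSet:
    clusters: list[OrthologCluster]
    genome_of: dict[str, str]

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self):
        return len(self.clusters)

    def copy_counts(self, cluster: OrthologCluster) -> dict[str, int]:
        counts: Counter = Counter(self.genome_of[g] for g in cluster.members)
        return dict(counts)

    def membership(self) -> dict[str, str]:
        return {g: c.id for c in self.clusters for g in c.members}


def _make_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _validate_protein(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"{label}: non-amino-acid characters {sorted(bad)}")


def align_pair(a: str, b: str, db_residues: int | None = None,
               aligner: Align.PairwiseAligner | None = None) -> SimilarityHit:
    """Optimal local alignment of two proteins under BLOSUM62 11/1.

    Identity is computed over aligned columns (gaps counted as
    mismatches); coverage is the aligned span divided by the full
    sequence length, for each sequence.
    """
    _validate_protein(a, "query")
    _validate_protein(b, "subject")
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return SimilarityHit("query", "subject", 0.0, 0.0, 0.0, 0.0, np.inf)
    matches = 0
    columns = 0
    prev_a = prev_b = None
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            columns += (sa - prev_a) + (sb - prev_b)  # gap columns
        seg_a, seg_b = a[sa:ea], b[sb:eb]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
        columns += ea - sa
        prev_a, prev_b = ea, eb
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    score = float(aln.score)
    e_value = estimate_evalue(max(score, 0.0), len(a), len(b), db_residues)
    return SimilarityHit(
        query="query", subject="subject", score=score,
        identity=100.0 * matches / columns,
        query_cov=span_a / len(a), subject_cov=span_b / len(b),
        e_value=e_value,
    )


def estimate_evalue(score: float, m: int, n: int,
                    db_residues: int | None = None,
                    K: float = KA_K, lam: float = KA_LAMBDA) -> float:
    """Karlin-Altschul expectation E = K * m * N * exp(-lambda * S).

    ``N`` is the searched residue total (``db_residues``), defaulting to
    the subject length for a single pairwise comparison.
    """
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    if score < 0:
        raise ValueError("score must be >= 0")
    N = db_residues if db_residues is not None else n
    if N <= 0:
        raise ValueError("db_residues must be positive")
    return float(K * m * N * np.exp(-lam * score))


def _kmer_candidates(genes: dict[str, str], k: int = 5, step: int = 2,
                     min_shared: int = 2) -> set[tuple[str, str]]:
    """Gene pairs sharing >= min_shared sampled k-mers."""
    index: dict[str, list[str]] = {}
    for gid, seq in genes.items():
        for i in range(0, max(len(seq) - k + 1, 0), step):
            index.setdefault(seq[i:i + k], []).append(gid)
    shared: Counter = Counter()
    for bucket in index.values():
        if len(bucket) < 2 or len(bucket) > 2000:
            continue
        for pair in itertools.combinations(sorted(set(bucket)), 2):
            shared[pair] += 1
    return {pair for pair, cnt in shared.items() if cnt >= min_shared}


def build_similarity_graph(genomes: GenomeSet, e_max: float = 1e-5,
                           cov_min: float = 0.75, kmer: int = 5,
                           kmer_step: int = 2,
                           min_shared_kmers: int = 2) -> SimilarityGraph:
    """Gate pairwise hits on E-value and bidirectional coverage.

    An edge (g, h) exists iff e_value < e_max and both coverages are
    >= cov_min.  Edge weight is -log10(E), floored at E = 1e-200.
    """
    gene_seqs = {g.id: g.aa for genome in genomes for g in genome.genes}
    if len(gene_seqs) < 2:
        raise ValueError("need at least 2 genes")
    genome_of = genomes.genome_of()
    db_residues = sum(len(s) for s in gene_seqs.values())
    aligner = _make_aligner()

    graph = nx.Graph()
    graph.add_nodes_from(gene_seqs)
    hits: dict[tuple[str, str], SimilarityHit] = {}
    for ga, gb in sorted(_kmer_candidates(gene_seqs, kmer, kmer_step,
                                          min_shared_kmers)):
        hit = align_pair(gene_seqs[ga], gene_seqs[gb],
                         db_residues=db_residues, aligner=aligner)
        hit = SimilarityHit(ga, gb, hit.score, hit.identity,
                            hit.query_cov, hit.subject_cov, hit.e_value)
        hits[(ga, gb)] = hit
        if (hit.e_value < e_max and hit.query_cov >= cov_min
                and hit.subject_cov >= cov_min):
            weight = -np.log10(max(hit.e_value, 1e-200))
            graph.add_edge(ga, gb, weight=float(weight))
    return SimilarityGraph(graph=graph, genome_of=genome_of, hits=hits)


def _mcl_component(adj: np.ndarray, inflation: float, prune: float,
                   tol: float, max_iter: int) -> list[list[int]]:
    n = adj.shape[0]
    M = adj.astype(float).copy()
    np.fill_diagonal(M, 0.0)
    # self-loops at each column's maximum stabilize the iteration
    col_max = M.max(axis=0)
    col_max[col_max == 0.0] = 1.0
    np.fill_diagonal(M, col_max)
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = M @ M
        inflated = expanded ** inflation
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0.0] = 1.0
        inflated /= colsum
        delta = np.abs(inflated - M).max()
        M = inflated
        if delta < tol:
            break
    else:
        raise MCLConvergenceError(f"MCL did not converge in {max_iter} iterations")
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(M > prune)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return [sorted(c) for c in nx.connected_components(support)]


def mcl_cluster(graph: SimilarityGraph | nx.Graph, inflation: float = 1.5,
                prune: float = 1e-6, tol: float = 1e-6,
                max_iter: int = 200) -> ClusterSet:
    """Markov clustering; runs per connected component (components never merge)."""
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    if isinstance(graph, SimilarityGraph):
        g, genome_of = graph.graph, graph.genome_of
    else:
        g, genome_of = graph, {n: str(n) for n in graph.nodes}
    member_groups: list[tuple[str, ...]] = []
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) == 1:
            member_groups.append((nodes[0],))
            continue
        sub = g.subgraph(nodes)
        adj = nx.to_numpy_array(sub, nodelist=nodes, weight="weight")
        for block in _mcl_component(adj, inflation, prune, tol, max_iter):
            member_groups.append(tuple(nodes[i] for i in block))
    member_groups.sort(key=lambda ms: ms[0])
    clusters = [OrthologCluster(f"C{i:05d}", ms)
                for i, ms in enumerate(member_groups)]
    return ClusterSet(clusters, genome_of)


def write_clusters_tsv(clusters: ClusterSet, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("cluster_id\tgene_id\tgenome_id\n")
        for cluster in clusters:
            for gene in cluster.members:
                fh.write(f"{cluster.id}\t{gene}\t{clusters.genome_of[gene]}\n")
    return path


def write_hits_tsv(graph: SimilarityGraph, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("query\tsubject\tscore\tidentity\tquery_cov\tsubject_cov\te_value\n")
        for (a, b), hit in sorted(graph.hits.items()):
            fh.write(f"{a}\t{b}\t{hit.score:g}\t{hit.identity:.6g}\t"
                     f"{hit.query_cov:.6g}\t{hit.subject_cov:.6g}\t{hit.e_value:.6g}\n")
    return path


def read_hits_tsv(path) -> SimilarityGraph:
    """Rebuild a hit store (graph edges are not restored) from TSV."""
    hits: dict[tuple[str, str], SimilarityHit] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("query"):
            raise ValueError(f"{path}: missing similarity TSV header")
        for line in fh:
            a, b, score, ident, qc, sc, ev = line.rstrip("\n").split("\t")
            hits[(a, b)] = SimilarityHit(a, b, float(score), float(ident),
                                         float(qc), float(sc), float(ev))
    return SimilarityGraph(graph=nx.Graph(), genome_of={}, hits=hits)


def read_clusters_tsv(path) -> ClusterSet:
    members: dict[str, list[str]] = {}
    genome_of: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("cluster_id"):
            raise ValueError(f"{path}: missing cluster TSV header")
        for line in fh:
            cid, gene, genome = line.rstrip("\n").split("\t")
            members.setdefault(cid, []).append(gene)
            genome_of[gene] = genome
    clusters = [OrthologCluster(cid, tuple(members[cid]))
                for cid in sorted(members)]
    return ClusterSet(clusters, genome_of)
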