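"""Per-gene alignment, distance trees and topological tree comparison.

Trees are unrooted, leaf-labeled, with branch lengths, held as a plain
adjacency map.  The nodal score between two trees on the same leaf set
is the RMSD of their leaf-pair path-length matrices, with path lengths
counted in edges on the unrooted topology (degree-2 nodes are
contracted first, so rooted Newick input compares correctly).
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import Align

_GAP = "-"
_BASES = "ACGT"


# ------------------------------------------------------------------ MSA

@dataclass
class MSA:
    names: list[str]
    rows: list[str]
    cluster_id: str | None = None

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("aligned rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def subset(self, names) -> "MSA":
        wanted = list(names)
        return MSA(wanted, [self.row(n) for n in wanted], self.cluster_id)


def _nt_aligner() -> Align.PairwiseAligner:
    # gap penalties deliberately harsh relative to mismatches so that
    # substitution-only homologs align gap-free (spurious shift gaps
    # would otherwise corrupt column coordinates)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -4.0
    return aligner


def _pair_distance(a: str, b: str, aligner: Align.PairwiseAligner) -> float:
    if len(a) == len(b):  # cheap path; identical to alignment for no-indel data
        return sum(x != y for x, y in zip(a, b))
    return -float(aligner.align(a, b).score)


def center_star_align(seqs: dict[str, str] | list[tuple[str, str]],
                      cluster_id: str | None = None) -> MSA:
    """Center-star multiple alignment ("once a gap, always a gap").

    The center is the sequence minimizing the summed pairwise distance;
    every other sequence is pairwise globally aligned against it and the
    alignments are merged on the center's coordinates.
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if len(items) < 2:
        raise ValueError("need >= 2 sequences")
    for name, s in items:
        if not s:
            raise ValueError(f"{name}: empty sequence")
        if set(s) - set(_BASES):
            raise ValueError(f"{name}: non-ACGT characters")
    names = [n for n, _ in items]
    seq_of = dict(items)
    aligner = _nt_aligner()

    sums = {n: 0.0 for n in names}
    for i, (na, sa) in enumerate(items):
        for nb, sb in items[i + 1:]:
            dd = _pair_distance(sa, sb, aligner)
            sums[na] += dd
            sums[nb] += dd
    center = min(names, key=lambda n: (sums[n], n))
    cseq = seq_of[center]
    L = len(cseq)

    # per sequence: gap runs in the center row before each center residue
    gapped: dict[str, tuple[str, str]] = {}
    ins: dict[str, list[int]] = {}
    for name in names:
        if name == center:
            continue
        aln = aligner.align(cseq, seq_of[name])[0]
        cg, sg = str(aln[0]), str(aln[1])
        runs = [0] * (L + 1)
        p = 0
        for ch in cg:
            if ch == _GAP:
                runs[p] += 1
            else:
                p += 1
        gapped[name] = (cg, sg)
        ins[name] = runs
    master = [0] * (L + 1)
    for runs in ins.values():
        for p, r in enumerate(runs):
            master[p] = max(master[p], r)

    rows = []
    for name in names:
        if name == center:
            out = []
            for p in range(L):
                out.append(_GAP * master[p] + cseq[p])
            out.append(_GAP * master[L])
            rows.append("".join(out))
            continue
        cg, sg = gapped[name]
        out = []
        p = 0
        i = 0
        pending: list[str] = []
        for j, ch in enumerate(cg):
            if ch == _GAP:
                pending.append(sg[j])
            else:
                out.append(_GAP * (master[p] - len(pending)) + "".join(pending))
                out.append(sg[j])
                pending = []
                p += 1
        out.append(_GAP * (master[L] - len(pending)) + "".join(pending))
        rows.append("".join(out))
    return MSA(names, rows, cluster_id)


def write_msa_fasta(msa: MSA, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, row in zip(msa.names, msa.rows):
            fh.write(f">{name}\n{row}\n")
    return path


def read_msa_fasta(path, cluster_id: str | None = None) -> MSA:
    names, rows, current = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if current:
                    rows.append("".join(current))
                    current = []
                names.append(line[1:].split()[0])
            elif line:
                current.append(line)
    if current:
        rows.append("".join(current))
    return MSA(names, rows, cluster_id)


# --------------------------------------------------------- JC distances

JC_DEFAULT_CAP = 5.0


@dataclass
class DistanceMatrix:
    names: list[str]
    matrix: np.ndarray
    capped_pairs: set[tuple[str, str]] = field(default_factory=set)


def jc_distance_matrix(msa: MSA, d_max: float = JC_DEFAULT_CAP
                       ) -> DistanceMatrix:
    """Jukes-Cantor distances with pairwise deletion of gapped sites.

    p >= 0.75 (formula undefined) is capped at ``d_max`` and flagged.
    """
    if len(msa.rows) < 2:
        raise ValueError("need >= 2 rows")
    arr = np.array([list(r) for r in msa.rows], dtype="U1")
    ungapped = arr != _GAP
    n = len(msa.names)
    D = np.zeros((n, n))
    capped: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            both = ungapped[i] & ungapped[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"{msa.names[i]} vs {msa.names[j]}: no comparable columns")
            p = float((arr[i, both] != arr[j, both]).sum()) / m
            if p >= 0.75:
                d = d_max
                capped.add((msa.names[i], msa.names[j]))
            else:
                d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            D[i, j] = D[j, i] = d
    if capped:
        warnings.warn(f"{len(capped)} pair(s) hit the JC cap d_max={d_max}")
    return DistanceMatrix(msa.names, D, capped)


# ----------------------------------------------------------------- Tree

@dataclass
class Tree:
    """Unrooted leaf-labeled tree as an adjacency map with branch lengths."""

    adjacency: dict[str, dict[str, float]]
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def leaves(self) -> set[str]:
        return {n for n, nbrs in self.adjacency.items()
                if len(nbrs) == 1 and not n.startswith("_")}

    def copy(self) -> "Tree":
        return Tree({n: dict(nb) for n, nb in self.adjacency.items()},
                    dict(self.supports))

    def to_newick(self, decimals: int = 8) -> str:
        leaves = sorted(self.leaves)
        if len(self.adjacency) == 1:
            return f"{leaves[0]};"
        root = next(n for n in sorted(self.adjacency)
                    if len(self.adjacency[n]) > 1)

        def render(node: str, parent: str | None) -> str:
            children = [c for c in sorted(self.adjacency[node]) if c != parent]
            if not children:
                return node
            inner = ",".join(
                f"{render(c, node)}:{self.adjacency[node][c]:.{decimals}g}"
                for c in children)
            return f"({inner})"

        return render(root, None) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        adjacency: dict[str, dict[str, float]] = {}
        counter = [0]
        names: dict[int, str] = {}

        def name_of(node) -> str:
            if id(node) in names:
                return names[id(node)]
            if node.taxon is not None:
                label = node.taxon.label.replace(" ", "_")
            else:
                label = f"_I{counter[0]}"
                counter[0] += 1
            names[id(node)] = label
            return label

        for node in dt.preorder_node_iter():
            name_of(node)
        for edge in dt.preorder_edge_iter():
            if edge.head_node is None or edge.tail_node is None:
                continue
            a = name_of(edge.tail_node)
            b = name_of(edge.head_node)
            length = edge.length if edge.length is not None else 1.0
            adjacency.setdefault(a, {})[b] = float(length)
            adjacency.setdefault(b, {})[a] = float(length)
        return cls(adjacency)


def _contracted_adjacency(tree: Tree) -> dict[str, dict[str, float]]:
    adj = {n: dict(nb) for n, nb in tree.adjacency.items()}
    leaves = tree.leaves
    changed = True
    while changed:
        changed = False
        for node in list(adj):
            if node in leaves or node not in adj:
                continue
            nbrs = adj[node]
            if len(nbrs) == 2:
                (a, la), (b, lb) = nbrs.items()
                del adj[node]
                del adj[a][node]
                del adj[b][node]
                adj[a][b] = la + lb
                adj[b][a] = la + lb
                changed = True
    return adj


def path_length_matrix(tree: Tree) -> pd.DataFrame:
    """Leaf-pair path lengths in edge counts on the contracted topology."""
    adj = _contracted_adjacency(tree)
    leaves = sorted(tree.leaves)
    mat = pd.DataFrame(0, index=leaves, columns=leaves, dtype=int)
    for src in leaves:
        dist = {src: 0}
        queue = deque([src])
        while queue:
            node = queue.popleft()
            for nbr in adj[node]:
                if nbr not in dist:
                    dist[nbr] = dist[node] + 1
                    queue.append(nbr)
        for dst in leaves:
            mat.loc[src, dst] = dist[dst]
    return mat


def nodal_distance(t1: Tree, t2: Tree) -> float:
    """RMSD of the two path-length matrices over all leaf pairs."""
    l1, l2 = t1.leaves, t2.leaves
    if l1 != l2:
        only1, only2 = sorted(l1 - l2), sorted(l2 - l1)
        raise ValueError(f"leaf sets differ: only in first {only1}, "
                         f"only in second {only2}")
    leaves = sorted(l1)
    p1 = path_length_matrix(t1).loc[leaves, leaves].values
    p2 = path_length_matrix(t2).loc[leaves, leaves].values
    iu = np.triu_indices(len(leaves), k=1)
    diffs = p1[iu].astype(float) - p2[iu].astype(float)
    return float(np.sqrt(np.mean(diffs ** 2)))


def bipartitions(tree: Tree) -> set[frozenset]:
    """Non-trivial leaf splits, canonicalized to the side without the
    lexicographically smallest leaf."""
    adj = _contracted_adjacency(tree)
    leaves = sorted(tree.leaves)
    anchor = leaves[0]
    splits: set[frozenset] = set()
    seen_edges = set()
    for a in adj:
        for b in adj[a]:
            key = (min(a, b), max(a, b))
            if key in seen_edges:
                continue
            seen_edges.add(key)
            # leaves on b's side when edge (a,b) is removed
            side = set()
            queue = deque([b])
            visited = {a, b}
            while queue:
                node = queue.popleft()
                if node in tree.leaves:
                    side.add(node)
                for nbr in adj[node]:
                    if nbr not in visited:
                        visited.add(nbr)
                        queue.append(nbr)
            if anchor in side:
                side = set(leaves) - side
            if 2 <= len(side) <= len(leaves) - 2:
                splits.add(frozenset(side))
    return splits


# ------------------------------------------------------------------- NJ

def nj_tree(dist: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q-minimization are broken on the lexicographically
    smallest node-name pair; negative branch estimates are clamped to 0.
    """
    names = list(dist.names)
    if len(names) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if len(set(names)) != len(names):
        raise ValueError("duplicate taxon names")
    D = {a: {} for a in names}
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if a != b:
                D[a][b] = float(dist.matrix[i, j])

    adjacency: dict[str, dict[str, float]] = {}
    next_internal = [0]

    def link(a: str, b: str, length: float):
        length = max(length, 0.0)
        adjacency.setdefault(a, {})[b] = length
        adjacency.setdefault(b, {})[a] = length

    active = sorted(names)
    while len(active) > 3:
        n = len(active)
        r = {a: sum(D[a][b] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * D[a][b] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        u = f"_N{next_internal[0]}"
        next_internal[0] += 1
        la = D[a][b] / 2.0 + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = D[a][b] - la
        link(a, u, la)
        link(b, u, lb)
        D[u] = {}
        for c in active:
            if c in (a, b):
                continue
            duc = (D[a][c] + D[b][c] - D[a][b]) / 2.0
            D[u][c] = duc
            D[c][u] = duc
        active = sorted([c for c in active if c not in (a, b)] + [u])
    a, b, c = active
    u = f"_N{next_internal[0]}"
    link(a, u, (D[a][b] + D[a][c] - D[b][c]) / 2.0)
    link(b, u, (D[a][b] + D[b][c] - D[a][c]) / 2.0)
    link(c, u, (D[a][c] + D[b][c] - D[a][b]) / 2.0)
    return Tree(adjacency)


# ------------------------------------------------- random-tree baseline

def random_topology(leaves, rng: np.random.Generator) -> Tree:
    """Uniformly distributed unrooted binary topology on the leaf set.

    Built by attaching leaves in order to a uniformly chosen existing
    edge (each of the (2n-5)!! topologies is equally likely)."""
    leaves = sorted(leaves)
    if len(leaves) < 4:
        raise ValueError("need >= 4 leaves")
    adjacency: dict[str, dict[str, float]] = {}
    counter = [0]

    def link(a, b):
        adjacency.setdefault(a, {})[b] = 1.0
        adjacency.setdefault(b, {})[a] = 1.0

    center = "_R0"
    counter[0] = 1
    for leaf in leaves[:3]:
        link(leaf, center)
    for leaf in leaves[3:]:
        edges = sorted((min(a, b), max(a, b))
                       for a in adjacency for b in adjacency[a])
        edges = sorted(set(edges))
        a, b = edges[int(rng.integers(len(edges)))]
        new = f"_R{counter[0]}"
        counter[0] += 1
        del adjacency[a][b]
        del adjacency[b][a]
        link(a, new)
        link(b, new)
        link(leaf, new)
    return Tree(adjacency)


def random_tree_baseline(leaves, focal: Tree, n_random: int = 10,
                         seed: int = 0) -> tuple[float, float]:
    """Mean and sd of the nodal distance from random topologies to ``focal``."""
    leaves = sorted(leaves)
    if len(leaves) < 4:
        raise ValueError("need >= 4 leaves")
    rng = np.random.default_rng(seed)
    scores = [nodal_distance(random_topology(leaves, rng), focal)
              for _ in range(n_random)]
    return float(np.mean(scores)), float(np.std(scores, ddof=1))


# -------------------------------------------------------------- bootstrap

def bootstrap_support(msa: MSA, n_replicates: int = 100, seed: int = 0
                      ) -> Tree:
    """NJ tree with bipartition supports from column resampling."""
    base = nj_tree(jc_distance_matrix(msa))
    splits = bipartitions(base)
    if not splits or n_replicates < 1:
        return base
    rng = np.random.default_rng(seed)
    arr = np.array([list(r) for r in msa.rows], dtype="U1")
    counts = {s: 0 for s in splits}
    for _ in range(n_replicates):
        cols = rng.integers(0, msa.length, size=msa.length)
        rep_rows = ["".join(row) for row in arr[:, cols]]
        rep = MSA(msa.names, rep_rows)
        try:
            rep_splits = bipartitions(nj_tree(jc_distance_matrix(rep)))
        except ValueError:
            continue
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    base.supports = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    return base


# ------------------------------------------------------ gene-tree screen

@dataclass
class NodalReport:
    table: pd.DataFrame          # per-gene scores and annotations
    lower_cut: float
    upper_cut: float
    lower_tail: list[str]
    upper_tail: list[str]
    skipped: list[str]

    def tail_summary(self, tail: str) -> dict[str, float]:
        genes = self.lower_tail if tail == "lower" else self.upper_tail
        sub = self.table.loc[genes]
        return {
            "mean_nodal": float(sub["nodal_distance"].mean()),
            "sd_nodal": float(sub["nodal_distance"].std(ddof=1)),
            "mean_length": float(sub["length"].mean()),
            "mean_snp_per_kb": float((sub["sum_snp"] /
                                      (sub["length"] / 1000.0)).mean()),
        }


def gene_tree_screen(msas: dict[str, MSA], reference: Tree,
                     n_random: int = 10, seed: int = 0,
                     lower_pct: float = 5.0, upper_pct: float = 95.0,
                     snp_reports: dict | None = None) -> NodalReport:
    """Per-gene NJ trees vs the reference; percentile tail memberships.

    Genes whose strains are not covered by the reference leaf set are
    logged and skipped.  Both the raw nodal RMSD and the random-baseline
    normalized score are reported.
    """
    if len(msas) < 20:
        warnings.warn("fewer than 20 genes; percentile tails are unstable")
    ref_leaves = reference.leaves
    rows = []
    skipped = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(msas))
    for (fam, msa), sub_seed in zip(sorted(msas.items()), child_seeds):
        if set(msa.names) != ref_leaves:
            warnings.warn(f"{fam}: leaf set mismatch with reference; skipped")
            skipped.append(fam)
            continue
        tree = nj_tree(jc_distance_matrix(msa))
        score = nodal_distance(tree, reference)
        bmean, bsd = random_tree_baseline(msa.names, tree,
                                          n_random=n_random,
                                          seed=int(sub_seed))
        length = len(msa.rows[0].replace(_GAP, ""))
        sum_snp = poly = np.nan
        if snp_reports and fam in snp_reports:
            rep = snp_reports[fam]
            sum_snp = rep.sum_snp
            poly = rep.polyvariable_positions
            length = rep.length
        rows.append({
            "gene": fam, "nodal_distance": score,
            "baseline_mean": bmean, "baseline_sd": bsd,
            "normalized": score / bmean if bmean > 0 else np.nan,
            "length": length, "sum_snp": sum_snp,
            "polyvariable": poly,
        })
    if not rows:
        raise ValueError("no gene could be compared to the reference")
    table = pd.DataFrame(rows).set_index("gene")
    scores = table["nodal_distance"].values
    lower_cut, upper_cut = np.percentile(scores, [lower_pct, upper_pct])
    if lower_cut == upper_cut:
        warnings.warn("degenerate nodal distribution; tails are empty")
    lower_tail = table.index[scores < lower_cut].tolist()
    upper_tail = table.index[scores > upper_cut].tolist()
    return NodalReport(table, float(lower_cut), float(upper_cut),
                       lower_tail, upper_tail, skipped)


def write_nodal_report_tsv(report: NodalReport, path) -> Path:
    path = Path(path)
    table = report.table.copy()
    table["snp_per_base"] = table["sum_snp"] / table["length"]
    table["tail"] = [
        "lower" if g in report.lower_tail
        else "upper" if g in report.upper_tail else ""
        for g in table.index
    ]
    table.to_csv(path, sep="\t", index_label="gene")
    return path
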