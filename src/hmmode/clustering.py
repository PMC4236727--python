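"""Similarity graphs and Markov clustering of sequence families.

Before profile building, each labelled family can be split into
fold-coherent clusters (separating isozymes and subunits filed under one
function) by running the Markov Cluster algorithm on an all-vs-all
similarity graph.  The graph can come from an internal shared-k-mer
measure or be imported from BLAST tabular output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


@dataclass
class SimilarityGraph:
    """Undirected weighted graph over sequence ids (no self-loops stored)."""

    nodes: List[str] = field(default_factory=list)
    edges: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def add_node(self, node: str) -> None:
        if node not in self._index:
            self._index[node] = len(self.nodes)
            self.nodes.append(node)

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            return
        if not np.isfinite(weight) or weight < 0:
            raise ValueError(f"edge weight must be finite and >= 0, got {weight}")
        self.add_node(a)
        self.add_node(b)
        key = (a, b) if a < b else (b, a)
        self.edges[key] = max(self.edges.get(key, 0.0), weight)

    def __post_init__(self):
        self._index = {n: i for i, n in enumerate(self.nodes)}

    def weight_matrix(self) -> np.ndarray:
        n = len(self.nodes)
        W = np.zeros((n, n))
        for (a, b), w in self.edges.items():
            i, j = self._index[a], self._index[b]
            W[i, j] = W[j, i] = w
        return W

    def to_abc(self, path) -> None:
        """Write the edge list in the three-column 'abc' format."""
        with open(path, "w") as fh:
            for (a, b), w in sorted(self.edges.items()):
                fh.write(f"{a}\t{b}\t{w:.6g}\n")

    @classmethod
    def from_abc(cls, path) -> "SimilarityGraph":
        g = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(f"line {lineno}: expected 3 columns")
                g.add_edge(parts[0], parts[1], float(parts[2]))
        return g


def _kmer_set(seq: str, k: int) -> Set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_similarity(pool: Sequence, k: int = 3) -> SimilarityGraph:
    """All-vs-all shared-k-mer similarity.

    Edge weight is the number of distinct shared k-mers divided by the
    smaller sequence's distinct k-mer count, hence in [0, 1].  Sequences
    shorter than k are skipped with a warning.  *pool* items need ``id``
    and ``seq`` attributes.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    g = SimilarityGraph()
    usable = []
    for rec in pool:
        if len(rec.seq) <= k:
            warnings.warn(f"sequence {rec.id!r} shorter than k={k}; skipped")
            continue
        usable.append((rec.id, _kmer_set(rec.seq, k)))
        g.add_node(rec.id)
    for i in range(len(usable)):
        id_i, set_i = usable[i]
        for j in range(i + 1, len(usable)):
            id_j, set_j = usable[j]
            shared = len(set_i & set_j)
            if shared:
                g.add_edge(id_i, id_j, shared / min(len(set_i), len(set_j)))
    return g


def import_blast_tab(source) -> SimilarityGraph:
    """Build a graph from 12-column BLAST tabular (-outfmt 6) rows.

    Weight is the bit-score column (12), symmetrized by maximum; self-hits
    are dropped.  *source* is a path or an iterable of lines.
    """
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            lines = fh.readlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = list(source)
    g = SimilarityGraph()
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 12:
            raise ValueError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(parts)}"
            )
        query, subject = parts[0], parts[1]
        try:
            bits = float(parts[11])
        except ValueError:
            raise ValueError(f"line {lineno}: bad bit-score field {parts[11]!r}")
        g.add_node(query)
        g.add_node(subject)
        if query != subject:
            g.add_edge(query, subject, bits)
    return g


def mcl_cluster(
    g: SimilarityGraph,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> List[Set[str]]:
    """Markov clustering: alternate expansion and inflation to convergence.

    Each node first receives a self-loop equal to its maximum incident
    weight (1 for isolated nodes); the matrix is made column-stochastic,
    then repeatedly squared (expansion) and entrywise powered/renormalized
    (inflation) until the largest column change falls below *tol*.
    Clusters are the connected components of the converged matrix's
    non-zero pattern; the result is a partition of all nodes.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if not g.nodes:
        raise ValueError("empty graph")
    W = g.weight_matrix()
    n = W.shape[0]
    loop = W.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(W, loop)
    T = W / W.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        prev = T
        T = T @ T
        T = np.power(T, inflation)
        colsum = T.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        T = T / colsum
        T[T < 1e-12] = 0.0
        colsum = T.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        T = T / colsum
        if np.abs(T - prev).max() < tol:
            break

    support = csr_matrix((T + T.T) > 1e-7)
    n_comp, labels = connected_components(support, directed=False)
    clusters: List[Set[str]] = [set() for _ in range(n_comp)]
    for idx, lab in enumerate(labels):
        clusters[lab].add(g.nodes[idx])
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return clusters


def write_assignments(clusters: Iterable[Set[str]], path) -> None:
    """Cluster assignments as a two-column TSV (id, cluster index)."""
    with open(path, "w") as fh:
        fh.write("id\tcluster\n")
        for ci, members in enumerate(clusters):
            for sid in sorted(members):
                fh.write(f"{sid}\t{ci}\n")
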