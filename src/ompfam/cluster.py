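"""Markov clustering and greedy centroid clustering.

``mcl`` is a native implementation of the Markov Cluster algorithm on a
weighted undirected similarity graph: self-loops are added, the
adjacency matrix is column-normalized to a stochastic matrix, and the
process alternates expansion (matrix power) with inflation (entrywise
power + renormalization) and pruning until the matrix stops changing.
The limit is interpreted as usual: nodes with positive diagonal mass are
attractors, and each attractor's row support is a cluster.

``greedy_centroid`` reduces a sequence set at an identity threshold the
way fast centroid-based tools do: sequences are scanned in decreasing
length and each joins the first existing centroid it matches at or above
the threshold, else it seeds a new cluster.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import math

import numpy as np

from . import _align
from .io import SequenceRecord
from .pairwise import AlignmentParams, PairHit


@dataclass
class SimilarityGraph:
    """Undirected weighted graph; edges keyed (i, j) by node order, i < j."""

    nodes: list[str]
    edges: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        index = {n: i for i, n in enumerate(self.nodes)}
        if len(index) != len(self.nodes):
            raise ValueError("duplicate node ids in graph")
        self._index = index
        for (i, j), w in self.edges.items():
            if i >= j:
                raise ValueError(f"edge ({i},{j}) must have i < j")
            if not (w >= 0 and math.isfinite(w)):
                raise ValueError(f"edge ({i},{j}) weight {w} invalid")

    def add_edge(self, a: str, b: str, weight: float) -> None:
        i, j = self._index[a], self._index[b]
        if i == j:
            return  # self-loops are not stored
        if i > j:
            i, j = j, i
        self.edges[(i, j)] = max(self.edges.get((i, j), 0.0), weight)

    def edges_by_name(self) -> dict[tuple[str, str], float]:
        return {(self.nodes[i], self.nodes[j]): w
                for (i, j), w in self.edges.items()}

    def to_matrix(self) -> np.ndarray:
        n = len(self.nodes)
        mat = np.zeros((n, n))
        for (i, j), w in self.edges.items():
            mat[i, j] = w
            mat[j, i] = w
        return mat


@dataclass
class Clustering:
    """A partition of ids into non-empty clusters, optionally labeled."""

    clusters: list[set[str]]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if not c:
                raise ValueError("empty cluster")
            if seen & c:
                raise ValueError(f"clusters overlap on {sorted(seen & c)[:3]}")
            seen |= c
        if self.labels is not None and len(self.labels) != len(self.clusters):
            raise ValueError("labels length must match clusters")

    @property
    def ids(self) -> set[str]:
        return set().union(*self.clusters) if self.clusters else set()

    def membership(self) -> dict[str, int]:
        return {m: k for k, c in enumerate(self.clusters) for m in c}


@dataclass
class MclOptions:
    inflation: float = 1.5
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iter: int = 100
    convergence_tol: float = 1e-9
    selfloop_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")


def default_weight(e: float, cap: float = 200.0) -> float:
    """Edge weight from an E-value: -log10(E), floored at 1e-200, capped."""
    return min(cap, -math.log10(max(e, 1e-200)))


def build_graph(pair_hits: Iterable[PairHit],
                weight_rule: Callable[[float], float] | None = None,
                evalue_cutoff: float = 1e-2,
                nodes: Sequence[str] | None = None) -> SimilarityGraph:
    """Similarity graph from pair hits with E <= cutoff.

    ``nodes``, when given, fixes the node set (isolated nodes included);
    otherwise nodes are the ids appearing in retained hits, in first-seen
    order. Parallel hits keep the heavier weight.
    """
    weight_rule = weight_rule or default_weight
    hits = [h for h in pair_hits if h.evalue <= evalue_cutoff and h.id_a != h.id_b]
    if nodes is None:
        ordered: list[str] = []
        seen: set[str] = set()
        for h in hits:
            for nid in (h.id_a, h.id_b):
                if nid not in seen:
                    seen.add(nid)
                    ordered.append(nid)
        nodes = ordered
    graph = SimilarityGraph(nodes=list(nodes))
    known = set(graph.nodes)
    for h in hits:
        if h.id_a in known and h.id_b in known:
            graph.add_edge(h.id_a, h.id_b, weight_rule(h.evalue))
    return graph


def mcl(graph: SimilarityGraph, options: MclOptions | None = None) -> Clustering:
    """Markov clustering of a similarity graph.

    Returns a partition: attractor-row supports, with nodes that appear
    in several supports assigned to the cluster of the smallest-index
    attractor. Isolated nodes come out as singletons. Non-convergence at
    ``max_iter`` raises a warning and interprets the current matrix.
    """
    options = options or MclOptions()
    if not graph.nodes:
        raise ValueError("empty graph")
    n = len(graph.nodes)
    M = graph.to_matrix()
    np.fill_diagonal(M, options.selfloop_weight)
    M /= M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(options.max_iter):
        prev = M
        M = np.linalg.matrix_power(M, options.expansion)
        M = np.power(M, options.inflation)
        M /= M.sum(axis=0, keepdims=True)
        M[M < options.prune_threshold] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0.0] = 1.0
        M /= colsum
        if np.max(np.abs(M - prev)) < options.convergence_tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iter; "
                      "interpreting the current matrix", RuntimeWarning)
    assigned: dict[int, int] = {}
    clusters_idx: list[list[int]] = []
    for a in range(n):
        if M[a, a] <= 0.0:
            continue
        support = np.flatnonzero(M[a, :] > 0.0)
        members = [int(j) for j in support if j not in assigned]
        if not members:
            continue
        k = len(clusters_idx)
        for j in members:
            assigned[j] = k
        clusters_idx.append(members)
    for j in range(n):  # nodes outside every attractor support: singletons
        if j not in assigned:
            assigned[j] = len(clusters_idx)
            clusters_idx.append([j])
    clusters = [{graph.nodes[j] for j in members} for members in clusters_idx]
    return Clustering(clusters=clusters)


def greedy_centroid(records: Sequence[SequenceRecord], identity_threshold: float,
                    params: AlignmentParams | None = None,
                    min_columns: int = 0,
                    ) -> tuple[Clustering, list[str]]:
    """Greedy centroid clustering at an identity threshold.

    Sequences are processed in decreasing length (ties by id); each joins
    the FIRST centroid with local-alignment identity >= threshold, else
    seeds a new cluster. Returns the clustering and centroid ids in
    creation order.

    ``min_columns`` > 0 additionally requires the qualifying alignment to
    span at least that many columns, guarding against degenerate
    high-identity matches over a handful of residues. The floor also
    yields a provable score lower bound for qualifying alignments (from
    the matrix's smallest diagonal entry and the worst per-column gap
    cost), letting a cheap score-only pass skip hopeless comparisons.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError("identity_threshold must be in (0, 1]")
    params = params or AlignmentParams()
    ordered = sorted(records, key=lambda r: (-len(r.residues), r.id))
    codes = {r.id: _align.encode(r.residues) for r in ordered}
    go, ge = float(params.gap_open), float(params.gap_extend)
    # any alignment with >= min_columns columns and identity >= t scores at
    # least min_columns * (t * min_diag - (1 - t) * (go + ge))
    min_diag = float(min(params.matrix[i, i] for i in range(20)))
    per_col = identity_threshold * min_diag - (1 - identity_threshold) * (go + ge)
    score_bound = max(0.0, min_columns * per_col) if min_columns > 0 else 0.0
    centroids: list[SequenceRecord] = []
    cen_rows: list[np.ndarray] = []
    clusters: list[set[str]] = []
    for rec in ordered:
        cb = codes[rec.id]
        placed = False
        for k, cen in enumerate(centroids):
            if score_bound > 0.0:
                if _align.sw_score(cen_rows[k], cb, go, ge) < score_bound:
                    continue
            ca = codes[cen.id]
            _, _, _, _, _, matches, cols = _align.sw_align(
                cen_rows[k], ca, cb, go, ge)
            identity = matches / cols if cols else 0.0
            if identity >= identity_threshold and cols >= min_columns:
                clusters[k].add(rec.id)
                placed = True
                break
        if not placed:
            centroids.append(rec)
            cen_rows.append(np.ascontiguousarray(params.matrix[codes[rec.id]]))
            clusters.append({rec.id})
    return Clustering(clusters=clusters), [c.id for c in centroids]


def write_clustering(clustering: Clustering, path: str | Path,
                     centroids: Sequence[str] | None = None) -> Path:
    """TSV export: cluster_id, member_id, is_centroid."""
    path = Path(path)
    centroid_set = set(centroids or [])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["cluster_id", "member_id", "is_centroid"])
        for k, members in enumerate(clustering.clusters):
            label = clustering.labels[k] if clustering.labels else f"cluster_{k}"
            for m in sorted(members):
                writer.writerow([label, m, int(m in centroid_set)])
    return path


def write_graph(graph: SimilarityGraph, path: str | Path) -> Path:
    """Edge-list TSV export: source, target, weight."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["source", "target", "weight"])
        for (i, j), w in sorted(graph.edges.items()):
            writer.writerow([graph.nodes[i], graph.nodes[j], f"{w:.4f}"])
    return path
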