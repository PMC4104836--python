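"""Sequence similarity networks and taxonomic distribution matrices.

Networks are built per region (full-length, barrel, N-terminus, POTRA):
the region's sequences are first reduced with greedy centroid clustering
(default identity 0.80; the POTRA path uses 0.50), then all centroids
are aligned all-vs-all and pairs below the E-value cutoff become edges
weighted -log10(E). Self-loops are never stored. Distribution matrices
follow the complete-proteome convention: a phylum/subfamily cell is the
percentage of the phylum's complete genomes containing at least one
member; phyla without complete genomes yield missing values, not zeros.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .cluster import Clustering, SimilarityGraph, build_graph, greedy_centroid
from .io import SequenceRecord, TaxonRecord
from .pairwise import AlignmentParams, PairHit, all_vs_all

ATTRIBUTE_KEYS = ("subfamily", "phylum", "region", "potra_index")


@dataclass
class AttributedNetwork:
    """A similarity graph whose nodes carry subfamily/phylum/region labels."""

    graph: SimilarityGraph
    node_attributes: dict[str, dict[str, str]] = field(default_factory=dict)
    reduction: Clustering | None = None
    centroids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for node in self.graph.nodes:
            attrs = self.node_attributes.setdefault(node, {})
            for key in ATTRIBUTE_KEYS:
                attrs.setdefault(key, "unknown")


def build_network(region_records: Sequence[SequenceRecord],
                  identity_reduction: float = 0.80,
                  evalue_cutoff: float = 1e-5,
                  attributes: Mapping[str, Mapping[str, str]] | None = None,
                  params: AlignmentParams | None = None,
                  precomputed_hits: Iterable[PairHit] | None = None,
                  min_columns: int = 0,
                  ) -> AttributedNetwork:
    """Reduce a region dataset to centroids and connect them by similarity.

    ``precomputed_hits`` may supply an existing all-vs-all hit table for
    (a superset of) the records; it is filtered to centroid pairs at the
    cutoff instead of re-aligning. ``min_columns`` is the reduction's
    alignment-coverage floor (see :func:`ompfam.cluster.greedy_centroid`).
    """
    attributes = attributes or {}
    reduction, centroid_ids = greedy_centroid(region_records,
                                              identity_reduction, params,
                                              min_columns=min_columns)
    centroid_set = set(centroid_ids)
    by_id = {r.id: r for r in region_records}
    centroid_records = [by_id[c] for c in centroid_ids]
    if precomputed_hits is not None:
        hits = [h for h in precomputed_hits
                if h.evalue <= evalue_cutoff and h.id_a != h.id_b
                and h.id_a in centroid_set and h.id_b in centroid_set]
    elif len(centroid_records) >= 2:
        hits = all_vs_all(centroid_records, params, evalue_cutoff,
                          include_self=False)
    else:
        hits = []
    graph = build_graph(hits, evalue_cutoff=evalue_cutoff, nodes=centroid_ids)
    node_attrs = {c: dict(attributes.get(c, {})) for c in centroid_ids}
    return AttributedNetwork(graph=graph, node_attributes=node_attrs,
                             reduction=reduction, centroids=centroid_ids)


def components(network: AttributedNetwork | SimilarityGraph) -> list[set[str]]:
    """Connected components, ordered by their smallest node id."""
    graph = network.graph if isinstance(network, AttributedNetwork) else network
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    for (i, j), w in graph.edges.items():
        g.add_edge(graph.nodes[i], graph.nodes[j], weight=w)
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: min(c))
    return comps


def presence_matrix(assignments: Mapping[str, tuple[str, str]],
                    taxa: Sequence[TaxonRecord]) -> pd.DataFrame:
    """Percent of complete genomes per phylum containing each subfamily.

    ``assignments`` maps id -> (subfamily, taxon_id). Taxa not flagged
    complete are excluded entirely; a phylum with zero complete genomes
    gets missing values (NaN), never 0.
    """
    complete = {t.taxon_id: t.phylum for t in taxa if t.complete_proteome}
    phyla = sorted({t.phylum for t in taxa})
    genomes_per_phylum = {p: sum(1 for ph in complete.values() if ph == p)
                          for p in phyla}
    subfamilies = sorted({sf for sf, _ in assignments.values()})
    hits: dict[tuple[str, str], set[str]] = {}
    for sf, taxon in assignments.values():
        phylum = complete.get(taxon)
        if phylum is None:
            continue
        hits.setdefault((phylum, sf), set()).add(taxon)
    mat = pd.DataFrame(index=phyla, columns=subfamilies, dtype=float)
    for p in phyla:
        for sf in subfamilies:
            n = genomes_per_phylum[p]
            if n == 0:
                continue  # undefined, stays NaN
            mat.loc[p, sf] = 100.0 * len(hits.get((p, sf), set())) / n
    mat.index.name = "phylum"
    return mat


def copy_numbers(assignments: Mapping[str, tuple[str, str]],
                 taxa: Sequence[TaxonRecord]) -> pd.DataFrame:
    """Per-taxon gene copy counts per subfamily, complete proteomes only."""
    complete = [t.taxon_id for t in taxa if t.complete_proteome]
    subfamilies = sorted({sf for sf, _ in assignments.values()})
    mat = pd.DataFrame(0, index=complete, columns=subfamilies, dtype=int)
    complete_set = set(complete)
    for sf, taxon in assignments.values():
        if taxon in complete_set:
            mat.loc[taxon, sf] += 1
    mat.index.name = "taxon_id"
    return mat


def write_network(network: AttributedNetwork, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>_edges.tsv`` (source, target, weight) and
    ``<prefix>_nodes.tsv`` (id + attributes)."""
    prefix = Path(prefix)
    edges_path = prefix.parent / (prefix.name + "_edges.tsv")
    nodes_path = prefix.parent / (prefix.name + "_nodes.tsv")
    graph = network.graph
    with open(edges_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["source", "target", "weight"])
        for (i, j), w in sorted(graph.edges.items()):
            writer.writerow([graph.nodes[i], graph.nodes[j], f"{w:.4f}"])
    with open(nodes_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", *ATTRIBUTE_KEYS])
        for node in graph.nodes:
            attrs = network.node_attributes[node]
            writer.writerow([node, *(attrs.get(k, "unknown")
                                     for k in ATTRIBUTE_KEYS)])
    return edges_path, nodes_path
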