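import numpy as np
import pytest

from oracles import mcl_reference

from ompfam.cluster import (Clustering, MclOptions, SimilarityGraph,
                            build_graph, default_weight, greedy_centroid, mcl)
from ompfam.io import AMINO_ACIDS, SequenceRecord
from ompfam.pairwise import PairHit, align_local


def _hit(a, b, e):
    return PairHit(id_a=a, id_b=b, raw_score=50, evalue=e, identity=0.5,
                   a_start=1, a_end=10, b_start=1, b_end=10)


class TestBuildGraph:
    def test_weight_is_negative_log10(self):
        g = build_graph([_hit("a", "b", 1e-10)])
        assert g.edges[(0, 1)] == pytest.approx(10.0)

    def test_zero_evalue_capped(self):
        g = build_graph([_hit("a", "b", 0.0)])
        assert g.edges[(0, 1)] == 200.0

    def test_cutoff_drops_weak_hits(self):
        g = build_graph([_hit("a", "b", 0.1)], evalue_cutoff=1e-2,
                        nodes=["a", "b"])
        assert g.edges == {}

    def test_fixed_node_set_keeps_isolated_nodes(self):
        g = build_graph([_hit("a", "b", 1e-5)], nodes=["a", "b", "c"])
        assert g.nodes == ["a", "b", "c"]


def _triangle_graph(weights_extra=()):
    """Two unit-weight triangles, optionally joined by extra edges."""
    nodes = list("abcdef")
    g = SimilarityGraph(nodes=nodes)
    for x, y in [("a", "b"), ("b", "c"), ("a", "c"),
                 ("d", "e"), ("e", "f"), ("d", "f")]:
        g.add_edge(x, y, 1.0)
    for x, y, w in weights_extra:
        g.add_edge(x, y, w)
    return g


class TestMcl:
    def test_disconnected_components_never_merge(self):
        g = _triangle_graph()
        clustering = mcl(g, MclOptions(inflation=1.2))
        assert sorted(map(sorted, clustering.clusters)) == \
            [["a", "b", "c"], ["d", "e", "f"]]

    def test_single_node_is_singleton(self):
        g = SimilarityGraph(nodes=["only"])
        clustering = mcl(g)
        assert clustering.clusters == [{"only"}]

    def test_weak_bridge_splits_at_inflation_two(self):
        g = _triangle_graph([("c", "d", 0.25)])
        clustering = mcl(g, MclOptions(inflation=2.0))
        assert sorted(map(sorted, clustering.clusters)) == \
            [["a", "b", "c"], ["d", "e", "f"]]
        # the independent fixed-point implementation agrees
        ref = mcl_reference(g.nodes, g.edges_by_name(), inflation=2.0)
        assert {frozenset(c) for c in clustering.clusters} == set(ref)

    def test_partition_property_on_random_graphs(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            nodes = [f"n{i}" for i in range(n)]
            g = SimilarityGraph(nodes=nodes)
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        g.add_edge(nodes[i], nodes[j],
                                   float(rng.choice([0.5, 1.0, 2.0])))
            clustering = mcl(g, MclOptions(inflation=1.5))
            covered = sorted(m for c in clustering.clusters for m in c)
            assert covered == sorted(nodes)  # coverage + disjointness

    def test_determinism(self):
        g1 = _triangle_graph([("c", "d", 0.25)])
        g2 = _triangle_graph([("c", "d", 0.25)])
        assert mcl(g1).clusters == mcl(g2).clusters

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            MclOptions(inflation=1.0)


class TestGreedyCentroid:
    def _records(self, seqs):
        return [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]

    def test_identical_sequences_one_cluster(self):
        recs = self._records(["MKLVANWGRTEDSYHQ"] * 4)
        clustering, centroids = greedy_centroid(recs, 0.8)
        assert len(clustering.clusters) == 1
        assert centroids == ["s0"]  # tie on length -> id order

    def test_dissimilar_sequences_all_singletons(self):
        rng = np.random.default_rng(9)
        recs = [SequenceRecord(f"s{i}", "".join(
            AMINO_ACIDS[j] for j in rng.integers(0, 20, 100)))
            for i in range(5)]
        # precondition: every pairwise identity is below the threshold
        for i in range(5):
            for j in range(i + 1, 5):
                assert align_local(recs[i], recs[j]).identity < 0.95
        clustering, centroids = greedy_centroid(recs, 0.95)
        assert len(centroids) == 5

    def test_first_match_rule(self):
        # seq0 longest; seq1 and seq2 both within threshold of seq0
        base = "MKLVANWGRTEDSYHQCFIPMKLVANWGRTEDSYHQCFIP"
        seq1 = base[:-2] + "GG"   # high identity to base
        seq2 = base[:-4] + "GGGG"
        recs = [SequenceRecord("s0", base), SequenceRecord("s1", seq1),
                SequenceRecord("s2", seq2)]
        ident01 = align_local(recs[0], recs[1]).identity
        ident02 = align_local(recs[0], recs[2]).identity
        assert ident01 >= 0.8 and ident02 >= 0.8
        clustering, centroids = greedy_centroid(recs, 0.8)
        assert centroids == ["s0"]
        assert clustering.clusters == [{"s0", "s1", "s2"}]

    def test_members_reach_threshold_to_their_centroid(self):
        rng = np.random.default_rng(10)
        base = "".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, 60))
        recs = []
        for i in range(12):
            seq = list(base)
            for p in rng.choice(60, size=int(rng.integers(0, 12)), replace=False):
                seq[p] = AMINO_ACIDS[rng.integers(0, 20)]
            recs.append(SequenceRecord(f"s{i}", "".join(seq)))
        clustering, centroids = greedy_centroid(recs, 0.85)
        by_id = {r.id: r for r in recs}
        for members, cen in zip(clustering.clusters, centroids):
            for m in members:
                if m != cen:
                    hit = align_local(by_id[cen], by_id[m])
                    assert hit.identity >= 0.85

    def test_min_columns_floor_blocks_short_matches(self):
        # 8-residue exact overlap inside otherwise unrelated sequences
        shared = "WWCHHMYW"
        a = SequenceRecord("a", "AG" * 20 + shared + "TS" * 20)
        b = SequenceRecord("b", "KD" * 20 + shared + "NE" * 20)
        no_floor, _ = greedy_centroid([a, b], 0.8, min_columns=0)
        floored, _ = greedy_centroid([a, b], 0.8, min_columns=50)
        assert len(no_floor.clusters) == 1      # degenerate short match merges
        assert len(floored.clusters) == 2       # floor keeps them apart

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            greedy_centroid([SequenceRecord("a", "ACDE")], 0.0)


class TestClustering:
    def test_overlapping_clusters_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            Clustering(clusters=[{"a", "b"}, {"b", "c"}])

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            Clustering(clusters=[set()])
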