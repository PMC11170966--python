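"""Fingerprints, Tanimoto, novelty, MST clustering, groups and IDs."""

import random

import networkx as nx
import pytest
from rdkit import DataStructs

from sideroscreen.fixtures import VETO_PARENT
from sideroscreen.simnet import (FingerprintSet, SimilarityGraph, assign_ids,
                                 build_joint_graph, define_groups,
                                 extract_clusters, fingerprint,
                                 fingerprint_set, infer_biosynthetic_type,
                                 is_novel, max_similarity_to_known, tanimoto)
from conftest import brute_force_mst_weight, record


def bitvec(bits, length=64):
    v = DataStructs.ExplicitBitVect(length)
    for b in bits:
        v.SetBit(b)
    return v


def fps_from_bits(bit_map, length=64):
    fps = FingerprintSet(scheme="circular-bitvector", radius=2, n_bits=length)
    fps.vectors = {rid: bitvec(bits, length) for rid, bits in bit_map.items()}
    return fps


class TestTanimoto:
    def test_identical_molecules_give_one(self, references):
        fp = fingerprint(references[0])
        assert tanimoto(fp, fp) == 1.0

    def test_set_overlap_value(self):
        assert tanimoto(bitvec({1, 2, 3}), bitvec({2, 3, 4})) == pytest.approx(0.5)

    def test_disjoint_sets_give_zero(self):
        assert tanimoto(bitvec({1, 2}), bitvec({5, 6})) == 0.0

    def test_chemically_sensible_ordering(self):
        ethanol = fingerprint(record("e", "CCO"))
        propanol = fingerprint(record("p", "CCCO"))
        octane = fingerprint(record("o", "CCCCCCCC"))
        assert tanimoto(ethanol, octane) < tanimoto(ethanol, propanol)

    def test_regeneration_is_bit_identical(self, references):
        for rec in references[:4]:
            assert fingerprint(rec) == fingerprint(rec)

    def test_distance_triangle_inequality(self):
        rng = random.Random(11)
        for _ in range(200):
            a, b, c = (
                bitvec({i for i in range(64) if rng.random() < 0.3})
                for _ in range(3)
            )
            dab = 1 - tanimoto(a, b)
            dbc = 1 - tanimoto(b, c)
            dac = 1 - tanimoto(a, c)
            assert dac <= dab + dbc + 1e-12


class TestNovelty:
    def test_member_of_knownset_has_similarity_one(self, references):
        fps = fingerprint_set(references)
        _, best = max_similarity_to_known(fps["F1"], fps)
        assert best == 1.0 and not is_novel(best)

    def test_tiny_molecule_is_novel(self, references):
        fps = fingerprint_set(references)
        methane = fingerprint(record("m", "C"))
        _, best = max_similarity_to_known(methane, fps)
        assert best < 0.1 and is_novel(best)

    def test_near_analog_is_not_novel(self, references, vetoed):
        fps = fingerprint_set(references)
        for construct in vetoed:
            best_id, best = max_similarity_to_known(fingerprint(construct), fps)
            assert best > 0.60 and not is_novel(best)
            assert best_id == VETO_PARENT[construct.record_id]

    def test_empty_knownset_errors(self):
        empty = FingerprintSet(scheme="circular-bitvector", radius=2, n_bits=64)
        with pytest.raises(ValueError, match="empty"):
            max_similarity_to_known(bitvec({1}), empty)


def dummy_records(ids, tag="knownset"):
    return [record(i, "CCO", source_tag=tag) for i in ids]


class TestJointGraph:
    def test_three_node_mst_uses_two_cheapest_edges(self):
        # crafted bit sets: d(a,b)=0.1, d(a,c)=0.2, d(b,c) larger
        fps = fps_from_bits({
            "a": set(range(9)),
            "b": set(range(10)),          # T(a,b) = 9/10
            "c": set(range(8)) | {20},    # T(a,c) = 8/10
        })
        g = build_joint_graph(dummy_records(["a", "b"]),
                              dummy_records(["c"], tag="background"),
                              k=2, fps=fps)
        pairs = {frozenset(e[:2]) for e in g.mst_edges}
        assert pairs == {frozenset({"a", "b"}), frozenset({"a", "c"})}

    def test_duplicate_molecule_adds_zero_weight_edge(self):
        recs = dummy_records(["a", "b"]) + [record("a2", "CCO", source_tag="knownset")]
        g = build_joint_graph(recs, k=2)
        zero = [e for e in g.mst_edges if e[2] == 0.0]
        assert len(zero) >= 1

    def test_mst_invariants(self, references, decoys):
        g = build_joint_graph(references, decoys, k=5)
        tree = g.mst()
        n = g.graph.number_of_nodes()
        assert tree.number_of_edges() == n - 1
        assert nx.is_connected(tree)
        assert nx.is_tree(tree)

    def test_disconnected_knn_graph_is_bridged(self):
        fps = fps_from_bits({
            "a": {1, 2, 3}, "b": {1, 2, 3, 4},
            "c": {40, 41, 42}, "d": {40, 41, 42, 43},
        })
        g = build_joint_graph(dummy_records(["a", "b", "c", "d"]), k=1, fps=fps)
        assert g.n_bridges >= 1
        assert nx.is_connected(g.mst())

    def test_mst_weight_matches_brute_force_on_random_graphs(self):
        """100 seeded random graphs of 4-8 nodes vs exhaustive enumeration."""
        for seed in range(100):
            rng = random.Random(seed)
            n = rng.randint(4, 8)
            ids = [f"n{i}" for i in range(n)]
            edges = []
            g = nx.Graph()
            g.add_nodes_from(ids)
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.7 or j == i + 1:  # keep connected
                        w = round(rng.random(), 6)
                        g.add_edge(ids[i], ids[j], weight=w)
                        edges.append((i, j, w))
            from sideroscreen.simnet import _mst_edges_scipy
            import numpy as np
            dist = np.zeros((n, n))
            for i, j, w in edges:
                dist[i, j] = dist[j, i] = w
            mst_edges = _mst_edges_scipy(ids, dist, g)
            total = sum(w for _, _, w in mst_edges)
            expect = brute_force_mst_weight(n, edges)
            assert total == pytest.approx(expect, abs=1e-9), seed


def chain_graph(sequence):
    """SimilarityGraph whose MST is a path over (id, tag) pairs."""
    g = nx.Graph()
    tags = {}
    for rid, tag in sequence:
        g.add_node(rid, source_tag=tag)
        tags[rid] = tag
    edges = []
    for (u, _), (v, _) in zip(sequence, sequence[1:]):
        g.add_edge(u, v, weight=0.5)
        edges.append((u, v, 0.5))
    return SimilarityGraph(graph=g, mst_edges=edges, source_tags=tags)


class TestClusters:
    def test_background_separates_chain(self):
        g = chain_graph([("k1", "knownset"), ("k2", "knownset"),
                         ("b1", "background"), ("k3", "knownset")])
        clusters = extract_clusters(g)
        assert clusters.cluster_sizes == {1: 2, 2: 1}
        assert clusters.cluster_of["k3"] == 2

    def test_no_background_gives_one_cluster(self, references):
        g = build_joint_graph(references, k=5)
        clusters = extract_clusters(g)
        assert clusters.n_clusters == 1
        assert clusters.cluster_sizes[1] == len(references)

    def test_size_rank_with_deterministic_ties(self):
        g = chain_graph([("b", "knownset"), ("x1", "background"),
                         ("a", "knownset"), ("x2", "background"),
                         ("c", "knownset")])
        clusters = extract_clusters(g)
        # three singleton clusters; tie broken by smallest member id
        assert clusters.members(1) == ["a"]
        assert clusters.members(2) == ["b"]
        assert clusters.members(3) == ["c"]

    def test_invariant_to_duplicate_background(self, references, decoys):
        base = extract_clusters(build_joint_graph(references, decoys, k=5))
        doubled = decoys + [
            record(f"{d.record_id}_dup", d.smiles_raw, source_tag="background")
            for d in decoys
        ]
        again = extract_clusters(build_joint_graph(references, doubled, k=5))
        assert base.cluster_of == again.cluster_of


class TestGroupsAndIDs:
    def test_two_blocks_two_groups(self):
        fps = fps_from_bits({
            "a1": {1, 2, 3, 4}, "a2": {1, 2, 3, 5},
            "b1": {40, 41, 42, 43}, "b2": {40, 41, 42, 44},
        })
        groups = define_groups(["a1", "a2", "b1", "b2"], fps, 0.6)
        assert sorted(map(sorted, groups)) == [["a1", "a2"], ["b1", "b2"]]

    def test_threshold_one_plus_epsilon_gives_singletons(self):
        fps = fps_from_bits({"a": {1, 2}, "b": {1, 2, 3}})
        groups = define_groups(["a", "b"], fps, 1.0)
        # only exact duplicates join at threshold 1
        assert len(groups) == 2

    def test_low_threshold_gives_one_group(self, references):
        fps = fingerprint_set(references)
        groups = define_groups([r.record_id for r in references], fps, 1e-9)
        assert len(groups) == 1

    def test_assign_ids_injective_and_append_stable(self):
        partition = {1: [["a", "b", "c"], ["d"]], 2: [["e"]]}
        ids = assign_ids(partition)
        assert len({str(v) for v in ids.values()}) == len(ids)
        assert str(ids["a"]) == "1.1.1" and str(ids["d"]) == "1.2.1"
        assert str(ids["e"]) == "2.1.1"
        grown = {1: [["a", "b", "c", "new"], ["d"]], 2: [["e"]]}
        ids2 = assign_ids(grown)
        for rid, sid in ids.items():
            assert ids2[rid] == sid
        assert str(ids2["new"]) == "1.1.4"

    def test_duplicate_membership_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            assign_ids({1: [["a"], ["a"]]})


class TestBiosyntheticInference:
    def test_majority_with_unknowns(self):
        call = infer_biosynthetic_type("1.1", ["NRPS", "NRPS", "unknown"])
        assert call.inferred_type == "NRPS" and not call.is_mixed

    def test_two_known_types_is_mixed(self):
        call = infer_biosynthetic_type("1.5", ["NRPS", "NIS"])
        assert call.is_mixed

    def test_all_unknown_stays_unknown(self):
        call = infer_biosynthetic_type("3.1", ["unknown", "unknown"])
        assert call.inferred_type == "unknown" and not call.is_mixed

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            infer_biosynthetic_type("1.1", [])
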