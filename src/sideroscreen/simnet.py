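"""Fingerprint similarity, novelty, and MST chemical-space clustering.

Siderophore chemical space is mapped the way large natural-product
libraries are commonly visualized: every molecule gets a circular
(Morgan/ECFP-like) fingerprint, a k-nearest-neighbour graph is built under
Tanimoto distance (1 - Tanimoto similarity), and a minimum spanning tree
of that graph gives the backbone of the space. Clusters of known
siderophores are the connected components that remain among ``knownset``
nodes after background natural products are deleted from the tree —
background molecules act as separators between siderophore islands.
Cluster indexes are 1-based and size-ranked (cluster 1 is the largest).

Within a cluster, *groups* are connected components of the pairwise
similarity graph thresholded at a structure-similarity coefficient
(default 0.60, the same threshold used for novelty). Every structure then
receives an ``x.y.z`` ID: cluster ``x``, group ``y`` within the cluster
(size-ranked), record ``z`` within the group (input order), which is
stable under append-only growth of the library.

Novelty of a candidate is its maximum Tanimoto similarity to the known
set; at most 0.60 the candidate counts as novel chemistry.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree as _scipy_mst

from .chemio import MoleculeRecord, mol_from_record

NOVELTY_THRESHOLD = 0.60  # max Tanimoto to knownset at/below which a
                          # candidate counts as novel
DEFAULT_RADIUS = 2
DEFAULT_NBITS = 2048
DEFAULT_KNN = 20

__all__ = [
    "FingerprintSet",
    "SimilarityGraph",
    "ClusterAssignment",
    "StructureID",
    "BiosyntheticCall",
    "fingerprint",
    "fingerprint_set",
    "tanimoto",
    "max_similarity_to_known",
    "is_novel",
    "build_joint_graph",
    "extract_clusters",
    "define_groups",
    "assign_ids",
    "infer_biosynthetic_type",
    "similarity_matrix",
]


@dataclass
class FingerprintSet:
    """Fingerprints for a set of records, all under one scheme."""

    scheme: str
    radius: int
    n_bits: int
    vectors: dict[str, DataStructs.ExplicitBitVect] = field(default_factory=dict)

    def __getitem__(self, record_id: str) -> DataStructs.ExplicitBitVect:
        return self.vectors[record_id]

    def __len__(self) -> int:
        return len(self.vectors)

    def ids(self) -> list[str]:
        return list(self.vectors)


def _generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def fingerprint(
    record: MoleculeRecord | Chem.Mol,
    scheme: str = "circular-bitvector",
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_NBITS,
) -> DataStructs.ExplicitBitVect:
    """Circular substructure bit-vector fingerprint (Morgan, radius 2, 2048
    bits by default). Regeneration from the same molecule is bit-identical."""
    if scheme != "circular-bitvector":
        raise ValueError(f"unsupported fingerprint scheme {scheme!r}")
    mol = record if isinstance(record, Chem.Mol) else mol_from_record(record)
    return _generator(radius, n_bits).GetFingerprint(mol)


def fingerprint_set(
    records: Iterable[MoleculeRecord],
    scheme: str = "circular-bitvector",
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_NBITS,
) -> FingerprintSet:
    fps = FingerprintSet(scheme=scheme, radius=radius, n_bits=n_bits)
    for rec in records:
        fps.vectors[rec.record_id] = fingerprint(rec, scheme, radius, n_bits)
    return fps


def tanimoto(a: DataStructs.ExplicitBitVect, b: DataStructs.ExplicitBitVect) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| in [0, 1]; 1 for identical, and by
    RDKit convention 1 for two all-zero vectors."""
    if a.GetNumBits() != b.GetNumBits():
        raise ValueError("fingerprints have different lengths")
    return DataStructs.TanimotoSimilarity(a, b)


def max_similarity_to_known(
    candidate_fp: DataStructs.ExplicitBitVect,
    known_fps: FingerprintSet,
) -> tuple[str, float]:
    """Exhaustive maximum Tanimoto similarity of a candidate to the known
    set. Returns ``(best_known_id, max_similarity)``. Ties resolve to the
    lexicographically smallest id."""
    if len(known_fps) == 0:
        raise ValueError("known set is empty")
    ids = sorted(known_fps.ids())
    sims = DataStructs.BulkTanimotoSimilarity(
        candidate_fp, [known_fps[i] for i in ids]
    )
    best = int(np.argmax(sims))
    return ids[best], float(sims[best])


def is_novel(max_sim: float, threshold: float = NOVELTY_THRESHOLD) -> bool:
    """Novel chemistry: no known structure exceeds the similarity threshold."""
    return max_sim <= threshold


@dataclass
class SimilarityGraph:
    """kNN similarity graph plus its minimum spanning tree.

    ``graph`` carries every kNN edge with ``weight = 1 - tanimoto``;
    ``mst_edges`` is the spanning-tree subset. ``n_bridges`` counts edges
    added to reconnect a disconnected kNN graph before the MST.
    """

    graph: nx.Graph
    mst_edges: list[tuple[str, str, float]]
    source_tags: dict[str, str]
    n_bridges: int = 0

    def mst(self) -> nx.Graph:
        t = nx.Graph()
        t.add_nodes_from(self.graph.nodes(data=True))
        t.add_weighted_edges_from(self.mst_edges)
        return t

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.mst_edges))


def _pairwise_similarity(fps: FingerprintSet, ids: Sequence[str]) -> np.ndarray:
    vecs = [fps[i] for i in ids]
    n = len(ids)
    sim = np.ones((n, n))
    for i in range(1, n):
        sim[i, :i] = DataStructs.BulkTanimotoSimilarity(vecs[i], vecs[:i])
        sim[:i, i] = sim[i, :i]
    return sim


def _mst_edges_scipy(
    ids: Sequence[str], dist: np.ndarray, graph: nx.Graph
) -> list[tuple[str, str, float]]:
    """MST restricted to the edges present in ``graph`` (scipy Kruskal-style
    routine on the sparse adjacency). Distances of exactly 0 are kept by
    offsetting weights, since csgraph treats 0 as 'no edge'."""
    index = {rid: i for i, rid in enumerate(ids)}
    rows, cols, data = [], [], []
    for u, v, w in graph.edges(data="weight"):
        rows.append(index[u]); cols.append(index[v]); data.append(w + 1.0)
    adj = csr_matrix((data, (rows, cols)), shape=(len(ids), len(ids)))
    tree = _scipy_mst(adj).tocoo()
    return [
        (ids[i], ids[j], float(dist[i, j]))
        for i, j in zip(tree.row, tree.col)
    ]


def build_joint_graph(
    knownset: Sequence[MoleculeRecord],
    background: Sequence[MoleculeRecord] = (),
    *,
    k: int = DEFAULT_KNN,
    fps: Optional[FingerprintSet] = None,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_NBITS,
) -> SimilarityGraph:
    """Merge known and background molecules into one kNN graph and take its
    minimum spanning tree.

    Each node is linked to its ``k`` most similar neighbours (Tanimoto
    distance). If the kNN graph is disconnected, components are joined by
    their single cheapest cross edge each (counted in ``n_bridges``) so a
    spanning tree exists.
    """
    records = list(knownset) + list(background)
    if len(records) < 2:
        raise ValueError("need at least 2 molecules to build a graph")
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record_id across knownset and background")
    tags = {r.record_id: r.source_tag for r in records}
    for r in knownset:
        tags[r.record_id] = "knownset"
    for r in background:
        tags[r.record_id] = "background"
    if fps is None:
        fps = fingerprint_set(records, radius=radius, n_bits=n_bits)
    sim = _pairwise_similarity(fps, ids)
    dist = 1.0 - sim

    g = nx.Graph()
    for rid in ids:
        g.add_node(rid, source_tag=tags[rid])
    n = len(ids)
    kk = min(k, n - 1)
    # argsort is deterministic (stable ties by index order)
    order = np.argsort(dist, axis=1, kind="stable")
    for i in range(n):
        neighbours = [j for j in order[i] if j != i][:kk]
        for j in neighbours:
            g.add_edge(ids[i], ids[int(j)], weight=float(dist[i, j]))

    n_bridges = 0
    comps = [sorted(c) for c in nx.connected_components(g)]
    while len(comps) > 1:
        # attach each extra component to the first by its cheapest cross edge
        comps.sort(key=lambda c: c[0])
        base, rest = comps[0], comps[1:]
        base_idx = [ids.index(x) for x in base]
        for comp in rest:
            comp_idx = [ids.index(x) for x in comp]
            sub = dist[np.ix_(base_idx, comp_idx)]
            bi, ci = np.unravel_index(np.argmin(sub), sub.shape)
            g.add_edge(base[bi], comp[ci], weight=float(sub[bi, ci]))
            n_bridges += 1
        comps = [sorted(c) for c in nx.connected_components(g)]

    mst_edges = _mst_edges_scipy(ids, dist, g)
    return SimilarityGraph(graph=g, mst_edges=mst_edges, source_tags=tags,
                           n_bridges=n_bridges)


@dataclass
class ClusterAssignment:
    """Size-ranked cluster index per knownset record."""

    cluster_of: dict[str, int]
    cluster_sizes: dict[int, int]

    def members(self, cluster_index: int) -> list[str]:
        return sorted(r for r, c in self.cluster_of.items() if c == cluster_index)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)


def extract_clusters(graph: SimilarityGraph) -> ClusterAssignment:
    """Delete background nodes from the MST; the connected components of
    the surviving knownset nodes are the clusters.

    Indexes are 1-based and sorted by descending member count; equal-sized
    clusters take the lower index if their smallest record_id sorts first.
    """
    tree = graph.mst()
    known_nodes = [n for n, d in tree.nodes(data=True)
                   if d.get("source_tag") == "knownset"]
    pruned = tree.subgraph(known_nodes)
    components = [sorted(c) for c in nx.connected_components(pruned)]
    components.sort(key=lambda c: (-len(c), c[0]))
    cluster_of, sizes = {}, {}
    for idx, comp in enumerate(components, start=1):
        sizes[idx] = len(comp)
        for rid in comp:
            cluster_of[rid] = idx
    return ClusterAssignment(cluster_of=cluster_of, cluster_sizes=sizes)


@dataclass(frozen=True)
class StructureID:
    """Hierarchical x.y.z identifier: cluster, group within cluster, record
    within group."""

    x: int
    y: int
    z: int

    def __str__(self) -> str:
        return f"{self.x}.{self.y}.{self.z}"


def define_groups(
    cluster_members: Sequence[str],
    fps: FingerprintSet,
    similarity_threshold: float = NOVELTY_THRESHOLD,
) -> list[list[str]]:
    """Partition one cluster into groups: connected components of the
    within-cluster graph with edges at Tanimoto >= threshold.

    Group order is size-ranked (ties by smallest member id); members keep
    their input order within each group.
    """
    if not 0.0 < similarity_threshold <= 1.0:
        raise ValueError("similarity_threshold must be in (0, 1]")
    members = list(cluster_members)
    sim = _pairwise_similarity(fps, members)
    g = nx.Graph()
    g.add_nodes_from(range(len(members)))
    n = len(members)
    for i in range(n):
        for j in range(i + 1, n):
            if sim[i, j] >= similarity_threshold:
                g.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(g)]
    groups = [[members[i] for i in comp] for comp in comps]
    groups.sort(key=lambda grp: (-len(grp), min(grp)))
    return groups


def assign_ids(
    partition: Mapping[int, Sequence[Sequence[str]]],
) -> dict[str, StructureID]:
    """Assign x.y.z IDs from a mapping cluster_index -> list of groups.

    ``z`` follows each group's record order, so appending new records to a
    group leaves existing IDs unchanged.
    """
    out: dict[str, StructureID] = {}
    for x, groups in partition.items():
        for y, group in enumerate(groups, start=1):
            for z, rid in enumerate(group, start=1):
                if rid in out:
                    raise ValueError(f"record {rid!r} appears in two groups")
                out[rid] = StructureID(x=x, y=y, z=z)
    return out


@dataclass(frozen=True)
class BiosyntheticCall:
    """Majority-vote biosynthetic type for one group."""

    group: str  # "x.y"
    inferred_type: str
    is_mixed: bool
    member_vote_counts: tuple[tuple[str, int], ...]


def infer_biosynthetic_type(
    group_label: str, member_types: Sequence[str]
) -> BiosyntheticCall:
    """Infer a group's biosynthetic route from members with known types.

    Majority vote among non-unknown members (ties to the alphabetically
    first type); ``is_mixed`` flags groups whose members span two or more
    known types. An all-unknown group stays ``unknown``.
    """
    if not member_types:
        raise ValueError("group is empty")
    votes = Counter(t for t in member_types if t != "unknown")
    if not votes:
        inferred = "unknown"
    else:
        top = max(votes.values())
        inferred = sorted(t for t, n in votes.items() if n == top)[0]
    return BiosyntheticCall(
        group=group_label,
        inferred_type=inferred,
        is_mixed=len(votes) >= 2,
        member_vote_counts=tuple(sorted(votes.items())),
    )


def similarity_matrix(
    fps: FingerprintSet, ids: Optional[Sequence[str]] = None
) -> "np.ndarray":
    """Dense ids x ids Tanimoto similarity matrix (for TSV export)."""
    if ids is None:
        ids = fps.ids()
    return _pairwise_similarity(fps, list(ids))


def write_similarity_matrix(
    fps: FingerprintSet, path, ids: Optional[Sequence[str]] = None
) -> None:
    """Write the ids x ids Tanimoto matrix as TSV (ids in header and first
    column)."""
    if ids is None:
        ids = fps.ids()
    ids = list(ids)
    sim = _pairwise_similarity(fps, ids)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(ids) + "\n")
        for i, rid in enumerate(ids):
            fh.write(rid + "\t" + "\t".join(f"{x:.6f}" for x in sim[i]) + "\n")
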