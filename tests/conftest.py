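import itertools

import pytest

from sideroscreen.chemio import MoleculeRecord
from sideroscreen.fixtures import decoy_set, reference_set, veto_constructs


@pytest.fixture(scope="session")
def references():
    return reference_set()

@pytest.fixture(scope="session")
def references_by_id(references):
    return {r.record_id: r for r in references}

@pytest.fixture(scope="session")
def decoys():
    return decoy_set()

@pytest.fixture(scope="session")
def vetoed():
    return veto_constructs()


def record(rid, smiles, name=None, **kw):
    """Shorthand for building a MoleculeRecord in tests."""
    return MoleculeRecord(record_id=rid, name=name or rid, smiles_raw=smiles, **kw)


def brute_force_mst_weight(n_nodes, edges):
    """Minimum spanning-tree weight by exhaustive enumeration.

    ``edges`` is a list of (u, v, w) with integer nodes 0..n-1. Tries every
    (n-1)-subset of edges and keeps the lightest one that spans all nodes
    acyclically. Independent of any library MST routine.
    """
    best = None
    for subset in itertools.combinations(edges, n_nodes - 1):
        parent = list(range(n_nodes))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        acyclic = True
        for u, v, _ in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                acyclic = False
                break
            parent[ru] = rv
        if acyclic and len({find(i) for i in range(n_nodes)}) == 1:
            w = sum(e[2] for e in subset)
            if best is None or w < best:
                best = w
    return best
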