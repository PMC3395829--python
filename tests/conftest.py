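"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest
from skbio import DistanceMatrix

from vtaxa import synthetic_data as sd


def random_additive_matrix(
    n: int, rng: np.random.Generator
) -> tuple[DistanceMatrix, set[frozenset], dict[frozenset, float]]:
    """Random unrooted binary tree -> its additive (path-length) matrix.

    Returns the matrix, the set of canonical nontrivial bipartitions, and the
    internal branch length per bipartition; the independent oracle for
    neighbor joining.
    """
    leaves = [f"L{i:02d}" for i in range(n)]
    G = nx.Graph()
    G.add_node("I0")
    for leaf in leaves[:3]:
        G.add_edge("I0", leaf, length=rng.uniform(0.1, 1.0))
    inner = 1
    for leaf in leaves[3:]:
        edges = list(G.edges(data=True))
        u, v, d = edges[rng.integers(0, len(edges))]
        G.remove_edge(u, v)
        mid = f"I{inner}"
        inner += 1
        w = d["length"] * rng.uniform(0.2, 0.8)
        G.add_edge(u, mid, length=w)
        G.add_edge(mid, v, length=d["length"] - w)
        G.add_edge(mid, leaf, length=rng.uniform(0.1, 1.0))

    dmat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        dij = nx.shortest_path_length(G, leaves[i], leaves[j], weight="length")
        dmat[i, j] = dmat[j, i] = dij

    anchor = min(leaves)
    bps: set[frozenset] = set()
    lengths: dict[frozenset, float] = {}
    for u, v in list(G.edges()):
        H = G.copy()
        H.remove_edge(u, v)
        comp = nx.node_connected_component(H, u)
        side = frozenset(x for x in comp if x in leaves)
        if 2 <= len(side) <= n - 2:
            canon = side if anchor not in side else frozenset(leaves) - side
            bps.add(canon)
            lengths[canon] = G[u][v]["length"]
    return DistanceMatrix(dmat, leaves), bps, lengths


def planted_dataset(
    n_taxa: int,
    members,
    seed: int,
    seq_length: int = 400,
    intra_mut: float = 0.02,
    inter_div: float = 0.20,
):
    """Planted-taxon records plus truth labels (seq id -> taxon id)."""
    cfg = sd.SynthConfig(
        n_taxa=n_taxa,
        members_per_taxon=members,
        seq_length=seq_length,
        intra_mut=intra_mut,
        inter_div=inter_div,
        seed=seed,
    )
    records, truth = sd.generate_taxa(cfg)
    labels = {s: t.taxon_id for t in truth for s in t.member_ids}
    return records, truth, labels


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture
def small_planted():
    """4 planted taxa x 5 members, well separated."""
    return planted_dataset(4, 5, seed=1)
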