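"""Shared fixtures: small synthetic study objects used across the suite."""

from __future__ import annotations

import random

import networkx as nx
import numpy as np
import pytest
from skbio import DistanceMatrix

from flyimm import synthetic as syn
from flyimm.triage import ReferenceSets


@pytest.fixture(scope="session")
def catalog() -> syn.GeneCatalog:
    return syn.generate_gene_catalog(40, seed=1)


@pytest.fixture(scope="session")
def genome(catalog) -> syn.SyntheticGenome:
    return syn.generate_genome(catalog, seed=2, n_unannotated=5, n_hidden_genes=4)


@pytest.fixture(scope="session")
def references(catalog, genome) -> ReferenceSets:
    mito = genome.segments_of("mito")[0]
    rrna = genome.segments_of("rrna")[0]
    return ReferenceSets(
        mito={"mito": genome.sequence[mito.start : mito.end]},
        rrna={"rrna": genome.sequence[rrna.start : rrna.end]},
        cds={g.gene_id: g.cds_sequence for g in catalog.entries},
    )


@pytest.fixture(scope="session")
def read_library(catalog, genome) -> syn.ReadSet:
    return syn.generate_read_library(
        catalog,
        genome,
        mix={"mito": 0.05, "rrna": 0.20, "gene": 0.55, "unannotated": 0.20},
        n_reads=2_000,
        seed=3,
        condition="infected",
    )


def random_additive_matrix(n_taxa: int, rng: np.random.Generator) -> DistanceMatrix:
    """Path-distance matrix of a random tree with positive branch lengths.

    Used as the construct-then-recover oracle for neighbor joining: NJ is
    exact on additive matrices, so the returned matrix determines a unique
    unrooted topology and set of branch lengths.
    """
    g = nx.Graph()
    leaves = []
    for i in range(3):
        g.add_edge("c0", f"t{i}", w=float(rng.uniform(0.05, 1.0)))
        leaves.append(f"t{i}")
    internal = 0
    for i in range(3, n_taxa):
        edge = random.Random(int(rng.integers(10**9))).choice(sorted(g.edges))
        w = g.edges[edge]["w"]
        g.remove_edge(*edge)
        internal += 1
        hub = f"c{internal}"
        split = float(rng.uniform(0.2, 0.8))
        g.add_edge(edge[0], hub, w=w * split)
        g.add_edge(hub, edge[1], w=w * (1.0 - split))
        g.add_edge(hub, f"t{i}", w=float(rng.uniform(0.05, 1.0)))
        leaves.append(f"t{i}")
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="w"))
    m = np.array([[dist[a][b] for b in leaves] for a in leaves])
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(m, ids=leaves)
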