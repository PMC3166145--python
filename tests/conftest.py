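"""Shared fixtures: small simulated reference databases and fitted engines."""

from __future__ import annotations

import numpy as np
import pytest

import phylopd as pp
from phylopd.likelihood import PartitionedModel
from phylopd.scaffold import Partition, concatenate


def make_partitioned_model(concat, alpha=0.7, n_categories=4):
    """Partitioned model with known shapes (no fitting) for placement tests."""
    parts = [
        Partition(p.family_id, p.start, p.end, 1.0, alpha)
        for p in concat.partitions
    ]
    return PartitionedModel(parts, n_categories=n_categories)


@pytest.fixture(scope="session")
def small_ref():
    """8-taxon reference: one 250-column family (enough informative columns
    for unambiguous self-placement)."""
    cfg = pp.SimulationConfig(
        n_reference_taxa=8, n_families=1, columns_per_family=250,
        n_samples=2, reads_per_sample=4, read_length=100, seed=20260101,
    )
    return pp.simulate_reference(cfg), cfg


@pytest.fixture(scope="session")
def small_engine(small_ref):
    ref, cfg = small_ref
    concat = concatenate(ref.families, sorted(ref.phylogeny.leaf_labels))
    model = make_partitioned_model(concat)
    return pp.PlacementEngine(ref.phylogeny, concat, model)


@pytest.fixture(scope="session")
def two_family_ref():
    """16-taxon reference with two families of unequal rates."""
    cfg = pp.SimulationConfig(
        n_reference_taxa=16, n_families=2, columns_per_family=150,
        n_samples=3, reads_per_sample=10, read_length=100,
        gamma_shape=[0.5, 1.5], seed=777,
    )
    return pp.simulate_reference(cfg), cfg


def adjacent_edges(phy, edge_num):
    """Edge numbers sharing a node with the given edge."""
    v = phy.node_of_edge(edge_num)
    adj = {c.edge_num for c in v.child_nodes()}
    u = v.parent_node
    if u is not None:
        if u.edge_num is not None:
            adj.add(u.edge_num)
        adj.update(s.edge_num for s in u.child_nodes())
    adj.discard(edge_num)
    return adj


def random_distance_matrix(rng: np.random.Generator, n: int):
    """Random metric-ish symmetric matrix (not necessarily tree-derived)."""
    pts = rng.random((n, 3)) * 2
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return pp.DistanceMatrix([f"s{i:02d}" for i in range(n)], d)
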