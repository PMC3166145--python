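"""Taxonomic assignment of placed reads from their placement distributions.

Each reference edge subtends a clade of reference genomes; the edge's lineage
is the longest ranked prefix shared by that clade.  A read's support at a
rank is the total bootstrap placement frequency over edges whose lineage
agrees with the read's ML-edge lineage at that rank, and the read is assigned
to the deepest rank with support strictly above the threshold (0.70 by
default).  Reads supported only at the root rank (e.g. 'Bacteria') are
flagged unusable and excluded from composition tables, mirroring the
common practice of discarding placements that cannot be phylotyped below
the domain level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import ConsistencyError, Phylogeny, SampleMap, TaxonomyTable
from .placement import Placement, PlacementDistribution

Lineage = tuple[tuple[str, str], ...]


@dataclass
class PhylotypeAssignment:
    read_id: str
    assigned_lineage: Lineage
    support_per_rank: dict[str, float]
    nearest_reference: str
    usable: bool


def edge_lineage(edge_num: int, ref_tree: Phylogeny,
                 taxonomy: TaxonomyTable) -> Lineage:
    """Longest lineage prefix shared by all reference leaves distal to the
    edge (relative to the canonical root)."""
    leaves = ref_tree.distal_leaves(edge_num)
    lineages = [taxonomy.of(leaf) for leaf in leaves]
    shared = []
    for entries in zip(*lineages):
        names = {name for _, name in entries}
        ranks = {rank for rank, _ in entries}
        if len(names) == 1 and len(ranks) == 1:
            shared.append(entries[0])
        else:
            break
    if not shared:
        raise ConsistencyError(
            f"edge {edge_num}: distal leaves share no lineage prefix"
        )
    return tuple(shared)


def _node_depths_from(tree, start_node) -> dict[int, float]:
    """Path length from an arbitrary start node to every node (tree metric)."""
    dist = {id(start_node): 0.0}
    stack = [start_node]
    while stack:
        nd = stack.pop()
        d = dist[id(nd)]
        neighbours = list(nd.child_nodes())
        if nd.parent_node is not None:
            neighbours.append(nd.parent_node)
        for nb in neighbours:
            if id(nb) in dist:
                continue
            edge = nd.edge if nb is nd.parent_node else nb.edge
            dist[id(nb)] = d + edge.length
            stack.append(nb)
    return dist


def nearest_reference_leaf(edge_num: int, ref_tree: Phylogeny) -> str:
    """Reference leaf at minimal patristic distance from the midpoint of the
    given edge; ties go to the lexicographically smallest label."""
    v = ref_tree.node_of_edge(edge_num)
    half = v.edge.length / 2.0
    below = _node_depths_from(ref_tree.tree, v)
    subtree = {id(x) for x in v.preorder_iter()}
    best = None
    for lf in ref_tree.tree.leaf_node_iter():
        d = below[id(lf)]
        # below the edge: d + half; above: route through the parent,
        # d - t + half (d already includes the full edge length t)
        if id(lf) in subtree:
            total = d + half
        else:
            total = d - v.edge.length + half
        label = lf.taxon.label
        if best is None or total < best[0] - 1e-15 or (
            abs(total - best[0]) <= 1e-15 and label < best[1]
        ):
            best = (total, label)
    return best[1]


def assign_phylotype(
    read_id: str,
    distribution: PlacementDistribution,
    ml_placement: Placement,
    ref_tree: Phylogeny,
    taxonomy: TaxonomyTable,
    min_support: float = 0.70,
) -> PhylotypeAssignment:
    """Assign a ranked lineage to one read from its placement distribution.

    The support threshold is strict: support exactly equal to ``min_support``
    does not qualify.
    """
    candidate = edge_lineage(ml_placement.edge_num, ref_tree, taxonomy)
    lineages = {
        e: edge_lineage(e, ref_tree, taxonomy) for e in distribution.freq
    }
    support: dict[str, float] = {}
    for depth, (rank, name) in enumerate(candidate):
        s = sum(
            f for e, f in distribution.freq.items()
            if len(lineages[e]) > depth and lineages[e][depth] == (rank, name)
        )
        support[rank] = s
    assigned: Lineage = ()
    for depth, (rank, name) in enumerate(candidate):
        if support[rank] > min_support:
            assigned = candidate[: depth + 1]
        else:
            break
    usable = len(assigned) > 1  # deeper than the root rank
    return PhylotypeAssignment(
        read_id=read_id,
        assigned_lineage=assigned,
        support_per_rank=support,
        nearest_reference=nearest_reference_leaf(
            ml_placement.edge_num, ref_tree
        ),
        usable=usable,
    )


def composition_table(
    assignments: list[PhylotypeAssignment],
    sample_map: SampleMap,
    rank: str,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-sample relative abundances of usable reads at the given rank.

    Returns (table, excluded_fraction per sample).  Rows sum to one; a read
    whose assigned lineage does not reach the rank is counted under
    'unresolved'.  Samples with no usable reads get an all-NaN-free zero row
    flagged via the excluded fraction (1.0).
    """
    counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    excluded: dict[str, int] = {}
    for a in assignments:
        sample = sample_map.read_to_sample[a.read_id]
        totals[sample] = totals.get(sample, 0) + 1
        if not a.usable:
            excluded[sample] = excluded.get(sample, 0) + 1
            continue
        name = dict(a.assigned_lineage).get(rank, "unresolved")
        counts.setdefault(sample, {})[name] = (
            counts.get(sample, {}).get(name, 0) + 1
        )
    taxa = sorted({n for c in counts.values() for n in c})
    samples = sorted(totals)
    mat = np.zeros((len(samples), len(taxa)))
    for i, s in enumerate(samples):
        row = counts.get(s, {})
        total_usable = sum(row.values())
        for j, taxon in enumerate(taxa):
            if total_usable:
                mat[i, j] = row.get(taxon, 0) / total_usable
    table = pd.DataFrame(mat, index=samples, columns=taxa)
    excluded_frac = {
        s: excluded.get(s, 0) / totals[s] for s in samples
    }
    return table, excluded_frac


def assignments_table(assignments: list[PhylotypeAssignment],
                      sample_map: SampleMap) -> pd.DataFrame:
    rows = []
    for a in assignments:
        deepest = a.assigned_lineage[-1] if a.assigned_lineage else ("", "")
        rows.append({
            "read_id": a.read_id,
            "sample_id": sample_map.read_to_sample.get(a.read_id, ""),
            "lineage": ";".join(n for _, n in a.assigned_lineage),
            "deepest_rank": deepest[0],
            "support": a.support_per_rank.get(deepest[0], 0.0),
            "nearest_reference": a.nearest_reference,
            "usable": a.usable,
        })
    return pd.DataFrame(rows)
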