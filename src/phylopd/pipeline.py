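"""End-to-end experiment drivers: simulate, place, prune, standardize.

These wire the stages together the way an analysis would: generate a
reference database and fragmentary reads, place the reads under the
partitioned WAG+G model, graft and prune to a query-only tree, and compute
per-sample SES_MPD.  They are used both programmatically and by the
reproducibility script.
"""

from __future__ import annotations

import numpy as np

from .diversity import CommunityMatrix, DistanceMatrix, patristic_matrix, ses_mpd
from .likelihood import PartitionedModel
from .placement import PlacementEngine, graft, prune_to_queries
from .scaffold import Partition, concatenate
from .simdata import SimulationConfig, simulate_queries, simulate_reference


def default_model(concat, alpha: float = 0.7,
                  n_categories: int = 4) -> PartitionedModel:
    """Partitioned model with the generator's gamma shape (no refitting)."""
    return PartitionedModel(
        [Partition(p.family_id, p.start, p.end, 1.0, alpha)
         for p in concat.partitions],
        n_categories=n_categories,
    )


def ses_run(clustering: float, seed: int, n_taxa: int = 24,
            n_families: int = 2, columns: int = 150, n_samples: int = 3,
            reads_per_sample: int = 12, read_length: int = 100,
            n_null: int = 199) -> list[float]:
    """One full pipeline run; returns per-sample SES_MPD on the ML tree."""
    cfg = SimulationConfig(
        n_reference_taxa=n_taxa, n_families=n_families,
        columns_per_family=columns, n_samples=n_samples,
        reads_per_sample=reads_per_sample, read_length=read_length,
        clustering=clustering, seed=seed,
    )
    ref = simulate_reference(cfg)
    concat = concatenate(ref.families, sorted(ref.phylogeny.leaf_labels))
    engine = PlacementEngine(ref.phylogeny, concat, default_model(concat))
    queries, sample_map, _ = simulate_queries(ref, cfg)
    placements = [engine.place(q) for q in queries]
    grafted = graft(ref.phylogeny,
                    [(p.read_id, p.edge_num, p.pendant_length)
                     for p in placements])
    query_tree = prune_to_queries(grafted)
    dm = patristic_matrix(query_tree)
    community = CommunityMatrix.from_sample_map(sample_map, dm.ids)
    return [
        ses_mpd(community.members(s), dm, n_null=n_null, seed=seed,
                sample_label=s).ses
        for s in community.samples
    ]


def sign_recovery(seed: int, n_runs: int = 20,
                  clustering: float = 0.9) -> tuple[int, int]:
    """How many of n_runs end-to-end runs recover the expected SES sign
    (negative for clustered, positive for overdispersed communities).
    The run statistic is the mean SES over samples."""
    expected_negative = clustering > 0
    correct = 0
    for k in range(n_runs):
        mean_ses = float(np.mean(ses_run(clustering, seed + 1000 * (k + 1))))
        if (mean_ses < 0) == expected_negative and mean_ses != 0:
            correct += 1
    return correct, n_runs


def placement_accuracy(seed: int, n_reads: int = 100, n_taxa: int = 32,
                       read_length: int = 100) -> tuple[int, int]:
    """Fraction of simulated reads placed on the true or an adjacent edge."""
    cfg = SimulationConfig(
        n_reference_taxa=n_taxa, n_families=2, columns_per_family=150,
        n_samples=2, reads_per_sample=(n_reads + 1) // 2,
        read_length=read_length, seed=seed,
    )
    ref = simulate_reference(cfg)
    phy = ref.phylogeny
    concat = concatenate(ref.families, sorted(phy.leaf_labels))
    engine = PlacementEngine(phy, concat, default_model(concat))
    queries, _, truth = simulate_queries(ref, cfg)
    queries = queries[:n_reads]
    hits = 0
    for q in queries:
        placement = engine.place(q)
        true_edge = truth[q.read_id]["true_edge"]
        v = phy.node_of_edge(true_edge)
        adjacent = {c.edge_num for c in v.child_nodes()}
        if v.parent_node is not None:
            if v.parent_node.edge_num is not None:
                adjacent.add(v.parent_node.edge_num)
            adjacent.update(s.edge_num for s in v.parent_node.child_nodes())
        adjacent.discard(true_edge)
        if placement.edge_num == true_edge or placement.edge_num in adjacent:
            hits += 1
    return hits, len(queries)


def self_placement_trials(seed: int, n_trials: int = 20, n_taxa: int = 8,
                          columns: int = 250) -> tuple[int, int]:
    """Trials where a query identical to a reference leaf row lands on that
    leaf's pendant edge with a near-zero pendant length."""
    successes = 0
    rng = np.random.default_rng(seed)
    for k in range(n_trials):
        cfg = SimulationConfig(
            n_reference_taxa=n_taxa, n_families=1, columns_per_family=columns,
            n_samples=1, reads_per_sample=1, read_length=columns,
            seed=int(rng.integers(2**31)),
        )
        ref = simulate_reference(cfg)
        concat = concatenate(ref.families, sorted(ref.phylogeny.leaf_labels))
        engine = PlacementEngine(ref.phylogeny, concat, default_model(concat))
        labels = sorted(ref.phylogeny.leaf_labels)
        # identifiability precondition: the source row must be unique, or
        # "that leaf's pendant edge" is not well defined
        rows = concat.rows
        unique = [l for l in labels
                  if sum(rows[o] == rows[l] for o in labels) == 1]
        taxon = unique[int(rng.integers(len(unique)))]
        from .formats import AlignedSequence
        from .scaffold import tile_query

        fam = ref.families[0]
        q = tile_query(
            AlignedSequence("self", concat.extract_partition(taxon,
                                                             fam.family_id)),
            fam.family_id, concat.partitions,
        )
        placement = engine.place(q)
        if (placement.edge_num == ref.phylogeny.pendant_edge_of(taxon)
                and placement.pendant_length < 1e-3):
            successes += 1
    return successes, n_trials


def null_calibration(seed: int, n_trials: int = 200, n_null: int = 199,
                     pool_size: int = 40) -> tuple[float, float]:
    """Mean and sd of SES_MPD over random subsets of a random pool; should
    be approximately standard normal if the null is well calibrated."""
    cfg = SimulationConfig(n_reference_taxa=pool_size, n_families=1,
                           columns_per_family=2, seed=seed)
    phy = simulate_reference(cfg).phylogeny
    labels, d = phy.patristic_distances()
    dm = DistanceMatrix(labels, d)
    rng = np.random.default_rng(seed)
    values = []
    for t in range(n_trials):
        n = int(rng.integers(5, 15))
        ids = list(rng.choice(labels, size=n, replace=False))
        r = ses_mpd(ids, dm, n_null=n_null, seed=int(rng.integers(2**31)),
                    sample_label=f"trial{t}")
        values.append(r.ses)
    arr = np.array(values)
    return float(arr.mean()), float(arr.std(ddof=1))
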