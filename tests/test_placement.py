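"""ML insertion placement, bootstrap, grafting, pruning, and filters."""

import numpy as np
import pytest

import phylopd as pp
from phylopd.formats import Phylogeny
from phylopd.likelihood import log_likelihood
from phylopd.placement import (
    PlacementEngine,
    build_replicate_trees,
    graft,
    long_branch_filter,
    prune_to_queries,
)
from phylopd.scaffold import Partition, concatenate, tile_query

from conftest import make_partitioned_model


def _self_query(ref, taxon, read_id="q_self"):
    concat = concatenate(ref.families, sorted(ref.phylogeny.leaf_labels))
    fam = ref.families[0]
    row = concat.extract_partition(taxon, fam.family_id)
    return tile_query(pp.AlignedSequence(read_id, row), fam.family_id,
                      concat.partitions)


class TestPlaceQuery:
    def test_self_placement_recovers_pendant_edge(self, small_ref,
                                                  small_engine):
        ref, _ = small_ref
        concat = concatenate(ref.families, sorted(ref.phylogeny.leaf_labels))
        labels = sorted(ref.phylogeny.leaf_labels)
        # pick a leaf whose row is unique so its pendant edge is identifiable
        taxon = next(
            l for l in labels
            if sum(concat.rows[o] == concat.rows[l] for o in labels) == 1
        )
        q = _self_query(ref, taxon)
        placement = small_engine.place(q)
        assert placement.edge_num == ref.phylogeny.pendant_edge_of(taxon)
        assert placement.pendant_length < 1e-3

    def test_symmetric_star_gives_equal_pendant_likelihoods(self):
        phy = Phylogeny.from_newick("(A:0.1,B:0.1,C:0.1);")
        rows = {"A": "ADKLEQ" * 10, "B": "ADKLEQ" * 10, "C": "ADKLEQ" * 10}
        concat = pp.ConcatenatedAlignment(
            ["A", "B", "C"], rows, [Partition("f", 0, 60)]
        )
        model = make_partitioned_model(concat)
        eng = PlacementEngine(phy, concat, model)
        q = tile_query(pp.AlignedSequence("q", "ADKLEQ" * 10), "f",
                       concat.partitions)
        _, table = eng.place(q, return_table=True)
        lls = {e: ll for e, ll, _ in table}
        pend = [lls[phy.pendant_edge_of(x)] for x in "ABC"]
        assert max(pend) - min(pend) < 1e-6

    @pytest.mark.parametrize("seed", [11, 29])
    def test_matches_grid_search_oracle(self, seed):
        cfg = pp.SimulationConfig(n_reference_taxa=5, n_families=1,
                                  columns_per_family=60, n_samples=1,
                                  reads_per_sample=1, read_length=40,
                                  seed=seed)
        ref = pp.simulate_reference(cfg)
        concat = concatenate(ref.families, sorted(ref.phylogeny.leaf_labels))
        model = make_partitioned_model(concat, n_categories=2)
        queries, _, _ = pp.simulate_queries(ref, cfg)
        q = queries[0]
        eng = PlacementEngine(ref.phylogeny, concat, model)
        placement = eng.place(q)
        rows = dict(concat.rows)
        rows[q.read_id] = q.row
        grid = np.logspace(np.log10(1e-8), np.log10(5.0), 200)
        best = None
        for e in ref.phylogeny.edge_numbers:
            for pend in grid:
                gt = graft(ref.phylogeny, [(q.read_id, e, float(pend))])
                nwk = gt.tree.as_string(schema="newick",
                                        suppress_rooting=True).strip()
                ll = log_likelihood(Phylogeny.from_newick(nwk), rows, model)
                if best is None or ll > best[0]:
                    best = (ll, e)
        assert placement.log_likelihood >= best[0] - 1e-4
        assert abs(placement.log_likelihood - best[0]) < 1e-2
        assert placement.edge_num == best[1]

    def test_uninformative_query_rejected(self, small_ref, small_engine):
        ref, _ = small_ref
        concat = concatenate(ref.families, sorted(ref.phylogeny.leaf_labels))
        q = tile_query(
            pp.AlignedSequence("empty", "-" * ref.families[0].n_columns),
            ref.families[0].family_id, concat.partitions,
        )
        with pytest.raises(ValueError, match="informative"):
            small_engine.place(q)


class TestBootstrap:
    def test_single_replicate_is_point_mass(self, small_ref, small_engine):
        ref, _ = small_ref
        q = _self_query(ref, sorted(ref.phylogeny.leaf_labels)[2], "qb")
        dist = small_engine.bootstrap(q, B=1, seed=5)
        assert len(dist.freq) == 1
        assert list(dist.freq.values()) == [1.0]

    def test_strong_signal_concentrates_on_pendant_edge(self, small_ref,
                                                        small_engine):
        ref, _ = small_ref
        taxon = sorted(ref.phylogeny.leaf_labels)[4]
        q = _self_query(ref, taxon, "qc")
        dist = small_engine.bootstrap(q, B=40, seed=5)
        assert sum(dist.freq.values()) == pytest.approx(1.0, abs=1e-12)
        assert dist.freq.get(ref.phylogeny.pendant_edge_of(taxon), 0) >= 0.95

    def test_order_independent_given_read_keyed_seeds(self, small_ref,
                                                      small_engine):
        ref, _ = small_ref
        labels = sorted(ref.phylogeny.leaf_labels)
        q1 = _self_query(ref, labels[1], "q1")
        q2 = _self_query(ref, labels[5], "q2")
        d12 = [small_engine.bootstrap(q, B=5, seed=3) for q in (q1, q2)]
        d21 = [small_engine.bootstrap(q, B=5, seed=3) for q in (q2, q1)]
        assert d12[0].freq == d21[1].freq
        assert d12[1].freq == d21[0].freq


class TestReplicateTrees:
    def test_point_mass_distributions_reproduce_ml_tree(self):
        phy = Phylogeny.from_newick("(A:0.1,(B:0.2,C:0.3):0.05);")
        placements = [pp.Placement("r1", 1, 0.02, -1.0),
                      pp.Placement("r2", 2, 0.05, -2.0)]
        dists = {"r1": pp.PlacementDistribution("r1", {1: 1.0}),
                 "r2": pp.PlacementDistribution("r2", {2: 1.0})}
        ml, reps = build_replicate_trees(phy, dists, placements, B=5, seed=1)
        ml_str = ml.tree.as_string(schema="newick")
        assert all(r.tree.as_string(schema="newick") == ml_str for r in reps)

    def test_attachment_counts_binomial(self):
        phy = Phylogeny.from_newick("((A:1.0,B:1.0):0.5,(C:1.0,D:1.0):0.5);")
        cd_edge = next(e for e in phy.edge_numbers
                       if sorted(phy.distal_leaves(e)) == ["C", "D"])
        c_edge = phy.pendant_edge_of("C")
        placements = [pp.Placement("r1", cd_edge, 0.02, -1.0)]
        dists = {"r1": pp.PlacementDistribution(
            "r1", {cd_edge: 0.7, c_edge: 0.3})}
        B = 1000
        _, reps = build_replicate_trees(phy, dists, placements, B=B, seed=9)
        count = 0
        for r in reps:
            lf = next(x for x in r.tree.leaf_node_iter()
                      if x.taxon.label == "r1")
            # attached on the CD stem iff both C and D hang below the
            # attachment node
            sibs = {s.taxon.label for s in
                    lf.parent_node.leaf_iter() if s is not lf}
            count += sibs == {"C", "D"}
        sd = np.sqrt(B * 0.7 * 0.3)
        assert abs(count - 0.7 * B) <= 3 * sd

    def test_missing_distribution_rejected(self):
        phy = Phylogeny.from_newick("(A:0.1,B:0.2);")
        placements = [pp.Placement("r1", 0, 0.1, -1.0)]
        with pytest.raises(Exception, match="distribution"):
            build_replicate_trees(phy, {}, placements, B=2, seed=0)


class TestPrune:
    def test_two_query_distance_split(self):
        phy = Phylogeny.from_newick("(A:0.1,(B:0.2,C:0.3):0.05);")
        gt = graft(phy, [("q1", 0, 0.01), ("q2", 2, 0.02)])
        pdm = gt.tree.phylogenetic_distance_matrix()
        tx = {t.label: t for t in gt.tree.taxon_namespace}
        d_graft = pdm.patristic_distance(tx["q1"], tx["q2"])
        qt = prune_to_queries(gt)
        leaves = list(qt.tree.leaf_node_iter())
        assert sorted(lf.taxon.label for lf in leaves) == ["q1", "q2"]
        total = sum(lf.edge.length for lf in leaves)
        assert total == pytest.approx(d_graft, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_distances_preserved_on_random_grafts(self, seed):
        rng = np.random.default_rng(seed)
        cfg = pp.SimulationConfig(n_reference_taxa=int(rng.integers(8, 20)),
                                  n_families=1, columns_per_family=2,
                                  seed=seed + 100)
        phy = pp.simulate_reference(cfg).phylogeny
        n_q = int(rng.integers(3, 8))
        attachments = [
            (f"q{i}", int(rng.integers(0, phy.n_edges)),
             float(rng.uniform(0.001, 0.5)))
            for i in range(n_q)
        ]
        gt = graft(phy, attachments)
        before = _query_distances(gt.tree, [a[0] for a in attachments])
        qt = prune_to_queries(gt)
        after = _query_distances(qt.tree, [a[0] for a in attachments])
        for pair in before:
            assert after[pair] == pytest.approx(before[pair], abs=1e-12)

    def test_cardinality_large_reference(self):
        cfg = pp.SimulationConfig(n_reference_taxa=40, n_families=1,
                                  columns_per_family=2, seed=8)
        phy = pp.simulate_reference(cfg).phylogeny
        gt = graft(phy, [("q1", 0, 0.1), ("q2", 5, 0.1), ("q3", 11, 0.1)])
        qt = prune_to_queries(gt)
        assert len(list(qt.tree.leaf_node_iter())) == 3

    def test_fewer_than_two_queries_rejected(self):
        phy = Phylogeny.from_newick("(A:0.1,B:0.2);")
        gt = graft(phy, [("q1", 0, 0.1)])
        with pytest.raises(ValueError):
            prune_to_queries(gt)


def _query_distances(tree, query_ids):
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace if t.label in query_ids}
    out = {}
    ids = sorted(query_ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            out[(ids[i], ids[j])] = pdm.patristic_distance(
                tx[ids[i]], tx[ids[j]]
            )
    return out


class TestLongBranchFilter:
    def _placements(self, lengths):
        return [pp.Placement(f"r{k:03d}", 0, l, -1.0)
                for k, l in enumerate(lengths)]

    def test_top_five_percent_dropped(self):
        pls = self._placements([0.01 * k for k in range(1, 101)])
        kept = long_branch_filter(pls, percentile=95)
        assert len(kept) == 95
        dropped = {p.read_id for p in pls} - set(kept)
        assert dropped == {f"r{k:03d}" for k in range(95, 100)}

    def test_equal_lengths_keep_all(self):
        pls = self._placements([0.2] * 30)
        assert len(long_branch_filter(pls, percentile=95)) == 30

    def test_percentile_100_is_identity(self):
        pls = self._placements([0.01 * k for k in range(1, 51)])
        assert len(long_branch_filter(pls, percentile=100)) == 50
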