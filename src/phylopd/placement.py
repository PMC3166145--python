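"""Maximum-likelihood placement of tiled reads on a fixed reference phylogeny.

Each query is attached in turn to the midpoint of every reference edge; only
the pendant branch length is optimised (bounded 1-D search).  Placement
uncertainty is quantified by a phylogenetic bootstrap that resamples the
query's non-missing columns (paired query/reference residues) and re-places
each resample; replicate grafted trees draw each query's attachment edge from
its bootstrap frequency distribution.

The engine exploits reversibility: conditional likelihood vectors toward the
tips (``down``) and away from each edge (``out``) are computed once per
partition, so evaluating one candidate attachment costs only the pendant-edge
transition term.  The insertion likelihood therefore agrees with a full
pruning pass on the physically grafted tree (a property the test suite checks
against a grid-search oracle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from hashlib import sha256

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .formats import ConsistencyError, Phylogeny
from .likelihood import (
    PartitionedModel,
    discrete_gamma_rates,
    encode_residues,
)
from .scaffold import ConcatenatedAlignment, TiledQuery

PENDANT_BOUNDS = (1e-8, 5.0)


@dataclass(frozen=True)
class Placement:
    read_id: str
    edge_num: int
    pendant_length: float
    log_likelihood: float


@dataclass(frozen=True)
class PlacementDistribution:
    read_id: str
    freq: dict[int, float]

    def __post_init__(self) -> None:
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ConsistencyError(
                f"read {self.read_id!r}: frequencies sum to {total}, not 1"
            )


@dataclass
class GraftedTree:
    """Reference tree with query tips attached; provenance 'ml' or a
    bootstrap replicate index."""

    tree: dendropy.Tree
    query_ids: list[str]
    provenance: str | int = "ml"


@dataclass
class QueryTree:
    """Query-only tree obtained by pruning all reference leaves."""

    tree: dendropy.Tree
    query_ids: list[str]
    provenance: str | int = "ml"


def _read_rng(seed: int, read_id: str) -> np.random.Generator:
    h = int.from_bytes(sha256(read_id.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))


class _PartitionContext:
    """Cached per-edge insertion factors for one gene family's columns."""

    def __init__(self, phy: Phylogeny, states: dict[str, np.ndarray],
                 model, alpha: float, mult: float):
        self.rates = discrete_gamma_rates(alpha, model.n_categories)
        self.mult = mult
        self.model = model
        K = model.n_categories
        pi = model.stationary_freqs
        cols = next(iter(states.values())).shape[0]
        tree = phy.tree

        def pmats(t: float) -> np.ndarray:
            return np.stack(
                [model.transition_matrix(t * mult * r) for r in self.rates]
            )

        down: dict[int, np.ndarray] = {}
        dscale: dict[int, np.ndarray] = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                st = states[nd.taxon.label]
                arr = np.zeros((cols, 20))
                obs = st >= 0
                arr[obs, st[obs]] = 1.0
                arr[~obs, :] = 1.0
                down[id(nd)] = np.broadcast_to(arr, (K, cols, 20)).copy()
                dscale[id(nd)] = np.zeros(cols)
                continue
            acc, scale = None, np.zeros(cols)
            for child in nd.child_nodes():
                pm = pmats(child.edge.length)
                contrib = np.einsum("kij,kcj->kci", pm, down[id(child)])
                acc = contrib if acc is None else acc * contrib
                scale = scale + dscale[id(child)]
            colmax = acc.max(axis=(0, 2))
            safe = np.where(colmax > 0, colmax, 1.0)
            acc = acc / safe[None, :, None]
            scale = scale + np.log(safe)
            down[id(nd)] = acc
            dscale[id(nd)] = scale

        # "out" pass: S[v] = likelihood of everything outside v's subtree,
        # conditioned on the state at v's parent
        S: dict[int, np.ndarray] = {}
        sscale: dict[int, np.ndarray] = {}
        up: dict[int, np.ndarray] = {id(tree.seed_node): np.ones((K, cols, 20))}
        uscale: dict[int, np.ndarray] = {id(tree.seed_node): np.zeros(cols)}
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            children = nd.child_nodes()
            sib_terms = []
            for child in children:
                pm = pmats(child.edge.length)
                sib_terms.append(
                    np.einsum("kij,kcj->kci", pm, down[id(child)])
                )
            for i, child in enumerate(children):
                acc = up[id(nd)].copy()
                scale = uscale[id(nd)].copy()
                for j, term in enumerate(sib_terms):
                    if j != i:
                        acc = acc * term
                        scale = scale + dscale[id(children[j])]
                colmax = acc.max(axis=(0, 2))
                safe = np.where(colmax > 0, colmax, 1.0)
                acc = acc / safe[None, :, None]
                scale = scale + np.log(safe)
                S[id(child)] = acc
                sscale[id(child)] = scale
                pm = pmats(child.edge.length)
                up[id(child)] = np.einsum("kij,kcj->kci", pm, acc)
                uscale[id(child)] = scale

        # per-edge midpoint factors W[e] = pi * P(t/2)down[v] * P(t/2)S[v]
        self.W: list[np.ndarray] = []
        self.Wscale: list[np.ndarray] = []
        for e in phy.edge_numbers:
            v = phy.node_of_edge(e)
            half = pmats(v.edge.length / 2.0)
            A = np.einsum("kij,kcj->kci", half, down[id(v)])
            B = np.einsum("kij,kcj->kci", half, S[id(v)])
            w = pi[None, None, :] * A * B
            self.W.append(w)
            self.Wscale.append(dscale[id(v)] + sscale[id(v)])
        # per-column reference log-likelihood of this partition
        root = tree.seed_node
        site = (down[id(root)] @ pi).mean(axis=0)
        self.ref_col_ll = np.log(site) + dscale[id(root)]


class PlacementEngine:
    """Places tiled queries on a reference phylogeny under a fitted
    partitioned WAG+G model; reference branch lengths are taken as given."""

    def __init__(self, ref_tree: Phylogeny, ref_alignment: ConcatenatedAlignment,
                 model: PartitionedModel):
        if set(ref_tree.leaf_labels) != set(ref_alignment.taxa):
            raise ConsistencyError(
                "reference tree leaves and alignment taxa differ"
            )
        self.phy = ref_tree
        self.concat = ref_alignment
        self.model = model
        self._encoded = {
            t: encode_residues(ref_alignment.rows[t]) for t in ref_alignment.taxa
        }
        self._ctx: dict[str, _PartitionContext] = {}
        self._total_ref_ll: float | None = None

    def _context(self, family_id: str) -> _PartitionContext:
        if family_id not in self._ctx:
            part = next(
                p for p in self.model.partitions if p.family_id == family_id
            )
            states = {
                t: enc[part.start:part.end] for t, enc in self._encoded.items()
            }
            self._ctx[family_id] = _PartitionContext(
                self.phy, states, self.model.base,
                part.gamma_shape, part.rate_multiplier,
            )
        return self._ctx[family_id]

    def reference_log_likelihood(self) -> float:
        """Log-likelihood of the reference alignment alone (all partitions)."""
        if self._total_ref_ll is None:
            total = 0.0
            for part in self.model.partitions:
                total += float(self._context(part.family_id).ref_col_ll.sum())
            self._total_ref_ll = total
        return self._total_ref_ll

    # -- single-query machinery --------------------------------------------

    def _query_states(self, query: TiledQuery):
        part = next(
            p for p in self.model.partitions if p.family_id == query.family_id
        )
        enc = encode_residues(query.row[part.start:part.end])
        idx = np.nonzero(enc >= 0)[0]
        return part, idx, enc[idx]

    def _edge_ll(self, ctx, edge_num: int, idx: np.ndarray,
                 states: np.ndarray, pendant: float,
                 weights: np.ndarray | None = None) -> float:
        """Insertion log-likelihood over the given informative columns only."""
        w = ctx.W[edge_num][:, idx, :]
        site = np.zeros(idx.shape[0])
        for k, r in enumerate(ctx.rates):
            p = ctx.model.transition_matrix(pendant * ctx.mult * r)
            site += np.einsum("ci,ic->c", w[k], p[:, states])
        site /= len(ctx.rates)
        col_ll = np.log(site) + ctx.Wscale[edge_num][idx]
        return float(col_ll @ weights) if weights is not None else float(col_ll.sum())

    def _best_pendant(self, ctx, edge_num: int, idx, states,
                      weights=None) -> tuple[float, float]:
        res = minimize_scalar(
            lambda p: -self._edge_ll(ctx, edge_num, idx, states, p, weights),
            bounds=PENDANT_BOUNDS, method="bounded", options={"xatol": 1e-6},
        )
        return float(res.x), -float(res.fun)

    def place(self, query: TiledQuery, return_table: bool = False):
        """ML placement of one query; ties broken toward the smallest edge."""
        part, idx, states = self._query_states(query)
        if idx.size == 0:
            raise ValueError(
                f"read {query.read_id!r} has no informative columns; it "
                "should have been removed by the length filter"
            )
        ctx = self._context(part.family_id)
        # constant: reference likelihood of every column the query misses
        const = self.reference_log_likelihood() - float(
            ctx.ref_col_ll[idx].sum()
        )
        best = None
        table = []
        for e in self.phy.edge_numbers:
            pend, ll = self._best_pendant(ctx, e, idx, states)
            total = ll + const
            table.append((e, total, pend))
            if best is None or total > best[1]:
                best = (e, total, pend)
        placement = Placement(query.read_id, best[0], best[2], best[1])
        return (placement, table) if return_table else placement

    def bootstrap(self, query: TiledQuery, B: int = 100,
                  seed: int = 0) -> PlacementDistribution:
        """Column bootstrap over the query's non-missing columns."""
        if B < 1:
            raise ValueError("need at least one bootstrap replicate")
        part, idx, states = self._query_states(query)
        ctx = self._context(part.family_id)
        rng = _read_rng(seed, query.read_id)
        counts: dict[int, int] = {}
        n = idx.size
        for _ in range(B):
            draw = rng.integers(0, n, size=n)
            weights = np.bincount(draw, minlength=n).astype(float)
            best = None
            for e in self.phy.edge_numbers:
                _, ll = self._best_pendant(ctx, e, idx, states, weights)
                if best is None or ll > best[1]:
                    best = (e, ll)
            counts[best[0]] = counts.get(best[0], 0) + 1
        freq = {e: c / B for e, c in sorted(counts.items())}
        return PlacementDistribution(query.read_id, freq)


def place_query(query: TiledQuery, ref_tree: Phylogeny,
                ref_alignment: ConcatenatedAlignment, model: PartitionedModel,
                return_table: bool = False):
    """Convenience wrapper; for many queries build one PlacementEngine."""
    return PlacementEngine(ref_tree, ref_alignment, model).place(
        query, return_table=return_table
    )


def bootstrap_place(query: TiledQuery, ref_tree: Phylogeny,
                    ref_alignment: ConcatenatedAlignment,
                    model: PartitionedModel, B: int = 100,
                    seed: int = 0) -> PlacementDistribution:
    return PlacementEngine(ref_tree, ref_alignment, model).bootstrap(
        query, B=B, seed=seed
    )


# ---------------------------------------------------------------------------
# Grafting and pruning
# ---------------------------------------------------------------------------

def _clone_with_edge_nums(phy: Phylogeny) -> dendropy.Tree:
    t = phy.tree.clone(depth=1)
    for orig, copy in zip(phy.tree.preorder_node_iter(),
                          t.preorder_node_iter()):
        copy.edge_num = orig.edge_num
    return t


def graft(phy: Phylogeny, attachments: list[tuple[str, int, float]],
          provenance: str | int = "ml") -> GraftedTree:
    """Attach query tips at the midpoints of their placement edges.

    Queries placed on the same edge share one attachment node at the original
    edge midpoint, so their mutual patristic distance is the sum of their
    pendant lengths.
    """
    t = _clone_with_edge_nums(phy)
    by_edge: dict[int, list[tuple[str, float]]] = {}
    for read_id, edge_num, pendant in attachments:
        by_edge.setdefault(edge_num, []).append((read_id, pendant))
    node_of = {nd.edge_num: nd for nd in t.preorder_node_iter()
               if nd.edge_num is not None}
    for edge_num, reads in sorted(by_edge.items()):
        v = node_of[edge_num]
        u = v.parent_node
        half = v.edge.length / 2.0
        u.remove_child(v)
        x = u.new_child(edge_length=half)
        x.add_child(v)
        v.edge.length = half
        for read_id, pendant in sorted(reads):
            taxon = t.taxon_namespace.require_taxon(label=read_id)
            x.new_child(taxon=taxon, edge_length=pendant)
    query_ids = sorted(r for r, _, _ in attachments)
    return GraftedTree(t, query_ids, provenance)


def build_replicate_trees(
    ref_tree: Phylogeny,
    distributions: dict[str, PlacementDistribution],
    placements: dict[str, dict[int, tuple[float, float]]] | list[Placement],
    B: int = 100,
    seed: int = 0,
) -> tuple[GraftedTree, list[GraftedTree]]:
    """ML grafted tree plus B replicate grafted trees.

    Replicate b attaches each query at an edge drawn independently from its
    bootstrap distribution; the pendant length used at an edge is the ML
    pendant length for that edge (``placements`` may be a per-read, per-edge
    table of (log_likelihood, pendant) pairs, or a flat list of ML
    placements, in which case the ML pendant length is reused on every edge).
    """
    if isinstance(placements, list):
        ml = {p.read_id: p for p in placements}
        pendant_of = {
            r: (lambda e, p=p: p.pendant_length) for r, p in ml.items()
        }
    else:
        ml = {}
        pendant_of = {}
        for read_id, table in placements.items():
            best_edge = max(table, key=lambda e: (table[e][0], -e))
            ml[read_id] = Placement(read_id, best_edge, table[best_edge][1],
                                    table[best_edge][0])
            pendant_of[read_id] = (lambda e, t=table: t[e][1])
    for read_id in ml:
        if read_id not in distributions or not distributions[read_id].freq:
            raise ConsistencyError(f"read {read_id!r} has no placement distribution")
    ml_tree = graft(
        ref_tree,
        [(r, p.edge_num, p.pendant_length) for r, p in sorted(ml.items())],
        provenance="ml",
    )
    replicates = []
    read_ids = sorted(ml)
    draws = {}
    for read_id in read_ids:
        dist = distributions[read_id]
        edges = np.array(sorted(dist.freq))
        probs = np.array([dist.freq[e] for e in edges])
        rng = _read_rng(seed, read_id)
        draws[read_id] = edges[rng.choice(len(edges), size=B, p=probs)]
    for b in range(B):
        attachments = [
            (r, int(draws[r][b]), float(pendant_of[r](int(draws[r][b]))))
            for r in read_ids
        ]
        replicates.append(graft(ref_tree, attachments, provenance=b))
    return ml_tree, replicates


def prune_to_queries(grafted: GraftedTree) -> QueryTree:
    """Remove all reference leaves, suppressing degree-2 nodes by summing
    branch lengths; query-query patristic distances are preserved."""
    if len(grafted.query_ids) < 2:
        raise ValueError("need at least 2 query leaves to prune to")
    t = grafted.tree.clone(depth=1)
    t.retain_taxa_with_labels(grafted.query_ids)
    # collapse a leftover unifurcate root into its child
    while len(t.seed_node.child_nodes()) == 1:
        child = t.seed_node.child_nodes()[0]
        for gc in list(child.child_nodes()):
            child.remove_child(gc)
            t.seed_node.add_child(gc)
        t.seed_node.remove_child(child)
        if child.is_leaf():
            break
    return QueryTree(t, list(grafted.query_ids), grafted.provenance)


def long_branch_filter(placements: list[Placement],
                       percentile: float = 95.0) -> list[str]:
    """Retain reads whose pendant length is <= the given percentile
    (linear interpolation) of all pendant lengths."""
    if not placements:
        raise ValueError("no placements to filter")
    lengths = np.array([p.pendant_length for p in placements])
    cut = np.percentile(lengths, percentile)
    return [p.read_id for p in placements if p.pendant_length <= cut]
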