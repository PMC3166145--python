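"""Independent oracles: brute-force implementations used only by tests.

These deliberately avoid the code paths they check — exhaustive enumeration
for the pruning likelihood, grid search for placement, naive clustering and
path-walking for distances.
"""

from __future__ import annotations

import itertools

import numpy as np

from phylopd.formats import Phylogeny
from phylopd.likelihood import (
    SubstitutionModel,
    discrete_gamma_rates,
    encode_residues,
)


def enumeration_log_likelihood(phy: Phylogeny, rows: dict[str, str],
                               alpha: float, K: int,
                               mult: float = 1.0) -> float:
    """Sum over all internal-state assignments and rate categories."""
    model = SubstitutionModel(n_categories=K)
    rates = discrete_gamma_rates(alpha, K)
    pi = model.stationary_freqs
    t = phy.tree
    nodes = list(t.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    enc = {k: encode_residues(v) for k, v in rows.items()}
    ncols = len(next(iter(rows.values())))
    total = 0.0
    for c in range(ncols):
        site = 0.0
        for r in rates:
            P = {
                id(n): model.transition_matrix((n.edge.length or 0) * mult * r)
                for n in nodes
            }
            s_r = 0.0
            for assign in itertools.product(range(20), repeat=len(internal)):
                st = {id(n): a for n, a in zip(internal, assign)}
                for n in nodes:
                    if n.is_leaf():
                        st[id(n)] = enc[n.taxon.label][c]
                prob = pi[st[id(t.seed_node)]]
                for n in nodes:
                    if n is t.seed_node:
                        continue
                    cs = st[id(n)]
                    if cs < 0:
                        continue  # missing data marginalizes to 1
                    prob *= P[id(n)][st[id(n.parent_node)], cs]
                s_r += prob
            site += s_r / len(rates)
        total += np.log(site)
    return float(total)


def naive_complete_linkage(d: np.ndarray, cutoff: float) -> list[frozenset]:
    """O(n^3) agglomerative complete linkage: merge the closest pair of
    clusters while their complete-linkage distance stays <= cutoff."""
    clusters = [frozenset([i]) for i in range(d.shape[0])]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = max(
                    d[i, j] for i in clusters[a] for j in clusters[b]
                )
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        if best[0] > cutoff:
            break
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return clusters


def path_distance(tree, label_a: str, label_b: str) -> float:
    """Patristic distance by explicitly walking parent chains to the MRCA."""
    nodes = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    def chain(nd):
        out = []
        while nd is not None:
            out.append(nd)
            nd = nd.parent_node
        return out
    ca = chain(nodes[label_a])
    cb = set(id(n) for n in chain(nodes[label_b]))
    dist = 0.0
    nd = nodes[label_a]
    while id(nd) not in cb:
        dist += nd.edge.length
        nd = nd.parent_node
    mrca = nd
    nd = nodes[label_b]
    while nd is not mrca:
        dist += nd.edge.length
        nd = nd.parent_node
    return dist


def gaussian_aic(x: np.ndarray, y: np.ndarray, degree: int) -> float:
    """From-scratch OLS + Gaussian ML AIC with the variance counted as a
    free parameter."""
    X = np.vander(x, degree + 1, increasing=True)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    n = y.size
    sigma2 = float(resid @ resid) / n
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return 2 * (degree + 2) - 2 * ll
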