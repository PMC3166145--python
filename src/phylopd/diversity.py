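"""Null-model phylogenetic diversity and OTU richness per sample.

The central statistic is the standardized effect size of mean pairwise
phylogenetic distance:

    SES_MPD = (MPD_obs - mean(MPD_null)) / sd(MPD_null)

where the null distribution comes from repeatedly drawing the observed number
of sequences uniformly, without replacement, from the pool of all placed
reads in the query tree (999 draws by default).  Negative values indicate
phylogenetic clustering (co-occurring reads more closely related than
chance), positive values phylogenetic evenness.  Because every read is a tip,
relative abundance enters the statistic directly, with no OTU binning.

Taxonomic diversity is computed separately as OTU richness under
complete-linkage clustering of the tree-derived distances at a distance
cutoff (a similarity cutoff s maps to distance 1 - s).
"""

from __future__ import annotations

from dataclasses import dataclass
from hashlib import sha256

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .formats import ConsistencyError, SampleMap
from .placement import QueryTree


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")
        self._index = {x: i for i, x in enumerate(self.ids)}

    def submatrix(self, ids: list[str]) -> np.ndarray:
        idx = np.array([self._index[x] for x in ids])
        return self.d[np.ix_(idx, idx)]


@dataclass
class CommunityMatrix:
    """Sample x sequence incidence (each read belongs to one sample)."""

    samples: list[str]
    sequence_ids: list[str]
    incidence: np.ndarray

    @classmethod
    def from_sample_map(cls, sample_map: SampleMap,
                        sequence_ids: list[str]) -> "CommunityMatrix":
        samples = sample_map.samples
        inc = np.zeros((len(samples), len(sequence_ids)), dtype=int)
        srow = {s: i for i, s in enumerate(samples)}
        for j, read in enumerate(sequence_ids):
            if read not in sample_map.read_to_sample:
                raise ConsistencyError(f"read {read!r} missing from sample map")
            inc[srow[sample_map.read_to_sample[read]], j] = 1
        return cls(samples, list(sequence_ids), inc)

    def members(self, sample_id: str) -> list[str]:
        i = self.samples.index(sample_id)
        return [s for s, v in zip(self.sequence_ids, self.incidence[i]) if v]


@dataclass
class DiversityResult:
    sample_id: str
    n_seqs: int
    mpd_obs: float
    null_mean: float
    null_sd: float
    ses: float
    null_rank_p: float
    degenerate: bool = False
    tree_provenance: str | int = "ml"


def patristic_matrix(tree: QueryTree) -> DistanceMatrix:
    """All pairwise path-length distances between query leaves."""
    t = tree.tree
    leaves = [lf for lf in t.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("need at least 2 leaves")
    labels = sorted(lf.taxon.label for lf in leaves)
    pdm = t.phylogenetic_distance_matrix()
    taxon = {lf.taxon.label: lf.taxon for lf in leaves}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(
                taxon[labels[i]], taxon[labels[j]]
            )
    return DistanceMatrix(labels, d)


def mpd(sample_ids: list[str], dm: DistanceMatrix) -> float:
    """Mean pairwise distance over all unordered distinct pairs."""
    n = len(sample_ids)
    if n < 2:
        raise ValueError("MPD requires at least 2 sequences")
    sub = dm.submatrix(sample_ids)
    iu = np.triu_indices(n, k=1)
    return float(sub[iu].mean())


def _null_rng(seed: int, sample_id: str, tree_index) -> np.random.Generator:
    h = int.from_bytes(sha256(f"{sample_id}|{tree_index}".encode()).digest()[:4],
                       "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))


def ses_mpd(
    sample_ids: list[str],
    dm: DistanceMatrix,
    n_null: int = 999,
    seed: int = 0,
    sample_label: str = "",
    tree_provenance: str | int = "ml",
) -> DiversityResult:
    """Standardized effect size of MPD against the random-draw null.

    Null replicates draw ``len(sample_ids)`` ids uniformly without
    replacement from all ids in the distance matrix.  A degenerate null
    (sd = 0, e.g. a star tree) is reported as ses = 0 with a flag.
    """
    n = len(sample_ids)
    pool = dm.ids
    if not 2 <= n <= len(pool):
        raise ValueError(f"sample size {n} outside [2, pool size {len(pool)}]")
    if n == len(pool):
        raise ValueError("sample equals the whole pool: null sd is zero")
    obs = mpd(sample_ids, dm)
    rng = _null_rng(seed, sample_label or ",".join(sample_ids[:3]),
                    tree_provenance)
    pool_arr = np.arange(len(pool))
    iu = np.triu_indices(n, k=1)
    nulls = np.empty(n_null)
    for b in range(n_null):
        idx = rng.choice(pool_arr, size=n, replace=False)
        nulls[b] = dm.d[np.ix_(idx, idx)][iu].mean()
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1))
    degenerate = null_sd < 1e-12
    ses = 0.0 if degenerate else (obs - null_mean) / null_sd
    rank = 1 + int((nulls < obs).sum())
    return DiversityResult(
        sample_id=sample_label,
        n_seqs=n,
        mpd_obs=obs,
        null_mean=null_mean,
        null_sd=null_sd,
        ses=float(ses),
        null_rank_p=rank / (n_null + 1),
        degenerate=degenerate,
        tree_provenance=tree_provenance,
    )


def ses_over_trees(
    trees: list[QueryTree],
    community: CommunityMatrix,
    n_null: int = 999,
    seed: int = 0,
) -> list[DiversityResult]:
    """One DiversityResult per (sample, tree); the null pool is each tree's
    own full leaf set (each replicate tree is standardized against itself)."""
    leaf_sets = {frozenset(lf.taxon.label for lf in t.tree.leaf_node_iter())
                 for t in trees}
    if len(leaf_sets) != 1:
        raise ConsistencyError("replicate trees have differing leaf sets")
    results = []
    for t in trees:
        dm = patristic_matrix(t)
        for sample in community.samples:
            ids = community.members(sample)
            if len(ids) < 2:
                continue
            results.append(
                ses_mpd(ids, dm, n_null=n_null, seed=seed,
                        sample_label=sample, tree_provenance=t.provenance)
            )
    return results


def results_table(results: list[DiversityResult],
                  sample_map: SampleMap | None = None) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "sample": r.sample_id, "n_seqs": r.n_seqs, "mpd_obs": r.mpd_obs,
            "null_mean": r.null_mean, "null_sd": r.null_sd, "ses": r.ses,
            "rank_p": r.null_rank_p, "tree": r.tree_provenance,
            "degenerate": r.degenerate,
        }
        if sample_map is not None:
            row["depth_m"] = sample_map.sample_depth[r.sample_id]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# OTU binning
# ---------------------------------------------------------------------------

def otu_bin(dm: DistanceMatrix, cutoff: float) -> dict[str, int]:
    """Complete-linkage OTUs: merge while the maximum within-cluster pairwise
    distance stays <= cutoff.  Returns sequence id -> OTU label (1-based)."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    n = len(dm.ids)
    if n == 1:
        return {dm.ids[0]: 1}
    z = linkage(squareform(dm.d, checks=False), method="complete")
    labels = fcluster(z, t=cutoff, criterion="distance")
    return dict(zip(dm.ids, (int(x) for x in labels)))


def otu_richness(assignment: dict[str, int],
                 community: CommunityMatrix) -> dict[str, int]:
    """Number of OTUs with at least one read in each sample."""
    out = {}
    for sample in community.samples:
        otus = {assignment[r] for r in community.members(sample)}
        out[sample] = len(otus)
    return out


def similarity_to_distance_cutoff(similarity: float) -> float:
    """Map a similarity cutoff (e.g. 0.95) to a distance cutoff (0.05)."""
    if not 0 <= similarity <= 1:
        raise ValueError("similarity must be in [0, 1]")
    return 1.0 - similarity
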