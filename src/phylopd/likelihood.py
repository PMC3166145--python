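"""Partitioned amino-acid likelihood engine (WAG exchangeabilities + discrete Γ).

The engine evaluates the likelihood of aligned amino-acid data on a *fixed*
tree (topology and branch lengths given) by Felsenstein's pruning algorithm,
with among-site rate variation modelled by K equal-probability discrete gamma
categories and among-family rate variation by per-partition gamma shapes and
mean-one rate multipliers.  Gaps, ``X`` and lowercase (masked) residues are
all treated as missing data: their conditional likelihood vector is all ones,
so a column that is missing in every row contributes exactly zero
log-likelihood.

State order follows the PAML convention ``ARNDCQEGHILKMFPSTWYV``; the WAG
exchangeabilities and stationary frequencies are the published Whelan-Goldman
(2001) constants.  Empirical (+F) frequencies are deliberately not used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
from scipy.optimize import minimize_scalar

from .formats import ConsistencyError
from .scaffold import ConcatenatedAlignment, Partition

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_STATE_OF = {c: i for i, c in enumerate(AA_ORDER)}

# Whelan & Goldman (2001) exchangeabilities, upper triangle row-major in the
# AA_ORDER state order (s[i][j] for i < j), and stationary frequencies.
WAG_EXCHANGEABILITIES_UPPER = [
    0.551571, 0.509848, 0.738998, 1.02704, 0.908598, 1.58285, 1.41672,
    0.316954, 0.193335, 0.397915, 0.906265, 0.893496, 0.210494, 1.43855,
    3.37079, 2.12111, 0.113133, 0.240735, 2.00601, 0.635346, 0.147304,
    0.528191, 3.0355, 0.439157, 0.584665, 2.13715, 0.186979, 0.497671,
    5.35142, 0.683162, 0.102711, 0.679489, 1.22419, 0.554413, 1.16392,
    0.381533, 0.251849, 5.42942, 0.265256, 1.54364, 0.947198, 1.12556,
    3.95629, 0.554236, 0.131528, 3.01201, 0.198221, 0.0961621, 0.195081,
    3.97423, 2.03006, 0.0719167, 1.086, 0.196246, 0.0302949, 0.616783,
    6.17416, 0.865584, 0.930676, 0.039437, 0.0848047, 0.479855, 0.103754,
    0.0467304, 0.423984, 1.07176, 0.374866, 0.129767, 0.325711, 0.152335,
    0.0988179, 0.021352, 0.306674, 0.248972, 0.170135, 0.384287, 0.0740339,
    0.390482, 0.39802, 0.109404, 1.40766, 0.512984, 0.71707, 0.543833,
    1.00214, 5.46947, 0.330052, 4.29411, 0.113917, 0.869489, 3.8949,
    1.54526, 0.0999208, 0.933372, 1.02887, 0.857928, 0.215737, 0.22771,
    0.301281, 0.567717, 0.570025, 0.127395, 0.154263, 2.58443, 0.315124,
    0.0811339, 0.682355, 0.704939, 0.822765, 0.156557, 0.196303, 0.588731,
    0.24941, 0.0304501, 0.0613037, 0.373558, 0.1741, 0.049931, 0.24357,
    1.34182, 0.225833, 0.336983, 0.103604, 0.187247, 0.13819, 0.499462,
    0.890432, 0.404141, 0.679371, 0.696198, 0.740169, 0.473307, 0.262569,
    3.87344, 0.118358, 3.17097, 0.323832, 4.25746, 1.05947, 0.0999288,
    0.31944, 1.45816, 0.212483, 0.42017, 7.8213, 0.257555, 4.85402, 2.11517,
    0.415844, 0.344739, 0.326622, 0.665309, 0.398618, 1.80034, 0.934276,
    0.088836, 0.556896, 0.96713, 1.38698, 0.137505, 0.133264, 0.305434,
    1.19063, 0.171329, 0.493905, 1.51612, 0.515706, 0.428437, 2.05845,
    0.161444, 0.545931, 0.171903, 1.52964, 6.45428, 0.649892, 1.61328,
    0.795384, 0.139405, 0.216046, 0.314887, 4.37802, 0.523742, 0.786993,
    0.232739, 0.110864, 0.291148, 1.38823, 2.48539, 0.365369, 0.31473,
]

WAG_FREQS = np.array([
    0.0866279, 0.043972, 0.0390894, 0.0570451, 0.0193078, 0.0367281,
    0.0580589, 0.0832518, 0.0244313, 0.048466, 0.0862090, 0.0620286,
    0.0195027, 0.0384319, 0.0457631, 0.0695179, 0.0610127, 0.0143859,
    0.0352742, 0.0708956,
])
WAG_FREQS = WAG_FREQS / WAG_FREQS.sum()


def _exchange_matrix(upper: list[float]) -> np.ndarray:
    s = np.zeros((20, 20))
    k = 0
    for i in range(20):
        for j in range(i + 1, 20):
            s[i, j] = s[j, i] = upper[k]
            k += 1
    return s


def encode_residues(residues: str) -> np.ndarray:
    """Map a row of residues to state indices; -1 marks missing data
    (gap, X, or lowercase/masked)."""
    return np.array([_STATE_OF.get(c, -1) for c in residues], dtype=np.int64)


def discrete_gamma_rates(alpha: float, K: int = 4) -> np.ndarray:
    """Mean-one discrete gamma rates: the mean of each of K equal-probability
    quantile bins of Gamma(alpha, 1/alpha) (Yang's standard discretisation)."""
    if alpha <= 0:
        raise ValueError(f"gamma shape must be > 0, got {alpha}")
    if K < 1:
        raise ValueError(f"need at least one category, got {K}")
    if K == 1:
        return np.ones(1)
    edges = stats.gamma.ppf(np.arange(K + 1) / K, a=alpha, scale=1.0 / alpha)
    # E[X | bin] * P(bin)^-1 with E[X·1{X<q}] = F_{alpha+1}(q) for mean-1 gamma
    upper_cdf = special.gammainc(alpha + 1.0, edges * alpha)
    rates = K * np.diff(upper_cdf)
    return rates


@dataclass
class SubstitutionModel:
    """Reversible amino-acid CTMC with discrete-gamma rate variation.

    The rate matrix Q built from the exchangeabilities and stationary
    frequencies is normalised to one expected substitution per site per unit
    branch length.
    """

    exchangeabilities: np.ndarray = field(
        default_factory=lambda: _exchange_matrix(WAG_EXCHANGEABILITIES_UPPER)
    )
    stationary_freqs: np.ndarray = field(default_factory=lambda: WAG_FREQS.copy())
    gamma_shape: float = 1.0
    n_categories: int = 4

    def __post_init__(self) -> None:
        pi = np.asarray(self.stationary_freqs, dtype=float)
        if abs(pi.sum() - 1.0) > 1e-8 or (pi <= 0).any():
            raise ValueError("stationary frequencies must be positive and sum to 1")
        s = np.asarray(self.exchangeabilities, dtype=float)
        if (s < 0).any() or not np.allclose(s, s.T):
            raise ValueError("exchangeabilities must be symmetric and non-negative")
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        q /= mu
        self.Q = q
        # symmetrized eigendecomposition for fast, stable matrix exponentials
        sqrt_pi = np.sqrt(pi)
        b = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        lam, v = np.linalg.eigh((b + b.T) / 2.0)
        self._lam = lam
        self._left = v / sqrt_pi[:, None]       # D^{-1/2} V
        self._right = (v * sqrt_pi[:, None]).T  # V^T D^{1/2}
        self.stationary_freqs = pi

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one."""
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        p = (self._left * np.exp(self._lam * t)) @ self._right
        return np.clip(p, 0.0, None)

    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    return model.transition_matrix(t)


@dataclass
class PartitionedModel:
    """Shared WAG exchangeabilities/frequencies with per-partition gamma shape
    and mean-one rate multiplier (stored on each :class:`Partition`)."""

    partitions: list[Partition]
    base: SubstitutionModel = field(default_factory=SubstitutionModel)
    n_categories: int = 4

    def __post_init__(self) -> None:
        self.base.n_categories = self.n_categories

    def params_of(self, family_id: str) -> tuple[float, float]:
        p = next(p for p in self.partitions if p.family_id == family_id)
        return p.gamma_shape, p.rate_multiplier

    def to_json(self, path) -> None:
        doc = {
            "model": "WAG+G",
            "n_categories": self.n_categories,
            "partitions": [
                {"family_id": p.family_id, "start": p.start, "end": p.end,
                 "gamma_shape": p.gamma_shape,
                 "rate_multiplier": p.rate_multiplier}
                for p in self.partitions
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PartitionedModel":
        with open(path) as fh:
            doc = json.load(fh)
        parts = [
            Partition(d["family_id"], d["start"], d["end"],
                      d["rate_multiplier"], d["gamma_shape"])
            for d in doc["partitions"]
        ]
        return cls(partitions=parts, n_categories=int(doc["n_categories"]))


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

_SCALE_EVERY = 1e-280


def _tip_conditionals(states: np.ndarray, K: int) -> np.ndarray:
    """(K, cols, 20) conditional likelihoods for a tip; missing -> ones."""
    cols = states.shape[0]
    out = np.zeros((cols, 20))
    observed = states >= 0
    out[observed, states[observed]] = 1.0
    out[~observed, :] = 1.0
    return np.broadcast_to(out, (K, cols, 20)).copy()


def _prune_partition(
    phy,
    states_by_label: dict[str, np.ndarray],
    model: SubstitutionModel,
    alpha: float,
    multiplier: float,
) -> float:
    """Log-likelihood of one partition's columns on a fixed tree."""
    K = model.n_categories
    rates = discrete_gamma_rates(alpha, K)
    pi = model.stationary_freqs
    partials: dict[int, np.ndarray] = {}
    scalers: dict[int, np.ndarray] = {}
    for nd in phy.tree.postorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label
            if label not in states_by_label:
                raise ConsistencyError(f"leaf {label!r} has no alignment row")
            partials[id(nd)] = _tip_conditionals(states_by_label[label], K)
            scalers[id(nd)] = np.zeros(states_by_label[label].shape[0])
            continue
        acc = None
        scale = None
        for child in nd.child_nodes():
            t = child.edge.length * multiplier
            pmats = np.stack([model.transition_matrix(t * r) for r in rates])
            contrib = np.einsum("kij,kcj->kci", pmats, partials.pop(id(child)))
            acc = contrib if acc is None else acc * contrib
            cs = scalers.pop(id(child))
            scale = cs if scale is None else scale + cs
        # rescale columns that are drifting toward underflow
        colmax = acc.max(axis=(0, 2))
        small = colmax < _SCALE_EVERY
        if small.any():
            factor = np.where(small, colmax, 1.0)
            acc = acc / factor[None, :, None]
            scale = scale + np.log(factor, where=factor > 0,
                                   out=np.zeros_like(factor))
        partials[id(nd)] = acc
        scalers[id(nd)] = scale
    root = phy.tree.seed_node
    site_lik = (partials[id(root)] @ pi).mean(axis=0)
    return float(np.log(site_lik).sum() + scalers[id(root)].sum())


def log_likelihood(
    phy,
    rows: dict[str, str] | ConcatenatedAlignment,
    pmodel: PartitionedModel,
) -> float:
    """Total log-likelihood: sum of per-partition pruning log-likelihoods,
    each with its own gamma shape and rate multiplier."""
    if isinstance(rows, ConcatenatedAlignment):
        rows = rows.rows
    leaf_set = set(phy.leaf_labels)
    if leaf_set - set(rows):
        raise ConsistencyError(
            f"leaves without alignment rows: {sorted(leaf_set - set(rows))}"
        )
    encoded = {label: encode_residues(rows[label]) for label in leaf_set}
    total = 0.0
    for part in pmodel.partitions:
        states = {
            label: enc[part.start:part.end] for label, enc in encoded.items()
        }
        total += _prune_partition(
            phy, states, pmodel.base, part.gamma_shape, part.rate_multiplier
        )
    return total


# ---------------------------------------------------------------------------
# Model fitting on a fixed tree
# ---------------------------------------------------------------------------

_ALPHA_BOUNDS = (0.03, 50.0)
_MULT_BOUNDS = (0.05, 20.0)


def _partition_ll_fn(phy, concat: ConcatenatedAlignment, base, part: Partition):
    encoded = {
        t: encode_residues(concat.rows[t][part.start:part.end])
        for t in concat.taxa
    }

    def ll(alpha: float, mult: float) -> float:
        return _prune_partition(phy, encoded, base, alpha, mult)

    return ll


def fit_gamma_shapes(
    phy,
    concat: ConcatenatedAlignment,
    mode: str = "partitioned",
    n_categories: int = 4,
    max_sweeps: int = 3,
) -> tuple[PartitionedModel, float]:
    """Fit gamma shapes (and, for the partitioned model, mean-one rate
    multipliers) on a fixed tree by bounded 1-D optimisation.

    ``mode='unpartitioned'`` fits one global shape with all multipliers 1;
    ``mode='partitioned'`` fits a shape per gene family plus per-family rate
    multipliers constrained to mean one.  The partitioned optimum is searched
    by per-partition profile optimisation followed by a feasible line search,
    starting from the unpartitioned fit so the partitioned log-likelihood can
    never fall below it (the models are nested).
    """
    if mode not in ("partitioned", "unpartitioned"):
        raise ValueError(f"unknown mode {mode!r}")
    base = SubstitutionModel(n_categories=n_categories)
    ll_fns = [_partition_ll_fn(phy, concat, base, p) for p in concat.partitions]
    P = len(concat.partitions)

    def total_ll(alphas, mults) -> float:
        return sum(f(a, m) for f, a, m in zip(ll_fns, alphas, mults))

    # global single-shape fit (always the starting point)
    res = minimize_scalar(
        lambda a: -total_ll([a] * P, [1.0] * P),
        bounds=_ALPHA_BOUNDS, method="bounded",
        options={"xatol": 1e-4},
    )
    alpha0, ll_global = float(res.x), -float(res.fun)

    if mode == "unpartitioned" or P == 1:
        # with one partition the mean-one constraint forces multiplier 1, so
        # the partitioned and unpartitioned fits coincide
        parts = [
            Partition(p.family_id, p.start, p.end, 1.0, alpha0)
            for p in concat.partitions
        ]
        return PartitionedModel(parts, base, n_categories), ll_global

    alphas = [alpha0] * P
    mults = [1.0] * P
    best_ll = ll_global
    for _ in range(max_sweeps):
        # unconstrained per-partition profile optimum (separable)
        prof_alphas, prof_mults = [], []
        for f, a in zip(ll_fns, alphas):
            ra = minimize_scalar(lambda x: -f(x, 1.0), bounds=_ALPHA_BOUNDS,
                                 method="bounded", options={"xatol": 1e-4})
            rm = minimize_scalar(lambda m: -f(float(ra.x), m),
                                 bounds=_MULT_BOUNDS, method="bounded",
                                 options={"xatol": 1e-4})
            prof_alphas.append(float(ra.x))
            prof_mults.append(float(rm.x))
        target = np.array(prof_mults) / np.mean(prof_mults)  # project to mean 1
        # feasible line search: mean stays 1 along the segment
        cur = np.array(mults)
        best_gamma, improved = 0.0, False
        for g in np.linspace(0.0, 1.0, 11):
            cand = cur + g * (target - cur)
            ll = total_ll(prof_alphas, cand)
            if ll > best_ll + 1e-9:
                best_ll, best_gamma, improved = ll, g, True
        mults = list(cur + best_gamma * (target - cur))
        # re-profile shapes at the accepted multipliers (monotone, feasible)
        new_alphas = []
        for f, m, a in zip(ll_fns, mults, prof_alphas):
            ra = minimize_scalar(lambda x: -f(x, m), bounds=_ALPHA_BOUNDS,
                                 method="bounded", options={"xatol": 1e-4})
            new_alphas.append(float(ra.x))
        alphas = new_alphas
        ll_now = total_ll(alphas, mults)
        if ll_now > best_ll:
            best_ll = ll_now
        if not improved:
            break
    parts = [
        Partition(p.family_id, p.start, p.end, m, a)
        for p, a, m in zip(concat.partitions, alphas, mults)
    ]
    return PartitionedModel(parts, base, n_categories), best_ll


def likelihood_ratio_test(
    ll_partitioned: float, ll_unpartitioned: float, df: int
) -> tuple[float, float]:
    """Chi-squared LRT of the partitioned against the single-shape model.

    The statistic is 2(llp - llu); df is the number of extra free parameters
    of the partitioned model (P shapes + P-1 mean-one multipliers vs one
    global shape, i.e. 2(P-1)).
    """
    stat = 2.0 * (ll_partitioned - ll_unpartitioned)
    if stat < -1e-6:
        raise ValueError(
            f"negative LRT statistic {stat}: optimizer failed to reach the "
            "nested optimum"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, p


def partitioned_df(n_partitions: int) -> int:
    """Extra free parameters of the partitioned model over the global one."""
    return 2 * (n_partitions - 1)
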