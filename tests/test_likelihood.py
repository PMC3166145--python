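"""WAG+G likelihood engine: CTMC properties, discrete gamma, pruning, fitting."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import phylopd as pp
from phylopd.formats import ConsistencyError, Phylogeny
from phylopd.likelihood import (
    AA_ORDER,
    PartitionedModel,
    SubstitutionModel,
    discrete_gamma_rates,
    fit_gamma_shapes,
    likelihood_ratio_test,
    log_likelihood,
    partitioned_df,
)
from phylopd.scaffold import Partition, concatenate

from oracles import enumeration_log_likelihood

AA = AA_ORDER


class TestTransitionMatrix:
    model = SubstitutionModel()

    def test_zero_time_is_identity(self):
        assert np.allclose(self.model.transition_matrix(0.0), np.eye(20))

    def test_rows_are_distributions(self):
        p = self.model.transition_matrix(0.37)
        assert (p >= 0).all()
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_ergodic_limit_is_stationary(self):
        p = self.model.transition_matrix(1e4)
        assert np.abs(p - self.model.stationary_freqs[None, :]).max() < 1e-6

    def test_detailed_balance(self):
        pi = self.model.stationary_freqs
        p = self.model.transition_matrix(0.3)
        flux = pi[:, None] * p
        assert np.abs(flux - flux.T).max() < 1e-10

    def test_chapman_kolmogorov(self):
        p1 = self.model.transition_matrix(0.11)
        p2 = self.model.transition_matrix(0.43)
        p12 = self.model.transition_matrix(0.54)
        assert np.abs(p1 @ p2 - p12).max() < 1e-9

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            self.model.transition_matrix(-0.1)

    def test_mean_rate_normalized_to_one(self):
        pi = self.model.stationary_freqs
        assert abs(-(pi * np.diag(self.model.Q)).sum() - 1.0) < 1e-12


class TestDiscreteGamma:
    def test_single_category(self):
        assert discrete_gamma_rates(0.5, 1) == pytest.approx([1.0])

    def test_huge_shape_collapses_to_one(self):
        assert np.abs(discrete_gamma_rates(1e6, 4) - 1.0).max() < 1e-2

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 1.0, 3.7])
    def test_matches_quadrature_oracle(self, alpha):
        K = 4
        edges = stats.gamma.ppf(np.arange(K + 1) / K, a=alpha, scale=1 / alpha)
        expected = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m, _ = integrate.quad(
                lambda x: x * stats.gamma.pdf(x, a=alpha, scale=1 / alpha),
                lo, hi if np.isfinite(hi) else np.inf, limit=200,
            )
            expected.append(K * m)
        got = discrete_gamma_rates(alpha, K)
        assert np.abs(got - np.array(expected)).max() < 1e-6

    @pytest.mark.parametrize("alpha,K", [(0.1, 4), (0.7, 8), (2.0, 4)])
    def test_positive_nondecreasing_mean_one(self, alpha, K):
        r = discrete_gamma_rates(alpha, K)
        assert (r > 0).all()
        assert (np.diff(r) >= 0).all()
        assert abs(r.mean() - 1.0) < 1e-9

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            discrete_gamma_rates(0.0, 4)


def _random_rows(rng, labels, ncols, gap_rate=0.2):
    return {
        lab: "".join(
            "-" if rng.random() < gap_rate else AA[rng.integers(20)]
            for _ in range(ncols)
        )
        for lab in labels
    }


class TestLogLikelihood:
    def test_single_leaf_closed_form(self):
        phy = Phylogeny.from_newick("(A:0.1,B:0.2);")
        model = SubstitutionModel(n_categories=1)
        pm = PartitionedModel([Partition("f", 0, 1, 1.0, 1.0)],
                              n_categories=1)
        # B missing: only A's stationary term and the missing column survive
        ll = log_likelihood(phy, {"A": "A", "B": "-"}, pm)
        assert ll == pytest.approx(math.log(model.stationary_freqs[0]),
                                   abs=1e-12)

    def test_all_missing_column_contributes_zero(self):
        phy = Phylogeny.from_newick("(A:0.1,(B:0.2,C:0.3):0.05);")
        pm = PartitionedModel([Partition("f", 0, 2, 1.0, 0.8)],
                              n_categories=2)
        base = log_likelihood(phy, {"A": "AC", "B": "AD", "C": "-C"}, pm)
        pm_wide = PartitionedModel([Partition("f", 0, 3, 1.0, 0.8)],
                                   n_categories=2)
        wide = log_likelihood(phy, {"A": "AC-", "B": "AD-", "C": "-C-"},
                              pm_wide)
        assert wide == pytest.approx(base, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nl = int(rng.integers(3, 6))
        cfg = pp.SimulationConfig(n_reference_taxa=nl, n_families=1,
                                  columns_per_family=4,
                                  seed=int(rng.integers(10_000)))
        phy = pp.simulate_reference(cfg).phylogeny
        ncols = int(rng.integers(2, 5))
        rows = _random_rows(rng, phy.leaf_labels, ncols)
        K = int(rng.integers(1, 3))
        alpha = float(rng.uniform(0.3, 2.0))
        pm = PartitionedModel([Partition("f", 0, ncols, 1.0, alpha)],
                              n_categories=K)
        assert log_likelihood(phy, rows, pm) == pytest.approx(
            enumeration_log_likelihood(phy, rows, alpha, K), abs=1e-8
        )

    def test_invariant_to_serialized_rooting(self):
        rows = {"A": "ACDE", "B": "AC-E", "C": "GCDE", "D": "AKDE"}
        pm = PartitionedModel([Partition("f", 0, 4, 1.0, 0.9)],
                              n_categories=2)
        t1 = Phylogeny.from_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.1):0.07);")
        t2 = Phylogeny.from_newick("(C:0.3,(D:0.1,(A:0.1,B:0.2):0.12):0.0);")
        assert log_likelihood(t1, rows, pm) == pytest.approx(
            log_likelihood(t2, rows, pm), abs=1e-8
        )

    def test_leaf_row_mismatch_rejected(self):
        phy = Phylogeny.from_newick("(A:0.1,B:0.2);")
        pm = PartitionedModel([Partition("f", 0, 1, 1.0, 1.0)])
        with pytest.raises(ConsistencyError):
            log_likelihood(phy, {"A": "A"}, pm)


class TestFitting:
    def test_shape_recovery_from_simulation(self):
        cfg = pp.SimulationConfig(n_reference_taxa=16, n_families=1,
                                  columns_per_family=2000, gamma_shape=0.7,
                                  seed=31)
        ref = pp.simulate_reference(cfg)
        concat = concatenate(ref.families, sorted(ref.phylogeny.leaf_labels))
        model, _ = fit_gamma_shapes(ref.phylogeny, concat,
                                    mode="unpartitioned")
        assert abs(model.partitions[0].gamma_shape - 0.7) < 0.2

    def test_single_partition_fits_coincide(self, small_ref):
        ref, _ = small_ref
        concat = concatenate(ref.families, sorted(ref.phylogeny.leaf_labels))
        m_u, ll_u = fit_gamma_shapes(ref.phylogeny, concat,
                                     mode="unpartitioned")
        m_p, ll_p = fit_gamma_shapes(ref.phylogeny, concat,
                                     mode="partitioned")
        assert ll_p == pytest.approx(ll_u, abs=1e-6)
        assert m_p.partitions[0].rate_multiplier == 1.0

    def test_partitioned_never_below_unpartitioned(self, two_family_ref):
        ref, _ = two_family_ref
        concat = concatenate(ref.families, sorted(ref.phylogeny.leaf_labels))
        _, ll_u = fit_gamma_shapes(ref.phylogeny, concat,
                                   mode="unpartitioned")
        model, ll_p = fit_gamma_shapes(ref.phylogeny, concat,
                                       mode="partitioned")
        assert ll_p >= ll_u - 1e-6
        mults = [p.rate_multiplier for p in model.partitions]
        assert np.mean(mults) == pytest.approx(1.0, abs=1e-9)


class TestLikelihoodRatioTest:
    def test_reported_model_comparison_arithmetic(self):
        # published fixed-tree fits: partitioned -1,968,521 vs global
        # -1,969,550 -> statistic 2058, significant at any plausible df
        stat, _ = likelihood_ratio_test(-1_968_521.0, -1_969_550.0, 60)
        assert stat == pytest.approx(2058.0)
        for df in (1, 10, 30, 60):
            _, p = likelihood_ratio_test(-1_968_521.0, -1_969_550.0, df)
            assert p < 0.001

    def test_equal_likelihoods(self):
        stat, p = likelihood_ratio_test(-10.0, -10.0, 3)
        assert stat == 0.0
        assert p == 1.0

    def test_chi2_quantile(self):
        _, p = likelihood_ratio_test(-8.08, -10.0, 1)  # stat = 3.84
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(-11.0, -10.0, 1)

    def test_df_counting(self):
        assert partitioned_df(1) == 0
        assert partitioned_df(31) == 60
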