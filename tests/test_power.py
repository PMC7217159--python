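import itertools

import numpy as np
import pytest
from scipy import stats

from opencohort import (BlockExchangeableComponents, ConstantChurn,
                        PowerQuery, SingularDesignError, TrialDesign,
                        clusters_required, compute_r,
                        cov_matrix_block_exchangeable, design_effect,
                        expand_to_clusters, gls_power, gls_variance,
                        individually_randomized_n, parallel_design,
                        power_curve, power_from_design_effect, stepped_wedge)

GRID = list(itertools.product(
    [0.0, 0.05, 0.33],      # rho
    [0.5, 0.9, 1.0],        # pi
    [0.0, 0.7],             # tau
    [0.0, 0.3, 1.0],        # chi
    [1, 10],                # m
    [2, 3],                 # stepped wedge sequences
))


def brute_force_gls_variance(design, V):
    """Independent oracle: invert the full fixed-effects information matrix
    built from the stacked KT-vector of cluster-period means."""
    Xc = expand_to_clusters(design).astype(float)
    K, T = Xc.shape
    Sigma = np.kron(np.eye(K), V)
    Z = np.zeros((K * T, T + 1))
    for k in range(K):
        Z[k * T:(k + 1) * T, :T] = np.eye(T)      # period effects
        Z[k * T:(k + 1) * T, T] = Xc[k]           # treatment
    info = Z.T @ np.linalg.solve(Sigma, Z)
    return np.linalg.inv(info)[T, T]


class TestR:
    def test_cross_sectional_form(self):
        vc = BlockExchangeableComponents(25, 0.33, 0.9, 0.7)
        assert compute_r(vc, 10, 1.0) == pytest.approx(
            10 * 0.33 * 0.9 / (1 + 9 * 0.33))

    def test_closed_cohort_form(self):
        vc = BlockExchangeableComponents(25, 0.33, 0.9, 0.7)
        assert compute_r(vc, 10, 0.0) == pytest.approx(
            (10 * 0.33 * 0.9 + 0.67 * 0.7) / (1 + 9 * 0.33))

    @pytest.mark.parametrize("rho, pi, tau, chi, m, _", GRID)
    def test_matches_component_ratio(self, rho, pi, tau, chi, m, _):
        # Same r by the variance-component ratio: the covariance between two
        # cluster-period means over their common variance
        vc = BlockExchangeableComponents(25, rho, pi, tau)
        num = vc.sigma2_c + vc.sigma2_eta * (1 - chi) / m
        den = vc.sigma2_c + vc.sigma2_cp + (vc.sigma2_eta + vc.sigma2_eps) / m
        assert compute_r(vc, m, chi) == pytest.approx(num / den, abs=1e-12)
        assert 0 <= compute_r(vc, m, chi) <= 1


class TestDesignEffect:
    def test_uncorrelated_parallel_design_is_neutral(self):
        Xc = np.array([[1], [0]])
        assert design_effect(Xc, 0.0) == pytest.approx(1.0)

    def test_invariant_under_cluster_replication(self):
        base = stepped_wedge(3).schematic
        expanded = expand_to_clusters(stepped_wedge(3, (4, 4, 4), 10))
        for r in (0.0, 0.5, 0.866):
            assert design_effect(base, r) == pytest.approx(
                design_effect(expanded, r), rel=1e-12)

    def test_continuity_in_r(self):
        Xc = expand_to_clusters(stepped_wedge(3, (4, 4, 4), 10))
        grid = np.linspace(0, 0.999, 400)
        vals = np.array([design_effect(Xc, r) for r in grid])
        assert np.abs(np.diff(vals)).max() < 0.05

    def test_all_treated_design_is_singular(self):
        with pytest.raises(SingularDesignError):
            design_effect(np.ones((4, 3), dtype=int), 0.2)


class TestIndividualN:
    def test_closed_form(self):
        q = PowerQuery(theta=2, alpha=0.05, target_power=0.893)
        z = stats.norm.ppf(0.975) + stats.norm.ppf(0.893)
        assert individually_randomized_n(q, 25) == pytest.approx(25 * z * z)

    def test_scales_with_variance_and_vanishes_for_huge_effects(self):
        q = PowerQuery(theta=2, alpha=0.05, target_power=0.8)
        assert individually_randomized_n(q, 50) == pytest.approx(
            2 * individually_randomized_n(q, 25))
        huge = PowerQuery(theta=1e6, alpha=0.05, target_power=0.8)
        assert individually_randomized_n(huge, 25) < 1e-9


class TestGlsVariance:
    def test_linear_in_covariance_scale(self, school_design, school_components):
        V = cov_matrix_block_exchangeable(
            school_components, ConstantChurn(0.3), 10, 4)
        assert gls_variance(school_design, 3.0 * V) == pytest.approx(
            3.0 * gls_variance(school_design, V))

    def test_information_additivity_over_clusters(self, school_components):
        V = cov_matrix_block_exchangeable(
            school_components, ConstantChurn(0.3), 10, 4)
        single = stepped_wedge(3, (2, 2, 2), 10)
        double = stepped_wedge(3, (4, 4, 4), 10)
        assert gls_variance(double, V) == pytest.approx(
            gls_variance(single, V) / 2)

    @pytest.mark.parametrize("rho, pi, tau, chi, m, S", GRID[::3])
    def test_against_brute_force_oracle(self, rho, pi, tau, chi, m, S):
        vc = BlockExchangeableComponents(25, rho, pi, tau)
        design = stepped_wedge(S, m=m)
        V = cov_matrix_block_exchangeable(vc, ConstantChurn(chi), m, S + 1)
        assert gls_variance(design, V) == pytest.approx(
            brute_force_gls_variance(design, V), abs=1e-10, rel=1e-10)

    def test_no_contrast_design_is_singular(self, school_components):
        V = cov_matrix_block_exchangeable(
            school_components, ConstantChurn(0.3), 10, 4)
        all_control = TrialDesign(np.zeros((3, 4), dtype=int), (1, 1, 1), 10)
        with pytest.raises(SingularDesignError):
            gls_variance(all_control, V)


class TestPathEquivalence:
    @pytest.mark.parametrize("rho, pi, tau, chi, m, S", GRID)
    def test_design_effect_equals_gls_power(self, rho, pi, tau, chi, m, S):
        vc = BlockExchangeableComponents(25, rho, pi, tau)
        design = stepped_wedge(S, (2,) * S, m)
        q = PowerQuery(theta=1.0, alpha=0.05)
        V = cov_matrix_block_exchangeable(vc, ConstantChurn(chi), m, S + 1)
        assert power_from_design_effect(design, vc, chi, q) == pytest.approx(
            gls_power(design, V, q), abs=1e-8)

    @pytest.mark.parametrize("rho, pi, m, S", list(itertools.product(
        [0.05, 0.33], [0.5, 0.9], [10], [3])))
    def test_power_nonincreasing_in_churn(self, rho, pi, m, S):
        vc = BlockExchangeableComponents(25, rho, pi, 0.7)
        design = stepped_wedge(S, (2,) * S, m)
        q = PowerQuery(theta=1.0, alpha=0.05)
        powers = [power_from_design_effect(design, vc, chi, q)
                  for chi in np.linspace(0, 1, 11)]
        assert all(a >= b - 1e-12 for a, b in zip(powers, powers[1:]))


class TestGlsPower:
    def test_null_effect_rejects_at_half_alpha(self, school_design,
                                               school_components):
        V = cov_matrix_block_exchangeable(
            school_components, ConstantChurn(0.0), 10, 4)
        assert gls_power(school_design, V,
                         PowerQuery(theta=0.0, alpha=0.05)) == pytest.approx(0.025)

    def test_vanishing_variance_gives_certain_rejection(self, school_design,
                                                        school_components):
        V = cov_matrix_block_exchangeable(
            school_components, ConstantChurn(0.0), 10, 4)
        assert gls_power(school_design, 1e-10 * V,
                         PowerQuery(theta=2.0)) == pytest.approx(1.0)


class TestClustersRequired:
    def test_school_example_needs_four_per_sequence(self, school_components):
        design = stepped_wedge(3, m=10)
        q = PowerQuery(theta=2.0, alpha=0.05, target_power=0.893)
        res = clusters_required(design, school_components, 0.0, q)
        assert res.clusters_per_sequence == 4
        assert res.power >= 0.893
        # one fewer cluster per sequence undershoots the target
        smaller = stepped_wedge(3, (3, 3, 3), 10)
        V = cov_matrix_block_exchangeable(
            school_components, ConstantChurn(0.0), 10, 4)
        assert gls_power(smaller, V, q) < 0.893

    def test_single_measurement_assumption_is_conservative(self,
                                                           school_components):
        design = stepped_wedge(3, m=10)
        q = PowerQuery(theta=2.0, alpha=0.05, target_power=0.893)
        open_res = clusters_required(design, school_components, 0.0, q)
        cross = clusters_required(design, school_components, 1.0, q)
        assert cross.clusters_longitudinal >= open_res.clusters_longitudinal

    def test_no_within_period_clustering(self):
        # rho = 0: K_L collapses to DE(r) * n_i / m
        vc = BlockExchangeableComponents(25, 0.0, 1.0, 0.5)
        design = stepped_wedge(3, m=10)
        q = PowerQuery(theta=2.0, alpha=0.05, target_power=0.8)
        res = clusters_required(design, vc, 0.3, q)
        assert res.clusters_longitudinal == pytest.approx(
            res.design_effect * res.n_individual / 10)
        assert res.clusters_parallel == pytest.approx(res.n_individual / 10)


class TestPowerCurve:
    def test_boundary_identities(self, school_design, school_components,
                                 school_query):
        core = power_curve(school_design, school_components, school_query,
                           family="core_group")
        rot = power_curve(school_design, school_components, school_query,
                          family="in_for_p")
        closed = gls_power(school_design, cov_matrix_block_exchangeable(
            school_components, ConstantChurn(0.0), 10, 4), school_query)
        cross = gls_power(school_design, cov_matrix_block_exchangeable(
            school_components, ConstantChurn(1.0), 10, 4), school_query)
        # proportion 1 = closed cohort; proportion 0 = one measurement each
        assert core.power.iloc[-1] == pytest.approx(closed)
        assert core.power.iloc[0] == pytest.approx(cross)
        # p = 1 coincides with core proportion 0
        assert rot.power.iloc[0] == pytest.approx(core.power.iloc[0])
        # rotation never reaches closed-cohort power when tau > 0
        assert rot.power.iloc[-1] < closed

    def test_monotone_in_scheme_parameter(self, school_design,
                                          school_components, school_query):
        core = power_curve(school_design, school_components, school_query,
                           family="core_group")
        rot = power_curve(school_design, school_components, school_query,
                          family="in_for_p")
        assert (np.diff(core.power) > 0).all()
        assert (np.diff(rot.power) > 0).all()

    def test_unknown_family_rejected(self, school_design, school_components,
                                     school_query):
        with pytest.raises(ValueError):
            power_curve(school_design, school_components, school_query,
                        family="nope")
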