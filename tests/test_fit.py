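"""Null-model optimization: profile fits, enumeration, nesting, recovery."""

import numpy as np
import pytest

from polyseg import fit as FT
from polyseg import freq as F
from polyseg import meiosis as M
from polyseg import simulate as S
from polyseg.likelihood import GenotypeCounts, make_loglik

from oracles import grid_best_loglik_pi


def _sim_counts(q, n, seed):
    return S.sample_genotypes(q, n, np.random.default_rng(seed))


class TestFitAuto:
    def test_pi_at_boundary_under_clean_null(self):
        spec = F.NullModelSpec(4, "auto", 2, 2)
        q = F.null_genotype_freq(spec, F.NullParams())
        data = _sim_counts(q, 50000, 3)
        fit = FT.fit_auto(data, spec)
        assert fit.params.pi < 5e-3
        assert fit.loglik >= make_loglik(data)(q) - 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_brent_matches_dense_grid(self, seed):
        spec = F.NullModelSpec(4, "auto", 1, 2)
        q_true = F.null_genotype_freq(spec, F.NullParams(pi=0.02))
        data = _sim_counts(q_true, 40, seed)
        fit = FT.fit_auto(data, spec)
        qc = F.null_genotype_freq(spec, F.NullParams())
        pi_grid, ll_grid = grid_best_loglik_pi(
            make_loglik(data), qc, spec.outlier_vector(), spec.pi_max, 201
        )
        assert fit.loglik >= ll_grid - 1e-6
        assert abs(fit.params.pi - pi_grid) < 1e-3

    def test_pi_max_zero_degenerate(self):
        spec = F.NullModelSpec(4, "auto", 2, 2, pi_max=0.0)
        data = _sim_counts(np.array([1, 8, 18, 8, 1]) / 36, 100, 0)
        fit = FT.fit_auto(data, spec)
        assert fit.params.pi == 0.0


class TestFitAllo:
    def test_recovers_point_mass_configuration(self):
        # duplex parent with configuration (1,0,1) only emits dosage-1 gametes
        spec = F.NullModelSpec(4, "allo", 2, 0)
        data = GenotypeCounts(np.array([0, 100, 0, 0, 0]))
        fit = FT.fit_allo(data, spec)
        assert fit.chosen_config[0] == M.PairingConfiguration(1, 0, 1)

    def test_single_configuration_reduces_to_auto_brent(self):
        # simplex x nulliplex: allo has exactly one configuration pair
        spec = F.NullModelSpec(6, "allo", 1, 0)
        data = GenotypeCounts(np.array([55, 43, 2, 0, 0, 0, 0]))
        fit = FT.fit_allo(data, spec)
        auto = FT.fit_auto(data, F.NullModelSpec(6, "auto", 1, 0))
        assert fit.loglik == pytest.approx(auto.loglik, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_joint_grid_search(self, seed):
        spec = F.NullModelSpec(4, "allo", 2, 2)
        rng = np.random.default_rng(seed)
        data = _sim_counts(rng.dirichlet(np.ones(5)), 60, seed + 100)
        fit = FT.fit_allo(data, spec)
        # oracle: exhaustive (configuration pair) x dense pi grid
        best = -np.inf
        ll_fn = make_loglik(data)
        configs = M.enumerate_configurations(4, 2)
        for i in range(2):
            for j in range(2):
                g1, g2 = np.zeros(2), np.zeros(2)
                g1[i], g2[j] = 1, 1
                qc = F.null_genotype_freq(spec, F.NullParams(gamma1=g1, gamma2=g2))
                _, ll = grid_best_loglik_pi(
                    ll_fn, qc, spec.outlier_vector(), spec.pi_max, 401
                )
                best = max(best, ll)
        assert fit.loglik >= best - 1e-6


class TestFitSegmental:
    @pytest.mark.parametrize("seed", range(5))
    def test_nesting_ladder(self, seed):
        rng = np.random.default_rng(seed)
        spec = F.NullModelSpec(6, "segmental", 2, 3)
        data = _sim_counts(rng.dirichlet(np.ones(7)), 80, seed)
        seg = FT.fit_segmental(data, spec)
        allo = FT.fit_allo(data, spec)
        auto = FT.fit_auto(data, spec)
        assert seg.loglik >= allo.loglik - 1e-6
        assert seg.loglik >= auto.loglik - 1e-6

    def test_parameter_recovery_duplex(self):
        spec = F.NullModelSpec(4, "segmental", 2, 2, allow_outliers=False)
        g = np.array([0.5, 0.5])
        q_true = F.null_genotype_freq(spec, F.NullParams(gamma1=g, gamma2=g))
        data = _sim_counts(q_true, 10000, 7)
        fit = FT.fit_segmental(data, spec)
        # gamma itself is weakly identified; q is the contract
        assert np.abs(fit.q0 - q_true).max() < 0.02

    @pytest.mark.parametrize("seed", range(20))
    def test_profile_smoke_vs_dense_grid(self, seed):
        """Attained loglik at least as good as a dense null-space grid (K=4)."""
        rng = np.random.default_rng(seed)
        spec = F.NullModelSpec(4, "segmental", 2, 2)
        data = _sim_counts(rng.dirichlet(np.ones(5)), 30, seed + 50)
        fit = FT.fit_segmental(data, spec)
        ll_fn = make_loglik(data)
        d = spec.outlier_vector()
        best = -np.inf
        grid = np.linspace(0, 1, 41)
        for t1 in grid:
            for t2 in grid:
                q = F.null_genotype_freq(
                    spec,
                    F.NullParams(
                        gamma1=np.array([t1, 1 - t1]), gamma2=np.array([t2, 1 - t2])
                    ),
                )
                for pi in np.linspace(0, spec.pi_max, 7):
                    ll = ll_fn((1 - pi) * q + pi * d)
                    best = max(best, ll)
        assert fit.loglik >= best - 1e-4

    def test_bounds_respected(self):
        spec = F.NullModelSpec(6, "segmental", 1, 4)
        data = GenotypeCounts(np.array([10, 30, 40, 15, 5, 0, 0]))
        fit = FT.fit_segmental(data, spec)
        assert 0 <= fit.params.pi <= spec.pi_max + 1e-12
        assert 0 <= fit.params.beta1 <= M.ces_beta_max(6) + 1e-12
        g = fit.params.gamma2
        assert np.all(g >= -1e-12) and abs(g.sum() - 1) < 1e-8


class TestFitAutoDR:
    def test_nests_auto(self):
        spec = F.NullModelSpec(6, "auto_dr", 2, 3)
        data = GenotypeCounts(np.array([5, 20, 30, 25, 15, 4, 1]))
        dr = FT.fit_auto_dr(data, spec)
        auto = FT.fit_auto(data, spec)
        assert dr.loglik >= auto.loglik - 1e-6

    def test_recovers_double_reduction_signal(self):
        # simplex x nulliplex cross: dosage-2 offspring only arise via DR
        K = 6
        alpha = M.ces_alpha_max(K)
        q_true = F.convolve_gametes(
            M.dr_gamete_freq(K, 1, alpha), M.dr_gamete_freq(K, 0, alpha)
        )
        data = _sim_counts(q_true, 5000, 11)
        spec = F.NullModelSpec(K, "auto_dr", 1, 0, allow_outliers=False)
        fit = FT.fit_auto_dr(data, spec)
        assert fit.params.alpha1[0] > 0.1
        assert np.abs(fit.q0 - q_true).max() < 0.02


class TestUnknownParents:
    def test_recovery_from_deep_data(self):
        K = 8
        spec = F.NullModelSpec(K, "segmental", None, None)
        sc_q = F.convolve_gametes(
            np.array([1, 0, 0, 0, 0.0]),
            M.segmental_gamete_freq(K, 6, np.array([0.5, 0.5])),
        )
        data = _sim_counts(sc_q, 300, 5)
        fit = FT.fit_unknown_parents(data, spec)
        assert fit.chosen_parents == (0, 6)

    def test_known_truth_wins_consistency(self):
        spec_known = F.NullModelSpec(4, "auto", 1, 1)
        q = F.null_genotype_freq(spec_known, F.NullParams())
        data = _sim_counts(q, 500, 9)
        known = FT.fit_auto(data, spec_known)
        unknown = FT.fit_unknown_parents(
            data, F.NullModelSpec(4, "auto", None, None)
        )
        assert unknown.loglik >= known.loglik - 1e-9
        assert unknown.chosen_parents == (1, 1)

    def test_single_individual_tie_break_documented(self):
        # one dosage-0 individual: many parent pairs tie; first in order wins
        data = GenotypeCounts(np.array([1, 0, 0, 0, 0]))
        fit = FT.fit_unknown_parents(data, F.NullModelSpec(4, "auto", None, None))
        assert fit.chosen_parents == (0, 0)

    def test_support_filter_excludes_impossible_parents(self):
        # without outliers, a nulliplex x nulliplex candidate cannot explain
        # dosage-2 offspring
        data = GenotypeCounts(np.array([50, 30, 20, 0, 0]))
        fit = FT.fit_unknown_parents(
            data, F.NullModelSpec(4, "segmental", None, None, allow_outliers=False)
        )
        l1, l2 = fit.chosen_parents
        assert (l1, l2) != (0, 0)
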