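"""Gamete-model combinatorics against enumeration oracles and hand values."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from polyseg import meiosis as M
from polyseg.meiosis import PairingConfiguration as PC

from conftest import assert_distribution
from oracles import (
    ces_alpha_enum,
    dr_gamete_freq_enum,
    gamete_freq_from_matchings,
    matching_config_weights,
)

ALL_KL = [(K, l) for K in M.VALID_PLOIDIES for l in range(K + 1)]


class TestConfigurations:
    @pytest.mark.parametrize(
        "K,l,expected", [(4, 2, 2), (8, 4, 3), (6, 0, 1), (4, 1, 1), (12, 6, 4)]
    )
    def test_counts(self, K, l, expected):
        assert M.n_configurations(K, l) == expected

    @pytest.mark.parametrize("K,l", ALL_KL)
    def test_count_matches_enumeration(self, K, l):
        configs = M.enumerate_configurations(K, l)
        assert len(configs) == M.n_configurations(K, l)
        # brute force: all integer triples
        brute = [
            (m0, m1, m2)
            for m0 in range(K // 2 + 1)
            for m1 in range(K // 2 + 1)
            for m2 in range(K // 2 + 1)
            if m0 + m1 + m2 == K // 2 and m1 + 2 * m2 == l
        ]
        assert sorted((c.m0, c.m1, c.m2) for c in configs) == sorted(brute)
        # fixed order: descending m1
        m1s = [c.m1 for c in configs]
        assert m1s == sorted(m1s, reverse=True)

    def test_enumeration_examples(self):
        assert M.enumerate_configurations(4, 2) == [PC(0, 2, 0), PC(1, 0, 1)]
        assert M.enumerate_configurations(4, 1) == [PC(1, 1, 0)]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            M.n_configurations(5, 2)
        with pytest.raises(ValueError):
            M.n_configurations(4, 5)
        with pytest.raises(ValueError):
            M.enumerate_configurations(4, -1)


class TestConfigGameteFreq:
    def test_worked_examples(self):
        np.testing.assert_allclose(
            M.config_gamete_freq(PC(0, 2, 0)), [0.25, 0.5, 0.25]
        )
        np.testing.assert_allclose(M.config_gamete_freq(PC(1, 0, 1)), [0, 1, 0])
        np.testing.assert_allclose(
            M.config_gamete_freq(PC(3, 0, 0)), [1, 0, 0, 0]
        )

    @pytest.mark.parametrize("K,l", ALL_KL)
    def test_valid_distribution_and_reversal_symmetry(self, K, l):
        for m in M.enumerate_configurations(K, l):
            p = M.config_gamete_freq(m)
            assert_distribution(p, K // 2 + 1)
            # allele relabeling: reversed configuration reverses the dosage axis
            np.testing.assert_allclose(
                M.config_gamete_freq(m.reversed()), p[::-1], atol=1e-15
            )


class TestSegmental:
    def test_autotetraploid_duplex_pattern(self):
        # the classic 1:4:1 duplex gamete ratio
        p = M.segmental_gamete_freq(4, 2, [2 / 3, 1 / 3])
        np.testing.assert_allclose(p, np.array([1, 4, 1]) / 6)

    @pytest.mark.parametrize("K,l", [(4, 2), (6, 3), (8, 4), (6, 2)])
    def test_one_hot_degeneracy(self, K, l):
        configs = M.enumerate_configurations(K, l)
        for i, m in enumerate(configs):
            gamma = np.zeros(len(configs))
            gamma[i] = 1.0
            np.testing.assert_allclose(
                M.segmental_gamete_freq(K, l, gamma), M.config_gamete_freq(m)
            )

    def test_uniform_mixture_is_average(self):
        configs = M.enumerate_configurations(6, 3)
        expected = np.mean([M.config_gamete_freq(m) for m in configs], axis=0)
        np.testing.assert_allclose(
            M.segmental_gamete_freq(6, 3, [0.5, 0.5]), expected
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            M.segmental_gamete_freq(4, 2, [1.0])


class TestAutoPairingWeights:
    def test_autotetraploid_duplex(self):
        w = M.auto_pairing_weights(4, 2)
        np.testing.assert_allclose(w, [2 / 3, 1 / 3])  # (0,2,0) first

    @pytest.mark.parametrize("K", [2, 4, 6, 8])
    def test_matches_matching_enumeration(self, K):
        for l in range(K + 1):
            oracle = matching_config_weights(K, l)
            configs = M.enumerate_configurations(K, l)
            w = M.auto_pairing_weights(K, l)
            assert set(oracle) == {(c.m0, c.m1, c.m2) for c in configs}
            for c, wi in zip(configs, w):
                assert abs(wi - float(oracle[(c.m0, c.m1, c.m2)])) < 1e-12

    def test_nulliplex(self):
        np.testing.assert_allclose(M.auto_pairing_weights(6, 0), [1.0])


class TestSimplexDoubleReduction:
    def test_no_double_reduction(self):
        p = M.simplex_dr_gamete_freq(6, 0.0)
        np.testing.assert_allclose(p, [0.5, 0.5, 0, 0])

    @pytest.mark.parametrize("K", [4, 6, 8, 10, 12])
    def test_structural_identities(self, K):
        beta = M.ces_beta_max(K) / 3
        p = M.simplex_dr_gamete_freq(K, beta)
        assert_distribution(p, K // 2 + 1)
        assert p[2] == pytest.approx(beta)
        assert p[0] - p[2] == pytest.approx(0.5)

    def test_beta_out_of_bounds(self):
        with pytest.raises(ValueError):
            M.simplex_dr_gamete_freq(4, 0.2)
        with pytest.raises(ValueError):
            M.simplex_dr_gamete_freq(4, -0.01)


class TestGenerativeDoubleReduction:
    def test_tetraploid_simplex_closed_form(self):
        a = 0.12
        np.testing.assert_allclose(
            M.dr_gamete_freq(4, 1, [a]), [0.5 + a / 4, 0.5 - a / 2, a / 4]
        )

    def test_saturated_parent(self):
        np.testing.assert_allclose(M.dr_gamete_freq(6, 6, [0.2]), [0, 0, 0, 1])

    @pytest.mark.parametrize("K", [4, 6, 8])
    def test_alpha_zero_is_hypergeometric(self, K):
        for l in range(K + 1):
            p = M.dr_gamete_freq(K, l, np.zeros(K // 4))
            expected = hypergeom.pmf(np.arange(K // 2 + 1), K, l, K // 2)
            np.testing.assert_allclose(p, expected, atol=1e-12)

    @pytest.mark.parametrize("K,l", [(4, 1), (4, 2), (6, 3), (8, 2)])
    def test_matches_enumeration(self, K, l):
        alpha = 0.6 * M.ces_alpha_max(K)
        oracle = dr_gamete_freq_enum(K, l, alpha)
        np.testing.assert_allclose(
            M.dr_gamete_freq(K, l, alpha), [float(f) for f in oracle], atol=1e-9
        )

    @pytest.mark.parametrize("K", [4, 6, 8, 10, 12])
    def test_simplex_equivalence(self, K, rng):
        """The generative model collapses to the two-parameter simplex law."""
        amax = M.ces_alpha_max(K)
        for _ in range(100):
            alpha = rng.uniform(0, amax)
            beta = float(np.arange(1, alpha.size + 1) @ alpha / K)
            dev = np.abs(
                M.dr_gamete_freq(K, 1, alpha) - M.simplex_dr_gamete_freq(K, beta)
            ).max()
            assert dev < 1e-12

    @pytest.mark.parametrize("K", [4, 6, 8])
    def test_polysomic_consistency(self, K):
        """alpha=0 equals the bivalent polysomic mixture for every dosage."""
        for l in range(K + 1):
            seg = M.segmental_gamete_freq(K, l, M.auto_pairing_weights(K, l))
            np.testing.assert_allclose(
                M.dr_gamete_freq(K, l, np.zeros(K // 4)), seg, atol=1e-12
            )

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            M.dr_gamete_freq(4, 1, [1.5])
        with pytest.raises(ValueError):
            M.dr_gamete_freq(8, 2, [0.1])  # wrong length


class TestCESBounds:
    @pytest.mark.parametrize("K", [4, 6, 8, 10, 12])
    def test_table_matches_ces_enumeration(self, K):
        oracle = [float(a) for a in ces_alpha_enum(K)]
        np.testing.assert_allclose(M.ces_alpha_max(K), oracle, atol=1e-9)

    def test_tetraploid_classical_value(self):
        # the textbook CES maximum for tetraploids
        assert M.ces_alpha_max(4)[0] == pytest.approx(1 / 6, abs=1e-15)

    @pytest.mark.parametrize("K", [4, 6, 8, 10, 12])
    def test_beta_consistency(self, K):
        amax = M.ces_alpha_max(K)
        expected = float(np.arange(1, amax.size + 1) @ amax / K)
        assert M.ces_beta_max(K) == pytest.approx(expected, abs=1e-15)


class TestPolysomicGametesVsMatchings:
    @pytest.mark.parametrize("K", [2, 4, 6, 8])
    def test_full_distribution(self, K):
        for l in range(K + 1):
            oracle = gamete_freq_from_matchings(K, l)
            p = M.segmental_gamete_freq(K, l, M.auto_pairing_weights(K, l))
            np.testing.assert_allclose(p, [float(f) for f in oracle], atol=1e-12)
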