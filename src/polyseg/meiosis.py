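"""Gamete-frequency models for even-ploidy bivalent and multivalent meiosis.

A ``K``-ploid parent with ``l`` copies of the counted allele transmits
gametes carrying ``0..K/2`` copies.  This module collects the gamete dosage
distributions that the segregation-distortion null models are built from:

* **Pairing configurations.**  Under strict bivalent formation the parent's
  ``K`` chromosome copies form ``K/2`` pairs.  A configuration
  ``m = (m0, m1, m2)`` records how many pairs carry 0, 1, or 2 copies of the
  allele; each configuration implies a binomial gamete distribution
  (:func:`config_gamete_freq`).  Disomic (allopolyploid) inheritance fixes a
  single configuration; polysomic (autopolyploid) inheritance mixes them with
  the random-matching weights of :func:`auto_pairing_weights`; arbitrary
  mixtures (:func:`segmental_gamete_freq`) model segmental allopolyploids
  with partial preferential pairing.

* **Double reduction at simplex loci.**  When multivalents form, both
  products of a single chromosome can enter one gamete.  For a simplex
  parent (``l = 1``) the gamete distribution depends on the double-reduction
  rates only through the scalar ``beta = (1/K) * sum_i i * alpha_i``
  (:func:`simplex_dr_gamete_freq`).

* **A generative multivalent model** (:func:`dr_gamete_freq`) with arbitrary
  double-reduction rates ``alpha``, used both as a simulation truth and as a
  fittable polysomic-with-double-reduction null.

* **CES bounds.**  Upper bounds on ``alpha`` (and hence ``beta``) under the
  complete-equational-segregation model of meiosis
  (:func:`ces_alpha_max`, :func:`ces_beta_max`).

All returned distributions are ``numpy`` vectors of length ``K/2 + 1`` that
are nonnegative and sum to one to within 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, factorial

import numpy as np

__all__ = [
    "VALID_PLOIDIES",
    "PairingConfiguration",
    "n_configurations",
    "enumerate_configurations",
    "config_gamete_freq",
    "auto_pairing_weights",
    "segmental_gamete_freq",
    "simplex_dr_gamete_freq",
    "dr_gamete_freq",
    "ces_alpha_max",
    "ces_beta_max",
    "n_dr_rates",
]

VALID_PLOIDIES = (2, 4, 6, 8, 10, 12)


def check_ploidy(ploidy: int) -> int:
    ploidy = int(ploidy)
    if ploidy not in VALID_PLOIDIES:
        raise ValueError(f"ploidy must be one of {VALID_PLOIDIES}, got {ploidy}")
    return ploidy


def check_dosage(ploidy: int, dosage: int) -> int:
    check_ploidy(ploidy)
    dosage = int(dosage)
    if not 0 <= dosage <= ploidy:
        raise ValueError(f"parent dosage must be in 0..{ploidy}, got {dosage}")
    return dosage


def n_dr_rates(ploidy: int) -> int:
    """Number of free double-reduction rates, ``floor(K/4)``."""
    check_ploidy(ploidy)
    return ploidy // 4


@dataclass(frozen=True, order=True)
class PairingConfiguration:
    """Bivalent pairing configuration ``m = (m0, m1, m2)``.

    ``mj`` is the number of chromosome pairs carrying ``j`` copies of the
    counted allele, so ``m0 + m1 + m2 = K/2`` and the parent dosage is
    ``m1 + 2*m2``.
    """

    m0: int
    m1: int
    m2: int

    def __post_init__(self) -> None:
        if min(self.m0, self.m1, self.m2) < 0:
            raise ValueError(f"pair counts must be nonnegative, got {self}")

    @property
    def ploidy(self) -> int:
        return 2 * (self.m0 + self.m1 + self.m2)

    @property
    def dosage(self) -> int:
        return self.m1 + 2 * self.m2

    def reversed(self) -> "PairingConfiguration":
        """Configuration after relabeling the two alleles (``l -> K - l``)."""
        return PairingConfiguration(self.m2, self.m1, self.m0)


def n_configurations(ploidy: int, dosage: int) -> int:
    """Number of pairing configurations ``b_{Kl}`` for a parent.

    ``b = K/2 - ceil(l/2) + 1`` when ``l >= K/2``, else ``floor(l/2) + 1``.
    """
    check_dosage(ploidy, dosage)
    if dosage >= ploidy // 2:
        return ploidy // 2 - (dosage + 1) // 2 + 1
    return dosage // 2 + 1


def enumerate_configurations(ploidy: int, dosage: int) -> list[PairingConfiguration]:
    """All pairing configurations for a parent, in descending ``m1`` order.

    The ordering (most mixed pairs first) is fixed and load-bearing: mixture
    weight vectors ``gamma`` are indexed by it.
    """
    check_dosage(ploidy, dosage)
    half = ploidy // 2
    out = []
    for m1 in range(min(dosage, ploidy - dosage), -1, -1):
        if (dosage - m1) % 2:
            continue
        m2 = (dosage - m1) // 2
        m0 = half - m1 - m2
        if m0 >= 0:
            out.append(PairingConfiguration(m0, m1, m2))
    assert len(out) == n_configurations(ploidy, dosage)
    return out


def config_gamete_freq(m: PairingConfiguration) -> np.ndarray:
    """Gamete dosage distribution implied by one pairing configuration.

    Each of the ``m1`` mixed pairs contributes one allele copy with
    probability 1/2; the ``m2`` double pairs always contribute one copy, so
    ``p_k = C(m1, k - m2) / 2^m1`` for ``m2 <= k <= m1 + m2``.
    """
    half = m.ploidy // 2
    p = np.zeros(half + 1)
    for k in range(m.m2, m.m1 + m.m2 + 1):
        p[k] = comb(m.m1, k - m.m2) / 2.0 ** m.m1
    return p


def _double_factorial(n: int) -> int:
    # (-1)!! == 1 by convention
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def auto_pairing_weights_exact(ploidy: int, dosage: int) -> list[Fraction]:
    """Rational configuration weights under uniformly random bivalent pairing.

    Counts perfect matchings of ``K`` labeled chromosomes (``l`` of them
    carrying the allele) that realize each configuration, out of the
    ``(K-1)!!`` total matchings.
    """
    check_dosage(ploidy, dosage)
    total = _double_factorial(ploidy - 1)
    weights = []
    for m in enumerate_configurations(ploidy, dosage):
        count = (
            comb(dosage, 2 * m.m2)
            * _double_factorial(2 * m.m2 - 1)
            * comb(ploidy - dosage, 2 * m.m0)
            * _double_factorial(2 * m.m0 - 1)
            * factorial(m.m1)
        )
        weights.append(Fraction(count, total))
    assert sum(weights) == 1
    return weights


def auto_pairing_weights(ploidy: int, dosage: int) -> np.ndarray:
    """Configuration weights giving polysomic (autopolyploid) inheritance."""
    return np.array([float(w) for w in auto_pairing_weights_exact(ploidy, dosage)])


def segmental_gamete_freq(ploidy: int, dosage: int, gamma) -> np.ndarray:
    """Gamete distribution under a mixture ``gamma`` over pairing configurations.

    A one-hot ``gamma`` reproduces disomic inheritance; the weights from
    :func:`auto_pairing_weights` reproduce polysomic inheritance; anything in
    between models partial preferential pairing.
    """
    configs = enumerate_configurations(ploidy, dosage)
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != (len(configs),):
        raise ValueError(
            f"gamma must have length {len(configs)} for ploidy {ploidy}, "
            f"dosage {dosage}; got shape {gamma.shape}"
        )
    if np.any(gamma < -1e-12) or abs(gamma.sum() - 1.0) > 1e-8:
        raise ValueError("gamma must be a probability vector")
    p = np.zeros(ploidy // 2 + 1)
    for w, m in zip(gamma, configs):
        if w > 0:
            p += w * config_gamete_freq(m)
    return p


# --- double reduction -------------------------------------------------------

# Maximum double-reduction rates alpha_i under complete equational
# segregation (CES).  Derived from the CES meiosis model: each chromosome's
# two chromatid segments sit on the dyads of its (reciprocal, complete)
# exchange partner pair; dyads assort uniformly at random at division I; each
# dyad then contributes one chromatid to the gamete.  The table is exact and
# is cross-checked against a brute-force enumeration of CES segregations in
# the test suite.
_CES_ALPHA_MAX: dict[int, tuple[Fraction, ...]] = {
    2: (),
    4: (Fraction(1, 6),),
    6: (Fraction(3, 10),),
    8: (Fraction(27, 70), Fraction(3, 140)),
    10: (Fraction(55, 126), Fraction(5, 84)),
    12: (Fraction(285, 616), Fraction(65, 616), Fraction(5, 1848)),
}


def ces_alpha_max(ploidy: int) -> np.ndarray:
    """CES upper bounds ``(alpha_1, ..., alpha_{floor(K/4)})``.

    ``alpha_i`` is the probability that a gamete carries ``i`` pairs of
    alleles identical by double reduction; CES (complete equational
    segregation) yields the meiotic maximum.
    """
    check_ploidy(ploidy)
    return np.array([float(a) for a in _CES_ALPHA_MAX[ploidy]])


def ces_beta_max(ploidy: int) -> float:
    """CES upper bound for the simplex-locus summary ``beta``."""
    check_ploidy(ploidy)
    alphas = _CES_ALPHA_MAX[ploidy]
    return float(sum((i + 1) * a for i, a in enumerate(alphas)) / ploidy)


def simplex_dr_gamete_freq(ploidy: int, beta: float) -> np.ndarray:
    """Simplex-parent gamete distribution under double reduction.

    ``p = (1/2 + beta, 1/2 - 2*beta, beta, 0, ..., 0)`` where
    ``beta = (1/K) * sum_i i * alpha_i`` summarizes the double-reduction
    rates.  ``beta = 0`` recovers the single simplex pairing configuration.
    """
    check_ploidy(ploidy)
    beta = float(beta)
    bmax = ces_beta_max(ploidy)
    if not -1e-12 <= beta <= bmax + 1e-12:
        raise ValueError(f"beta must be in [0, {bmax:.6g}] for ploidy {ploidy}, got {beta}")
    beta = min(max(beta, 0.0), bmax)
    half = ploidy // 2
    p = np.zeros(half + 1)
    p[0] = 0.5 + beta
    p[1] = 0.5 - 2.0 * beta
    if half >= 2:
        p[2] = beta
    return p


def dr_gamete_freq(ploidy: int, dosage: int, alpha) -> np.ndarray:
    """Gamete distribution under the multivalent double-reduction model.

    Generative model: with probability ``alpha_i`` the gamete carries ``i``
    doubled chromosomes (both copies identical by double reduction) and
    ``K/2 - 2i`` singletons, the underlying chromosomes being drawn without
    replacement from the parent's ``K`` (of which ``dosage`` carry the
    allele).  ``alpha = 0`` reduces to the polysomic bivalent model, i.e. a
    hypergeometric draw of ``K/2`` chromosomes from ``K``.

    Computed by exact summation over (doubled, singleton) carrier counts.
    """
    check_dosage(ploidy, dosage)
    imax = ploidy // 4
    alpha = np.asarray(alpha, dtype=float).reshape(-1)
    if alpha.size == 1 and imax > 1 and alpha[0] == 0.0:
        alpha = np.zeros(imax)  # scalar 0 shorthand for "no double reduction"
    if imax == 0:
        if alpha.size and np.any(alpha != 0.0):
            raise ValueError(f"double reduction is impossible at ploidy {ploidy}")
        alpha = np.zeros(0)
    elif alpha.size != imax:
        raise ValueError(
            f"alpha must have length {imax} for ploidy {ploidy}, got {alpha.size}"
        )
    if np.any(alpha < -1e-12) or alpha.sum() > 1 + 1e-12:
        raise ValueError("alpha entries must be nonnegative and sum to at most 1")
    K, l, half = ploidy, dosage, ploidy // 2
    weights = np.concatenate(([1.0 - alpha.sum()], alpha))
    p = np.zeros(half + 1)
    for i, w in enumerate(weights):
        if w <= 0:
            continue
        s = half - 2 * i  # number of singleton chromosomes
        for d in range(0, min(i, l) + 1):  # doubled carriers
            if i - d > K - l:
                continue
            pd = comb(l, d) * comb(K - l, i - d) / comb(K, i)
            for j in range(0, min(s, l - d) + 1):  # singleton carriers
                if s - j > (K - l) - (i - d):
                    continue
                pj = comb(l - d, j) * comb((K - l) - (i - d), s - j) / comb(K - i, s)
                p[2 * d + j] += w * pd * pj
    return p
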