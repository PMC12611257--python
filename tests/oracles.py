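"""Brute-force enumeration oracles, independent of the production code paths.

Everything here works in exact rational arithmetic and enumerates the
underlying sample spaces directly; the package's closed-form combinatorics
are tested against these.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def perfect_matchings(items):
    """Yield all perfect matchings of an even-length sequence as pair tuples."""
    items = list(items)
    if not items:
        yield ()
        return
    first, rest = items[0], items[1:]
    for i, other in enumerate(rest):
        remaining = rest[:i] + rest[i + 1 :]
        for sub in perfect_matchings(remaining):
            yield ((first, other),) + sub


def matching_config_weights(ploidy: int, dosage: int) -> dict[tuple, Fraction]:
    """Pairing-configuration probabilities under uniform random matching.

    Labels chromosomes 0..K-1 with the first ``dosage`` carrying the allele,
    enumerates all (K-1)!! perfect matchings, and classifies each by its
    (m0, m1, m2) pair-type counts.
    """
    carriers = set(range(dosage))
    counts: dict[tuple, int] = {}
    total = 0
    for matching in perfect_matchings(range(ploidy)):
        m = [0, 0, 0]
        for a, b in matching:
            m[(a in carriers) + (b in carriers)] += 1
        counts[tuple(m)] = counts.get(tuple(m), 0) + 1
        total += 1
    return {k: Fraction(v, total) for k, v in counts.items()}


def gamete_freq_from_matchings(ploidy: int, dosage: int) -> list[Fraction]:
    """Polysomic gamete distribution via matchings + per-pair coin flips."""
    weights = matching_config_weights(ploidy, dosage)
    half = ploidy // 2
    p = [Fraction(0)] * (half + 1)
    for (m0, m1, m2), w in weights.items():
        for k in range(m2, m1 + m2 + 1):
            p[k] += w * Fraction(comb(m1, k - m2), 2**m1)
    return p


def ces_alpha_enum(ploidy: int) -> list[Fraction]:
    """Double-reduction rates under complete equational segregation, enumerated.

    Model: chromosomes form reciprocal exchange pairs (the distribution is
    invariant to which pairing, so the canonical (0,1),(2,3),... is fixed);
    after exchange, dyad ``d`` carries its own first chromatid segment and
    the second segment of its partner.  Division I sends a uniformly random
    half of the dyads to each pole; division II takes one chromatid from
    each dyad, independently and uniformly.  ``alpha_i`` is the probability
    that the gamete holds exactly ``i`` sister-segment pairs.
    """
    K = ploidy
    half = K // 2
    partner = {}
    for a in range(0, K, 2):
        partner[a], partner[a + 1] = a + 1, a
    counts: dict[int, Fraction] = {}
    subsets = list(itertools.combinations(range(K), half))
    for pole in subsets:
        pole_set = set(pole)
        for picks in itertools.product((0, 1), repeat=half):
            # slot 0 of dyad d = segment (d, first); slot 1 = (partner[d], second)
            segs = set()
            for d, slot in zip(pole, picks):
                segs.add((d, 0) if slot == 0 else (partner[d], 1))
            ndr = sum(
                1 for c in range(K) if (c, 0) in segs and (c, 1) in segs
            )
            counts[ndr] = counts.get(ndr, Fraction(0)) + Fraction(
                1, len(subsets) * 2**half
            )
    imax = K // 4
    return [counts.get(i, Fraction(0)) for i in range(1, imax + 1)]


def dr_gamete_freq_enum(ploidy: int, dosage: int, alpha) -> list[Fraction]:
    """Multivalent double-reduction gamete distribution by direct enumeration.

    Enumerates every (doubled set, singleton set) draw of chromosomes.
    """
    K, half = ploidy, ploidy // 2
    alpha = [Fraction(a).limit_denominator(10**12) for a in np.atleast_1d(alpha)]
    weights = [1 - sum(alpha)] + alpha
    carriers = set(range(dosage))
    p = [Fraction(0)] * (half + 1)
    for i, w in enumerate(weights):
        if w == 0:
            continue
        s = half - 2 * i
        for doubled in itertools.combinations(range(K), i):
            rest = [c for c in range(K) if c not in doubled]
            for singles in itertools.combinations(rest, s):
                k = 2 * sum(1 for c in doubled if c in carriers) + sum(
                    1 for c in singles if c in carriers
                )
                p[k] += w * Fraction(1, comb(K, i) * comb(K - i, s))
    return p


def grid_best_loglik_pi(loglik_fn, q_conv, outlier_dist, pi_max, n_grid=201):
    """Dense-grid profile over the outlier proportion."""
    best = -np.inf
    best_pi = 0.0
    for pi in np.linspace(0.0, pi_max, n_grid):
        ll = loglik_fn((1 - pi) * q_conv + pi * outlier_dist)
        if ll > best:
            best, best_pi = ll, pi
    return best_pi, best
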