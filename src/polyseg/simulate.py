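"""Simulation engine: genotypes, sequencing reads, genotype likelihoods,
and the null / robustness / power experiment designs.

Offspring genotypes are multinomial draws from a genotype-frequency vector.
The sequencing model produces allele-specific read counts from a
beta-binomial: given genotype ``k`` at ploidy ``K``, the allele fraction is
``f = k/K``, distorted by a sequencing error rate ``e`` into
``xi = f(1-e) + (1-f)e`` (and optionally by allele bias ``h``), and the
counted-allele read total at fixed depth is beta-binomial with mean ``xi``
and overdispersion ``od``.  Genotype likelihoods are beta-binomial pmfs of
the observed count under each candidate genotype.  Infinite depth is the
known-genotype case.

The scenario grids reproduce the factorial designs of the null experiment
(7,920 scenarios) and the double-reduction robustness experiment (852
scenarios); power alternatives are drawn uniformly from the genotype
simplex ("easy") or from convolved uniform gamete simplices ("hard").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import betabinom, binom

from . import freq, meiosis
from .likelihood import GenotypeCounts, GenotypeLikelihoods

__all__ = [
    "SeqParams",
    "Scenario",
    "sample_genotypes",
    "sample_reads",
    "genotype_likelihoods_from_reads",
    "simulate_dataset",
    "null_scenario_grid",
    "robustness_scenario_grid",
    "power_alternative",
    "scenario_genotype_freq",
    "simulate_scenario",
]

DEFAULT_ERROR = 0.01
DEFAULT_OD = 0.01


@dataclass(frozen=True)
class SeqParams:
    """Sequencing model parameters.

    ``depth = math.inf`` means genotypes are observed without error.
    Defaults follow the simulation conditions used throughout: error rate
    0.01, overdispersion 0.01, no allele bias.
    """

    depth: float = 10
    error: float = DEFAULT_ERROR
    od: float = DEFAULT_OD
    bias: float = 1.0

    def __post_init__(self):
        if not (self.depth == math.inf or (float(self.depth).is_integer() and self.depth >= 0)):
            raise ValueError("depth must be a nonnegative integer or inf")
        if not 0.0 <= self.error < 0.5:
            raise ValueError("error must be in [0, 0.5)")
        if not 0.0 <= self.od < 1.0:
            raise ValueError("overdispersion must be in [0, 1)")
        if not self.bias > 0:
            raise ValueError("bias must be positive")

    @property
    def known_genotypes(self) -> bool:
        return self.depth == math.inf


def _allele_mean(k: int, ploidy: int, params: SeqParams) -> float:
    f = k / ploidy
    xi = f * (1.0 - params.error) + (1.0 - f) * params.error
    if params.bias != 1.0:
        xi = xi / (xi + (1.0 - xi) * params.bias)
    return xi


def sample_genotypes(q: np.ndarray, n: int, rng) -> GenotypeCounts:
    """Multinomial offspring genotype counts; reproducible under a seeded rng."""
    rng = np.random.default_rng(rng)
    q = np.asarray(q, dtype=float)
    return GenotypeCounts(rng.multinomial(n, q / q.sum()))


def sample_reads(k: int, ploidy: int, params: SeqParams, rng) -> tuple[int, int]:
    """Draw (counted-allele reads, other-allele reads) for one individual.

    Beta-binomial with mean ``xi_k``; ``od = 0`` degenerates to binomial.
    """
    rng = np.random.default_rng(rng)
    if params.known_genotypes:
        raise ValueError("cannot draw reads at infinite depth")
    depth = int(params.depth)
    xi = _allele_mean(k, ploidy, params)
    if depth == 0:
        return 0, 0
    if params.od == 0.0 or xi in (0.0, 1.0):
        a = int(rng.binomial(depth, xi))
    else:
        rho = params.od
        shape1 = xi * (1.0 - rho) / rho
        shape2 = (1.0 - xi) * (1.0 - rho) / rho
        a = int(rng.binomial(depth, rng.beta(shape1, shape2)))
    return a, depth - a


def genotype_likelihoods_from_reads(
    a_reads: int, depth: int, ploidy: int, params: SeqParams
) -> np.ndarray:
    """Log genotype-likelihood row for one individual's read counts.

    ``g_k`` is the beta-binomial (binomial when ``od = 0``) probability of
    the counted-allele read total under genotype ``k``.  Zero depth yields
    an uninformative flat row.
    """
    if depth == 0:
        return np.zeros(ploidy + 1)
    out = np.empty(ploidy + 1)
    for k in range(ploidy + 1):
        xi = _allele_mean(k, ploidy, params)
        if params.od == 0.0 or xi in (0.0, 1.0):
            out[k] = binom.logpmf(a_reads, depth, xi)
        else:
            rho = params.od
            out[k] = betabinom.logpmf(
                a_reads, depth, xi * (1 - rho) / rho, (1 - xi) * (1 - rho) / rho
            )
    return out


def _bb_logpmf_table(depth: int, ploidy: int, params: SeqParams) -> np.ndarray:
    """(depth+1) x (ploidy+1) table of log P(a reads | genotype k)."""
    a = np.arange(depth + 1)
    out = np.empty((depth + 1, ploidy + 1))
    for k in range(ploidy + 1):
        xi = _allele_mean(k, ploidy, params)
        if params.od == 0.0 or xi in (0.0, 1.0):
            out[:, k] = binom.logpmf(a, depth, xi)
        else:
            rho = params.od
            out[:, k] = betabinom.logpmf(
                a, depth, xi * (1 - rho) / rho, (1 - xi) * (1 - rho) / rho
            )
    return out


def simulate_dataset(q: np.ndarray, n: int, params: SeqParams, rng):
    """Simulate one locus: counts at infinite depth, else genotype likelihoods."""
    rng = np.random.default_rng(rng)
    counts = sample_genotypes(q, n, rng)
    if params.known_genotypes:
        return counts
    ploidy = counts.ploidy
    depth = int(params.depth)
    genotypes = np.repeat(np.arange(ploidy + 1), counts.x)
    xi = np.array([_allele_mean(k, ploidy, params) for k in range(ploidy + 1)])
    mean = xi[genotypes]
    if params.od == 0.0:
        a_reads = rng.binomial(depth, mean)
    else:
        rho = params.od
        p = mean.copy()
        inner = (mean > 0.0) & (mean < 1.0)  # xi in {0,1} stays degenerate
        if np.any(inner):
            m = mean[inner]
            p[inner] = rng.beta(m * (1 - rho) / rho, (1 - m) * (1 - rho) / rho)
        a_reads = rng.binomial(depth, p)
    table = _bb_logpmf_table(depth, ploidy, params)
    return GenotypeLikelihoods(table[a_reads])


# --- scenario grids ---------------------------------------------------------

ParentSetting = tuple  # ("fixed", None) | ("beta", b) | ("gamma", tuple) | ("alpha", tuple)


@dataclass(frozen=True)
class Scenario:
    """One simulation condition: a true genotype-frequency model plus n/depth."""

    ploidy: int
    l1: int
    l2: int
    n: int
    depth: float
    pi: float
    parent1: ParentSetting
    parent2: ParentSetting
    kind: str  # "null" | "robustness"


def _gamete_from_setting(ploidy: int, l: int, setting: ParentSetting) -> np.ndarray:
    tag, value = setting
    if tag == "fixed":
        p = np.zeros(ploidy // 2 + 1)
        p[l // 2] = 1.0
        return p
    if tag == "beta":
        p = meiosis.simplex_dr_gamete_freq(ploidy, value)
        return p[::-1].copy() if l == ploidy - 1 else p
    if tag == "gamma":
        return meiosis.segmental_gamete_freq(ploidy, l, np.asarray(value, dtype=float))
    if tag == "alpha":
        return meiosis.dr_gamete_freq(ploidy, l, np.asarray(value, dtype=float))
    raise ValueError(f"unknown parent setting {tag!r}")


def scenario_genotype_freq(sc: Scenario) -> np.ndarray:
    """The true offspring genotype frequencies of a scenario."""
    p1 = _gamete_from_setting(sc.ploidy, sc.l1, sc.parent1)
    p2 = _gamete_from_setting(sc.ploidy, sc.l2, sc.parent2)
    q = freq.convolve_gametes(p1, p2)
    if sc.pi > 0:
        q = (1 - sc.pi) * q + sc.pi / (sc.ploidy + 1)
    return q


def _null_parent_options(ploidy: int, l: int) -> list[ParentSetting]:
    if l in (0, ploidy):
        return [("fixed", None)]
    if l in (1, ploidy - 1):
        a = meiosis.ces_beta_max(ploidy)
        return [("beta", 0.0), ("beta", a / 2), ("beta", a)]
    b = meiosis.n_configurations(ploidy, l)
    if b == 2:
        return [("gamma", (1.0, 0.0)), ("gamma", (0.5, 0.5)), ("gamma", (0.0, 1.0))]
    if b == 3:  # octoploid tetraplex parent
        return [
            ("gamma", (1.0, 0.0, 0.0)),
            ("gamma", (0.0, 1.0, 0.0)),
            ("gamma", (0.0, 0.0, 1.0)),
            ("gamma", (0.5, 0.5, 0.0)),
            ("gamma", (0.5, 0.0, 0.5)),
            ("gamma", (0.0, 0.5, 0.5)),
            ("gamma", (1 / 3, 1 / 3, 1 / 3)),
        ]
    raise AssertionError(f"unexpected configuration count {b}")


def null_scenario_grid() -> list[Scenario]:
    """The full factorial null design: 7,920 scenarios.

    Ploidy in {4, 6, 8}; unordered parent dosage pairs; per-parent model
    options (3 beta levels at simplex dosages, 3 two-component mixtures, 7
    three-component mixtures at the octoploid tetraplex dosage); n in
    {20, 200}; depth in {10, inf}; outlier proportion in {0, 0.015, 0.03}.
    """
    out = []
    for K in (4, 6, 8):
        for l1 in range(K + 1):
            for l2 in range(l1, K + 1):
                for s1 in _null_parent_options(K, l1):
                    for s2 in _null_parent_options(K, l2):
                        for n in (20, 200):
                            for depth in (10, math.inf):
                                for pi in (0.0, 0.015, 0.03):
                                    out.append(
                                        Scenario(K, l1, l2, n, depth, pi, s1, s2, "null")
                                    )
    return out


def robustness_scenario_grid() -> list[Scenario]:
    """The double-reduction robustness design: 852 scenarios.

    Genotypes are generated from the polysomic multivalent model with
    double-reduction rates at 0, half, or all of the CES maximum; parent 1
    takes any dosage, parent 2 a non-extreme, non-simplex dosage; no
    outliers.
    """
    out = []
    for K in (4, 6, 8):
        amax = meiosis.ces_alpha_max(K)
        for level in (0.0, 0.5, 1.0):
            alpha = tuple(level * amax)
            for l1 in range(K + 1):
                for l2 in range(2, K - 1):
                    for n in (20, 200):
                        for depth in (10, math.inf):
                            s1 = ("fixed", None) if l1 in (0, K) else ("alpha", alpha)
                            s2 = ("alpha", alpha)
                            out.append(
                                Scenario(K, l1, l2, n, depth, 0.0, s1, s2, "robustness")
                            )
    return out


def power_alternative(ploidy: int, mode: str, rng) -> np.ndarray:
    """Draw a distorted genotype-frequency vector.

    ``easy``: uniform on the (K+1)-cell simplex.  ``hard``: two gamete
    vectors drawn uniformly on the (K/2+1)-cell simplex and convolved, so
    the alternative keeps the null's convolution structure and is harder to
    distinguish.
    """
    rng = np.random.default_rng(rng)
    meiosis.check_ploidy(ploidy)
    if mode == "easy":
        return rng.dirichlet(np.ones(ploidy + 1))
    if mode == "hard":
        p1 = rng.dirichlet(np.ones(ploidy // 2 + 1))
        p2 = rng.dirichlet(np.ones(ploidy // 2 + 1))
        return freq.convolve_gametes(p1, p2)
    raise ValueError(f"mode must be 'easy' or 'hard', got {mode!r}")


def simulate_scenario(sc: Scenario, rng, *, error: float = DEFAULT_ERROR,
                      od: float = DEFAULT_OD):
    """Simulate one replicate dataset for a scenario."""
    q = scenario_genotype_freq(sc)
    params = SeqParams(depth=sc.depth, error=error, od=od)
    return simulate_dataset(q, sc.n, params, rng)
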