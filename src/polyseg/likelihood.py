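"""Likelihoods for known and uncertain genotypes, and the alternative MLE.

Two data regimes are supported.  With *known genotypes* the dosage counts
``x = (x_0, ..., x_K)`` are multinomial given the genotype frequencies
``q``.  With *uncertain genotypes* each individual ``i`` carries a genotype
likelihood vector ``g_i``, where ``g_ik`` is the probability of the raw data
(e.g. sequencing reads) given genotype ``k``, and the marginal likelihood is

    f(G | q) = prod_i sum_k g_ik * q_k .

The unconstrained (alternative-hypothesis) MLE of ``q`` is ``x/n`` in the
known case and the fixed point of a standard mixture EM in the uncertain
case.  All arithmetic is carried out in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

ZERO_TOL = 1e-6
"""Estimated frequencies below this count as zero for support bookkeeping."""

__all__ = [
    "GenotypeCounts",
    "GenotypeLikelihoods",
    "AltFit",
    "loglik_known",
    "loglik_gl",
    "em_alt_mle",
    "make_loglik",
    "alt_fit_known",
    "fit_alternative",
    "data_loglik",
    "ZERO_TOL",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Known-genotype data: counts of offspring per dosage class 0..K."""

    x: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=np.int64)
        if x.ndim != 1 or np.any(x < 0):
            raise ValueError("counts must be a 1-D nonnegative integer vector")
        if x.sum() < 1:
            raise ValueError("need at least one individual")
        object.__setattr__(self, "x", x)

    @property
    def n(self) -> int:
        return int(self.x.sum())

    @property
    def ploidy(self) -> int:
        return self.x.size - 1


class GenotypeLikelihoods:
    """An ``n x (K+1)`` matrix of genotype likelihoods, stored as natural logs.

    Rows are individuals; entries are likelihoods of the raw data given each
    genotype and need not sum to one across genotypes.  Every row must have
    at least one finite entry — an all-impossible individual carries no
    information and must be filtered (or flattened) upstream.
    """

    def __init__(self, log_g: np.ndarray):
        log_g = np.asarray(log_g, dtype=float)
        if log_g.ndim != 2:
            raise ValueError("genotype likelihoods must form an n x (K+1) matrix")
        if np.any(np.isnan(log_g)) or np.any(log_g == np.inf):
            raise ValueError("genotype log-likelihoods must be finite or -inf")
        if np.any(np.all(np.isinf(log_g), axis=1)):
            raise ValueError(
                "row with no finite genotype likelihood; "
                "uninformative individuals must be pre-filtered"
            )
        self.log_g = log_g

    @classmethod
    def from_linear(cls, g: np.ndarray) -> "GenotypeLikelihoods":
        g = np.asarray(g, dtype=float)
        if np.any(g < 0):
            raise ValueError("likelihoods must be nonnegative")
        with np.errstate(divide="ignore"):
            return cls(np.log(g))

    @classmethod
    def one_hot(cls, genotypes, ploidy: int) -> "GenotypeLikelihoods":
        """Known genotypes represented as 0/1 likelihood rows."""
        genotypes = np.asarray(genotypes, dtype=np.int64)
        log_g = np.full((genotypes.size, ploidy + 1), -np.inf)
        log_g[np.arange(genotypes.size), genotypes] = 0.0
        return cls(log_g)

    @classmethod
    def from_counts(cls, counts: GenotypeCounts) -> "GenotypeLikelihoods":
        genotypes = np.repeat(np.arange(counts.ploidy + 1), counts.x)
        return cls.one_hot(genotypes, counts.ploidy)

    @property
    def n(self) -> int:
        return self.log_g.shape[0]

    @property
    def ploidy(self) -> int:
        return self.log_g.shape[1] - 1

    def normalized_linear(self) -> np.ndarray:
        """Rows rescaled to max 1 (a per-row constant; harmless in ratios)."""
        shift = self.log_g.max(axis=1, keepdims=True)
        return np.exp(self.log_g - shift)


@dataclass(frozen=True)
class AltFit:
    """Unconstrained MLE of the genotype frequencies."""

    q_hat: np.ndarray
    loglik: float
    support: np.ndarray  # boolean: q_hat >= ZERO_TOL
    n_iter: int = 0


def loglik_known(counts: GenotypeCounts, q: np.ndarray) -> float:
    """Multinomial log-likelihood of dosage counts.

    Includes the multinomial coefficient (a constant that cancels in
    likelihood ratios).  A class with ``q_k = 0`` but ``x_k > 0`` yields
    ``-inf`` rather than an exception.
    """
    q = np.asarray(q, dtype=float)
    x = counts.x
    if q.shape != x.shape:
        raise ValueError(f"count/frequency length mismatch: {x.shape} vs {q.shape}")
    if np.any((q <= 0) & (x > 0)):
        return -np.inf
    coeff = gammaln(counts.n + 1) - gammaln(x + 1).sum()
    active = x > 0
    return float(coeff + (x[active] * np.log(q[active])).sum())


def loglik_gl(gl: GenotypeLikelihoods, q: np.ndarray) -> float:
    """Genotype-likelihood log-likelihood ``sum_i log sum_k g_ik q_k``."""
    q = np.asarray(q, dtype=float)
    if q.shape != (gl.ploidy + 1,):
        raise ValueError(f"frequency vector must have length {gl.ploidy + 1}")
    with np.errstate(divide="ignore"):
        log_q = np.log(q)
    return float(logsumexp(gl.log_g + log_q[None, :], axis=1).sum())


def make_loglik(data):
    """Precompiled log-likelihood ``q -> float`` for repeated evaluation.

    Numerically identical to :func:`data_loglik` but hoists the
    data-dependent constants (multinomial coefficient, per-row scaling) out
    of the optimizer loop.
    """
    if isinstance(data, GenotypeCounts):
        x = data.x.astype(float)
        coeff = float(gammaln(data.n + 1) - gammaln(data.x + 1).sum())
        active = data.x > 0
        xa = x[active]

        def ll(q: np.ndarray) -> float:
            qa = q[active]
            if np.any(qa <= 0):
                return -np.inf
            return coeff + float(xa @ np.log(qa))

        return ll
    if isinstance(data, GenotypeLikelihoods):
        g = data.normalized_linear()
        const = float(data.log_g.max(axis=1).sum())

        def ll(q: np.ndarray) -> float:
            mix = g @ q
            if np.any(mix <= 0):
                return -np.inf
            return const + float(np.log(mix).sum())

        return ll
    raise TypeError(f"unsupported data type {type(data).__name__}")


def data_loglik(data, q: np.ndarray) -> float:
    """Dispatch on the data regime (counts vs genotype likelihoods)."""
    if isinstance(data, GenotypeCounts):
        return loglik_known(data, q)
    if isinstance(data, GenotypeLikelihoods):
        return loglik_gl(data, q)
    raise TypeError(f"unsupported data type {type(data).__name__}")


def alt_fit_known(counts: GenotypeCounts) -> AltFit:
    """Alternative MLE for known genotypes: ``q_hat = x / n`` exactly."""
    q = counts.x / counts.n
    return AltFit(q_hat=q, loglik=loglik_known(counts, q), support=q >= ZERO_TOL)


def em_alt_mle(
    gl: GenotypeLikelihoods,
    *,
    tol: float = 1e-8,
    max_iter: int = 1000,
    init: np.ndarray | None = None,
    debug: bool = False,
) -> AltFit:
    """Alternative MLE under genotype likelihoods, via mixture EM.

    E-step: responsibilities ``r_ik ∝ g_ik q_k``; M-step: ``q_k = mean_i
    r_ik``.  The log-likelihood is concave in ``q`` on the simplex for fixed
    ``G``, so the uniform initialization affects speed only.  Converged when
    the log-likelihood gain drops below ``tol``.
    """
    K1 = gl.ploidy + 1
    g = gl.normalized_linear()
    const = float(gl.log_g.max(axis=1).sum())  # row scaling, restored in loglik
    q = np.full(K1, 1.0 / K1) if init is None else np.asarray(init, dtype=float).copy()
    ll = const + float(np.log(g @ q).sum())
    it = 0
    for it in range(1, max_iter + 1):
        w = g * q[None, :]
        s = w.sum(axis=1)
        q = (w / s[:, None]).mean(axis=0)
        ll_new = const + float(np.log(g @ q).sum())
        if debug and ll_new < ll - 1e-9:
            raise AssertionError(f"EM log-likelihood decreased: {ll} -> {ll_new}")
        gain, ll = ll_new - ll, ll_new
        if gain < tol:
            break
    return AltFit(q_hat=q, loglik=ll, support=q >= ZERO_TOL, n_iter=it)


def fit_alternative(data) -> AltFit:
    """Unconstrained MLE for either data regime."""
    if isinstance(data, GenotypeCounts):
        return alt_fit_known(data)
    if isinstance(data, GenotypeLikelihoods):
        return em_alt_mle(data)
    raise TypeError(f"unsupported data type {type(data).__name__}")
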