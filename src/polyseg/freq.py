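"""Offspring genotype-frequency models for F1 crosses.

The null model for the offspring dosage distribution ``q = (q_0, ..., q_K)``
is a two-stage mixture:

1. each parent's gamete distribution (from :mod:`polyseg.meiosis`) is chosen
   by the null *family* — polysomic (``auto``), polysomic with double
   reduction (``auto_dr``), disomic (``allo``), or an arbitrary segmental
   mixture (``segmental``);
2. the parental gametes are convolved, and the result is mixed with an
   outlier distribution (uniform by default, or a point mass at dosage 0 in
   null-allele mode) with proportion ``pi``:

   ``q_k = (1 - pi) * (p1 * p2)_k + pi * outlier_k``.

Segregation distortion is any deviation of the offspring dosage frequencies
from every ``q`` attainable under the chosen family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import meiosis
from .meiosis import (
    auto_pairing_weights,
    ces_beta_max,
    check_dosage,
    check_ploidy,
    dr_gamete_freq,
    enumerate_configurations,
    n_configurations,
    segmental_gamete_freq,
    simplex_dr_gamete_freq,
)

__all__ = [
    "FAMILIES",
    "OutlierModel",
    "NullModelSpec",
    "NullParams",
    "convolve_gametes",
    "mix_outliers",
    "outlier_distribution",
    "parent_gamete_freq",
    "null_genotype_freq",
    "parent_free_info",
]

FAMILIES = ("auto", "auto_dr", "allo", "segmental")


def outlier_distribution(ploidy: int, kind="uniform") -> np.ndarray:
    """Outlier (invalid-genotype) dosage distribution.

    ``"uniform"`` spreads outliers over all ``K+1`` dosages; ``"zero"`` is a
    point mass at dosage 0, appropriate when outliers are suspected null
    alleles (individuals with no reads supporting the counted allele).
    A custom length-``K+1`` probability vector is also accepted.
    """
    check_ploidy(ploidy)
    if isinstance(kind, str):
        if kind == "uniform":
            return np.full(ploidy + 1, 1.0 / (ploidy + 1))
        if kind == "zero":
            d = np.zeros(ploidy + 1)
            d[0] = 1.0
            return d
        raise ValueError(f"unknown outlier distribution {kind!r}")
    d = np.asarray(kind, dtype=float)
    if d.shape != (ploidy + 1,) or np.any(d < 0) or abs(d.sum() - 1) > 1e-8:
        raise ValueError("custom outlier distribution must be a length-(K+1) probability vector")
    return d


@dataclass(frozen=True)
class OutlierModel:
    """Outlier mixture component: proportion ``pi`` bounded by ``pi_max``."""

    pi: float = 0.0
    pi_max: float = 0.03
    dist: object = "uniform"  # "uniform", "zero", or a length-(K+1) vector

    def __post_init__(self):
        if not 0.0 <= self.pi <= self.pi_max <= 1.0:
            raise ValueError(
                f"need 0 <= pi <= pi_max <= 1, got pi={self.pi}, pi_max={self.pi_max}"
            )


@dataclass(frozen=True)
class NullModelSpec:
    """Which null family to test against, and what is known about the cross.

    Parameters
    ----------
    ploidy
        Even ploidy ``K`` of both parents and the offspring.
    family
        ``"auto"`` (polysomic, bivalent), ``"auto_dr"`` (polysomic with free
        double-reduction rates), ``"allo"`` (disomic; best single pairing
        configuration), or ``"segmental"`` (free configuration mixtures; the
        general model).
    l1, l2
        Parental dosages; ``None`` marks a parent whose dosage must be
        estimated.
    allow_outliers, pi_max, outlier_dist
        Outlier mixture settings.  ``allow_outliers=False`` pins ``pi = 0``.
    """

    ploidy: int
    family: str = "segmental"
    l1: int | None = None
    l2: int | None = None
    allow_outliers: bool = True
    pi_max: float = 0.03
    outlier_dist: object = "uniform"

    def __post_init__(self):
        check_ploidy(self.ploidy)
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        for l in (self.l1, self.l2):
            if l is not None:
                check_dosage(self.ploidy, l)
        if not 0.0 <= self.pi_max <= 1.0:
            raise ValueError("pi_max must be in [0, 1]")

    @property
    def parents_known(self) -> bool:
        return self.l1 is not None and self.l2 is not None

    def with_parents(self, l1: int, l2: int) -> "NullModelSpec":
        return replace(self, l1=l1, l2=l2)

    def outlier_vector(self) -> np.ndarray:
        return outlier_distribution(self.ploidy, self.outlier_dist)


@dataclass(frozen=True)
class NullParams:
    """Free parameters of a null model (only those the family uses are set)."""

    gamma1: np.ndarray | None = None
    gamma2: np.ndarray | None = None
    beta1: float | None = None
    beta2: float | None = None
    alpha1: np.ndarray | None = None
    alpha2: np.ndarray | None = None
    pi: float = 0.0

    def parent(self, j: int) -> dict:
        if j == 1:
            return {"gamma": self.gamma1, "beta": self.beta1, "alpha": self.alpha1}
        return {"gamma": self.gamma2, "beta": self.beta2, "alpha": self.alpha2}


def convolve_gametes(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Offspring dosage distribution: discrete convolution of parental gametes."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape or p1.ndim != 1:
        raise ValueError(f"gamete vectors must share length K/2+1, got {p1.shape}, {p2.shape}")
    return np.convolve(p1, p2)


def mix_outliers(q: np.ndarray, outlier: OutlierModel) -> np.ndarray:
    """Mix genotype frequencies with the outlier distribution."""
    q = np.asarray(q, dtype=float)
    if outlier.pi == 0.0:
        return q
    d = outlier_distribution(q.size - 1, outlier.dist)
    return (1.0 - outlier.pi) * q + outlier.pi * d


def is_simplex_dosage(ploidy: int, dosage: int) -> bool:
    return dosage in (1, ploidy - 1)


def parent_free_info(spec: NullModelSpec, j: int) -> dict:
    """What is free for parent ``j`` under ``spec``.

    Returns a dict with ``kind`` in ``{"fixed", "beta", "gamma", "alpha"}``
    plus bound metadata.  ``fixed`` covers nulliplex/full-dosage parents and
    every parent under the ``auto``/``allo`` families (where nothing varies
    continuously).
    """
    K = spec.ploidy
    l = spec.l1 if j == 1 else spec.l2
    if l is None:
        raise ValueError("parent dosage unknown; resolve parents first")
    if l in (0, K):
        return {"kind": "fixed"}
    if spec.family == "auto_dr":
        if meiosis.n_dr_rates(K) == 0:
            return {"kind": "fixed"}
        return {"kind": "alpha", "upper": meiosis.ces_alpha_max(K)}
    if spec.family in ("auto", "allo"):
        return {"kind": "fixed"}
    # segmental
    if is_simplex_dosage(K, l):
        bmax = ces_beta_max(K)
        if bmax == 0.0:
            return {"kind": "fixed"}
        return {"kind": "beta", "upper": bmax}
    return {"kind": "gamma", "size": n_configurations(K, l)}


def parent_gamete_freq(
    ploidy: int,
    dosage: int,
    *,
    gamma=None,
    beta=None,
    alpha=None,
    family: str = "segmental",
) -> np.ndarray:
    """Gamete distribution for one parent given its per-family parameters.

    Exactly the parameters the family consults may be supplied; anything
    else raises, so a caller cannot silently pass an ignored parameter.
    """
    K, l = check_ploidy(ploidy), check_dosage(ploidy, dosage)
    half = K // 2
    supplied = {n for n, v in (("gamma", gamma), ("beta", beta), ("alpha", alpha)) if v is not None}

    def expect(allowed: set[str]):
        extra = supplied - allowed
        if extra:
            raise ValueError(
                f"parameters {sorted(extra)} are not free under family {family!r} "
                f"for ploidy {K}, dosage {l}"
            )

    if l in (0, K):
        expect(set())
        p = np.zeros(half + 1)
        p[l // 2] = 1.0
        return p
    if family == "auto":
        expect(set())
        return segmental_gamete_freq(K, l, auto_pairing_weights(K, l))
    if family == "auto_dr":
        expect({"alpha"})
        return dr_gamete_freq(K, l, 0.0 if alpha is None else alpha)
    if family == "allo":
        expect({"gamma"})
        if is_simplex_dosage(K, l):
            gamma = np.ones(1) if gamma is None else gamma
        if gamma is None:
            raise ValueError("allo family needs a one-hot gamma (chosen configuration)")
        gamma = np.asarray(gamma, dtype=float)
        if not np.all(np.isin(gamma, (0.0, 1.0))) or gamma.sum() != 1.0:
            raise ValueError("allo family requires a one-hot gamma")
        return segmental_gamete_freq(K, l, gamma)
    if family == "segmental":
        if is_simplex_dosage(K, l):
            expect({"beta"})
            p = simplex_dr_gamete_freq(K, 0.0 if beta is None else beta)
            return p[::-1].copy() if l == K - 1 else p
        expect({"gamma"})
        if gamma is None:
            raise ValueError(
                f"segmental family needs gamma for ploidy {K}, dosage {l}"
            )
        return segmental_gamete_freq(K, l, gamma)
    raise ValueError(f"unknown family {family!r}")


def null_genotype_freq(spec: NullModelSpec, params: NullParams) -> np.ndarray:
    """Offspring genotype frequencies under a null family at given parameters.

    Composes per-parent gamete distributions, the gamete convolution, and
    the outlier mixture.  Deterministic in ``params``.
    """
    if not spec.parents_known:
        raise ValueError("parent dosages must be known to evaluate the null model")
    if not spec.allow_outliers and params.pi != 0.0:
        raise ValueError("pi must be 0 when outliers are not allowed")
    gametes = []
    for j, l in ((1, spec.l1), (2, spec.l2)):
        kw = params.parent(j)
        gametes.append(parent_gamete_freq(spec.ploidy, l, family=spec.family, **kw))
    q = convolve_gametes(*gametes)
    out = OutlierModel(pi=params.pi, pi_max=max(spec.pi_max, params.pi), dist=spec.outlier_dist)
    return mix_outliers(q, out)
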