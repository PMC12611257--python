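"""The likelihood-ratio test with data-dependent degrees of freedom.

The statistic is twice the gap between the unconstrained and the null
maximized log-likelihoods, referred to a central chi-squared distribution.
The degrees of freedom are estimated from the data to cope with two
finite-sample pathologies of the null parameter space:

* **Boundary parameters.**  A null parameter sitting on a bound of its
  space (e.g. ``pi = 0``) contributes no local dimension, so only interior
  parameters are counted.
* **Weak identifiability.**  Distinct pairing-mixture parameters can map to
  nearly the same genotype frequencies.  The effective null dimension is
  taken as the numeric rank of the Jacobian of the parameter-to-frequency
  map at the MLE, counting singular values at least one-thousandth of the
  largest.

``df = max(1, df_alternative - df_null)`` where the alternative dimension
is the ploidy minus the dosages estimated empty under both hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .fit import NullFit, fit_null, free_blocks
from .freq import NullModelSpec, null_genotype_freq
from .likelihood import (
    AltFit,
    GenotypeCounts,
    GenotypeLikelihoods,
    ZERO_TOL,
    fit_alternative,
)

__all__ = [
    "TestResult",
    "lrt_stat",
    "df_alternative",
    "df_null",
    "bic_null",
    "outlier_posterior",
    "test_locus",
]

INTERIOR_TOL = 1e-6
"""A parameter closer than this to any bound counts as a boundary parameter."""

_JAC_STEP = 1e-6
_RANK_RTOL = 1e-3  # singular values >= sigma_max/1000 count toward the rank


def lrt_stat(null_fit: NullFit, alt_fit: AltFit) -> float:
    """Likelihood-ratio statistic, clamped at zero."""
    return max(0.0, 2.0 * (alt_fit.loglik - null_fit.loglik))


def df_alternative(alt_fit: AltFit, null_fit: NullFit, ploidy: int,
                   zero_tol: float = ZERO_TOL) -> int:
    """Alternative dimension: ploidy minus dosages empty under both fits."""
    both_zero = (np.asarray(alt_fit.q_hat) < zero_tol) & (null_fit.q0 < zero_tol)
    return int(ploidy - both_zero.sum())


def _interior_directions(null_fit: NullFit) -> list[dict]:
    """Perturbation directions for the interior free parameters.

    Box parameters perturb one coordinate; simplex-valued ``gamma`` blocks
    move along ``e_i - e_ref`` within the simplex, with one direction per
    positive entry beyond the first (the local dimension of the face the
    estimate sits on).
    """
    params = null_fit.params
    dirs: list[dict] = []
    for blk in free_blocks(null_fit.spec):
        if blk.kind == "simplex":
            gamma = np.asarray(getattr(params, blk.name), dtype=float)
            pos = np.flatnonzero(gamma > INTERIOR_TOL)
            if pos.size >= 2:
                ref = pos[-1]
                for i in pos[:-1]:
                    d = np.zeros(blk.size)
                    d[i], d[ref] = 1.0, -1.0
                    dirs.append({"block": blk.name, "dir": d})
        else:
            val = getattr(params, blk.name)
            val = np.atleast_1d(np.asarray(val, dtype=float))
            for i in range(blk.size):
                lo, hi = blk.lower[i], blk.upper[i]
                if val[i] > lo + INTERIOR_TOL and val[i] < hi - INTERIOR_TOL:
                    d = np.zeros(blk.size)
                    d[i] = 1.0
                    dirs.append({"block": blk.name, "dir": d})
    return dirs


def _perturbed_q(null_fit: NullFit, block: str, direction: np.ndarray,
                 step: float) -> np.ndarray:
    params = null_fit.params
    val = getattr(params, block)
    if block.startswith(("beta", "pi")):
        new = float(val) + step * float(direction[0])
    else:
        new = np.asarray(val, dtype=float) + step * direction
    from dataclasses import replace

    return null_genotype_freq(null_fit.spec, replace(params, **{block: new}))


def df_null(null_fit: NullFit) -> int:
    """Effective number of free null parameters.

    ``min`` of the interior-parameter count and the numeric rank of the
    central-difference Jacobian of the parameter-to-frequency map,
    restricted to interior directions.
    """
    dirs = _interior_directions(null_fit)
    if not dirs:
        return 0
    cols = []
    for d in dirs:
        qp = _perturbed_q(null_fit, d["block"], d["dir"], _JAC_STEP)
        qm = _perturbed_q(null_fit, d["block"], d["dir"], -_JAC_STEP)
        cols.append((qp - qm) / (2.0 * _JAC_STEP))
    J = np.column_stack(cols)
    sv = np.linalg.svd(J, compute_uv=False)
    if sv.size == 0 or sv[0] == 0.0:
        return 0
    rank = int(np.sum(sv >= sv[0] * _RANK_RTOL))
    return min(len(dirs), rank)


def bic_null(null_fit: NullFit, n: int) -> float:
    """BIC of the fitted null model; lower is better."""
    return -2.0 * null_fit.loglik + df_null(null_fit) * np.log(n)


def outlier_posterior(data, null_fit: NullFit) -> np.ndarray:
    """Per-individual posterior probability of being an outlier.

    With outlier proportion ``pi`` and outlier dosage distribution ``d``,
    the posterior is ``pi*f0 / (pi*f0 + (1-pi)*f1)`` where ``f1`` is the
    likelihood under the fitted non-outlier frequencies and ``f0`` under
    ``d``.  For counts data individuals are ordered by ascending dosage.
    """
    pi = null_fit.params.pi
    qc = null_fit.q_nonoutlier
    d = null_fit.spec.outlier_vector()
    if isinstance(data, GenotypeCounts):
        genotypes = np.repeat(np.arange(data.ploidy + 1), data.x)
        f1 = qc[genotypes]
        f0 = d[genotypes]
    elif isinstance(data, GenotypeLikelihoods):
        g = data.normalized_linear()
        f1 = g @ qc
        f0 = g @ d
    else:
        raise TypeError(f"unsupported data type {type(data).__name__}")
    num = pi * f0
    den = num + (1.0 - pi) * f1
    with np.errstate(invalid="ignore", divide="ignore"):
        post = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.clip(post, 0.0, 1.0)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one segregation-distortion test."""

    stat: float
    df: int
    p_value: float
    null_fit: NullFit
    alt_fit: AltFit
    bic: float
    df_alt: int
    df_null: int
    outlier_posteriors: np.ndarray | None = None


def test_locus(data, spec: NullModelSpec, **fit_opts) -> TestResult:
    """Run the segregation-distortion LRT for one locus.

    ``data`` is either :class:`~polyseg.likelihood.GenotypeCounts` (known
    genotypes) or :class:`~polyseg.likelihood.GenotypeLikelihoods`.
    """
    alt = fit_alternative(data)
    nf = fit_null(data, spec, **fit_opts)
    stat = lrt_stat(nf, alt)
    dfa = df_alternative(alt, nf, spec.ploidy)
    dfn = df_null(nf)
    df = max(1, dfa - dfn)
    p = float(chi2.sf(stat, df))
    n = data.n
    return TestResult(
        stat=stat,
        df=df,
        p_value=p,
        null_fit=nf,
        alt_fit=alt,
        bic=bic_null(nf, n),
        df_alt=dfa,
        df_null=dfn,
        outlier_posteriors=outlier_posterior(data, nf),
    )
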