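"""Maximum-likelihood fits of the null segregation models.

Each null family defines a constrained parameter space:

* ``auto`` — no continuous meiosis parameters; only the outlier proportion
  ``pi`` is free, profiled with Brent's method on ``[0, pi_max]``.
* ``allo`` — one latent pairing configuration per parent; every
  configuration pair is enumerated and ``pi`` profiled for each.
* ``segmental`` — configuration mixtures ``gamma`` on the simplex (and the
  double-reduction summary ``beta`` at simplex parents), optimized by a
  bounded quasi-Newton method on an unconstrained stick-breaking
  parameterization, initialized from a deterministic Sobol multistart.
* ``auto_dr`` — per-parent double-reduction rates ``alpha`` in the box
  ``[0, ces_alpha_max]``, fitted the same way.

Unknown parental dosages are handled by enumerating candidate dosage pairs,
fitting each, and keeping the best (ties broken by enumeration order).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit
from scipy.stats import qmc

from .freq import (
    NullModelSpec,
    NullParams,
    null_genotype_freq,
    parent_free_info,
)
from .likelihood import GenotypeCounts, data_loglik, make_loglik

__all__ = ["NullFit", "fit_auto", "fit_allo", "fit_segmental", "fit_auto_dr",
           "fit_null", "fit_unknown_parents", "free_blocks", "FreeBlock"]

_SOBOL_SEED = 20240917  # fixed: the global-init search is deterministic
_NESTING_TOL = 1e-9


@dataclass(frozen=True)
class FreeBlock:
    """One block of free parameters on its natural scale."""

    name: str  # "gamma1", "gamma2", "beta1", "beta2", "alpha1", "alpha2", "pi"
    kind: str  # "simplex" or "box"
    size: int  # natural length (b for a simplex block)
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    @property
    def free_dim(self) -> int:
        return self.size - 1 if self.kind == "simplex" else self.size


def free_blocks(spec: NullModelSpec) -> list[FreeBlock]:
    """Free-parameter layout for a fully specified null model."""
    if not spec.parents_known:
        raise ValueError("free_blocks needs known parent dosages")
    blocks: list[FreeBlock] = []
    for j in (1, 2):
        info = parent_free_info(spec, j)
        if info["kind"] == "gamma":
            blocks.append(FreeBlock(f"gamma{j}", "simplex", info["size"]))
        elif info["kind"] == "beta":
            blocks.append(
                FreeBlock(f"beta{j}", "box", 1, np.zeros(1), np.array([info["upper"]]))
            )
        elif info["kind"] == "alpha":
            up = np.asarray(info["upper"], dtype=float)
            blocks.append(FreeBlock(f"alpha{j}", "box", up.size, np.zeros(up.size), up))
    if spec.allow_outliers and spec.pi_max > 0:
        blocks.append(FreeBlock("pi", "box", 1, np.zeros(1), np.array([spec.pi_max])))
    return blocks


def _stick_break(u: np.ndarray, b: int) -> np.ndarray:
    """Map ``b-1`` unconstrained reals to a point of the ``b``-simplex.

    Centered so that ``u = 0`` yields the uniform vector.
    """
    gamma = np.empty(b)
    rem = 1.0
    for i in range(b - 1):
        frac = expit(u[i] - np.log(b - 1 - i))
        gamma[i] = rem * frac
        rem -= gamma[i]
    gamma[b - 1] = rem
    return gamma


def _unpack(u: np.ndarray, blocks: list[FreeBlock]) -> dict[str, np.ndarray | float]:
    out: dict[str, np.ndarray | float] = {}
    pos = 0
    for blk in blocks:
        seg = u[pos : pos + blk.free_dim]
        pos += blk.free_dim
        if blk.kind == "simplex":
            out[blk.name] = _stick_break(seg, blk.size)
        else:
            val = blk.lower + (blk.upper - blk.lower) * expit(seg)
            out[blk.name] = float(val[0]) if blk.name.startswith(("beta", "pi")) else val
    return out


def _params_from_values(values: dict) -> NullParams:
    kw = {}
    for name, val in values.items():
        kw[name] = val
    if "pi" in kw:
        kw["pi"] = float(kw["pi"])
    return NullParams(**kw)


def _make_fit(data, spec: NullModelSpec, params: NullParams, loglik=None,
              chosen_config=None, chosen_parents=None) -> "NullFit":
    q0 = null_genotype_freq(spec, params)
    q_non = null_genotype_freq(spec, replace(params, pi=0.0))
    if loglik is None:
        loglik = data_loglik(data, q0)
    return NullFit(
        spec=spec,
        params=params,
        loglik=float(loglik),
        q0=q0,
        q_nonoutlier=q_non,
        chosen_config=chosen_config,
        chosen_parents=chosen_parents,
    )


@dataclass(frozen=True)
class NullFit:
    """A fitted null model.

    ``q0`` includes the outlier component; ``q_nonoutlier`` is the pure
    meiosis convolution at the same parameters.  ``loglik`` is on the same
    scale as the alternative fit (multinomial coefficient included for
    counts data), so ``loglik <= alt.loglik`` up to optimizer tolerance.
    """

    spec: NullModelSpec
    params: NullParams
    loglik: float
    q0: np.ndarray
    q_nonoutlier: np.ndarray
    chosen_config: tuple | None = None
    chosen_parents: tuple | None = None


# --- pi profiling (Brent) ---------------------------------------------------

def _profile_pi(data, spec: NullModelSpec, q_conv: np.ndarray,
                ll_fn=None) -> tuple[float, float]:
    """Maximize over ``pi`` with the meiosis convolution held fixed."""
    ll_fn = make_loglik(data) if ll_fn is None else ll_fn
    if not spec.allow_outliers or spec.pi_max == 0.0:
        return 0.0, ll_fn(q_conv)
    d = spec.outlier_vector()

    def ll(pi: float) -> float:
        return ll_fn((1.0 - pi) * q_conv + pi * d)

    res = minimize_scalar(
        lambda p: -ll(p), bounds=(0.0, spec.pi_max), method="bounded",
        options={"xatol": 1e-10},
    )
    cand = [(float(res.x), ll(float(res.x))), (0.0, ll(0.0)), (spec.pi_max, ll(spec.pi_max))]
    # prefer an exact boundary when it is as good as the interior point
    best_ll = max(v for _, v in cand)
    for pi, v in cand[1:] + cand[:1]:
        if v >= best_ll - 1e-9:
            return pi, v
    raise AssertionError("unreachable")


def fit_auto(data, spec: NullModelSpec, **_opts) -> NullFit:
    """Polysomic (bivalent, no double reduction) null: profile ``pi`` only."""
    spec = replace(spec, family="auto")
    base = null_genotype_freq(spec, NullParams())
    pi, ll = _profile_pi(data, spec, base)
    return _make_fit(data, spec, NullParams(pi=pi), loglik=ll)


def fit_allo(data, spec: NullModelSpec, **_opts) -> NullFit:
    """Disomic null: enumerate configuration pairs, profile ``pi`` for each."""
    from .meiosis import enumerate_configurations

    spec = replace(spec, family="allo")
    K = spec.ploidy
    choices = []
    for l in (spec.l1, spec.l2):
        if l in (0, K):
            choices.append([None])
        else:
            choices.append(list(enumerate_configurations(K, l)))
    ll_fn = make_loglik(data)
    best = None
    for i1, c1 in enumerate(choices[0]):
        for i2, c2 in enumerate(choices[1]):
            g1 = _one_hot(len(choices[0]), i1) if c1 is not None else None
            g2 = _one_hot(len(choices[1]), i2) if c2 is not None else None
            params = NullParams(gamma1=g1, gamma2=g2)
            q_conv = null_genotype_freq(spec, params)
            pi, ll = _profile_pi(data, spec, q_conv, ll_fn)
            if best is None or ll > best[0] + _NESTING_TOL:
                best = (ll, replace(params, pi=pi), (c1, c2))
    ll, params, config = best
    return _make_fit(data, spec, params, loglik=ll, chosen_config=config)


def _one_hot(size: int, idx: int) -> np.ndarray:
    v = np.zeros(size)
    v[idx] = 1.0
    return v


# --- multistart quasi-Newton fits ------------------------------------------

def _make_q_builder(spec: NullModelSpec):
    """Precompiled ``values -> q`` map for the optimizer's inner loop.

    Every family's gamete distribution is affine in its free block (a
    configuration matrix for ``gamma``, an affine ray for ``beta``, a
    component matrix for ``alpha``), so the per-evaluation work reduces to
    small matrix products and one convolution.  Agrees with
    :func:`polyseg.freq.null_genotype_freq` by construction (checked in the
    tests).
    """
    from .meiosis import (
        config_gamete_freq,
        dr_gamete_freq,
        enumerate_configurations,
        n_dr_rates,
    )

    K = spec.ploidy
    half = K // 2
    d_out = spec.outlier_vector()
    parts = []
    for j, l in ((1, spec.l1), (2, spec.l2)):
        info = parent_free_info(spec, j)
        kind = info["kind"]
        if kind == "fixed":
            vec = parent_gamete_freq_fixed(spec, l)
            parts.append(("const", None, vec))
        elif kind == "gamma":
            cmat = np.array(
                [config_gamete_freq(m) for m in enumerate_configurations(K, l)]
            )
            parts.append(("gamma", f"gamma{j}", cmat))
        elif kind == "beta":
            base = np.zeros(half + 1)
            base[0] = base[1] = 0.5
            ray = np.zeros(half + 1)
            ray[0], ray[1], ray[2] = 1.0, -2.0, 1.0
            if l == K - 1:
                base, ray = base[::-1].copy(), ray[::-1].copy()
            parts.append(("beta", f"beta{j}", (base, ray)))
        else:  # alpha
            imax = n_dr_rates(K)
            W = np.empty((imax + 1, half + 1))
            for i in range(imax + 1):
                a = np.zeros(imax)
                if i > 0:
                    a[i - 1] = 1.0
                W[i] = dr_gamete_freq(K, l, a)
            parts.append(("alpha", f"alpha{j}", W))

    def build(values: dict) -> np.ndarray:
        gametes = []
        for kind, name, payload in parts:
            if kind == "const":
                gametes.append(payload)
            elif kind == "gamma":
                gametes.append(values[name] @ payload)
            elif kind == "beta":
                base, ray = payload
                gametes.append(base + values[name] * ray)
            else:
                a = values[name]
                w = np.concatenate(([1.0 - a.sum()], a))
                gametes.append(w @ payload)
        q = np.convolve(gametes[0], gametes[1])
        pi = values.get("pi", 0.0)
        if pi:
            q = (1.0 - pi) * q + pi * d_out
        return q

    return build


def parent_gamete_freq_fixed(spec: NullModelSpec, l: int) -> np.ndarray:
    from .freq import parent_gamete_freq

    return parent_gamete_freq(spec.ploidy, l, family=spec.family)


def _fit_blocks(data, spec: NullModelSpec, *, n_starts: int = 32,
                n_polish: int = 2) -> NullFit:
    blocks = free_blocks(spec)
    dim = sum(b.free_dim for b in blocks)
    if dim == 0:
        params = NullParams()
        return _make_fit(data, spec, params)
    ll_fn = make_loglik(data)
    q_build = _make_q_builder(spec)

    def negll(u: np.ndarray) -> float:
        q = q_build(_unpack(u, blocks))
        val = ll_fn(q)
        return -val if np.isfinite(val) else 1e30

    sob = qmc.Sobol(dim, scramble=True, seed=_SOBOL_SEED)
    starts = 8.0 * sob.random(max(n_starts, 32)) - 4.0
    starts = np.vstack([np.zeros(dim), starts])
    vals = np.array([negll(u) for u in starts])
    order = np.argsort(vals)

    best_u, best_val = starts[order[0]], vals[order[0]]
    bounds = [(-12.0, 12.0)] * dim
    for idx in order[:n_polish]:
        res = minimize(negll, starts[idx], method="L-BFGS-B", bounds=bounds)
        if res.fun < best_val:
            best_u, best_val = res.x, res.fun
    params = _params_from_values(_unpack(best_u, blocks))
    # recompute the loglik through the reference path for exact consistency
    return _make_fit(data, spec, params, loglik=None)


def _segmental_params_from(fit: NullFit, spec: NullModelSpec) -> NullParams:
    """Embed an auto/allo solution into the segmental parameter space."""
    from .meiosis import auto_pairing_weights

    K = spec.ploidy
    kw: dict = {"pi": fit.params.pi}
    for j, l in ((1, spec.l1), (2, spec.l2)):
        info = parent_free_info(spec, j)
        if info["kind"] == "gamma":
            if fit.spec.family == "auto":
                kw[f"gamma{j}"] = auto_pairing_weights(K, l)
            else:
                src = fit.params.gamma1 if j == 1 else fit.params.gamma2
                kw[f"gamma{j}"] = src
        elif info["kind"] == "beta":
            kw[f"beta{j}"] = 0.0
    return NullParams(**kw)


def fit_segmental(data, spec: NullModelSpec, *, n_starts: int = 32,
                  n_polish: int = 3) -> NullFit:
    """General (segmental) null fit.

    Multistart quasi-Newton on the stick-breaking parameterization, floored
    by the embedded disomic and polysomic profile fits (both are boundary
    points of the segmental space, so the segmental optimum can never fall
    below them).
    """
    spec = replace(spec, family="segmental")
    fit = _fit_blocks(data, spec, n_starts=n_starts, n_polish=n_polish)
    for sub in (fit_allo(data, spec), fit_auto(data, spec)):
        if sub.loglik > fit.loglik + _NESTING_TOL:
            params = _segmental_params_from(sub, spec)
            fit = _make_fit(data, spec, params, chosen_config=sub.chosen_config)
    return fit


def fit_auto_dr(data, spec: NullModelSpec, *, n_starts: int = 32,
                n_polish: int = 3) -> NullFit:
    """Polysomic-with-double-reduction null fit (alpha free, CES-bounded)."""
    spec = replace(spec, family="auto_dr")
    fit = _fit_blocks(data, spec, n_starts=n_starts, n_polish=n_polish)
    sub = fit_auto(data, spec)  # alpha = 0 boundary
    if sub.loglik > fit.loglik + _NESTING_TOL:
        from .meiosis import n_dr_rates

        m = n_dr_rates(spec.ploidy)
        kw = {"pi": sub.params.pi}
        for j, l in ((1, spec.l1), (2, spec.l2)):
            if 0 < l < spec.ploidy and m > 0:
                kw[f"alpha{j}"] = np.zeros(m)
        fit = _make_fit(data, spec, NullParams(**kw))
    return fit


_FITTERS = {
    "auto": fit_auto,
    "allo": fit_allo,
    "segmental": fit_segmental,
    "auto_dr": fit_auto_dr,
}


def _achievable_support(spec: NullModelSpec) -> list[np.ndarray]:
    """Boolean support masks attainable under ``spec`` (one per branch).

    For the allo family each configuration pair is a branch; the other
    families attain their union support at a single interior point.
    """
    from .meiosis import ces_alpha_max, ces_beta_max, n_configurations, n_dr_rates
    from .freq import is_simplex_dosage, outlier_distribution

    K = spec.ploidy
    extra = np.zeros(K + 1, dtype=bool)
    if spec.allow_outliers and spec.pi_max > 0:
        extra = outlier_distribution(K, spec.outlier_dist) > 0

    def interior_kw(j, l):
        if l in (0, K):
            return {}
        if spec.family == "auto_dr":
            m = n_dr_rates(K)
            return {f"alpha{j}": ces_alpha_max(K) / 2} if m else {}
        if spec.family == "segmental":
            if is_simplex_dosage(K, l):
                bmax = ces_beta_max(K)
                return {f"beta{j}": bmax / 2} if bmax > 0 else {}
            b = n_configurations(K, l)
            return {f"gamma{j}": np.full(b, 1.0 / b)}
        return {}

    if spec.family == "allo":
        from .meiosis import enumerate_configurations

        masks = []
        choices = []
        for l in (spec.l1, spec.l2):
            if l in (0, K):
                choices.append([None])
            else:
                choices.append(list(range(n_configurations(K, l))))
        for i1 in choices[0]:
            for i2 in choices[1]:
                kw = {}
                if i1 is not None:
                    kw["gamma1"] = _one_hot(len(choices[0]), i1)
                if i2 is not None:
                    kw["gamma2"] = _one_hot(len(choices[1]), i2)
                q = null_genotype_freq(spec, NullParams(**kw))
                masks.append((q > 1e-12) | extra)
        return masks
    kw = {}
    kw.update(interior_kw(1, spec.l1))
    kw.update(interior_kw(2, spec.l2))
    q = null_genotype_freq(spec, NullParams(**kw))
    return [(q > 1e-12) | extra]


def fit_unknown_parents(data, spec: NullModelSpec, **opts) -> NullFit:
    """Joint maximization over unknown parental dosages and null parameters.

    Candidate dosage pairs are enumerated (unordered when both parents are
    unknown, since the likelihood is swap-symmetric), restricted to those
    whose attainable support covers the observed genotypes when genotypes
    are known and outliers are disallowed.  The family fit runs for each
    candidate; the best log-likelihood wins, first-in-order on ties.
    """
    K = spec.ploidy
    if spec.l1 is None and spec.l2 is None:
        candidates = [(a, b) for a in range(K + 1) for b in range(a, K + 1)]
    elif spec.l1 is None:
        candidates = [(a, spec.l2) for a in range(K + 1)]
    elif spec.l2 is None:
        candidates = [(spec.l1, b) for b in range(K + 1)]
    else:
        raise ValueError("both parent dosages are known")

    observed = None
    if isinstance(data, GenotypeCounts):
        observed = data.x > 0

    best = None
    for l1, l2 in candidates:
        cand_spec = spec.with_parents(l1, l2)
        if observed is not None:
            if not any(
                np.all(mask[observed]) for mask in _achievable_support(cand_spec)
            ):
                continue
        fit = _FITTERS[spec.family](data, cand_spec, **opts)
        if best is None or fit.loglik > best.loglik + _NESTING_TOL:
            best = replace(fit, chosen_parents=(l1, l2))
    if best is None:
        raise ValueError(
            "no candidate parental dosages can explain the observed genotypes"
        )
    return best


def fit_null(data, spec: NullModelSpec, **opts) -> NullFit:
    """Fit the null model, dispatching on family and parent knowledge."""
    if not spec.parents_known:
        return fit_unknown_parents(data, spec, **opts)
    return _FITTERS[spec.family](data, spec, **opts)
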