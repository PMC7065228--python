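"""Deterministic quadrature kernels for one-factor Gaussian and Student-t orthants.

Every joint law in a many-to-one comparison design has product correlation
structure: the score statistics of the D treatment-versus-control comparisons
share the control arm, so ``corr(W_i, W_h) = a_i * a_h`` with loading
``a_i = sigma_0 * sqrt(Lambda_i)`` (``= sqrt(lambda_i / (1 + lambda_i))`` for a
common variance).  Conditioning on the shared factor renders the arms
independent, which reduces every orthant probability needed by the package --
Dunnett tail probabilities, group-sequential non-crossing probabilities over up
to three stages, and conditional error rates -- to low-dimensional smooth
integrals evaluated here with fixed Gauss-Hermite / Gauss-Legendre rules.
All routines are bit-for-bit reproducible (no Monte Carlo).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import ndtr, ndtri, roots_hermitenorm, roots_legendre
from scipy.stats import chi

__all__ = [
    "onefactor_lower",
    "onefactor_t_lower",
    "path_lower",
    "path_exit_probs",
]

_GH_NODES = 96  # factor integrals
_GL_NODES = 48  # truncated inner integrals / chi mixing


@lru_cache(maxsize=None)
def _gh(n: int):
    """Probabilists' Gauss-Hermite rule: integrates f(z) phi(z) dz exactly for
    polynomials up to degree 2n-1."""
    x, w = roots_hermitenorm(n)
    return x, w / np.sqrt(2.0 * np.pi)


@lru_cache(maxsize=None)
def _gl_raw(n: int):
    return roots_legendre(n)


@lru_cache(maxsize=None)
def _gl01(n: int):
    """Gauss-Legendre rule mapped to (0, 1)."""
    x, w = roots_legendre(n)
    return (x + 1.0) / 2.0, w / 2.0


def _phi(x):
    return np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)


def onefactor_lower(upper, loadings, mean=0.0, sd=1.0, n_gh: int = _GH_NODES):
    """P(Z_i <= upper_i for all i) for a one-factor Gaussian vector.

    Z_i = mean_i + sd_i * (a_i * F + sqrt(1 - a_i^2) * eps_i) with F, eps_i
    iid standard normal.  ``upper`` may carry leading batch dimensions; the
    last axis indexes the k components.
    """
    upper = np.asarray(upper, dtype=float)
    a = np.broadcast_to(np.asarray(loadings, dtype=float), upper.shape[-1:])
    if np.any((a < 0.0) | (a >= 1.0)):
        raise ValueError("factor loadings must lie in [0, 1)")
    s = np.sqrt(1.0 - a * a)
    u = (upper - mean) / sd
    z, w = _gh(n_gh)
    # shape (..., n_gh, k)
    t = (u[..., None, :] - a * z[:, None]) / s
    vals = np.prod(ndtr(t), axis=-1)
    out = vals @ w
    return np.clip(out, 0.0, 1.0)


def onefactor_t_lower(upper, loadings, df, n_gh: int = _GH_NODES,
                      n_s: int = 64):
    """P(T_i <= upper_i for all i) for a central one-factor multivariate t.

    T_i = Z_i / (S / sqrt(df)) with Z one-factor standard Gaussian and
    S ~ chi(df) independent.  Infinite ``df`` falls back to the Gaussian case.
    """
    if not np.isfinite(df):
        return onefactor_lower(upper, loadings, n_gh=n_gh)
    if df < 1:
        raise ValueError("df must be >= 1")
    upper = np.asarray(upper, dtype=float)
    q, w = _gl01(n_s)
    # exact probability transform of the scale mixture variable
    s = chi.ppf(q, df) / np.sqrt(df)
    scaled = upper[..., None, :] * s[:, None]
    vals = onefactor_lower(scaled, loadings, n_gh=n_gh)
    return np.clip(vals @ w, 0.0, 1.0)


def bvn_lower(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Vectorized port of Genz's angular-integral formula (accurate to ~1e-14
    for |rho| <= 0.925); beyond that a dense truncated conditioning
    quadrature is used as fallback.  h, k, rho broadcast elementwise.
    """
    h, k, rho = np.broadcast_arrays(*map(np.asarray, (h, k, rho)))
    h = h.astype(float); k = k.astype(float); rho = rho.astype(float)
    out = np.empty(h.shape, dtype=float)
    main = np.abs(rho) <= 0.925
    if np.any(main):
        hh, kk, r = h[main], k[main], rho[main]
        x, w = _gl_raw(24)
        asr = np.arcsin(r)
        sn = np.sin(asr[..., None] * (x + 1.0) / 2.0)
        with np.errstate(invalid="ignore", over="ignore"):
            hk = (hh * kk)[..., None]
            hs = ((hh * hh + kk * kk) / 2.0)[..., None]
            f = np.exp((sn * hk - hs) / (1.0 - sn * sn))
            val = (f @ w) * asr / (4.0 * np.pi) + ndtr(hh) * ndtr(kk)
        out[main] = val
    rest = ~main
    if np.any(rest):
        hh, kk, r = h[rest], k[rest], rho[rest]
        # conditioning integral over the first coordinate, probability substitution
        q, w = _gl01(400)
        p1 = ndtr(hh)
        z = ndtri(np.clip(q * np.maximum(p1[..., None], 1e-300),
                          1e-300, 1.0 - 1e-16))
        t = ndtr((kk[..., None] - r[..., None] * z)
                 / np.sqrt(1.0 - r[..., None] ** 2))
        out[rest] = p1 * (t @ w)
    # handle infinities explicitly (arcsin form already fine, but be safe)
    out = np.where(np.isneginf(h) | np.isneginf(k), 0.0, out)
    out = np.where(np.isposinf(h), ndtr(k), out)
    out = np.where(np.isposinf(k), np.where(np.isposinf(h), 1.0, ndtr(h)), out)
    return np.clip(out, 0.0, 1.0)


def _trunc_nodes(alpha, q):
    """Nodes of the probability substitution e = ndtri(q * Phi(alpha)) for the
    integral of phi(e) over (-inf, alpha).  Returns (Phi(alpha), e-nodes)."""
    p = ndtr(alpha)
    arg = np.clip(q * np.maximum(p, 1e-300), 1e-300, 1.0 - 1e-16)
    return p, ndtri(arg)


def path_lower(upper, inc_sd, loadings, inc_mean=None,
               n_gh: int = None, n_gl: int = None):
    """Non-crossing probability of a multiarm score path over J <= 3 stages.

    P(W_{ij} <= upper[j, i] for all stages j and arms i) where
    W_{ij} = sum_{l <= j} V_i(l) and the stage-l increment vector V(l) is
    one-factor Gaussian: V_i(l) = inc_mean[l, i] + inc_sd[l, i] *
    (a_i * F_l + sqrt(1 - a_i^2) * eps_{il}), independent across stages.

    Parameters
    ----------
    upper : (J, k) cumulative upper bounds (np.inf allowed).
    inc_sd : (J, k) increment standard deviations, all > 0.
    loadings : (k,) factor loadings a_i.
    inc_mean : (J, k) increment means, default 0.
    """
    upper = np.atleast_2d(np.asarray(upper, dtype=float))
    inc_sd = np.broadcast_to(np.asarray(inc_sd, dtype=float), upper.shape)
    J, k = upper.shape
    a = np.broadcast_to(np.asarray(loadings, dtype=float), (k,))
    if inc_mean is None:
        c = upper.copy()
    else:
        inc_mean = np.broadcast_to(np.asarray(inc_mean, dtype=float), upper.shape)
        c = upper - np.cumsum(inc_mean, axis=0)
    if np.any(inc_sd <= 0):
        raise ValueError("increment standard deviations must be positive")
    if J == 1:
        return float(onefactor_lower(c[0], a, sd=inc_sd[0]))
    if k == 1:
        # a single arm's path law does not depend on the factor split;
        # dropping the factor removes the outer integrals entirely
        a = np.zeros(1)
        n_gh, n_gl = 1, (n_gl or 64)
    s = np.sqrt(1.0 - a * a)
    g = inc_sd * s          # (J, k) idiosyncratic increment sd
    h = inc_sd * a          # (J, k) factor increment loading
    if J == 2:
        return _path_lower_2(c, g, h, n_gh or 48, n_gl or 48)
    if J == 3:
        return _path_lower_3(c, g, h, n_gh or 32, n_gl or 24)
    raise NotImplementedError("path probabilities implemented for J <= 3 stages")


def _path_lower_2(c, g, h, n_gh, n_gl):
    z, wz = _gh(n_gh)
    k = c.shape[1]
    # accumulate product over arms of A_i(z1, z2); the per-arm probability is
    # an exact bivariate normal rectangle in (e1, g1*e1 + g2*e2)
    prod = np.ones((n_gh, n_gh))
    for i in range(k):
        d1 = c[0, i] - h[0, i] * z            # (n1,)
        d2 = (c[1, i] - h[0, i] * z[:, None]
              - h[1, i] * z[None, :])          # (n1, n2)
        s2 = np.hypot(g[0, i], g[1, i])
        rho = g[0, i] / s2
        prod *= bvn_lower(d1[:, None] / g[0, i], d2 / s2, rho)
    return float(np.clip(wz @ prod @ wz, 0.0, 1.0))


def _path_lower_3(c, g, h, n_gh, n_gl):
    z, wz = _gh(n_gh)
    q1, wq1 = _gl01(n_gl)
    k = c.shape[1]
    total = 0.0
    for i1, z1 in enumerate(z):
        prod = np.ones((n_gh, n_gh))  # over (z2, z3)
        for i in range(k):
            alpha = (c[0, i] - h[0, i] * z1) / g[0, i]  # scalar
            p1, e1 = _trunc_nodes(alpha, q1)            # scalar, (m1,)
            d2 = c[1, i] - h[0, i] * z1 - h[1, i] * z    # (n2,)
            d3 = (c[2, i] - h[0, i] * z1 - h[1, i] * z[:, None]
                  - h[2, i] * z[None, :])                # (n2, n3)
            # given e1, the remaining event is a bivariate rectangle in
            # (e2, g2*e2 + g3*e3)
            beta = (d2[:, None] - g[0, i] * e1[None, :]) / g[1, i]  # (n2, m1)
            s3 = np.hypot(g[1, i], g[2, i])
            gamma = (d3[:, :, None] - g[0, i] * e1[None, None, :]) / s3  # (n2, n3, m1)
            inner = bvn_lower(beta[:, None, :], gamma, g[1, i] / s3)  # (n2, n3, m1)
            prod *= p1 * (inner @ wq1)
        total += wz[i1] * (wz @ prod @ wz)
    return float(np.clip(total, 0.0, 1.0))


def path_exit_probs(upper, inc_sd, loadings, inc_mean=None):
    """P(first boundary crossing happens at stage j), j = 1..J.

    Crossing at stage j means max_i W_{ij} >= upper[j, i-bound] with no
    crossing at any earlier stage.  The probabilities plus the never-crossing
    probability sum to one.
    """
    upper = np.atleast_2d(np.asarray(upper, dtype=float))
    J = upper.shape[0]
    lowers = [1.0]
    for j in range(1, J + 1):
        sub = None if inc_mean is None else inc_mean[:j]
        lowers.append(path_lower(upper[:j], inc_sd[:j], loadings, sub))
    return np.array([lowers[j - 1] - lowers[j] for j in range(1, J + 1)])
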