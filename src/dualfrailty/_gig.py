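"""Exact generalised-inverse-Gaussian sampling and the fast Gibbs sweep.

The GIG density kernel is ``z^{lam-1} exp{-(psi z + chi/z)/2}``.  On the log
scale ``t = log z`` the standardised density ``exp(lam t - omega cosh t)``
(with ``omega = sqrt(chi psi)``) is log-concave, so a single exact rejection
scheme covers the whole parameter range: a flat hat around the mode between
the two points where the log density has dropped by one, and tangent
exponential tails beyond them.  Expected trials are bounded by a small
constant uniformly in (lam, omega).

All kernels consume pre-generated uniforms from a caller-supplied buffer so
randomness stays in one numpy Generator stream; a kernel that runs out of
buffer returns a resume point and the caller refills.  This keeps draws
bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["sample_gig", "gig_log_kernel"]

_EXHAUSTED = -1


@njit(cache=True)
def _h(lam, omega, t):
    return lam * t - omega * math.cosh(t)


@njit(cache=True)
def _gig_std(lam, omega, u, iu):
    """One draw from density prop. to exp(lam*t - omega*cosh t), x = e^t.

    Requires lam >= 0, omega > 0.  Returns (x, next_index) or (nan, -1) when
    the uniform buffer is exhausted.
    """
    m = math.asinh(lam / omega)
    hm = _h(lam, omega, m)
    target = hm - 1.0

    # right crossing of h = hm - 1
    step = 1.0
    while _h(lam, omega, m + step) > target:
        step *= 2.0
    lo, hi = m, m + step
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        if _h(lam, omega, mid) > target:
            lo = mid
        else:
            hi = mid
    tr = 0.5 * (lo + hi)

    # left crossing
    step = 1.0
    while _h(lam, omega, m - step) > target:
        step *= 2.0
    lo, hi = m - step, m
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        if _h(lam, omega, mid) > target:
            hi = mid
        else:
            lo = mid
    tl = 0.5 * (lo + hi)

    sl = lam - omega * math.sinh(tl)        # h'(tl) > 0
    sr = omega * math.sinh(tr) - lam        # -h'(tr) > 0
    ac = tr - tl
    ar = math.exp(-1.0) / sr
    al = math.exp(-1.0) / sl
    atot = ac + ar + al

    while True:
        if iu + 3 > u.size:
            return np.nan, _EXHAUSTED
        u1 = u[iu] * atot
        u2 = u[iu + 1]
        u3 = u[iu + 2]
        iu += 3
        if u2 <= 0.0 or u3 <= 0.0:
            continue
        if u1 < ac:
            t = tl + u2 * ac
            loghat = 0.0
        elif u1 < ac + ar:
            t = tr - math.log(u2) / sr
            loghat = -1.0 - sr * (t - tr)
        else:
            t = tl + math.log(u2) / sl
            loghat = -1.0 + sl * (t - tl)
        if math.log(u3) <= _h(lam, omega, t) - hm - loghat:
            return math.exp(t), iu


@njit(cache=True)
def _gamma_std(shape, u, iu):
    """Marsaglia-Tsang gamma(shape, 1) draw from the uniform buffer."""
    boost = 1.0
    if shape < 1.0:
        if iu + 1 > u.size:
            return np.nan, _EXHAUSTED
        ub = u[iu]
        iu += 1
        if ub <= 0.0:
            ub = 1e-300
        boost = ub ** (1.0 / shape)
        shape += 1.0
    d = shape - 1.0 / 3.0
    c = 1.0 / math.sqrt(9.0 * d)
    while True:
        if iu + 3 > u.size:
            return np.nan, _EXHAUSTED
        u1 = u[iu]
        u2 = u[iu + 1]
        u3 = u[iu + 2]
        iu += 3
        if u1 <= 0.0 or u3 <= 0.0:
            continue
        x = math.sqrt(-2.0 * math.log(u1)) * math.cos(2.0 * math.pi * u2)
        v = 1.0 + c * x
        if v <= 0.0:
            continue
        v = v * v * v
        if u3 < 1.0 - 0.0331 * x * x * x * x:
            return boost * d * v, iu
        if math.log(u3) < 0.5 * x * x + d * (1.0 - v + math.log(v)):
            return boost * d * v, iu


@njit(cache=True)
def _gig_draw(lam, chi, psi, u, iu):
    """GIG(lam, chi, psi) draw; chi = 0 degenerates to gamma(lam, rate psi/2)."""
    if chi <= 0.0:
        g, iu = _gamma_std(lam, u, iu)
        if iu < 0:
            return np.nan, iu
        return g * 2.0 / psi, iu
    flip = lam < 0.0
    if flip:
        lam = -lam
        chi, psi = psi, chi
    omega = math.sqrt(chi * psi)
    alpha = math.sqrt(chi / psi)
    x, iu = _gig_std(lam, omega, u, iu)
    if iu < 0:
        return np.nan, iu
    x *= alpha
    if flip:
        x = 1.0 / x
    return x, iu


@njit(cache=True)
def _gibbs_sweep(Z, M, g, h_scrap, eB, inv_xi, u, iu, start, Btot, Gtot):
    """Sequential frailty sweep under uniform company activity.

    For company c the full conditional is GIG with
      lam = M_c + 1/xi,  psi = 2*(D1_c + 1/xi),  chi = 2*D2_c,
      D1_c = g_c * (buyer sum excluding c) + scrap exposure,
      D2_c = eB_c * (seller-weighted exposure excluding c),
    maintained incrementally through the scalars Btot = sum Z^-1 eB and
    Gtot = sum Z g.  Returns (next_company, next_iu, Btot, Gtot); a negative
    iu means the uniform buffer ran out at company ``next_company``.
    """
    N = Z.size
    for c in range(start, N):
        zc = Z[c]
        Bminus = Btot - eB[c] / zc
        if Bminus < 0.0:
            Bminus = 0.0
        Gminus = Gtot - g[c] * zc
        if Gminus < 0.0:
            Gminus = 0.0
        D1 = g[c] * Bminus + h_scrap[c]
        D2 = eB[c] * Gminus
        lam = M[c] + inv_xi
        chi = 2.0 * D2
        psi = 2.0 * (D1 + inv_xi)
        x, iu2 = _gig_draw(lam, chi, psi, u, iu)
        if iu2 < 0:
            return c, _EXHAUSTED, Btot, Gtot
        iu = iu2
        Z[c] = x
        Btot = Bminus + eB[c] / x
        Gtot = Gminus + g[c] * x
    return N, iu, Btot, Gtot


# ---------------------------------------------------------------------------
# python-facing wrappers
# ---------------------------------------------------------------------------

def gig_log_kernel(z, lam: float, chi: float, psi: float):
    """Unnormalised log density (lam-1)*log z - (psi*z + chi/z)/2."""
    z = np.asarray(z, dtype=float)
    return (lam - 1.0) * np.log(z) - 0.5 * (psi * z + chi / z)


def _validate_gig(lam: float, chi: float, psi: float) -> None:
    if not psi > 0:
        raise ValueError("psi must be positive")
    if chi < 0:
        raise ValueError("chi must be nonnegative")
    if chi == 0 and lam <= 0:
        raise ValueError("chi = 0 requires lam > 0 (gamma degeneracy)")


def sample_gig(
    lam: float, chi: float, psi: float, rng: np.random.Generator,
    size: int | None = None,
):
    """Exact draw(s) from the GIG kernel z^{lam-1} exp{-(psi z + chi/z)/2}.

    ``size=None`` returns a scalar, otherwise a 1-d array of that length.
    """
    _validate_gig(lam, chi, psi)
    n = 1 if size is None else int(size)
    out = np.empty(n)
    buf = rng.random(64)
    iu = 0
    for i in range(n):
        while True:
            x, iu2 = _gig_draw(lam, chi, psi, buf, iu)
            if iu2 >= 0:
                out[i] = x
                iu = iu2
                break
            buf = rng.random(max(256, 2 * buf.size))
            iu = 0
    return float(out[0]) if size is None else out
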