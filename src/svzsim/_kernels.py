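"""Compiled hot path for the semi-discrete right-hand side.

The numpy implementations in :mod:`svzsim.numerics` are the reference;
this module provides an equivalent numba-compiled kernel used by
``System.rhs`` when numba is importable.  Equality of the two paths is
asserted by the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is a hard dep in practice
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco(a[0]) if a and callable(a[0]) else deco


@njit(cache=True)
def _add_laplacian(u, coeff, L, R, h2, out):
    for f in range(L.size):
        d = coeff * (u[R[f]] - u[L[f]]) / h2
        out[L[f]] += d
        out[R[f]] -= d


@njit(cache=True)
def _add_taxis(u, pot, coeff, s, L, R, LLs, RRs, HL, HR, h, out):
    for f in range(L.size):
        l, r = L[f], R[f]
        v = s * coeff * (pot[r] - pot[l]) / h
        du = u[r] - u[l]
        if v >= 0.0:
            num = (u[l] - u[LLs[f]]) * HL[f]
        else:
            num = (u[RRs[f]] - u[r]) * HR[f]
        phi = 0.0
        if du != 0.0:
            rr = num / du
            phi = (rr + abs(rr)) / (1.0 + abs(rr))
        if v >= 0.0:
            uf = u[l] + 0.5 * phi * du
        else:
            uf = u[r] - 0.5 * phi * du
        J = v * uf / h
        out[l] -= J
        out[r] += J


@njit(cache=True)
def rhs_kernel(y, svz_idx, beta_A, gamma_A_eff, zeta, q, gfield,
               fxL, fxR, fxLL, fxRR, fxHL, fxHR,
               fyL, fyR, fyLL, fyRR, fyHL, fyHR,
               h, pv):
    """Packed rhs: y = [nB|svz, nC|svz, nA, nN, fA].

    ``pv`` carries the rate constants in the canonical coordinate order
    (beta_B, beta_C, beta_Ai, beta_Ao, alpha_C, alpha_A, gamma_B,
    gamma_C, gamma_A, gamma_N, delta_A, delta_N, delta_fA, eta_A,
    eta_N, kappa_A, kappa_B, kappa_C, kappa_D, lam, ...).
    ``gamma_A_eff`` is the per-cell gamma_A + eps + zeta sink and
    ``beta_A`` the per-cell logistic rate of type-A cells.
    """
    n = beta_A.size
    m = svz_idx.size
    o = 2 * m
    nA = y[o:o + n]
    nN = y[o + n:o + 2 * n]
    fA = y[o + 2 * n:o + 3 * n]
    out = np.zeros(y.size)

    beta_B, beta_C = pv[0], pv[1]
    alpha_C, alpha_A = pv[4], pv[5]
    gamma_B, gamma_C, gamma_N = pv[6], pv[7], pv[9]
    delta_A, delta_N, delta_fA = pv[10], pv[11], pv[12]
    eta_A, eta_N = pv[13], pv[14]
    kappa_A, kappa_B, kappa_C, kappa_D = pv[15], pv[16], pv[17], pv[18]
    lam = pv[19]

    dA = out[o:o + n]
    dN = out[o + n:o + 2 * n]
    dF = out[o + 2 * n:o + 3 * n]

    # pointwise kinetics
    for c in range(n):
        a = nA[c]
        dA[c] = beta_A[c] * a * (1.0 - a) - gamma_A_eff[c] * a
        dN[c] = zeta[c] * a - gamma_N * nN[c]
        dF[c] = (kappa_A * a - kappa_D * fA[c] * a - lam * fA[c] + q[c])
    for k in range(m):
        c = svz_idx[k]
        b, cc = y[k], y[m + k]
        out[k] = beta_B * b * (1.0 - b) - (alpha_C + gamma_B) * b
        out[m + k] = (beta_C * cc * (1.0 - cc) + alpha_C * b
                      - (alpha_A + gamma_C) * cc)
        dA[c] += alpha_A * cc
        dF[c] += kappa_B * b + kappa_C * cc

    h2 = h * h
    _add_laplacian(nA, delta_A, fxL, fxR, h2, dA)
    _add_laplacian(nA, delta_A, fyL, fyR, h2, dA)
    _add_laplacian(nN, delta_N, fxL, fxR, h2, dN)
    _add_laplacian(nN, delta_N, fyL, fyR, h2, dN)
    _add_laplacian(fA, delta_fA, fxL, fxR, h2, dF)
    _add_laplacian(fA, delta_fA, fyL, fyR, h2, dF)
    _add_taxis(nA, fA, eta_A, 1.0, fxL, fxR, fxLL, fxRR, fxHL, fxHR, h, dA)
    _add_taxis(nA, fA, eta_A, 1.0, fyL, fyR, fyLL, fyRR, fyHL, fyHR, h, dA)
    _add_taxis(nN, gfield, eta_N, -1.0, fxL, fxR, fxLL, fxRR, fxHL, fxHR, h, dN)
    _add_taxis(nN, gfield, eta_N, -1.0, fyL, fyR, fyLL, fyRR, fyHL, fyHR, h, dN)
    return out
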