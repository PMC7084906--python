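"""Compiled inner loop of the conditional (Laplace) likelihood.

This mirrors the vectorised numpy implementation in
:mod:`pkbridge.population` operation for operation — same closed-form
kinetics, same finite-difference inner Newton (step 1e-4, |delta| < 1e-6,
max 50 iterations), same log-determinant correction — but runs the
per-subject loops under numba.  The numpy path remains the reference; the
two are cross-checked in the test suite and the engine falls back to numpy
when numba is unavailable.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*a, **k):  # noqa: D103
        def wrap(f):
            return f

        return wrap(a[0]) if a and callable(a[0]) else wrap


_EIG_TOL = 1e-9


@njit(cache=True)
def _b2s(a: float, b: float, t: float) -> float:
    scale = max(abs(a), abs(b))
    if abs(a - b) <= _EIG_TOL * scale:
        return t * math.exp(-a * t)
    return (math.exp(-a * t) - math.exp(-b * t)) / (b - a)


@njit(cache=True)
def _pair3(k: float, m: float, t: float, scale: float) -> float:
    d = m - k
    if abs(d) <= _EIG_TOL * scale:
        return 0.5 * t * t * math.exp(-k * t)
    return (t * math.exp(-k * t) * d - math.exp(-k * t) + math.exp(-m * t)) / (d * d)


@njit(cache=True)
def _b3s(a: float, b: float, c: float, t: float) -> float:
    scale = max(max(abs(a), abs(b)), abs(c))
    ab = abs(a - b) <= _EIG_TOL * scale
    ac = abs(a - c) <= _EIG_TOL * scale
    bc = abs(b - c) <= _EIG_TOL * scale
    if ab and ac:
        return 0.5 * t * t * math.exp(-a * t)
    if ab:
        return _pair3(a, c, t, scale)
    if ac:
        return _pair3(a, b, t, scale)
    if bc:
        return _pair3(b, a, t, scale)
    return (
        math.exp(-a * t) / ((b - a) * (c - a))
        + math.exp(-b * t) / ((a - b) * (c - b))
        + math.exp(-c * t) / ((a - c) * (b - c))
    )


@njit(cache=True)
def _conc(ka, fpm, clp, clpm, vp, clm, vm, tlag, dose, t, metab, depot):
    tt = t - tlag
    if tt <= 0.0:
        return 1e-10
    kel = (clp + clpm) / vp
    kem = clm / vm
    if not metab:
        c = dose * (1.0 - fpm) * ka * _b2s(kel, ka, tt) / vp * 1000.0
    else:
        kpm = clpm / vp
        conv = dose * (1.0 - fpm) * ka * kpm * _b3s(ka, kel, kem, tt)
        fp_in = dose * fpm * ka * _b2s(kem, ka, tt) if depot else dose * fpm * math.exp(-kem * tt)
        c = (fp_in + conv) / vm * 1000.0
    if not (c > 1e-10) or not math.isfinite(c):
        return 1e-10
    return c


@njit(cache=True)
def _h_subj(theta, sp2, sm2, omega, eta, eta_tgt, t, y, metab, dose, ppl,
            i0, i1, depot):
    q = eta.shape[0]
    ka = theta[0]
    fpm = theta[1]
    clp = theta[2]
    clpm = theta[3]
    vp = theta[4]
    clm = theta[5]
    vm = theta[6]
    for j in range(q):
        e = min(max(eta[j], -50.0), 50.0)
        m = math.exp(e)
        tg = eta_tgt[j]
        if tg == 0:
            ka *= m
        elif tg == 1:
            fpm *= m
        elif tg == 2:
            clp *= m
        elif tg == 3:
            clpm *= m
        elif tg == 4:
            vp *= m
        elif tg == 5:
            clm *= m
        else:
            vm *= m
    fpm = fpm * (1.0 - theta[8] * ppl / (ppl + theta[9]))
    if fpm > 0.9999:
        fpm = 0.9999
    clpm = clpm * (1.0 - theta[10] * ppl / (ppl + theta[11]))
    clp = clp * (1.0 - theta[12] * ppl / (ppl + theta[13]))
    h = 0.0
    two_pi = 2.0 * math.pi
    for i in range(i0, i1):
        f = _conc(ka, fpm, clp, clpm, vp, clm, vm, theta[7], dose, t[i],
                  metab[i], depot)
        s2 = sm2 if metab[i] else sp2
        g = s2 * f * f
        d = y[i] - f
        val = math.log(two_pi * g) + d * d / g
        if not math.isfinite(val) or val > 1e12:
            val = 1e12
        h += val
    for j in range(q):
        e = min(max(eta[j], -50.0), 50.0)
        h += e * e / omega[j] + math.log(two_pi * omega[j])
    return h


@njit(cache=True)
def _chol_logdet_half(a):
    """Cholesky of a (q,q) copy; returns (ok, log det(a/2))."""
    q = a.shape[0]
    L = a.copy()
    logdet = 0.0
    for i in range(q):
        for j in range(i + 1):
            s = L[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return False, 0.0
                L[i, i] = math.sqrt(s)
                logdet += 2.0 * math.log(L[i, i])
            else:
                L[i, j] = s / L[j, j]
    return True, logdet - q * math.log(2.0)


@njit(cache=True)
def _solve_spd(a, b):
    """Solve a x = b for small symmetric positive-definite a (in place ok)."""
    q = a.shape[0]
    L = a.copy()
    for i in range(q):
        for j in range(i + 1):
            s = L[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                L[i, i] = math.sqrt(max(s, 1e-30))
            else:
                L[i, j] = s / L[j, j]
    x = b.copy()
    for i in range(q):
        for k in range(i):
            x[i] -= L[i, k] * x[k]
        x[i] /= L[i, i]
    for i in range(q - 1, -1, -1):
        for k in range(i + 1, q):
            x[i] -= L[k, i] * x[k]
        x[i] /= L[i, i]
    return x


@njit(cache=True)
def ofv_kernel(theta, sp, sm, omega, eta_tgt, t, y, metab, offsets, dose,
               ppl, warm, depot):
    """Per-subject -2 log marginal likelihood (Laplace), kernel version.

    ``warm`` (S, q) holds inner-eta warm starts and is updated in place.
    Returns the per-subject OFV components.
    """
    S = offsets.shape[0] - 1
    q = omega.shape[0]
    comp = np.empty(S)
    sp2 = sp * sp
    sm2 = sm * sm
    d = 1e-4
    two_pi_log = math.log(2.0 * math.pi)
    for s in range(S):
        i0 = offsets[s]
        i1 = offsets[s + 1]
        if q == 0:
            comp[s] = _h_subj(theta, sp2, sm2, omega, np.zeros(0), eta_tgt,
                              t, y, metab, dose[s], ppl[s], i0, i1, depot)
            continue
        eta = warm[s].copy()
        h0 = _h_subj(theta, sp2, sm2, omega, eta, eta_tgt, t, y, metab,
                     dose[s], ppl[s], i0, i1, depot)
        grad = np.empty(q)
        hess = np.empty((q, q))
        hp = np.empty(q)
        hm = np.empty(q)
        for _it in range(50):
            for j in range(q):
                e = eta.copy()
                e[j] += d
                hp[j] = _h_subj(theta, sp2, sm2, omega, e, eta_tgt, t, y,
                                metab, dose[s], ppl[s], i0, i1, depot)
                e[j] -= 2 * d
                hm[j] = _h_subj(theta, sp2, sm2, omega, e, eta_tgt, t, y,
                                metab, dose[s], ppl[s], i0, i1, depot)
                grad[j] = (hp[j] - hm[j]) / (2 * d)
                hess[j, j] = (hp[j] + hm[j] - 2 * h0) / (d * d)
            for i in range(q):
                for j in range(i + 1, q):
                    e = eta.copy()
                    e[i] += d
                    e[j] += d
                    hpp = _h_subj(theta, sp2, sm2, omega, e, eta_tgt, t, y,
                                  metab, dose[s], ppl[s], i0, i1, depot)
                    hess[i, j] = (hpp - hp[i] - hp[j] + h0) / (d * d)
                    hess[j, i] = hess[i, j]
            # ridge until positive definite
            ridge = 0.0
            ok, _ld = _chol_logdet_half(hess)
            while not ok and ridge < 1e8:
                ridge = 1e-6 if ridge == 0.0 else ridge * 10.0
                hr = hess.copy()
                for i in range(q):
                    hr[i, i] += ridge
                ok, _ld = _chol_logdet_half(hr)
            hr = hess.copy()
            for i in range(q):
                hr[i, i] += ridge
            delta = _solve_spd(hr, grad)
            mx = 0.0
            for j in range(q):
                delta[j] = -delta[j]
                if abs(delta[j]) > mx:
                    mx = abs(delta[j])
            # trust-region cap: |eta| steps beyond a few SDs are never useful
            if mx > 4.0:
                for j in range(q):
                    delta[j] *= 4.0 / mx
            scale = 1.0
            applied = 0.0
            for _halve in range(20):
                trial = eta.copy()
                for j in range(q):
                    trial[j] += scale * delta[j]
                ht = _h_subj(theta, sp2, sm2, omega, trial, eta_tgt, t, y,
                             metab, dose[s], ppl[s], i0, i1, depot)
                if ht <= h0 + 1e-12:
                    eta = trial
                    h0 = ht
                    applied = scale
                    break
                scale *= 0.5
            maxstep = 0.0
            for j in range(q):
                a = abs(applied * delta[j])
                if a > maxstep:
                    maxstep = a
            if maxstep < 1e-6:
                break
        # final Hessian at the converged eta for the Laplace correction
        for j in range(q):
            e = eta.copy()
            e[j] += d
            hp[j] = _h_subj(theta, sp2, sm2, omega, e, eta_tgt, t, y, metab,
                            dose[s], ppl[s], i0, i1, depot)
            e[j] -= 2 * d
            hm[j] = _h_subj(theta, sp2, sm2, omega, e, eta_tgt, t, y, metab,
                            dose[s], ppl[s], i0, i1, depot)
            hess[j, j] = (hp[j] + hm[j] - 2 * h0) / (d * d)
        for i in range(q):
            for j in range(i + 1, q):
                e = eta.copy()
                e[i] += d
                e[j] += d
                hpp = _h_subj(theta, sp2, sm2, omega, e, eta_tgt, t, y, metab,
                              dose[s], ppl[s], i0, i1, depot)
                hess[i, j] = (hpp - hp[i] - hp[j] + h0) / (d * d)
                hess[j, i] = hess[i, j]
        ok, logdet = _chol_logdet_half(hess)
        if not ok:
            hr = hess.copy()
            for i in range(q):
                hr[i, i] += 1e-6
            ok, logdet = _chol_logdet_half(hr)
            if not ok:
                logdet = 0.0
        warm[s] = eta
        comp[s] = h0 - q * two_pi_log + logdet
    return comp
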