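"""Compiled teacher-forced replay kernel.

A numba implementation of the per-fixation likelihood replay, used by
:mod:`scenewalk.likelihood` for speed during MCMC.  The reference
implementation is :class:`scenewalk.engine.SceneWalkEngine`; the two are
held equal (to floating-point tolerance) by the test suite, and the
reference path remains available via ``scanpath_loglik(..., fast=False)``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["replay_log2"]


@njit(cache=True)
def _gaussian(x, y, cx, cy, sx, sy):
    nx, ny = x.size, y.size
    out = np.empty((nx, ny))
    gx = np.empty(nx)
    gy = np.empty(ny)
    for i in range(nx):
        gx[i] = math.exp(-((x[i] - cx) ** 2) / (2.0 * sx * sx))
    for j in range(ny):
        gy[j] = math.exp(-((y[j] - cy) ** 2) / (2.0 * sy * sy))
    for i in range(nx):
        for j in range(ny):
            out[i, j] = gx[i] * gy[j]
    return out


@njit(cache=True)
def _attention_target(S, x, y, cx, cy, sigma):
    g = _gaussian(x, y, cx, cy, sigma, sigma)
    s = 0.0
    for i in range(x.size):
        for j in range(y.size):
            g[i, j] *= S[i, j]
            s += g[i, j]
    return g / s


@njit(cache=True)
def _evolve(M, target, omega, dt):
    decay = math.exp(-omega * dt)
    for i in range(M.shape[0]):
        for j in range(M.shape[1]):
            M[i, j] = target[i, j] + decay * (M[i, j] - target[i, j])


@njit(cache=True)
def _evolve_for(M, target, omega_fast, omega_slow, x, y, px, py, nu, dt):
    df = math.exp(-omega_fast * dt)
    ds = math.exp(-omega_slow * dt)
    for i in range(M.shape[0]):
        in_x = abs(x[i] - px) < nu
        for j in range(M.shape[1]):
            d = ds if (in_x and abs(y[j] - py) < nu) else df
            M[i, j] = target[i, j] + d * (M[i, j] - target[i, j])


@njit(cache=True)
def _pi_at(A, F, gamma, C_F, zeta, psi, chi, omp_subtract,
           x, y, fx, fy, ci, cj):
    """Selection probability at one cell, building the full map internally."""
    nx, ny = A.shape
    n_cells = nx * ny
    sa = 0.0
    sf = 0.0
    a = np.empty((nx, ny))
    f = np.empty((nx, ny))
    for i in range(nx):
        for j in range(ny):
            av = A[i, j]
            a[i, j] = (av if av > 0.0 else 0.0) ** gamma
            sa += a[i, j]
            fv = F[i, j] ** gamma
            f[i, j] = fv
            sf += fv
    use_f = sf > 0.0
    # oculomotor potential (normalized) when psi != 0
    s_omp = 0.0
    omp = np.zeros((nx, ny))
    if psi != 0.0:
        for i in range(nx):
            dx2 = (x[i] - fx) ** 2
            for j in range(ny):
                base = dx2 * (y[j] - fy) ** 2
                if chi == 0.0:
                    omp[i, j] = 1.0 if base > 0.0 else 0.0
                else:
                    omp[i, j] = base ** chi
                s_omp += omp[i, j]
    su = 0.0
    u = np.empty((nx, ny))
    for i in range(nx):
        for j in range(ny):
            v = a[i, j] / sa - (C_F * f[i, j] / sf if use_f else 0.0)
            if psi != 0.0:
                t = psi * omp[i, j] / s_omp
                v = v - t if omp_subtract else v + abs(-t)
            if v < 0.0:
                v = 0.0
            u[i, j] = v
            su += v
    if su > 0.0 and zeta < 1.0:
        p = (1.0 - zeta) * u[ci, cj] / su + zeta / n_cells
    elif zeta > 0.0:
        # rectified map vanished entirely: selection falls back to uniform
        p = 1.0 / n_cells
    else:
        p = 0.0
    return p


@njit(cache=True)
def replay_log2(
    S, x, y, px, py, dur, cells_i, cells_j,
    omega_A, omega_F, sigma_A, sigma_F, gamma, C_F, zeta,
    tau_pre, tau_post, eta, sigma_post, nu, omega_FoR,
    chi, psi, omp_subtract, facilitation,
    center_bias, omega_CB, sigma_CB_x, sigma_CB_y,
):
    """Per-fixation log2 probabilities of an observed scan path."""
    n = px.size
    nx, ny = x.size, y.size
    n_cells = nx * ny
    out = np.empty(n)
    LN2 = math.log(2.0)

    # first fixation from the initial map
    if center_bias:
        A = _gaussian(x, y, (x[0] + x[nx - 1]) / 2.0, (y[0] + y[ny - 1]) / 2.0,
                      sigma_CB_x, sigma_CB_y)
        sA = A.sum()
        A /= sA
        p0 = (1.0 - zeta) * A[cells_i[0], cells_j[0]] / A.sum() + zeta / n_cells
        F = np.zeros((nx, ny))
    else:
        A = np.full((nx, ny), 1.0 / n_cells)
        F = np.full((nx, ny), 1.0 / n_cells)
        p0 = 1.0 / n_cells
    out[0] = math.log(p0) / LN2 if p0 > 0.0 else -np.inf

    for k in range(n - 1):
        fx, fy = px[k], py[k]
        d = dur[k]
        pre = tau_pre if tau_pre < d else d
        has_remap = (k > 0 and tau_post > 0.0
                     and (px[k - 1] != fx or py[k - 1] != fy))
        post = 0.0
        if has_remap:
            post = tau_post if tau_post < d - pre else d - pre
        main = d - pre - post
        fac = facilitation and k > 0

        gf = _gaussian(x, y, fx, fy, sigma_F, sigma_F)
        gf /= gf.sum()

        if post > 0.0:
            ddx = fx - px[k - 1]
            ddy = fy - py[k - 1]
            nrm = math.hypot(ddx, ddy)
            target = _attention_target(S, x, y, fx + ddx / nrm * eta,
                                       fy + ddy / nrm * eta, sigma_post)
            if fac:
                _evolve_for(A, target, omega_A, omega_FoR, x, y,
                            px[k - 1], py[k - 1], nu, post)
            else:
                _evolve(A, target, omega_A, post)
        if main > 0.0:
            target = _attention_target(S, x, y, fx, fy, sigma_A)
            rate = omega_CB if (k == 0 and center_bias) else omega_A
            if fac:
                _evolve_for(A, target, rate, omega_FoR, x, y,
                            px[k - 1], py[k - 1], nu, main)
            else:
                _evolve(A, target, rate, main)
        if post + main > 0.0:
            _evolve(F, gf, omega_F, post + main)

        p = _pi_at(A, F, gamma, C_F, zeta, psi, chi, omp_subtract,
                   x, y, fx, fy, cells_i[k + 1], cells_j[k + 1])
        out[k + 1] = math.log(p) / LN2 if p > 0.0 else -np.inf

        if pre > 0.0:
            target = _attention_target(S, x, y, px[k + 1], py[k + 1], sigma_A)
            if fac:
                _evolve_for(A, target, omega_A, omega_FoR, x, y,
                            px[k - 1], py[k - 1], nu, pre)
            else:
                _evolve(A, target, omega_A, pre)
            _evolve(F, gf, omega_F, pre)

    return out
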