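"""Compiled per-node kernels for the fibre solver's inner loop.

These mirror the vectorised reference implementations in :mod:`cell_br`
exactly (same formulas, same singularity guards, same frozen-Jacobian
iteration); the solver falls back to the numpy path when numba is not
importable.  Agreement between the two paths is asserted in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap

_SING_EPS = 1e-9

# consts vector layout shared with solver.py
# [g_na, g_nac, e_na, g_s, g_x1, g_k1, ca_uptake, ca_scale,
#  es_offset, es_slope, ca_newton_tol, ca_newton_maxit]
N_CONSTS = 12


def pack_consts(p) -> np.ndarray:
    return np.array(
        [p.g_na, p.g_nac, p.e_na, p.g_s, p.g_x1, p.g_k1,
         p.ca_uptake, p.ca_scale, p.es_offset, p.es_slope,
         p.ca_newton_tol, float(p.ca_newton_maxit)],
        dtype=np.float64,
    )


@njit(cache=False, fastmath=True)
def _rate_s(v, c1, c2, c3, c4, c5, c6, c7):
    dv = v + c3
    if c1 == 0.0:
        num = c4 * (v + c5)
    elif c2 == 0.0:
        num = c1 + c4 * (v + c5)
    else:
        num = c1 * math.exp(c2 * dv) + c4 * (v + c5)
    if c6 == 0.0:
        return num / (1.0 + c7)
    den = math.exp(c6 * dv) + c7
    if abs(den) < _SING_EPS:
        return (c1 * c2 * math.exp(c2 * dv) + c4) / (c6 * math.exp(c6 * dv))
    return num / den


@njit(cache=False, fastmath=True)
def _iion_s(v, m, h, j, d, f, x1, ca, c):
    i_na = (c[0] * m * m * m * h * j + c[1]) * (v - c[2])
    e_s = c[8] + c[9] * math.log(c[7] * ca)
    i_s = c[3] * d * f * (v - e_s)
    i_x1 = x1 * c[4] * (math.exp(0.04 * (v + 77.0)) - 1.0) / math.exp(0.04 * (v + 35.0))
    t1 = 4.0 * (math.exp(0.04 * (v + 85.0)) - 1.0) / (
        math.exp(0.08 * (v + 53.0)) + math.exp(0.04 * (v + 53.0))
    )
    den = 1.0 - math.exp(-0.04 * (v + 23.0))
    if abs(den) < _SING_EPS:
        t2 = 0.2 / 0.04
    else:
        t2 = 0.2 * (v + 23.0) / den
    i_k1 = c[5] * (t1 + t2)
    return i_na + i_s + i_x1 + i_k1


@njit(cache=False, fastmath=True)
def reaction_g(v, m, h, j, d, f, x1, ca, istim, inv_cm, table, consts, g_out):
    """g_i = (-Iion_i + istim_i) / Cm for every node."""
    for i in range(v.shape[0]):
        g_out[i] = (-_iion_s(v[i], m[i], h[i], j[i], d[i], f[i], x1[i],
                             ca[i], consts) + istim[i]) * inv_cm


@njit(cache=False, fastmath=True)
def update_state(v, m, h, j, d, f, x1, ca, dt, table, consts):
    """In-place implicit gate and calcium updates at the (already updated)
    voltage.  Returns the worst unconverged calcium residual, or -1.0 when
    every node converged."""
    tol = consts[10]
    maxit = int(consts[11])
    k_up = consts[6]
    worst = -1.0
    for i in range(v.shape[0]):
        vi = v[i]
        # six linear gates: exact implicit Euler via the BDF expression
        for g in range(6):
            a = _rate_s(vi, table[2 * g, 0], table[2 * g, 1], table[2 * g, 2],
                        table[2 * g, 3], table[2 * g, 4], table[2 * g, 5],
                        table[2 * g, 6])
            b = _rate_s(vi, table[2 * g + 1, 0], table[2 * g + 1, 1],
                        table[2 * g + 1, 2], table[2 * g + 1, 3],
                        table[2 * g + 1, 4], table[2 * g + 1, 5],
                        table[2 * g + 1, 6])
            if g == 0:
                m[i] = (m[i] + dt * a) / (1.0 + dt * (a + b))
            elif g == 1:
                h[i] = (h[i] + dt * a) / (1.0 + dt * (a + b))
            elif g == 2:
                j[i] = (j[i] + dt * a) / (1.0 + dt * (a + b))
            elif g == 3:
                d[i] = (d[i] + dt * a) / (1.0 + dt * (a + b))
            elif g == 4:
                f[i] = (f[i] + dt * a) / (1.0 + dt * (a + b))
            else:
                x1[i] = (x1[i] + dt * a) / (1.0 + dt * (a + b))
        # calcium: implicit Euler solved by frozen-Jacobian Newton
        c0 = ca[i]
        gdf = consts[3] * d[i] * f[i]
        jac = 1.0 - dt * (consts[9] * gdf / c0 - k_up)
        # explicit-Euler predictor as the Newton start (the Jacobian stays
        # frozen at c0); saves iterations without changing the converged root
        e_s0 = consts[8] + consts[9] * math.log(consts[7] * c0)
        c = c0 + dt * (-gdf * (vi - e_s0) + k_up * (1.0 - c0))
        if c < 1e-12:
            c = 1e-12
        converged = False
        resid = 0.0
        for _ in range(maxit):
            e_s = consts[8] + consts[9] * math.log(consts[7] * c)
            rhs = -gdf * (vi - e_s) + k_up * (1.0 - c)
            resid = c - c0 - dt * rhs
            if abs(resid) < tol:
                converged = True
                break
            c = c - resid / jac
            if c < 1e-12:
                c = 1e-12
        ca[i] = c
        if not converged and abs(resid) > worst:
            worst = abs(resid)
    return worst
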