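"""Finite-difference monodomain solver used as an independent cross-check.

Solves the standard (alpha = 2) monodomain equation with the classical
second-order three-point Laplacian and zero-flux boundaries imposed through
ghost nodes (mirror reflection), advanced with the same splitting as the
spectral solver: backward Euler for diffusion, reaction frozen at the old
time level, then the implicit gate/calcium updates.  Because the spatial
operator is discretised by an entirely different route, trace-level agreement
with the spectral solver at alpha = 2 validates the spectral diffusion path.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded

from . import _kernels
from .cell_br import BRParameters, CalciumConvergenceError, CellState
from .solver import (
    ModelConfig,
    SimulationResult,
    FibreState,
    VoltageTrace,
    _record_indices,
    _check_finite,
)

__all__ = ["simulate_fd"]


def _banded_matrix(cfg: ModelConfig) -> np.ndarray:
    """Banded form of I - dt * D/(chi*Cm) * L_h with Neumann (mirror) ends."""
    n = cfg.N + 1
    h = cfg.L / cfg.N
    r = cfg.dt * cfg.diffusivity / h**2
    ab = np.zeros((3, n))
    ab[1, :] = 1.0 + 2.0 * r     # diagonal
    ab[0, 1:] = -r               # superdiagonal
    ab[2, :-1] = -r              # subdiagonal
    ab[0, 1] = -2.0 * r          # ghost-node reflection at x = 0
    ab[2, -2] = -2.0 * r         # and at x = L
    return ab


def simulate_fd(cfg: ModelConfig, params: BRParameters | None = None) -> SimulationResult:
    """Run the finite-difference monodomain simulation (requires alpha = 2)."""
    if cfg.alpha != 2.0:
        raise ValueError("the finite-difference reference solver is defined "
                         "only for the classical case alpha = 2")
    p = params or BRParameters()
    n = cfg.N + 1
    h = cfg.L / cfg.N
    x = np.arange(n) * h
    ab = _banded_matrix(cfg)

    cell = CellState.resting_initial(shape=(n,))
    v = np.array(cell.v, copy=True)
    m, hh, jg, d, f, x1, ca = (np.array(getattr(cell, k), copy=True)
                               for k in ("m", "h", "j", "d", "f", "x1", "ca"))
    table = np.ascontiguousarray(p.rate_table)
    consts = _kernels.pack_consts(p)
    stim_vec = np.where(x <= cfg.stim_extent + 1e-12, cfg.stim_amplitude, 0.0)
    zero_vec = np.zeros_like(stim_vec)
    g = np.empty_like(v)
    inv_cm = 1.0 / cfg.Cm
    t_on, t_off = cfg.stim_start, cfg.stim_start + cfg.stim_duration

    nt = cfg.n_steps
    rec_idx = _record_indices(cfg, x)
    rec_buf = np.empty((len(rec_idx), nt + 1))
    rec_buf[:, 0] = v[rec_idx]

    for k in range(nt):
        t = k * cfg.dt
        istim = stim_vec if (t_on <= t < t_off) else zero_vec
        if cfg.reaction:
            _kernels.reaction_g(v, m, hh, jg, d, f, x1, ca, istim, inv_cm,
                                table, consts, g)
        else:
            np.multiply(istim, inv_cm, out=g)
        v = solve_banded((1, 1), ab, v + cfg.dt * g)
        if cfg.reaction:
            worst = _kernels.update_state(v, m, hh, jg, d, f, x1, ca, cfg.dt,
                                          table, consts)
            if worst >= 0.0:
                raise CalciumConvergenceError(worst, p.ca_newton_maxit)
        rec_buf[:, k + 1] = v[rec_idx]
        if (k + 1) % 500 == 0:
            _check_finite(v, (k + 1) * cfg.dt)
    _check_finite(v, nt * cfg.dt)

    meta = {"config_hash": cfg.config_hash(), "alpha": cfg.alpha,
            "solver": "finite-difference"}
    traces = {}
    for r, c in enumerate(cfg.record):
        traces[c] = VoltageTrace(x=float(x[rec_idx[r]]), dt=cfg.dt,
                                 v=rec_buf[r].copy(), stim_start=cfg.stim_start,
                                 meta=dict(meta))
    final_cell = CellState(v=v, m=m, h=hh, j=jg, d=d, f=f, x1=x1, ca=ca)
    final = FibreState(time=nt * cfg.dt, cell=final_cell,
                       vhat=np.zeros(n))
    return SimulationResult(config=cfg, traces=traces, final_state=final)
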