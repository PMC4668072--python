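"""Semi-implicit spectral time integration of the space-fractional monodomain
model on an insulated 1-D fibre.

The system solved is

    Cm dv/dt = -(D / chi) (-Delta)^(alpha/2) v - Iion(v, z) + Istim
    dz/dt    = f(v, z)

with the fractional Laplacian of :mod:`fraccable.spectral` and the
Beeler–Reuter reaction terms of :mod:`fraccable.cell_br`.  Each step follows
the Whiteley splitting: first the voltage is advanced with the diffusion term
implicit and the reaction term frozen at the previous time level, then the
gating/calcium vector is updated implicitly at the new voltage.  In the
eigenbasis the voltage update is fully diagonal,

    vhat_j(k+1) = (vhat_j(k) + dt * ghat_j(k)) / (1 + dt * D/(chi*Cm) * lambda_j^(alpha/2)),

where ghat is the transform of g = (-Iion + Istim) / Cm.  The spectral
coefficients of v are carried between steps, so one forward transform (of g)
and one inverse transform (of v) are needed per step.

Units: mV, ms, cm, uF/cm^2, mS/cm.  The stimulus amplitude is the membrane
current density (uA/cm^2) delivered uniformly to every node of the stimulated
subinterval [0, stim_extent] during the half-open window
[stim_start, stim_start + stim_duration).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace, asdict
from typing import Mapping

import numpy as np
from scipy.fft import dct

from . import _kernels
from .cell_br import (
    BRParameters,
    CalciumConvergenceError,
    CellState,
    ionic_current,
    update_calcium,
    update_gates,
)
from .spectral import SpectralOperator, build_operator

__all__ = [
    "ModelConfig",
    "FibreState",
    "VoltageTrace",
    "SimulationResult",
    "ThresholdResult",
    "NumericalDivergenceError",
    "stimulus_current",
    "initial_fibre_state",
    "step",
    "simulate",
    "diastolic_threshold",
]

#: default probe coordinates P1, P2, P3 of the unit fibre
DEFAULT_RECORD = (0.25, 0.5, 0.75)


class NumericalDivergenceError(RuntimeError):
    """The voltage field became non-finite during time integration."""

    def __init__(self, time: float, node: int, variable: str = "v"):
        self.time = time
        self.node = node
        self.variable = variable
        super().__init__(
            f"non-finite {variable} at t = {time:.6g} ms, node {node}"
        )


@dataclass(frozen=True)
class ModelConfig:
    """Simulation configuration with the standard defaults of the study:
    a 1 cm fibre, N = 400 intervals, dt = 0.01 ms, 500 ms of activity,
    Cm = 1 uF/cm^2, chi = 1400 cm^-1, D = 1 mS/cm, and a 2 ms, 40 uA/cm^2
    stimulus on [0, 0.05 cm] starting at t = 10 ms (twice the diastolic
    threshold of the standard alpha = 2 fibre)."""

    L: float = 1.0
    N: int = 400
    dt: float = 0.01
    t_final: float = 500.0
    alpha: float = 2.0
    Cm: float = 1.0
    chi: float = 1400.0
    D: float = 1.0
    stim_amplitude: float = 40.0
    stim_extent: float = 0.05
    stim_start: float = 10.0
    stim_duration: float = 2.0
    record: tuple = DEFAULT_RECORD
    snapshot_interval: float | None = None
    reaction: bool = True

    def __post_init__(self):
        checks = [
            (self.L > 0, "L", "must be positive"),
            (isinstance(self.N, (int, np.integer)) and self.N >= 2,
             "N", "must be an integer >= 2"),
            (self.dt > 0, "dt", "must be positive"),
            (1.0 < self.alpha <= 2.0, "alpha", "must lie in (1, 2]"),
            (self.Cm > 0, "Cm", "must be positive"),
            (self.chi > 0, "chi", "must be positive"),
            (self.D > 0, "D", "must be positive"),
            (self.stim_amplitude >= 0, "stim_amplitude", "must be non-negative"),
            (0 < self.stim_extent < self.L, "stim_extent", "must lie in (0, L)"),
            (self.stim_start >= 0, "stim_start", "must be non-negative"),
            (self.stim_duration > 0, "stim_duration", "must be positive"),
            (self.stim_amplitude == 0
             or self.t_final >= self.stim_start + self.stim_duration,
             "t_final", "must cover the stimulus window"),
        ]
        for ok, name, msg in checks:
            if not ok:
                raise ValueError(f"config field '{name}' {msg} "
                                 f"(got {getattr(self, name)!r})")
        object.__setattr__(self, "record", tuple(float(x) for x in self.record))
        for x in self.record:
            if not (0.0 <= x <= self.L):
                raise ValueError(f"config field 'record' coordinates must lie "
                                 f"in [0, L] (got {x!r})")
        nt = self.t_final / self.dt
        if abs(nt - round(nt)) > 1e-8:
            raise ValueError("config field 't_final' must be an integer "
                             "multiple of 'dt'")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_final / self.dt))

    @property
    def diffusivity(self) -> float:
        """D / (chi * Cm) in cm^2/ms."""
        return self.D / (self.chi * self.Cm)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["record"] = list(d["record"])
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelConfig":
        data = dict(data)
        if "record" in data and data["record"] is not None:
            data["record"] = tuple(data["record"])
        if "N" in data:
            data["N"] = int(data["N"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class VoltageTrace:
    """Voltage time series at one node, sampled every dt."""

    x: float
    dt: float
    v: np.ndarray
    t0: float = 0.0
    stim_start: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.v)) * self.dt

    def __len__(self):
        return len(self.v)

    def shifted(self, offset: float) -> "VoltageTrace":
        """The same samples displaced in time by ``offset`` ms."""
        s = None if self.stim_start is None else self.stim_start + offset
        return VoltageTrace(x=self.x, dt=self.dt, v=self.v.copy(),
                            t0=self.t0 + offset, stim_start=s,
                            meta=dict(self.meta))


@dataclass
class FibreState:
    """Full model state at one time: per-node cell state plus the spectral
    coefficients of the voltage (which the scheme carries between steps)."""

    time: float
    cell: CellState
    vhat: np.ndarray


@dataclass
class SimulationResult:
    config: ModelConfig
    traces: dict
    final_state: FibreState
    snapshot_times: np.ndarray | None = None
    snapshots: np.ndarray | None = None

    def trace(self, x: float) -> VoltageTrace:
        """Trace recorded at the requested coordinate (exact key match)."""
        return self.traces[x]


def stimulus_current(x, t: float, cfg: ModelConfig):
    """Stimulus density (uA/cm^2) at position ``x`` (cm) and time ``t`` (ms):
    the configured amplitude on the closed region [0, stim_extent] during the
    half-open window [stim_start, stim_start + stim_duration), else zero."""
    x = np.asarray(x, dtype=float)
    active = cfg.stim_start <= t < cfg.stim_start + cfg.stim_duration
    if not active:
        return np.zeros_like(x) if x.ndim else 0.0
    out = np.where(x <= cfg.stim_extent + 1e-12, cfg.stim_amplitude, 0.0)
    return out if x.ndim else float(out)


def initial_fibre_state(cfg: ModelConfig, op: SpectralOperator | None = None,
                        cell: CellState | None = None) -> FibreState:
    op = op or build_operator(cfg.L, cfg.N, cfg.alpha)
    if cell is None:
        cell = CellState.resting_initial(shape=(cfg.N + 1,))
    return FibreState(time=0.0, cell=cell, vhat=op.forward(cell.v))


def step(state: FibreState, op: SpectralOperator, cfg: ModelConfig,
         params: BRParameters | None = None) -> FibreState:
    """One split step of length cfg.dt, reference (pure numpy) path.

    (i) evaluate g = (-Iion + Istim)/Cm at the current state, (ii) transform,
    (iii) advance each mode by its diagonal semi-implicit factor, (iv) invert
    to obtain the new voltage, (v) update gates then calcium implicitly at the
    new voltage.
    """
    p = params or BRParameters()
    dt = cfg.dt
    cell = state.cell
    istim = stimulus_current(op.x, state.time, cfg)
    if cfg.reaction:
        g = (-ionic_current(cell, p) + istim) / cfg.Cm
    else:
        g = np.broadcast_to(istim / cfg.Cm, op.x.shape)
    ghat = op.forward(g)
    vhat_new = (state.vhat + dt * ghat) / (
        1.0 + dt * cfg.diffusivity * op.frac_eigenvalues
    )
    v_new = op.inverse(vhat_new)
    if not np.all(np.isfinite(v_new)):
        bad = int(np.flatnonzero(~np.isfinite(v_new))[0])
        raise NumericalDivergenceError(state.time + dt, bad)
    if cfg.reaction:
        new_cell = update_gates(cell, v_new, dt, p)
        new_cell = replace(new_cell, ca=update_calcium(new_cell, v_new, dt, p))
    else:
        new_cell = replace(cell, v=v_new)
    return FibreState(time=state.time + dt, cell=new_cell, vhat=vhat_new)


def _record_indices(cfg: ModelConfig, x: np.ndarray):
    """Nearest grid node for each requested record coordinate."""
    idx = [int(round(c / (cfg.L / cfg.N))) for c in cfg.record]
    return np.array(idx, dtype=np.intp)


def simulate(cfg: ModelConfig, params: BRParameters | None = None,
             initial: CellState | None = None,
             fast: bool | None = None) -> SimulationResult:
    """Run the full simulation and record voltage traces every step at the
    configured coordinates (snapped to the nearest grid node).

    ``fast=None`` uses the compiled kernels when numba is available; the two
    paths implement the identical scheme.  The run is fully deterministic.
    """
    p = params or BRParameters()
    if fast is None:
        fast = _kernels.HAVE_NUMBA
    op = build_operator(cfg.L, cfg.N, cfg.alpha)
    state0 = initial_fibre_state(cfg, op, initial)

    nt = cfg.n_steps
    rec_idx = _record_indices(cfg, op.x)
    rec_buf = np.empty((len(rec_idx), nt + 1))
    rec_buf[:, 0] = np.asarray(state0.cell.v)[rec_idx]

    snap_every = None
    snaps = []
    snap_times = []
    if cfg.snapshot_interval is not None:
        snap_every = max(1, int(round(cfg.snapshot_interval / cfg.dt)))
        snaps.append(np.array(state0.cell.v, copy=True))
        snap_times.append(0.0)

    if fast:
        final = _run_fast(cfg, op, state0, p, rec_idx, rec_buf,
                          snap_every, snaps, snap_times)
    else:
        final = _run_reference(cfg, op, state0, p, rec_idx, rec_buf,
                               snap_every, snaps, snap_times)

    meta = {"config_hash": cfg.config_hash(), "alpha": cfg.alpha}
    traces = {}
    for r, c in enumerate(cfg.record):
        traces[c] = VoltageTrace(
            x=float(op.x[rec_idx[r]]), dt=cfg.dt, v=rec_buf[r].copy(),
            stim_start=cfg.stim_start, meta=dict(meta),
        )
    snap_times_arr = np.array(snap_times) if snap_every else None
    snaps_arr = np.array(snaps) if snap_every else None
    return SimulationResult(config=cfg, traces=traces, final_state=final,
                            snapshot_times=snap_times_arr, snapshots=snaps_arr)


def _check_finite(v, time):
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise NumericalDivergenceError(time, bad)


def _run_reference(cfg, op, state, p, rec_idx, rec_buf,
                   snap_every, snaps, snap_times):
    for k in range(cfg.n_steps):
        state.time = k * cfg.dt  # avoid accumulated float drift in the
        state = step(state, op, cfg, p)  # stimulus-window test
        rec_buf[:, k + 1] = np.asarray(state.cell.v)[rec_idx]
        if snap_every and (k + 1) % snap_every == 0:
            snaps.append(np.array(state.cell.v, copy=True))
            snap_times.append(state.time)
    return state


def _run_fast(cfg, op, state, p, rec_idx, rec_buf,
              snap_every, snaps, snap_times):
    dt = cfg.dt
    nt = cfg.n_steps
    cell = state.cell
    v = np.array(cell.v, dtype=np.float64, copy=True)
    m = np.array(cell.m, dtype=np.float64, copy=True)
    h = np.array(cell.h, dtype=np.float64, copy=True)
    jg = np.array(cell.j, dtype=np.float64, copy=True)
    d = np.array(cell.d, dtype=np.float64, copy=True)
    f = np.array(cell.f, dtype=np.float64, copy=True)
    x1 = np.array(cell.x1, dtype=np.float64, copy=True)
    ca = np.array(cell.ca, dtype=np.float64, copy=True)
    vhat = np.array(state.vhat, dtype=np.float64, copy=True)

    table = np.ascontiguousarray(p.rate_table)
    consts = _kernels.pack_consts(p)
    decay = 1.0 / (1.0 + dt * cfg.diffusivity * op.frac_eigenvalues)
    a_fwd = op.normalizers * (op.h / 2.0)
    w = op.normalizers
    stim_vec = np.where(op.x <= cfg.stim_extent + 1e-12,
                        cfg.stim_amplitude, 0.0)
    zero_vec = np.zeros_like(stim_vec)
    g = np.empty_like(v)
    inv_cm = 1.0 / cfg.Cm
    t_on, t_off = cfg.stim_start, cfg.stim_start + cfg.stim_duration
    use_reaction = cfg.reaction

    for k in range(nt):
        t = k * dt
        istim = stim_vec if (t_on <= t < t_off) else zero_vec
        if use_reaction:
            _kernels.reaction_g(v, m, h, jg, d, f, x1, ca, istim, inv_cm,
                                table, consts, g)
        else:
            np.multiply(istim, inv_cm, out=g)
        ghat = dct(g, type=1)
        ghat *= a_fwd
        vhat += dt * ghat
        vhat *= decay
        dbuf = vhat * w
        dbuf[1:-1] *= 0.5
        v = dct(dbuf, type=1)
        if use_reaction:
            worst = _kernels.update_state(v, m, h, jg, d, f, x1, ca, dt,
                                          table, consts)
            if worst >= 0.0:
                raise CalciumConvergenceError(worst, p.ca_newton_maxit)
        rec_buf[:, k + 1] = v[rec_idx]
        if snap_every and (k + 1) % snap_every == 0:
            snaps.append(v.copy())
            snap_times.append((k + 1) * dt)
        if (k + 1) % 500 == 0:
            _check_finite(v, (k + 1) * dt)
    _check_finite(v, nt * dt)
    new_cell = CellState(v=v, m=m, h=h, j=jg, d=d, f=f, x1=x1, ca=ca)
    return FibreState(time=nt * dt, cell=new_cell, vhat=vhat)


@dataclass
class ThresholdResult:
    threshold: float
    tolerance: float
    history: list  # (amplitude, propagated) pairs in evaluation order


def diastolic_threshold(cfg: ModelConfig, lo: float = 0.0, hi: float = 80.0,
                        tol: float = 0.5, probe_x: float | None = None,
                        params: BRParameters | None = None) -> ThresholdResult:
    """Minimum stimulus amplitude that produces a propagated excitation,
    located by bisection to absolute tolerance ``tol`` (uA/cm^2).

    Success means the voltage at the probe node (default x = 0.75 L) rises
    above 0 mV.  Raises if the upper bracket does not propagate.
    """
    probe = 0.75 * cfg.L if probe_x is None else probe_x
    history = []

    def propagates(amp: float) -> bool:
        c = replace(cfg, stim_amplitude=amp, record=(probe,),
                    snapshot_interval=None)
        res = simulate(c, params)
        ok = bool(np.max(next(iter(res.traces.values())).v) > 0.0)
        history.append((amp, ok))
        return ok

    if not propagates(hi):
        raise RuntimeError(
            f"upper bracket amplitude {hi} uA/cm^2 does not propagate; "
            "cannot bisect for the diastolic threshold"
        )
    if lo > 0 and propagates(lo):
        raise RuntimeError(f"lower bracket amplitude {lo} already propagates")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if propagates(mid):
            hi = mid
        else:
            lo = mid
    return ThresholdResult(threshold=hi, tolerance=tol, history=history)
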