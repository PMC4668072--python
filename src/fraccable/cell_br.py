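"""Beeler–Reuter (1977) ventricular ionic model.

The model describes the transmembrane potential ``v`` of a ventricular
myocardial cell together with seven secondary variables: six Hodgkin–Huxley
gating variables (m, h, j for the fast sodium current; d, f for the slow
inward current; x1 for the time-activated outward current) and a scaled
intracellular calcium concentration.

Every gate ``y`` obeys ``dy/dt = alpha_y(v) * (1 - y) - beta_y(v) * y`` with
rate functions of the common Beeler–Reuter form

    rate(v) = (C1 * exp(C2 * (v + C3)) + C4 * (v + C5))
              / (exp(C6 * (v + C3)) + C7)

in ms^-1.  The calcium concentration is stored scaled by 1e-7 mol/l so that
its resting value is 1; its dynamics are nonlinear because the slow-inward
reversal potential depends logarithmically on calcium.

The per-step updates used inside the operator-splitting scheme live here as
well: the unconditionally stable backward-differentiation update for the six
linear gate equations and a frozen-Jacobian Newton iteration for the implicit
Euler step of the calcium equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "GATE_NAMES",
    "BRParameters",
    "CellState",
    "CalciumConvergenceError",
    "gate_rates",
    "gate_steady_states",
    "ionic_currents",
    "ionic_current",
    "update_gates",
    "update_calcium",
    "resting_state",
    "simulate_cell",
]

GATE_NAMES = ("m", "h", "j", "d", "f", "x1")

#: Rate-function coefficients C1..C7, two rows (alpha, beta) per gate in
#: GATE_NAMES order.  Transcribed from Beeler & Reuter (1977), Table 1.
_DEFAULT_RATE_TABLE = np.array(
    [
        # C1      C2      C3     C4    C5    C6      C7
        [0.0, 0.0, 47.0, -1.0, 47.0, -0.1, -1.0],      # alpha_m
        [40.0, -0.056, 72.0, 0.0, 0.0, 0.0, 0.0],      # beta_m
        [0.126, -0.25, 77.0, 0.0, 0.0, 0.0, 0.0],      # alpha_h
        [1.7, 0.0, 22.5, 0.0, 0.0, -0.082, 1.0],       # beta_h
        [0.055, -0.25, 78.0, 0.0, 0.0, -0.2, 1.0],     # alpha_j
        [0.3, 0.0, 32.0, 0.0, 0.0, -0.1, 1.0],         # beta_j
        [0.095, -0.01, -5.0, 0.0, 0.0, -0.072, 1.0],   # alpha_d
        [0.07, -0.017, 44.0, 0.0, 0.0, 0.05, 1.0],     # beta_d
        [0.012, -0.008, 28.0, 0.0, 0.0, 0.15, 1.0],    # alpha_f
        [0.0065, -0.02, 30.0, 0.0, 0.0, -0.2, 1.0],    # beta_f
        [0.0005, 0.083, 50.0, 0.0, 0.0, 0.057, 1.0],   # alpha_x1
        [0.0013, -0.06, 20.0, 0.0, 0.0, -0.04, 1.0],   # beta_x1
    ]
)

_SINGULARITY_EPS = 1e-9


class CalciumConvergenceError(RuntimeError):
    """Frozen-Jacobian Newton iteration for calcium failed to converge."""

    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"calcium update did not converge after {iterations} iterations "
            f"(max |residual| = {residual:.3e})"
        )


@dataclass(frozen=True)
class BRParameters:
    """Constants of the Beeler–Reuter model.

    Defaults reproduce Beeler & Reuter (1977).  Conductances are in
    mS/cm^2, potentials in mV, rates in ms^-1.  ``ca_scale`` converts the
    stored dimensionless calcium (resting value 1) to mol/l inside the
    reversal-potential formula.
    """

    rate_table: np.ndarray = field(
        default_factory=lambda: _DEFAULT_RATE_TABLE.copy()
    )
    g_na: float = 4.0        # fast sodium conductance
    g_nac: float = 0.003     # background sodium conductance
    e_na: float = 50.0       # sodium reversal potential
    g_s: float = 0.09        # slow inward (calcium) conductance
    g_x1: float = 0.8        # scale of the time-activated outward current
    g_k1: float = 0.35       # scale of the time-independent potassium current
    ca_uptake: float = 0.07  # calcium re-uptake rate (ms^-1)
    ca_scale: float = 1e-7   # mol/l per unit of stored scaled calcium
    es_offset: float = -82.3     # slow-inward reversal: offset (mV)
    es_slope: float = -13.0287   # slow-inward reversal: log-slope (mV)
    ca_newton_tol: float = 1e-10
    ca_newton_maxit: int = 50

    def __post_init__(self):
        table = np.asarray(self.rate_table, dtype=float)
        if table.shape != (12, 7):
            raise ValueError("rate_table must have shape (12, 7)")
        object.__setattr__(self, "rate_table", table)

    # -- flat key/value serialisation -------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for g, name in enumerate(GATE_NAMES):
            for r, kind in enumerate(("alpha", "beta")):
                row = self.rate_table[2 * g + r]
                for c in range(7):
                    out[f"rate_{kind}_{name}_C{c + 1}"] = float(row[c])
        for key in (
            "g_na", "g_nac", "e_na", "g_s", "g_x1", "g_k1",
            "ca_uptake", "ca_scale", "es_offset", "es_slope",
            "ca_newton_tol", "ca_newton_maxit",
        ):
            out[key] = getattr(self, key)
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "BRParameters":
        data = dict(data)
        table = _DEFAULT_RATE_TABLE.copy()
        for g, name in enumerate(GATE_NAMES):
            for r, kind in enumerate(("alpha", "beta")):
                for c in range(7):
                    key = f"rate_{kind}_{name}_C{c + 1}"
                    if key in data:
                        table[2 * g + r, c] = float(data.pop(key))
        kwargs = {"rate_table": table}
        for key, value in data.items():
            if key == "ca_newton_maxit":
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass
class CellState:
    """State of one cell (scalars) or of a whole fibre (equal-shape arrays)."""

    v: np.ndarray | float
    m: np.ndarray | float
    h: np.ndarray | float
    j: np.ndarray | float
    d: np.ndarray | float
    f: np.ndarray | float
    x1: np.ndarray | float
    ca: np.ndarray | float

    @classmethod
    def resting_initial(cls, shape=None) -> "CellState":
        """The conventional initial condition: v = -85 mV, gates
        [0, 1, 1, 0, 1, 0], scaled calcium 1."""
        vals = dict(v=-85.0, m=0.0, h=1.0, j=1.0, d=0.0, f=1.0, x1=0.0, ca=1.0)
        if shape is not None:
            vals = {k: np.full(shape, x) for k, x in vals.items()}
        return cls(**vals)

    def gates(self):
        return (self.m, self.h, self.j, self.d, self.f, self.x1)

    def copy(self) -> "CellState":
        def _c(x):
            return np.array(x, dtype=float, copy=True) if np.ndim(x) else float(x)
        return CellState(*(_c(getattr(self, k))
                           for k in ("v", "m", "h", "j", "d", "f", "x1", "ca")))


def _rate(v, coeffs):
    """One Beeler–Reuter rate function, with the removable singularity of the
    C4*(v+C5)/(exp(C6*(v+C3)) + C7) form replaced by its analytic limit."""
    c1, c2, c3, c4, c5, c6, c7 = coeffs
    dv = v + c3
    num = c1 * np.exp(c2 * dv) + c4 * (v + c5)
    den = np.exp(c6 * dv) + c7
    small = np.abs(den) < _SINGULARITY_EPS
    if np.any(small):
        # L'Hopital at the zero of the denominator (numerator vanishes there
        # too for the BR coefficient sets that can reach it).
        lim = (c1 * c2 * np.exp(c2 * dv) + c4) / (c6 * np.exp(c6 * dv))
        return np.where(small, lim, num / np.where(small, 1.0, den))
    return num / den


def gate_rates(v, params: BRParameters | None = None):
    """Opening/closing rates (alpha_y, beta_y) for the six gates at voltage
    ``v`` (mV), each in ms^-1.

    Returns two arrays of shape ``(6,) + shape(v)`` in GATE_NAMES order.
    """
    p = params or _DEFAULT_PARAMS
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("non-finite membrane potential passed to gate_rates")
    alphas = np.stack([_rate(v, p.rate_table[2 * g]) for g in range(6)])
    betas = np.stack([_rate(v, p.rate_table[2 * g + 1]) for g in range(6)])
    return alphas, betas


def gate_steady_states(v, params: BRParameters | None = None):
    """Voltage-dependent gate steady states y_inf = alpha / (alpha + beta)."""
    a, b = gate_rates(v, params)
    return a / (a + b)


def ionic_currents(s: CellState, params: BRParameters | None = None):
    """The four Beeler–Reuter membrane currents (uA/cm^2) at state ``s``.

    Returns ``(i_na, i_s, i_x1, i_k1)``; outward currents are positive.
    """
    p = params or _DEFAULT_PARAMS
    v = np.asarray(s.v, dtype=float)
    i_na = (p.g_na * s.m ** 3 * s.h * s.j + p.g_nac) * (v - p.e_na)
    e_s = p.es_offset + p.es_slope * np.log(p.ca_scale * s.ca)
    i_s = p.g_s * s.d * s.f * (v - e_s)
    i_x1 = s.x1 * p.g_x1 * (np.exp(0.04 * (v + 77.0)) - 1.0) / np.exp(0.04 * (v + 35.0))
    # time-independent potassium current; its second term has a removable
    # singularity at v = -23 mV
    t1 = 4.0 * (np.exp(0.04 * (v + 85.0)) - 1.0) / (
        np.exp(0.08 * (v + 53.0)) + np.exp(0.04 * (v + 53.0))
    )
    den = 1.0 - np.exp(-0.04 * (v + 23.0))
    small = np.abs(den) < _SINGULARITY_EPS
    t2 = np.where(
        small,
        0.2 / 0.04,
        0.2 * (v + 23.0) / np.where(small, 1.0, den),
    )
    i_k1 = p.g_k1 * (t1 + t2)
    return i_na, i_s, i_x1, i_k1


def ionic_current(s: CellState, params: BRParameters | None = None):
    """Total membrane ionic current (uA/cm^2), outward positive."""
    i_na, i_s, i_x1, i_k1 = ionic_currents(s, params)
    return i_na + i_s + i_x1 + i_k1


def update_gates(s: CellState, v_new, dt: float,
                 params: BRParameters | None = None) -> CellState:
    """Implicit (backward-differentiation) update of the six gates at the new
    voltage, ``y_new = (y + dt * alpha) / (1 + dt * (alpha + beta))``.

    The gate equations are linear in the gate, so this is the exact implicit
    Euler solution and is unconditionally stable; it maps [0, 1] into [0, 1]
    for every dt >= 0.  Returns a new state carrying ``v_new``; calcium is
    left untouched.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    a, b = gate_rates(v_new, params)
    new = {}
    for i, name in enumerate(GATE_NAMES):
        y = getattr(s, name)
        new[name] = (y + dt * a[i]) / (1.0 + dt * (a[i] + b[i]))
    return CellState(v=v_new, ca=s.ca, **new)


def update_calcium(s: CellState, v_new, dt: float,
                   params: BRParameters | None = None):
    """Implicit Euler step of the scaled-calcium equation
    ``dc/dt = -i_s(v, d, f, c) + ca_uptake * (1 - c)`` solved by a Newton
    iteration whose Jacobian is frozen at the first iterate.

    Uses the gate values stored in ``s`` (i.e. the already-updated d and f in
    the splitting scheme).  Returns the new scaled calcium; raises
    :class:`CalciumConvergenceError` if the residual tolerance is not met.
    """
    p = params or _DEFAULT_PARAMS
    if dt < 0:
        raise ValueError("dt must be non-negative")
    c0 = np.asarray(s.ca, dtype=float)
    if dt == 0.0:
        return c0.copy() if c0.ndim else float(c0)
    v = np.asarray(v_new, dtype=float)
    gdf = p.g_s * np.asarray(s.d) * np.asarray(s.f)
    k = p.ca_uptake

    def residual(c):
        e_s = p.es_offset + p.es_slope * np.log(p.ca_scale * c)
        rhs = -gdf * (v - e_s) + k * (1.0 - c)
        return c - c0 - dt * rhs

    # dR/dc = es_slope * gdf / c - k  (es_slope < 0, so dR/dc < 0)
    jac = 1.0 - dt * (p.es_slope * gdf / c0 - k)
    c = c0.copy() if c0.ndim else np.array(c0, dtype=float)
    for it in range(p.ca_newton_maxit):
        r = residual(c)
        if np.max(np.abs(r)) < p.ca_newton_tol:
            break
        c = np.maximum(c - r / jac, 1e-12)
    else:
        raise CalciumConvergenceError(float(np.max(np.abs(residual(c)))),
                                      p.ca_newton_maxit)
    return c if c0.ndim else float(c)


def resting_state(params: BRParameters | None = None,
                  settle_ms: float = 3000.0, dt: float = 0.05) -> CellState:
    """Settle an unstimulated cell from the conventional initial condition to
    its resting fixed point (a free run; no root finding)."""
    s = CellState.resting_initial()
    nsteps = int(round(settle_ms / dt))
    p = params or _DEFAULT_PARAMS
    for _ in range(nsteps):
        v_new = s.v - dt * ionic_current(s, p)  # Cm = 1 uF/cm^2
        s = update_gates(s, v_new, dt, p)
        s = replace(s, ca=update_calcium(s, v_new, dt, p))
    return s


def simulate_cell(params: BRParameters | None = None, *, dt: float = 0.01,
                  t_final: float = 500.0, stim_start: float = 10.0,
                  stim_duration: float = 2.0, stim_amplitude: float = 40.0,
                  cm: float = 1.0, initial: CellState | None = None):
    """Space-clamped (0-D) simulation with the same splitting as the fibre
    solver: explicit reaction step for v, then implicit gate and calcium
    updates at the new voltage.

    The stimulus (uA/cm^2) is applied on the half-open window
    [stim_start, stim_start + stim_duration).  Returns ``(t, v, states)``
    where ``states`` is the final :class:`CellState`.
    """
    p = params or _DEFAULT_PARAMS
    s = (initial or CellState.resting_initial()).copy()
    nsteps = int(round(t_final / dt))
    t = np.arange(nsteps + 1) * dt
    v_out = np.empty(nsteps + 1)
    v_out[0] = s.v
    for kstep in range(nsteps):
        tk = kstep * dt
        istim = stim_amplitude if stim_start <= tk < stim_start + stim_duration else 0.0
        g = (-ionic_current(s, p) + istim) / cm
        v_new = s.v + dt * g
        s = update_gates(s, v_new, dt, p)
        s = replace(s, ca=update_calcium(s, v_new, dt, p))
        v_out[kstep + 1] = s.v
    return t, v_out, s


_DEFAULT_PARAMS = BRParameters()
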