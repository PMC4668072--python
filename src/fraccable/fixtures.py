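"""Synthetic inputs with closed-form properties, for tests and examples.

Three kinds are provided:

* ``single_mode`` — a grid field proportional to one cosine eigenfunction,
  whose evolution under the reaction-free scheme is an exact geometric decay;
* ``triangle_ap`` — a piecewise-linear rest/rise/fall pulse whose activation
  time and APDs follow from the triangle geometry;
* ``br_morphology`` — a stylised spike-notch-dome trace with planted feature
  values for exercising the morphology detector.
"""

from __future__ import annotations

import numpy as np

from .solver import VoltageTrace
from .spectral import SpectralOperator, build_operator

__all__ = ["make_fixture", "single_mode_field", "triangle_ap", "br_morphology_trace"]


def single_mode_field(op: SpectralOperator, j: int, amplitude: float = 1.0) -> np.ndarray:
    """``amplitude * phi_j`` sampled on the operator's grid."""
    if not (0 <= j <= op.N):
        raise ValueError(f"mode index must lie in [0, N] = [0, {op.N}]")
    return amplitude * op.normalizers[j] * np.cos(j * np.pi * op.x / op.L)


def _sample_piecewise(knot_t, knot_v, dt, t_final):
    n = int(round(t_final / dt))
    t = np.arange(n + 1) * dt
    return t, np.interp(t, knot_t, knot_v)


def triangle_ap(rest: float = -85.0, peak: float = 30.0, rise: float = 2.0,
                fall: float = 200.0, t_stim: float = 10.0, dt: float = 0.01,
                t_final: float = 400.0) -> VoltageTrace:
    """Rest until ``t_stim``, linear rise to ``peak`` over ``rise`` ms,
    linear fall back to rest over ``fall`` ms.

    Closed forms: activation at ``t_stim + 0.1 * rise``; the downward
    crossing of fraction f of repolarization occurs at
    ``t_stim + rise + f * fall``.
    """
    knot_t = [0.0, t_stim, t_stim + rise, t_stim + rise + fall]
    knot_v = [rest, rest, peak, rest]
    t, v = _sample_piecewise(knot_t, knot_v, dt, t_final)
    return VoltageTrace(x=0.0, dt=dt, v=v, stim_start=t_stim,
                        meta={"fixture": "triangle_ap"})


def br_morphology_trace(rest: float = -85.0, peak: float = 30.0,
                        notch: float = 5.0, dome: float = 20.0,
                        t_stim: float = 10.0, dt: float = 0.01,
                        t_final: float = 400.0) -> VoltageTrace:
    """Stylised ventricular AP: 1 ms upstroke to ``peak``, decline to the
    ``notch`` minimum at +15 ms, recovery to the ``dome`` maximum at +45 ms,
    then linear repolarization to rest at +280 ms.  All breakpoints lie on
    whole samples so the planted extrema are recovered exactly."""
    t_up = t_stim + 1.0
    knot_t = [0.0, t_stim, t_up, t_up + 14.0, t_up + 44.0, t_up + 279.0]
    knot_v = [rest, rest, peak, notch, dome, rest]
    t, v = _sample_piecewise(knot_t, knot_v, dt, t_final)
    return VoltageTrace(x=0.0, dt=dt, v=v, stim_start=t_stim,
                        meta={"fixture": "br_morphology"})


def make_fixture(kind: str, **params):
    """Dispatch by kind: ``single_mode`` (needs ``L``, ``N``, ``j`` or an
    ``op``), ``triangle_ap`` or ``br_morphology``."""
    if kind == "single_mode":
        op = params.pop("op", None)
        if op is None:
            op = build_operator(params.pop("L", 1.0), params.pop("N", 64),
                                params.pop("alpha", 2.0))
        return single_mode_field(op, **params)
    if kind == "triangle_ap":
        return triangle_ap(**params)
    if kind == "br_morphology":
        return br_morphology_trace(**params)
    raise ValueError(f"unknown fixture kind {kind!r}")
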