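"""Action-potential biomarkers extracted from voltage traces.

Definitions used throughout:

* resting potential: the trace value immediately before stimulus onset
  (the settled pre-stimulus state), or the first sample when no stimulus
  metadata is present;
* activation time: first time the voltage reaches 10% of full depolarization
  (rest to trace maximum), linearly interpolated between samples;
* APD50 / APD90: time from activation to the first post-peak downward
  crossing of the 50% / 90% repolarization level, linearly interpolated;
* conduction velocity: distance between two nodes over the difference of
  their activation times, in cm/s;
* notch / dome: first local minimum after the depolarization peak and the
  subsequent local maximum, searched within 100 ms of activation (ties
  broken by the earliest sample) — reported as absent when the trace is a
  monotone single hump;
* AP foot width: time from 1% to 50% of full depolarization on the upstroke
  (a repo-defined operationalisation of the foot; its value is meaningful in
  comparisons across alpha rather than in absolute terms);
* APD dispersion: APD90 at a node minus the maximum APD90 over the profile
  (non-positive by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solver import VoltageTrace

__all__ = [
    "APBiomarkers",
    "DispersionProfile",
    "NoActivationError",
    "UnrepolarizedError",
    "resting_potential",
    "activation_time",
    "apd",
    "conduction_velocity",
    "ap_features",
    "extract_biomarkers",
    "apd_dispersion",
]

#: window after activation searched for the notch/dome pair (ms)
FEATURE_WINDOW = 100.0


class NoActivationError(ValueError):
    """The trace does not contain an action potential."""


class UnrepolarizedError(ValueError):
    """The trace does not repolarize to the requested level before it ends."""


@dataclass
class APBiomarkers:
    activation_time: float
    apd50: float
    apd90: float
    peak_v: float
    notch_v: float | None
    dome_v: float | None
    foot_width: float
    resting_v: float


@dataclass
class DispersionProfile:
    x: np.ndarray            # node coordinates (cm)
    apd90: np.ndarray        # per node (ms)
    dispersion: np.ndarray   # apd90 - max(apd90), <= 0 (ms)


def resting_potential(trace: VoltageTrace) -> float:
    """Trace value at the last sample not later than stimulus onset."""
    if trace.stim_start is None:
        return float(trace.v[0])
    i = int(np.searchsorted(trace.t, trace.stim_start + 1e-12, side="right")) - 1
    i = max(i, 0)
    return float(trace.v[i])


def _first_upward_crossing(t, v, level, start=0):
    """Linearly interpolated time of the first crossing v >= level at or
    after sample ``start``; None if it never crosses."""
    idx = np.flatnonzero(v[start:] >= level)
    if idx.size == 0:
        return None
    i = start + int(idx[0])
    if i == 0 or v[i - 1] >= level:
        return float(t[i])
    frac = (level - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def activation_time(trace: VoltageTrace, min_depolarization: float = 1.0) -> float:
    """First time the voltage reaches 10% of its full depolarization.

    Full depolarization is the excursion from the resting potential to the
    trace maximum.  Raises :class:`NoActivationError` when the excursion is
    below ``min_depolarization`` (mV) or the level is never crossed.
    """
    rest = resting_potential(trace)
    vmax = float(np.max(trace.v))
    if vmax - rest < min_depolarization:
        raise NoActivationError(
            f"trace at x={trace.x} never depolarizes (max excursion "
            f"{vmax - rest:.3g} mV)"
        )
    level = rest + 0.10 * (vmax - rest)
    at = _first_upward_crossing(trace.t, trace.v, level)
    if at is None:  # pragma: no cover - vmax >= level guarantees a crossing
        raise NoActivationError(f"no activation found at x={trace.x}")
    return at


def apd(trace: VoltageTrace, fraction: float = 0.9,
        min_depolarization: float = 1.0) -> float:
    """Action-potential duration at the given repolarization fraction.

    Measured from activation to the first post-peak downward crossing of
    ``rest + (1 - fraction) * (vmax - rest)``, linearly interpolated.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    at = activation_time(trace, min_depolarization)
    rest = resting_potential(trace)
    v = trace.v
    t = trace.t
    ipk = int(np.argmax(v))
    level = rest + (1.0 - fraction) * (float(v[ipk]) - rest)
    below = np.flatnonzero(v[ipk:] < level)
    if below.size == 0:
        raise UnrepolarizedError(
            f"trace at x={trace.x} does not reach {fraction:.0%} "
            "repolarization before it ends"
        )
    i = ipk + int(below[0])
    frac = (v[i - 1] - level) / (v[i - 1] - v[i])
    t_cross = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return t_cross - at


def conduction_velocity(trace_a: VoltageTrace, trace_b: VoltageTrace) -> float:
    """|x_b - x_a| / |AT_b - AT_a| in cm/s (coordinates cm, times ms)."""
    if trace_a.x == trace_b.x:
        raise ValueError("traces must come from distinct coordinates")
    at_a = activation_time(trace_a)
    at_b = activation_time(trace_b)
    if at_a == at_b:
        raise ValueError("equal activation times; conduction velocity undefined")
    return abs(trace_b.x - trace_a.x) / abs(at_b - at_a) * 1000.0


def _local_extrema(seg: np.ndarray):
    """Indices of strict-from-the-left local minima and maxima of ``seg``
    (ties resolved to the earliest sample)."""
    d = np.diff(seg)
    mins = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0)) + 1
    maxs = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
    return mins, maxs


def ap_features(trace: VoltageTrace, min_depolarization: float = 1.0):
    """Morphology features: ``(peak_v, notch_v, dome_v, foot_width)``.

    ``notch_v``/``dome_v`` are None when the AP lacks the spike-notch-dome
    shape (e.g. a monotone single hump).
    """
    at = activation_time(trace, min_depolarization)
    rest = resting_potential(trace)
    t = trace.t
    v = trace.v
    iwin = np.flatnonzero((t >= at) & (t <= at + FEATURE_WINDOW))
    win = v[iwin]
    mins, maxs = _local_extrema(win)
    # depolarization peak: the upstroke spike, i.e. the first local maximum
    # after activation (the window-global maximum can be the dome instead)
    ipk_local = int(maxs[0]) if maxs.size else int(np.argmax(win))
    peak_v = float(win[ipk_local])

    notch_v = dome_v = None
    seg = win[ipk_local:]
    mins, _ = _local_extrema(seg)
    if mins.size:
        inotch = int(mins[0])
        notch_v = float(seg[inotch])
        # dome: highest point of the plateau after the notch (taking the
        # first local max instead would latch onto sub-mV wiggles)
        if inotch + 1 < len(seg):
            cand = float(np.max(seg[inotch + 1:]))
            if cand > notch_v:
                dome_v = cand

    vmax = float(np.max(v))
    t01 = _first_upward_crossing(t, v, rest + 0.01 * (vmax - rest))
    t50 = _first_upward_crossing(t, v, rest + 0.50 * (vmax - rest))
    foot_width = float(t50 - t01)
    return peak_v, notch_v, dome_v, foot_width


def extract_biomarkers(trace: VoltageTrace,
                       min_depolarization: float = 1.0) -> APBiomarkers:
    """All biomarkers of one trace in a single pass."""
    peak_v, notch_v, dome_v, foot_width = ap_features(trace, min_depolarization)
    return APBiomarkers(
        activation_time=activation_time(trace, min_depolarization),
        apd50=apd(trace, 0.5, min_depolarization),
        apd90=apd(trace, 0.9, min_depolarization),
        peak_v=peak_v,
        notch_v=notch_v,
        dome_v=dome_v,
        foot_width=foot_width,
        resting_v=resting_potential(trace),
    )


def apd_dispersion(x, apd90) -> DispersionProfile:
    """Spatial APD dispersion: APD90 minus its maximum over the profile."""
    x = np.asarray(x, dtype=float)
    a = np.asarray(apd90, dtype=float)
    if x.shape != a.shape or x.size < 2:
        raise ValueError("need matching coordinate/APD arrays with >= 2 nodes")
    return DispersionProfile(x=x, apd90=a, dispersion=a - a.max())
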