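"""The computational experiments of the study: grid/time-step convergence,
the alpha sweep with curve fitting, and the reduced-alpha versus
reduced-conductivity comparison.

Everything here is deterministic: each experiment is a pure function of its
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .biomarkers import (
    apd,
    apd_dispersion,
    activation_time,
    conduction_velocity,
    ap_features,
    DispersionProfile,
)
from .solver import ModelConfig, SimulationResult, VoltageTrace, simulate

__all__ = [
    "ConvergenceReport",
    "FitResult",
    "SweepResult",
    "MatchedCVResult",
    "rel_norm_full",
    "convergence_study",
    "alpha_sweep",
    "fit",
    "matched_cv_comparison",
    "DEFAULT_SWEEP_ALPHAS",
    "DEFAULT_CONVERGENCE_ALPHAS",
    "profile_coordinates",
]

#: ten alpha values spanning (1, 2] used by the sweep experiments
DEFAULT_SWEEP_ALPHAS = tuple(np.round(np.arange(1.1, 2.01, 0.1), 10))
#: four alpha values used by the convergence studies
DEFAULT_CONVERGENCE_ALPHAS = (1.25, 1.5, 1.75, 2.0)

P1, P2, P3 = 0.25, 0.5, 0.75


def profile_coordinates(n: int = 48, lo: float = 0.06, hi: float = 1.0) -> np.ndarray:
    """Equally spaced profile nodes, excluding the stimulus neighbourhood."""
    return np.linspace(lo, hi, n)


def rel_norm_full(trace: VoltageTrace, ref: VoltageTrace) -> float:
    """Relative Euclidean norm ||v - v_ref||_2 / ||v_ref||_2 of the temporal
    profile at one node, on the coarsest common time grid.

    The reference time step must equal the trace's or divide it evenly; the
    reference is then subsampled onto the coarse grid.
    """
    v = trace.v
    vr = ref.v
    if abs(trace.dt - ref.dt) > 1e-12:
        stride = trace.dt / ref.dt
        if abs(stride - round(stride)) > 1e-9 or stride < 1:
            raise ValueError(
                f"incommensurate time steps {trace.dt} and {ref.dt}"
            )
        vr = vr[:: int(round(stride))]
    n = min(len(v), len(vr))
    denom = float(np.linalg.norm(vr[:n]))
    if denom == 0.0:
        raise ValueError("reference trace has zero norm")
    return float(np.linalg.norm(v[:n] - vr[:n]) / denom)


@dataclass
class ConvergenceReport:
    """Four relative error metrics along a refinement ladder of N or dt."""

    key: str                     # "N" or "dt"
    reference: float             # the reference rung (largest N / smallest dt)
    node: float                  # coordinate for norm and APD metrics
    cv_nodes: tuple              # coordinate pair for the CV metric
    table: pd.DataFrame          # columns: alpha, value, rel_norm_full,
                                 # rel_apd50, rel_apd90, rel_cv


def _run_metrics(res: SimulationResult, node: float, cv_nodes: tuple):
    tr = res.traces[node]
    a, b = (res.traces[c] for c in cv_nodes)
    return {
        "trace": tr,
        "apd50": apd(tr, 0.5),
        "apd90": apd(tr, 0.9),
        "cv": conduction_velocity(a, b),
    }


def convergence_study(base_cfg: ModelConfig, key: str,
                      ladder: Sequence[float],
                      alphas: Sequence[float] = DEFAULT_CONVERGENCE_ALPHAS,
                      node: float = P2,
                      cv_nodes: tuple = (P1, P3)) -> ConvergenceReport:
    """Refine N or dt along ``ladder`` and compare each rung against the
    ladder's own reference solution (largest N, or smallest dt) through the
    four relative metrics: trace norm at ``node``, APD50 and APD90 at
    ``node``, and conduction velocity between ``cv_nodes``.
    """
    if key not in ("N", "dt"):
        raise ValueError("key must be 'N' or 'dt'")
    ladder = sorted(set(float(q) for q in ladder))
    ref_value = ladder[-1] if key == "N" else ladder[0]
    record = tuple(sorted({node, *cv_nodes}))
    rows = []
    for alpha in alphas:
        if key == "N":
            ref_cfg = replace(base_cfg, alpha=alpha, N=int(ref_value),
                              record=record)
        else:
            ref_cfg = replace(base_cfg, alpha=alpha, dt=ref_value,
                              record=record)
        ref = _run_metrics(simulate(ref_cfg), node, cv_nodes)
        for q in ladder:
            if q == ref_value:
                rows.append({"alpha": alpha, key: q, "rel_norm_full": 0.0,
                             "rel_apd50": 0.0, "rel_apd90": 0.0, "rel_cv": 0.0})
                continue
            cfg = replace(ref_cfg, **({"N": int(q)} if key == "N" else {"dt": q}))
            cur = _run_metrics(simulate(cfg), node, cv_nodes)
            rows.append({
                "alpha": alpha,
                key: q,
                "rel_norm_full": rel_norm_full(cur["trace"], ref["trace"]),
                "rel_apd50": abs(cur["apd50"] - ref["apd50"]) / ref["apd50"],
                "rel_apd90": abs(cur["apd90"] - ref["apd90"]) / ref["apd90"],
                "rel_cv": abs(cur["cv"] - ref["cv"]) / ref["cv"],
            })
    return ConvergenceReport(key=key, reference=ref_value, node=node,
                             cv_nodes=cv_nodes,
                             table=pd.DataFrame(rows))


@dataclass
class SweepResult:
    """Biomarkers as functions of the fractional order."""

    table: pd.DataFrame      # one row per alpha
    profiles: dict           # alpha -> DataFrame(x, activation_time, apd90,
                             #                    dispersion)


def alpha_sweep(base_cfg: ModelConfig,
                alphas: Sequence[float] = DEFAULT_SWEEP_ALPHAS,
                profile_x: np.ndarray | None = None) -> SweepResult:
    """Simulate once per alpha and tabulate AP features at the midpoint,
    conduction velocity from P1/P3, activation times, and the APD90
    dispersion profile over ``profile_x`` (default: forty-eight equally
    spaced nodes in [0.06, L])."""
    if profile_x is None:
        profile_x = profile_coordinates(hi=base_cfg.L)
    probes = (P1, P2, P3)
    record = tuple(sorted({*probes, *(float(x) for x in profile_x)}))
    rows = []
    profiles = {}
    for alpha in alphas:
        cfg = replace(base_cfg, alpha=alpha, record=record)
        res = simulate(cfg)
        tr2 = res.traces[P2]
        peak_v, notch_v, dome_v, foot_width = ap_features(tr2)
        apd90s = np.array([apd(res.traces[float(x)], 0.9) for x in profile_x])
        ats = np.array([activation_time(res.traces[float(x)])
                        for x in profile_x])
        disp = apd_dispersion(profile_x, apd90s)
        profiles[float(alpha)] = pd.DataFrame({
            "x": profile_x, "activation_time": ats,
            "apd90": apd90s, "dispersion": disp.dispersion,
        })
        rows.append({
            "alpha": float(alpha),
            "peak_v": peak_v, "notch_v": notch_v, "dome_v": dome_v,
            "foot_width": foot_width,
            "cv": conduction_velocity(res.traces[P1], res.traces[P3]),
            "at_p1": activation_time(res.traces[P1]),
            "at_p2": activation_time(res.traces[P2]),
            "at_p3": activation_time(res.traces[P3]),
            "apd50_p2": apd(tr2, 0.5),
            "apd90_p2": apd(tr2, 0.9),
            "min_dispersion": float(disp.dispersion.min()),
        })
    return SweepResult(table=pd.DataFrame(rows), profiles=profiles)


@dataclass
class FitResult:
    """A least-squares fit of biomarker-versus-alpha data."""

    model: str               # "linear", "quadratic" or "power_law"
    names: tuple             # coefficient names
    params: np.ndarray
    stderr: np.ndarray
    ci_low: np.ndarray       # 95% confidence bounds (linearised covariance)
    ci_high: np.ndarray
    r2: float
    residuals: np.ndarray

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.model == "linear":
            return p[0] * x + p[1]
        if self.model == "quadratic":
            return p[0] * x**2 + p[1] * x + p[2]
        return p[0] * x ** p[1] + p[2]


def _finish_fit(model, names, params, jac, ys, resid):
    dof = max(len(ys) - len(params), 1)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    s2 = ss_res / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        stderr = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        stderr = np.full(len(params), np.nan)
    tval = stats.t.ppf(0.975, dof)
    return FitResult(model=model, names=names, params=params, stderr=stderr,
                     ci_low=params - tval * stderr,
                     ci_high=params + tval * stderr,
                     r2=r2, residuals=resid)


def fit(model: str, xs, ys) -> FitResult:
    """Fit one of the three model families to (alpha, biomarker) data:
    ``a*x + b`` (linear), ``a*x^2 + b*x + c`` (quadratic) or the power law
    ``a*x^b + c``.  Reports coefficients with 95% confidence bounds from the
    linearised covariance at the optimum, R^2 and residuals.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if model == "linear":
        names = ("a", "b")
        jac = np.column_stack([xs, np.ones_like(xs)])
    elif model == "quadratic":
        names = ("a", "b", "c")
        jac = np.column_stack([xs**2, xs, np.ones_like(xs)])
    elif model == "power_law":
        names = ("a", "b", "c")
        if np.any(xs <= 0):
            raise ValueError("power-law fit requires positive x values")
    else:
        raise ValueError(f"unknown fit model {model!r}")
    if len(xs) < len(names):
        raise ValueError(f"{model} fit needs at least {len(names)} points")

    if model in ("linear", "quadratic"):
        params, *_ = np.linalg.lstsq(jac, ys, rcond=None)
        resid = ys - jac @ params
        return _finish_fit(model, names, params, jac, ys, resid)

    def residual(p):
        return p[0] * xs ** p[1] + p[2] - ys

    best = None
    scale = ys.max() - ys.min() or 1.0
    for b0 in (-3.0, -1.0, 0.5, 1.0, 2.0, 4.0):
        for sign in (1.0, -1.0):
            p0 = np.array([sign * scale, b0,
                           ys.min() if sign > 0 else ys.max()])
            try:
                sol = optimize.least_squares(residual, p0, xtol=1e-15,
                                             ftol=1e-15, gtol=1e-15,
                                             max_nfev=5000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not best.success and best.cost > 1e-12:
        raise RuntimeError("power-law fit did not converge from any start")
    p = best.x
    jac = np.column_stack([xs ** p[1],
                           p[0] * xs ** p[1] * np.log(xs),
                           np.ones_like(xs)])
    return _finish_fit(model, ("a", "b", "c"), p, jac, ys, residual(p))


@dataclass
class MatchedCVResult:
    """Side-by-side biomarkers of the fractional run and the standard run
    whose conductivity was reduced to match its conduction velocity."""

    fractional: dict     # {"config", "cv", "biomarkers": {x: APBiomarkers}}
    standard: dict


def _branch(cfg: ModelConfig) -> dict:
    from .biomarkers import extract_biomarkers

    res = simulate(cfg)
    return {
        "config": cfg,
        "cv": conduction_velocity(res.traces[P1], res.traces[P3]),
        "biomarkers": {c: extract_biomarkers(t) for c, t in res.traces.items()},
    }


def matched_cv_comparison(base_cfg: ModelConfig | None = None,
                          alpha_frac: float = 1.5, D_frac: float = 1.0,
                          D_std: float = 0.093) -> MatchedCVResult:
    """Compare the fractional fibre (alpha_frac, D_frac) with the standard
    fibre (alpha = 2) whose conductivity D_std is chosen to match the
    fractional conduction velocity."""
    base = base_cfg or ModelConfig()
    record = (P1, P2, P3)
    frac = _branch(replace(base, alpha=alpha_frac, D=D_frac, record=record))
    std = _branch(replace(base, alpha=2.0, D=D_std, record=record))
    return MatchedCVResult(fractional=frac, standard=std)
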