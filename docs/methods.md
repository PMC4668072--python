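# Methods

## Model and assumptions

The package solves the monodomain equation for the transmembrane potential
`v` on an insulated fibre [0, L], with the classical diffusion operator
replaced by the spectral fractional Laplacian of order `α ∈ (1, 2]`:

    Cm ∂v/∂t = −(D/χ) (−Δ)^{α/2} v − I_ion(v, z) + I_stim,
    dz/dt    = f(v, z).

Assumptions inherited from this formulation: one spatial dimension; a single
effective conductivity `D` (monodomain, not bidomain); zero-flux boundaries
encoded spectrally (the operator's eigenbasis is the Neumann cosine basis, so
constants are annihilated for every α — the fibre is electrically insulated
in the standard and fractional cases alike); and the restriction α > 1, the
range in which this definition of the operator on a finite interval is
backed by theory.  `α = 2` reduces to the classical cable model exactly.

The ionic model is Beeler–Reuter (1977), transcribed from the original
publication: eight states (v; gates m, h, j, d, f, x1; calcium), four
currents (i_Na with background leak, slow inward i_s with
`E_s = −82.3 − 13.0287 ln[Ca]`, time-activated outward i_x1, and the
time-independent potassium current i_K1).  Calcium is stored scaled by
10⁻⁷ mol/l so its resting value is 1, which turns its rate equation into
`dc/dt = −i_s + 0.07 (1 − c)`; the scaling constant re-enters only inside the
logarithm of `E_s`, so the dynamics are algebraically identical to the
original formulation.  All rate-function coefficients and conductances live
in `BRParameters` and are overridable (flat key/value config), but the
defaults are the 1977 constants verbatim.

## Units and the stimulus convention

Units throughout: mV, ms, cm, μF/cm², mS/cm, μA/cm².  The diffusion
coefficient entering the scheme is `D/(χ Cm)` ≈ 7.14·10⁻⁴ cm²/ms at the
defaults (`D = 1 mS/cm`, `χ = 1400 cm⁻¹`, `Cm = 1 μF/cm²`).

The stimulus amplitude is interpreted as a membrane current density
(μA/cm²) applied uniformly to the nodes of the stimulated subinterval; the
default protocol is 40 μA/cm² on [0, 0.05 cm] for 2 ms starting at
t = 10 ms, i.e. twice the diastolic threshold of the standard (α = 2) fibre
(~20 μA/cm², reproducible with `diastolic_threshold`).  A per-tissue-volume
current divided by `χ = 1400 cm⁻¹` would deliver ~0.03 μA/cm², three orders
of magnitude below what can depolarize a Beeler–Reuter membrane, so the
per-area convention is the only one under which the stated protocol excites
the fibre at all; it is therefore the package's documented convention.

The stimulus window is half-open, [t_on, t_on + duration), so refining dt
never changes the total injected charge; the stimulated region is closed,
x ≤ x̄.  Before the stimulus the fibre runs freely from the conventional
initial state (v = −85 mV, gates [0, 1, 1, 0, 1, 0], scaled calcium 1),
which is within ~0.5 mV of the model's true resting point; biomarker
baselines use the settled pre-stimulus value rather than −85 exactly.

## Discretisation

Space: N + 1 nodes `x_i = iL/N`; the eigenfunction expansion is truncated at
the first N + 1 modes.  Integral coefficients are approximated by the
trapezoidal rule, which on this grid is algebraically a type-I discrete
cosine transform (even reflection at both ends, period 2L); `scipy.fft.dct`
is the fast path, and the literal O(N²) quadrature/summation forms are kept
as test oracles.  Discrete orthogonality is exact for modes j < N; the
Nyquist mode j = N is retained with its literal trapezoid coefficients, for
which a forward-after-inverse round trip doubles that single mode.  For this
reason the solver carries the spectral coefficients of v between steps (one
forward transform of the reaction term and one inverse transform of the
voltage per step) instead of re-transforming the voltage each step — the
re-transforming variant amplifies the Nyquist mode and is unstable for small
dt, while the carried-coefficient form is unconditionally stable and is also
the form in which each coefficient "updates independently".

Time: uniform step dt with operator splitting per step,

1. reaction term `g = (−I_ion(v^k, z^k) + I_stim(t_k)) / Cm` evaluated
   nodewise, transformed, and every mode advanced by the diagonal
   semi-implicit factor
   `v̂_j^{k+1} = (v̂_j^k + dt ĝ_j) / (1 + dt · D/(χCm) · λ_j^{α/2})`
   (diffusion implicit, reaction explicit);
2. the six gate equations, linear in the gate, are advanced by the exact
   implicit-Euler expression `y ← (y + dt α_y(v^{k+1})) / (1 + dt (α_y + β_y))`,
   which maps [0, 1] into [0, 1] unconditionally;
3. the nonlinear calcium equation is advanced by implicit Euler solved with
   a Newton iteration whose Jacobian is frozen at the first iterate
   (absolute residual tolerance 10⁻¹⁰, at most 50 iterations, explicit-Euler
   predictor as the starting point; non-convergence raises with the residual).

The scheme is first order in time (verified by self-convergence) and its
reaction-free per-mode decay is exact, which the tests assert to machine
precision as the solver's primary oracle.

Two implementations of the inner loop exist: a vectorised numpy path (the
reference) and a numba-compiled per-node path used automatically when numba
is importable.  They implement the identical formulas; the suite asserts
trace agreement between them (tolerance 10⁻⁶ over hundreds of steps — the
only difference is the per-node versus whole-field stopping rule of the
calcium iteration, both below its 10⁻¹⁰ residual tolerance, plus
floating-point reassociation in the compiled path).

Numerical guards: the removable singularities of the rate formulas (e.g. the
m-gate activation at v = −47 mV, the i_K1 term at v = −23 mV) switch to
their analytic limits when the denominator is below 10⁻⁹; non-finite fields
abort the run with the time and node of the failure.

## Default problem sizes

Production configuration (all overridable): L = 1 cm, N = 400, dt = 0.01 ms,
500 ms horizon, probes P1/P2/P3 at x = 0.25/0.5/0.75 cm, recording every
step.  Reference solutions for the refinement studies use N = 3200 (space)
and dt = 6.25·10⁻⁴ ms (time); dt-refined comparisons subsample the reference
onto the coarse time grid.  Solver unit tests run on reduced fibres
(N ≈ 50–200, tens of ms) whose behaviour is qualitatively identical; the
end-to-end acceptance tests and `scripts/acceptance.py` use the production
sizes above.

## Biomarker definitions

* resting potential: trace value immediately before stimulus onset;
* activation time: first crossing of 10% of full depolarization (rest →
  trace maximum), linearly interpolated; traces whose excursion is below
  1 mV signal "no activation" (used by the threshold bisection);
* APD50/APD90: activation to the first post-peak downward crossing of the
  50%/90% repolarization level, linearly interpolated;
* conduction velocity: distance over activation-time difference between two
  probes (default P1 and P3), in cm/s;
* upstroke peak: the first local maximum after activation.  This is a
  deliberate choice: at the default parameters the dome can slightly exceed
  the upstroke spike (16.47 vs 15.36 mV at α = 2, a converged property of
  the model, not a discretisation artifact), so a window-global maximum
  would conflate the two features;
* notch: first local minimum after the upstroke peak within 100 ms of
  activation (ties to the earliest sample); dome: the maximum of the plateau
  after the notch (taking the first local maximum instead would latch onto
  sub-mV wiggles at coarse resolution).  Both are reported as absent for
  traces without the spike–notch–dome shape;
* AP foot width: time from 1% to 50% of full depolarization on the upstroke.
  The foot has no formulaic definition in the literature this reproduces —
  this is a repo-defined metric whose meaningful content is its monotone
  widening as α decreases, not its absolute value;
* APD dispersion: APD90 minus its spatial maximum over the profile nodes
  (48 equally spaced nodes in [0.06, 1] cm, excluding the stimulus
  neighbourhood), non-positive by construction.

## Experiments

* Refinement studies (`convergence_study`): four relative metrics (trace
  norm at P2, APD50, APD90 at P2, CV from P1/P3) along a ladder in N or dt
  against the ladder's own reference rung; default α set
  {1.25, 1.5, 1.75, 2.0} (the study this reproduces used four unspecified
  values; this reconstruction is a package default, overridable).  The
  dt ladder divides 0.01 ms dyadically down to 6.25·10⁻⁴ ms.
* α sweep (`alpha_sweep`): default set {1.1, 1.2, …, 2.0} (again a
  reconstruction; the original ten values are unlisted).  Sweeps run on a
  700 ms horizon: the slowest fibre (α = 1.1, CV ≈ 2.4 cm/s) only completes
  APD90 at x = 1 around t ≈ 660 ms, so the 500 ms default would leave its
  dispersion profile undefined.
* Curve fits (`fit`): linear and quadratic by linear least squares,
  `a·α^b + c` by `scipy.optimize.least_squares` from a small grid of starts;
  95% confidence bounds from the linearised covariance at the optimum
  (t-distribution, n − p degrees of freedom).  Noiseless model-generated
  data is recovered to 10⁻⁶ (nonlinear) / 10⁻¹⁰ (linear families).
* Matched-CV comparison (`matched_cv_comparison`): the fractional fibre
  (α = 1.5, D = 1) against the standard fibre with D = 0.093 mS/cm chosen to
  match its conduction velocity.
* Diastolic threshold: bisection on the stimulus amplitude over [0, 80]
  μA/cm² to 0.5 μA/cm² absolute tolerance; "propagation" means the probe at
  x = 0.75 L exceeds 0 mV.  The probe and tolerance are package choices (the
  source text states neither).

## Convergence behaviour at the production sizes

The acceptance script recomputes, from scratch, the α = 1.5 conduction
velocity at the production discretisation and the worst-case dt-refinement
errors over {1.25, 1.5, 1.75, 2.0}.  The CV error of the coarse time step
grows with α (largest in the classical limit) while the trace-norm error
grows as α decreases; APD errors sit two orders of magnitude below the CV
error because the first-order time-stepping bias shifts activation and
repolarization nearly equally, cancelling in their difference.  The measured
worst-case CV change is ≈1.2% and the worst-case APD change ≈0.011% —
slightly above the ≤1% / ≤0.01% figures quoted for the same experiment in
the source study (whose exact four α values are unknown; for sets capped at
α = 1.5 the measured errors satisfy both quotes).  The α = 1.5 CV itself
reproduces the study's printed 12.2903 cm/s to five significant digits,
which is the strongest available evidence that the scheme is equivalent.

## Synthetic fixtures: what they do and do not show

`single_mode` fields exercise the exact per-mode algebra of the scheme;
`triangle_ap` and `br_morphology` traces have closed-form biomarkers and
planted features for exercising the extractors.  They emulate idealised
noise-free morphologies sampled on uniform grids — they contain no
measurement noise, baseline wander, alternans or multi-beat dynamics, so
biomarker tests passing on them demonstrates correctness of the definitions,
not robustness to experimental recordings.  Likewise all simulations here
are deterministic solutions of one deterministic model: agreement with the
study's numbers validates the numerics, and says nothing about fidelity to
real cardiac tissue.

## Known limitations

One spatial dimension only; single-stimulus protocols (no pacing trains or
restitution); the Beeler–Reuter model only, behind a reaction interface that
would admit other cell models; first-order accuracy in time; fits are
unweighted least squares.  The Nyquist-mode treatment follows the literal
trapezoid construction, which is one of several defensible conventions for
the j = N mode.
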