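# Methods

This note records the numerical and design choices behind `sddestab`: the
model and its state space, how each quantity is computed, the tolerances
and problem sizes used, and the known limitations.

## Model and state space

The model couples an ODE for stem cells to a delay equation for mature
cells; the delay is a threshold delay defined through the backward
maturity ODE `y'(s) = −g(y(s), ψ(−s))`, `y(0) = x2`, with `τ` the time at
which `y` reaches `x1`.  States are pairs of history functions on
`[−h, 0]`.  The horizon `h` must strictly dominate every threshold delay
encountered; the theory defines `h` from non-constructive bounds on `g`,
so the package instead uses `h = 2 · max_v τ(v)` over constant histories
`v ∈ [0, v_max]` (default `v_max = 10`, configurable) and re-validates
`τ < h` on every threshold solve, raising a `HorizonError` otherwise.
Histories with genuinely negative mature-cell values are rejected rather
than clipped; values above `−1e−8` (interpolation roundoff) are clamped to
zero.

## Threshold delay: three routes

* **Adaptive ODE route** — `solve_ivp` (RK45, `rtol = atol = 1e−10`) with
  a terminal event at `y = x1`; the crossing is located on the dense
  output by Brent's method (event tolerance ~1e−12).
* **Integral route** (g independent of maturity) — `y` is the explicit
  integral of `g(ψ)`, and `τ` solves the scalar threshold condition
  `∫_{−τ}^0 g(ψ(θ))dθ = δ` by Brent's method on a 24-point Gauss–Legendre
  arc function.  When `g` is one constant, `τ = δ/g` directly.
* **Fixed-step route** — classical RK4 with all abscissae at fixed
  fractions of `h` (384 steps) and cubic-Hermite crossing location.  This
  route is *less* accurate per step than the adaptive one (~1e−10 vs
  1e−12) but is a smooth function of the history values.  That matters
  because the pseudospectral Jacobian is built by finite differences: the
  step-acceptance decisions of an adaptive solver change discontinuously
  under state perturbations of size 1e−7, which injects noise of order
  `solver_tol / step ≈ 1e−3` into the differentiated rows.  We observed
  exactly this as a non-convergent rightmost eigenvalue for
  maturity-dependent rates; the fixed-step route removes it (eigenvalues
  then agree with independent characteristic-function roots to ~1e−8).
  `auto` dispatch: integral route when `D₁g ≡ 0`, fixed-step otherwise;
  the adaptive route remains available and is cross-checked against both
  (agreement to 1e−9 in the tests).

## Right-hand side and integration

The exponential (dilation) integral in the delayed term is evaluated by
Gauss–Legendre quadrature with order doubling until successive orders
agree to 1e−10 absolute; the integrand is smooth on `[0, τ]`, so this
converges in one or two doublings and vectorises over the stored
trajectory (an adaptive Gauss–Kronrod rule would serve equally; the
doubling rule was chosen for vectorisation, and the test suite uses
`scipy.integrate.quad` as the independent oracle).  When `d ≡ 0` and
`D₁g ≡ 0` the factor is exactly 1 and is skipped.

Time integration uses the method of steps: the history is the initial
pair plus the dense outputs of all accepted solver windows; each window
is capped at half the current threshold delay with `max_step` at 5 % of
it, and delayed lookups that overhang the last accepted step use a linear
continuous extension to the current stage value (first-order consistent;
the overhang is at most one `max_step`).  Default tolerances
`rtol = 1e−9`, `atol = 1e−11`.  Equilibrium histories are fixed points to
below 1e−8 drift over 50 time units, and post-transient states satisfy
the solution-manifold compatibility `(φ,ψ)'(0) = F(φ,ψ)` to 1e−6.

## Equilibria

`v` solves `q(v) = 0` by doubling-bracket plus Brent (`xtol = 1e−14`); `w`
follows in closed form with the same quadrature as the right-hand side,
so the full-functional residual certificate (required `< 1e−10`) is
self-consistent.  The transcritical threshold `p* = μ_w/(2a−1)` is exact.

## Characteristic equation

The kernel of the distributed-delay term needs the constant-history
trajectory `y(t, v)` to high accuracy: it is tabulated as `t(y)` by
per-panel 8-point Gauss–Legendre on 400 panels (machine-accurate panel
integrals) and inverted with a cubic spline, leaving ~1e−12 interpolation
error (a cumulative trapezoid at the same grid was measured at 8e−6 in
`y` — far too coarse for the kernel's cancellations — and was replaced).
Nested kernel integrals use 40-point Gauss–Legendre; the finite Laplace
transform doubles its order until 1e−10 relative agreement, caching
kernel samples per order.  Two structural facts are exploited and tested:
the kernel vanishes identically when `d ≡ 0` and `D₁g ≡ 0`, and it also
cancels exactly for separable rates `g(x,v) = G(x)A(v)` with `d ≡ 0` (a
calculation the tests verify numerically).

Roots are localised by the argument principle: adaptive phase tracking on
rectangle boundaries (segments refined while a step turns the phase by
more than π/2), recursive subdivision to unit winding count, then damped
Newton with a numerical derivative.  The printed fixed-delay closed form
carries the opposite overall sign from the preceding members of its
cascade; since root sets are sign-invariant the implementation keeps each
printed form and asserts the sign relation explicitly.

## Closed-form fixed-delay boundary

The parametrisation `r = ω/f_η(ω)`, `m = ω f_η(ω)/g_η(ω)` is evaluated
directly; singularities are bracketed per the half-π window catalogue
(alternating zeros of `f_η` and `g_η`, ordering depending on `η ≷ 1`) and
refined by Brent to 1e−12.  The sign of `dr/dω` reduces to the closed
numerator `N(ω) = (η−ω²) sin ω − ηω cos ω` (`N(π/2) = η − π²/4`, and
`N ~ ω³(η−3)/3` at the origin, which is why the shape thresholds are
`π²/4` and `3`).  Shape classification scans `N` on a 4001-point grid
with a 1e−4 margin around the origin, where the derivative vanishes to
third order; curve sampling excludes 1e−6 neighbourhoods of the
singularities, where `m` or `r` diverge.

## Time transformation

The forward/inverse maps are cumulative integrals of `g(v)` and `1/g(v)`
evaluated by per-interval Gauss–Legendre and inverted through monotone
PCHIP interpolation of the sampled pairs (no closed inverse exists for
general `g(v)` along a solution).  The arbitrary extension of the
reconstructed history beyond the transformed delay is taken as constant
continuation of the earliest available value.  The eigenvalue
correspondence `z ↔ z/g(v)` is verified between the collocation spectra of
the two systems after filtering discretisation artifacts: an eigenvalue
counts as physical when recomputing at `M+5` reproduces it within 1e−3 on
a `1+|λ|` scale.  With `M = 35` the six leading physical roots correspond
to better than 1e−6 for the scenarios with `v`-regulated maturation — the
deeper members of the root chain reach `|Im z|·h ≈ 30`, which sets the
resolution the discretisation must have before the comparison is
meaningful.

## Pseudospectral reduction

Chebyshev extremal nodes `θ_j = (h/2)(cos(jπ/M) − 1)`, the standard
differentiation matrix with the negative-sum diagonal trick, and
barycentric interpolation (weights `(−1)^j`, halved at the ends).  The
reduced system is `[F-rows; D-rows]`; since the D-rows are linear they
enter the Jacobian exactly and only the two functional rows are
differenced (central, relative step 1e−7 per coordinate).  At the
extinction state the functional is multilinear in the perturbations, so
the trivial spectrum `{q(0), −μ}` is recovered to ~1e−11 at `M = 15`.
Default `M = 15` with an `M → M+5` stability check for flagging
discretisation artifacts.  The interpolated mature-cell history is clamped
at zero: probe interpolants near the extinction state oscillate
infinitesimally below it, and the clamped values only ever multiply a zero
stem-cell factor there.

Spectral convergence is exercised on a long-delay configuration
(`τ = 8`): at shorter delays the `M = 10` error already sits at the
finite-difference noise floor (~1e−9) and the decay ratio cannot be
resolved.

## Boundary tracing

The rightmost physical eigenvalue's real part is a smooth function of `p`
near a simple Hopf crossing, so the crossing is located by a geometric
scan (12 points) followed by Brent's method (`xtol = 1e−10`); traces over
a `μ` grid reuse a secant prediction from the previous two points to
centre the bracket, falling back to the full range and flagging the point
when no sign change exists — a genuine outcome for the scenarios where
the equilibrium is stable for every division rate.  Search windows default
to `p ≤ 50`, matching the study's reported window.  All computations are
deterministic; no seeds are involved.

One modelling subtlety: for the `(pv)` scenarios the maturation-rate
coefficients are tied to the stem-cell parameters (`a_u = a`, `p_u = p`),
so configurations built from those scenario labels re-derive the profiles
whenever `p` or `a` changes during a parameter sweep (`track_profiles`).
Without this coupling the qualitative claims — stability for every `p`
under `(s)_s,(pv)_2`, no destabilisation under simultaneous regulation —
do not hold, because `g` would stop growing with `p`.  For `(pv)_0` the
constant rate `g` (equivalently `τ = δ/g`) is an independent free
parameter, and for `(px)` scenarios the printed profiles are fixed except
`p_u = p` in `(px)_2`.

## Problem sizes used in the validation suite

Boundary cross-validation uses 20 mortality values per `η ∈ {0.99, 1.5,
2.5}` with `M = 15`, sampled where the closed-form curve satisfies
`0 < r ≤ 0.96` and `0.05 ≤ m ≤ 20` — the window where all three routes
see a finite crossing below the `p` cap.  The trivial-spectrum check
draws 20 parameter sets with `μ ∈ [0.3, 2]`, `p ∈ [0.3, 3]`,
`τ ∈ [0.5, 2.5]`, moderate ranges where the collocation error at `M = 15`
is far below the 1e−8 assertion.  The qualitative claims (concavity flip
in `g0`, stable-for-all-`p` regions) are checked on coarse grids at
`M = 10–12`.

## What the scenario generator does and does not emulate

The built-in scenarios are parameter sets, not data: they exercise the
regulation structures of the model (which feedback acts on division,
self-renewal or maturation, and how maturation depends on maturity).
Passing tests demonstrate internal consistency of the three stability
routes and agreement with the closed forms — they say nothing about how
well the rate family describes any real hematopoietic system, and no
inference from measured cell counts is attempted.

## Known limitations

* The argument-principle root finder assumes roots off the contour;
  contours are perturbed once on detection, not proven root-free.
* The a-priori bound on unstable roots is a scan certificate over a
  finite rectangle, not a proof.
* The method-of-steps integrator targets smooth non-stiff regimes; the
  linear overhang extension limits accuracy to ~1e−8 per unit time near
  rapidly varying solutions, and no stiff or discontinuity-tracking
  support is provided.
* Fixed-step threshold solves use 384 RK4 steps (~1e−10 accuracy for the
  scenario family); pathological maturation rates may need more.
* Periodic orbits emerging at the Hopf boundary are not continued; only
  equilibrium stability is computed.
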