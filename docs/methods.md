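# Methods

## The model

`anisofield` estimates a node-wise anisotropy exponent from multichannel
timeseries. The underlying model is a scalable (mechanically similar)
Lagrangian field theory: a scale transformation maps a field configuration
φ(r) on space–time r = (t, x, y, z) to φ_s(r) = λ·φ(λ^{−α} r) with a
separate exponent α_ν per axis, and an action S[φ] = ∫ L(φ, ∂φ) d⁴r is
*scalable* when S[φ_s] = λⁿ S[φ] for every configuration. Expanding an
analytic Lagrangian density as a power series in the field and its first
derivatives, scalability holds iff every monomial C·φ^a·φ̇^{b_t}·φ_x^{b_x}·
φ_y^{b_y}·φ_z^{b_z} satisfies

    a + Σ_ν (1 − α_ν) b_ν = n − Σ_ν α_ν ,

which fixes the field exponent a given the derivative exponents. The
package's working model is the three-term two-dimensional special case
obtained with α_t = α_x and n = α_y + 2:

    L = φ̇² − φ_x² − φ^{2β} φ_y² ,     β = α_y − α_x ,

whose Euler–Lagrange equation is

    φ̈ = φ_xx + φ^{2β} φ_yy + β φ^{2β−1} φ_y² .

β = 0 is the isotropic (ordinary wave-equation) limit; β ≠ 0 means the two
in-plane directions scale differently, i.e. the dynamics are anisotropic.

For data on a grid the spatial derivatives are replaced by the standard
stencils (centred first difference in y, second differences in x and y, unit
node spacing), and the second-order equation is split into first-order
equations for (φ, θ = φ̇). The observer measures φ at every node with
additive i.i.d. Gaussian noise.

Conventions: the first array axis is x (plain Laplacian coupling), the
second is y (the φ^{2β}-weighted direction). Node flattening is row-major
(y fastest). Fractional powers of φ are defined only for φ > 0 and raise a
`DomainError` otherwise; integer 2β (e.g. β = −3) admits any non-zero φ.

## Forward simulation

Fixed-step integration (RK4 by default; explicit Euler available) with
mirror (zero-flux) boundaries by default, so a uniform field is a fixed
point; periodic and fixed-value boundaries are provided. Defaults: dt =
0.05 and 200 steps (a horizon of 10 time units). Non-finite values abort
integration with the offending step index rather than being clamped, so
anisotropy-driven blow-ups are visible. With initial values and rates of
change drawn uniformly from [1, 2] (the construct-validation setup) the
zero-flux boundary conserves the mean rate, so the field amplitude grows
roughly linearly through the horizon; runs for β ∈ {0, −3} are stable for
every seed tried.

## Inversion

The generative model for observed timeseries y (time × nodes) is the
deterministic forward sweep from unknown initial grids (φ₀, θ₀) and
exponent β, observed with noise precision exp(λ_obs). The estimator is
variational Laplace: Gaussian posteriors over (β, φ₀, θ₀) and λ_obs,
scored by the free energy

    F = ⟨log p(y | params)⟩_q − KL[q(params), p(params)] ,

which combines accuracy with a complexity penalty. The optimisation follows
a D/E/M pattern:

* **D step** — each node's series is embedded in generalized coordinates of
  motion (the series and its first three temporal derivatives, order 4,
  from Savitzky–Golay local polynomial fits whose window is set by the
  assumed fluctuation smoothness, default 2·dt). The embedding seeds the
  initial-condition estimates. Fluctuations on the states are carried as a
  log-precision hyperparameter with a Gaussian prior; because the forward
  sweep is deterministic the data do not update it, and a full dynamic
  state-noise filter is deliberately out of scope.
* **E step** — damped (Levenberg) Gauss–Newton ascent of F in (β, φ₀, θ₀)
  with central-difference Jacobians (relative step 1e−4), batched through
  the integrator.
* **M step** — Newton ascent of F in the observation log-precision
  (concave), with the Laplace variance 1/(½e^λ‖r‖²_eff + 1/v₀).

F is strongly non-convex in β (the exponent enters through φ^{2β}), and
joint Gauss–Newton from a cold start reliably stalls on ridges where
initial-state shifts mimic β changes. The scalar β is therefore *profiled*
first: 17 candidates spanning ±4 prior standard deviations are each fitted
with β clamped, warm-starting the states from the nearest already-fitted
candidate, and the joint refinement starts from the best profile point.
Candidate steps that would lower F are rejected, so the recorded
free-energy trace is non-decreasing by construction; convergence is
declared when the gain drops below 1e−2 nats (at most 64 iterations).

Default priors: β ~ N(0, 1); initial states ~ N(embedding seed, 1);
log-precisions ~ N(0, 16). Prior variances are declared defaults — the
construct they implement (a prior expectation of isotropy) is fixed, the
numbers are not canonical. A zero prior variance on β denotes the reduced
(perfectly isotropic) model: β is clamped rather than estimated.

### Identifiability of strongly negative β

Under the defaults (zero-flux boundaries, rates of change in [1, 2], noise
sd 0.05) the field grows away from the φ ≈ 1 regime where the y-coupling
φ^{2β} is appreciable, so the data inform β mainly through the early part
of the recording. On noise-free data, refitting the initial states with β
clamped at −2.2 reproduces a β = −3 trajectory to a residual RMS of ~0.001
per sample — fifty times below the observation noise — so the exact
posterior over β is a plateau covering roughly [−3.5, −2]. Consequences:

* β = 0 is recovered essentially exactly (posterior sd ~1e−3);
* for β = −3 the posterior mean lands on the plateau (typically −2.3 to
  −3.0) with a correspondingly wide posterior sd (~0.3–0.7), and a point
  estimate within ±0.5 of −3 is not guaranteed in every replicate — this
  is a property of the data-generating conditions, not of the optimiser;
* model *selection* is unaffected: the evidence gap between the isotropic
  and anisotropic explanations is thousands of nats.

Relatedly, the "posterior returns to the prior as noise grows" limit can
only be approached, not reached: at very large noise the fitted latent
field crosses zero and leaves the domain of the fractional powers (such
fits fail loudly). Tests assert the monotone trend.

## Bayesian model reduction

For a reduced model differing from the full one only in its prior over β,

    ΔF = log E_q[ p̃₀(β) / p₀(β) ] ,

a one-dimensional Gaussian integral over the β marginal of the posterior,
evaluated in closed form. The point-mass reduced prior (perfect isotropy)
is the analytic limit — the Savage–Dickey ratio ΔF = log q(0) − log p₀(0) —
and the reduced posterior is the full posterior conditioned on β = 0, which
propagates through the β/initial-state correlations of the joint
covariance. An ε-variance (1e−8) route exists purely as a numerical
cross-check, as does refitting with β clamped. Log evidences become model
probabilities by softmax under a uniform prior over the two models.

## Pixelwise mapping

For imaging movies, every second pixel (stride 2) inside the mask whose
four neighbours are also in the mask is inverted independently: the
neighbours' *measured* traces enter the stencils as known, time-varying
boundary data (linearly interpolated at RK4 half-steps), keeping each
inversion three-dimensional (β, φ₀, θ₀) plus a log-precision. Treating
neighbours as observed rather than latent keeps the problem local; the
price is that neighbour noise acts as unmodelled forcing, which inflates
per-pixel uncertainty but leaves region contrasts intact. The same
profile-then-refine scheme is used (9 candidates, vectorised across
pixels); failed pixels are marked missing and logged, never fatal.

Maps are combined in the order: average posteriors across trials, then
across subjects, then smooth. "Average the posteriors" is implemented as
the arithmetic mean of posterior means with mixture-moment variances
(mean of variances plus between-map variance of means); a
precision-weighted alternative sits behind a flag. Smoothing is a 2D
Gaussian moving average with a semi-width window of 7 pixels, σ =
semiwidth/2, hard truncation at the window, and mask-aware renormalisation
(weights on missing pixels are redistributed); stride gaps are left missing
rather than interpolated. Mean timecourses z-score each in-mask pixel over
time (zero-variance pixels excluded with a warning) and average spatially
per frame.

## Synthetic data

The generators are pure functions of their seed (SeedSequence spawn keys),
so every fixture regenerates bit-identically.

* **Construct-validation pair**: a 3×3 grid, per-node initial value and
  rate of change uniform in [1, 2], evolved under the discretized equations
  of motion with β = 0 and β = −3, identical everything else; observation
  noise sd 0.05 (a declared default). Unstable draws are regenerated from a
  fresh sub-seed (logged, at most 5 attempts).
* **Jitters**: initial conditions multiplied elementwise, and the noise sd
  once, by independent uniform draws on [1−f, 1+f] (default f = 0.10).
* **Movies**: masked grids with a *spatially varying* β field (each pixel's
  update uses its local exponent — an extension used only to create ground
  truth for per-pixel recovery), fresh uniform initial conditions per
  trial, out-of-mask pixels frozen at their fill values, noise added within
  the mask; 3 subjects × 2 conditions (rest/task) × 10 trials by default.
  The recovery experiments use 32×32 grids with 100 frames at dt = 0.05.

What the generators emulate is the *structure* of wide-field calcium
recordings (mask, trials, subjects, conditions, node-wise timeseries); they
do not emulate indicator kinetics, bleaching, hemodynamic contamination,
spatial correlations in the noise, or task structure beyond a label.
Passing recovery tests therefore demonstrates that the estimator works when
the generative model is correct — not that real cortical data satisfy the
model.

## Numerical choices

* Scalability algebra uses an exact integer path when all exponents are
  integers, otherwise an absolute tolerance of 1e−12.
* Actions are trapezoidal quadratures on regular grids (≥ 8 points/axis);
  derivatives by second-order central differences unless an analytic
  gradient is supplied. Because finite differences commute with the axis
  scalings, the mechanical-similarity identity holds to near machine
  precision on matched grids.
* Jacobians are central differences with relative step 1e−4; Levenberg
  damping multiplies the Hessian diagonal, growing ×10 on rejection and
  shrinking ×10 on acceptance.
* Degenerate inputs fail loudly: constant observations raise an
  unidentifiable-data error; non-finite trajectories raise with the step
  index; φ ≤ 0 against a fractional exponent raises a domain error.

## Problem sizes

The shipped experiments are desk-scale by design: 3×3 grids with 201
samples for inversion (ten replicate seeds), ten ±10% jitter replicates,
and 32×32 movies (100 frames, 60 movies, stride-2 lattice ≈ 225 pixels per
movie) for mapping. Pixel inversions are vectorised across pixels and
movies, with large batches processed in slices of 3000 pixels to bound
memory.

## Known limitations

* The estimator assumes the measured quantity is the field itself (no gain
  or offset term in the observer) and that sampling is uniform in time.
* Neighbour traces in pixelwise mapping are treated as noiseless boundary
  data; heavy observation noise therefore biases per-pixel estimates more
  than it would a joint latent-field inversion.
* The plateau geometry described above means strongly negative exponents
  are reported with honest but wide uncertainty; comparisons between
  regions (sign contrasts) are much more reliable than absolute values.
* No group-level (random-effects) model comparison and no registration of
  movies to an atlas; β maps are in pixel coordinates.
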