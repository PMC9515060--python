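# Methods

## Model

`gridfield` simulates a mean-field description of a grid-cell module: four
neuron populations with cardinal orientation preferences beta = 1..4 (north,
west, south, east) arranged on the periodic neural sheet
Omega = [-0.5, 0.5)^2 (a flat torus).  Each sheet location x and orientation
beta carries a probability density f^beta(t, x, s) over the nonnegative
activity level s, evolving by a Fokker-Planck equation

    tau df^beta/dt = -d/ds([Phi^beta(x) - s] f^beta) + sigma d2f^beta/ds2,

with no-flux boundary at s = 0 (activity cannot become negative; probability
mass is conserved) and the nonlocal firing rate

    Phi^beta(x) = Phi((1/4) sum_beta' int_Omega W(x - y - r^beta') <f^beta'>(y) dy + B^beta),

where W <= 0 is an inhibitory connectivity kernel, even in each coordinate
and periodically extended, r^beta = z e_beta are equal-length shifts along
the cardinal directions, Phi is a modulation (activation) function, and
B^beta the external input.  <f> denotes the local mean activity.  The drive
B^beta = B + alpha v(t) cos(theta(t) - theta^beta) couples an animal's speed
and heading into the four populations, translating the sheet pattern as the
animal moves; with alpha = 0 the input is a constant B.

The package answers: at which noise level sigma does the homogeneous
(patternless) network state destabilise into the spatial patterns that make
single-neuron firing fields hexagonal, and how do the patterned branches
depend on sigma (bifurcation diagram, hysteresis)?

### Homogeneous stationary states

For constant drive, the spatially homogeneous stationary density is the
truncated Gaussian f_inf(s) = Z^-1 exp(-(s - Phi0)^2 / 2 sigma) on s >= 0
with Z = sqrt(pi sigma / 2)(1 + erf(Phi0 / sqrt(2 sigma))), where
Phi0 = Phi(W0 <f_inf> + B) and W0 = int W dx.  The mean solves the scalar
consistency equation <f_inf> = Phi0 + sigma exp(-Phi0^2 / 2 sigma)/Z, which
we bracket on [0, Phi(B) + sqrt(sigma/2 pi) + 1] and solve with Brent's
method (tolerance 1e-12); bisection-style bracketing keeps non-smooth ReLU
modulations admissible.  Under inhibitory coupling (W0 <= 0) and
Phi'(W0 m + B) > 1/W0 the consistency map is strictly decreasing — the bound
rests on the gain g(eta) of the truncated-Gaussian mean with respect to its
location lying in [0, 1] — so the root is unique; outside those hypotheses a
root is still returned with a warning.  Means and the second central moment
M_inf(sigma) use the closed truncated-normal forms written with `erfcx` so
both deep truncation (Phi0 < 0) and negligible truncation (Phi0 >> sqrt(sigma))
are handled without loss of precision; an adaptive-quadrature route exists
as an independent cross-check.

### Linear stability and the critical noise

Perturbing f_inf by a single sheet mode k = 2 pi (k1, k2) (integers; the
torus admits only lattice modes) gives the growth factor

    F(k) = (1/4) Phi'(W0 <f_inf> + B) W_hat(k) [2 cos(2 pi k1 z) + 2 cos(2 pi k2 z)],

real by evenness of W.  Each mode contributes eigenvalues -1/tau (multiplicity
3, the rank-one structure of the four-population coupling) and (F(k) - 1)/tau.
Without noise the stability condition is F(k) < 1; with noise it relaxes to
F(k) < sigma / M_inf(sigma) >= 1 — noise stabilises the homogeneous state.
The critical noise sigma_c solves max_k F(k; sigma) = sigma / M_inf(sigma)
by bracketing on a logarithmic sigma grid and Brent refinement (tolerance
1e-6); Phi0, M_inf and F are re-solved at every iterate because the
stationary state depends on sigma.  As sigma -> 0, sigma/M_inf -> 1 whenever
Phi0 > 0, recovering the zero-noise condition.

For the reference kernel W(|x|) = -0.005 * 128^2 (1 + tanh(10 - 50 |x|))
(an inhibition disk of radius ~0.2) with shift z = 2/128, the lattice
maximisers of F on |k1|,|k2| <= 8 are the (4,0) orbit, closely followed by
(4,1) and (3,3); with the smooth-product modulation (eps = 0.01) and B = 3
the package computes sigma_c ≈ 0.0234.

## Numerical scheme

The s-operator is discretised by a conservative finite-volume scheme with
Scharfetter-Gummel/Chang-Cooper exponential-fitting interface weights: hop
rates between adjacent cells are proportional to the Bernoulli function
B(w) = w/(e^w - 1) of the interface Peclet number
w = (s_edge - Phi) ds / sigma.  Because the drift is linear in s, the
interface potential increments are exact and the cell-center samples of the
truncated Gaussian are an *exact* discrete stationary state (detailed
balance: up/down rate ratio e^-w).  No-flux is imposed at s = 0 and at the
truncation boundary s = s_max (default 3), so per-site mass is conserved to
round-off; a warning is issued when the stationary mean + 5 sqrt(sigma)
approaches s_max.

Time stepping is backward Euler in the linear s-operator with the nonlocal
rate Phi^beta frozen over the step.  The update matrix is an M-matrix, so
the scheme is unconditionally positive and mass-conservative; dt is chosen
for accuracy, with the conservative default 0.4 min(ds^2/2 sigma,
ds/max drift) and a warning (not an abort) for dt > tau.  The time scaling
of the discretisation was verified against an exact oracle: with constant
Phi and the boundary far away, the discrete generator reproduces the
Ornstein-Uhlenbeck spectrum {0, -1, -2, -3, ...}/tau to three digits at 256
cells.

The nonlocal coupling is a torus convolution evaluated spectrally.  The
shifted kernels W(. - r^beta) are re-sampled on the displacement lattice
(minimum-image convention) before transforming, so the spectral product
reproduces the direct quadrature double sum to round-off even when z is not
a grid multiple; for tabulated kernels, where re-sampling is impossible, the
shift falls back to an exact phase factor (band-limited interpolation).

The discrete fixed point of the homogeneous problem differs from the
analytic profile by the O(ds^2) quadrature error of the discrete mean
(~1e-3 in L1 at 512 cells); equilibrium-preservation tests therefore target
the scheme's own fixed point (preserved to 1e-10), and error-decay
experiments that use the analytic reference plateau at the quadrature gap
rather than machine precision.

### Relaxation-rate experiment

The homogeneous relaxation experiment places unit mass on 51 random cells of
a 512-cell grid on [0, 3] (height 512/153 each), evolves with the
smooth-product modulation (eps = 0.01), W0 = -20.6711, B = 3, sigma = 0.03,
tau = 1, and fits straight lines to log|<f> - <f_inf>| and to the log L1
distance against time over the pre-plateau window (samples above 1000x the
plateau floor, floor = mean of the trailing 10%).  Averaged over 100 seeds
the package obtains decay rates ~1.8 (mean difference) and ~1.1 (L1).  Two
caveats are documented rather than hidden: (i) the decay is not a single
exponential — a slow multi-mode transient precedes a faster asymptotic
stage whose rate equals the spectral gap 3.55 of the numerically assembled
Jacobian at these parameters — so the fitted value depends on the window
convention; (ii) the absolute scale of published reference rates for this
experiment depends on the time unit of the underlying runs, which is not
part of the model specification here; rates are reported in units of
tau = 1.

## Bifurcation continuation

Branches are tracked by sweeping sigma (either direction) and solving the
time-dependent system to stabilisation at each value, reusing the previous
steady field as the next initial datum.  Convergence is declared when the
relative L1 change of the field per unit time stays below the tolerance
(default 1e-6, checked every time unit); non-convergence is recorded and the
sweep continues from the last converged field.  The diagram records
max_x and min_x of the total mean activity sum_beta <f^beta>(x).

Because every site carries unit mass, admissible initial-data perturbations
deform the local density rather than scale it; all presets are built from
truncated-Gaussian profiles with site-dependent centres:

- `random` — centres drawn i.i.d. uniform on [0, 1] (generic data; the
  hexagonal branch has the largest basin of attraction and wins);
- `perturbed_homogeneous` — centres Phi0 + 1e-2 <f_inf> xi(x) with xi
  mean-zero uniform (probes local stability);
- `stripe_band` — mean activity one enforced in a horizontal band of width
  0.25 (seeds the stripe-like branch).

Patterns are classified from the Fourier signature of the total mean field:
homogeneous (all nonzero modes < 1e-6 of the zero mode), stripe-like (all
modes >= 25% of the leading one collinear), hexagonal-like (>= 3 pairwise
non-collinear dominant orbits of comparable amplitude), otherwise "other"
(the eye-like states land here; no automatic eye detector is attempted since
the initial data generating that branch is not specified).  The 25%
dominance threshold is a heuristic and is exposed as a parameter.

Desk-scale sweeps run at 32^2 sheet x 64 activity cells x 4 populations
(the published diagrams use 128^2; that resolution is config-reachable but
not exercised by tests).  At 32^2 the hexagonal branch persists up to
~sigma = 0.022-0.024 while the homogeneous branch is linearly stable above
sigma_c ≈ 0.0233; sweeping down from high noise with strict continuation
stays on the homogeneous branch (the instability has only round-off to grow
from), so the two sweep directions disagree over a finite sigma interval —
the operational hysteresis signature.  An optional re-seeding of the small
perturbation at every sigma is available for exploring jumps onto patterned
branches.

## Microscopic network

The particle module simulates the finite network the PDE upscales: activity
levels with Euler-Maruyama steps
ds = (Phi(coupling + B) - s) dt/tau + sqrt(2 sigma dt/tau) xi and reflection
at zero.  Reflection is clamp-to-zero with the clamped deficit booked as
boundary local time (the standard projection scheme for reflected SDEs);
mirroring (s <- |s|) is available as an option.  The all-to-all coupling
W0 * mean(s) is the finite-M analogue of the homogeneous equation — note a
single *sheet* column would couple through W evaluated at one displacement,
not W0, so the all-to-all form is the correct single-column comparison.
With M = 1e4, dt = 1e-3 tau, the empirical mean matches the PDE stationary
mean well within Monte-Carlo error (bias < 0.5 SE measured at these
settings).  For tau != 1 the noise amplitude is chosen so the particle
system's Fokker-Planck equation is exactly the PDE solved here.

## Synthetic trajectories and firing fields

Recorded rodent positions are not bundled; a synthetic forager stands in: an
Ornstein-Uhlenbeck-style heading random walk with speed fluctuating around a
configurable mean (default 15 cm/s, relative s.d. 0.15) inside a circular
arena (default radius 80 cm), with specular reflection of the heading at the
boundary.  It reproduces the coverage statistics relevant here (speed
within 10% of the requested mean, full-arena occupancy) but none of the
behavioural structure of real foraging (thigmotaxis, rest periods,
speed-heading correlations) — conclusions about firing-field *geometry* do
not depend on those, but dwell-time statistics would.

For firing-field maps the field is first stabilised with alpha = 0 at the
chosen noise level, then the trajectory (resampled to the PDE step by linear
interpolation, one second of trajectory time advancing the field by
`time_scale` units of tau) drives the inputs via B^beta(t).  A tracked
neuron fires at a sample when its rate exceeds the threshold (default
exactly Phi > 0, meaningful for ReLU-type modulations; strictly positive
sigmoids fire everywhere by construction, which the navigation module
documents and tests).  Velocity and heading are obtained from positions by
central differences with an optional smoothing window.

## Numerical choices and degenerate inputs

- Root brackets: consistency roots on [0, Phi(B) + sqrt(sigma/2 pi) + 1];
  sigma_c located on a 25-point log grid over [1e-4, 1] before refinement.
- sigma = 0 is a separate code path (fixed point of m = Phi(W0 m + B)).
- Bernoulli function evaluated piecewise (series below |w| = 1e-10,
  e^-w form for w > 0) to avoid overflow on both tails; the identity
  B(-w) = B(w) + w supplies the second interface weight.
- Tabulated kernels are symmetrised when the asymmetry is below 1e-12
  (relative) and rejected otherwise; kernels with positive values are
  rejected (inhibitory assumption).
- Dominant-mode ties are reported as the full symmetry orbit
  (lexicographic order, relative tolerance 1e-9).
- Degenerate trajectories (single point) yield empty drive series and empty
  firing fields rather than errors.

## Known limitations

- The published bifurcation diagrams at 128^2 resolution are reproduced
  only qualitatively at 32^2; jump locations are resolution-dependent.
- Unstable branches are not computable by time marching (continuation finds
  only attractors).
- Linear stability is asserted within the separable perturbation class
  (f_inf-weighted single-mode products), as in the underlying analysis.
- The eye-like branch is recognised only as "other"; its basin is not
  mapped.
- The connectivity integral of the reference tanh kernel evaluates to
  -20.7581 on every quadrature tried; the value -20.6711 used as the
  *input* W0 of the reference homogeneous experiments is adopted verbatim
  for those runs, and the ~0.4% discrepancy is surfaced by the acceptance
  checks rather than absorbed.
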