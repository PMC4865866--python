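# Methods

## Model

An IXS scan at fixed in-plane momentum transfer Q is modelled as a flat
background, an elastic line with the shape of the instrument resolution
function (RF) and free amplitude S(Q,0), and up to two damped-harmonic-
oscillator (DHO) phonon modes convolved with the RF:

    S(ω) = bg + S(Q,0)·RF(ω) + Σ_m [ I_m · B(ω,T) · D(ω; Ω_m, Γ_m) ] ⊛ RF.

Assumptions:

* the unresolved quasi-elastic dynamics (diffusion, relaxation) is absorbed
  into a δ(ω) term, so the central peak has exactly the RF shape — only its
  amplitude varies;
* the background is energy-independent over the ±15 meV window;
* each propagating excitation is described by the classical DHO kernel
  D(ω) = (1/π)·ΓΩ²/[(ω²−Ω²)² + (Γω)²], an even, unit-area density.  The DHO
  convention in the IXS literature varies in how the asymmetry and
  normalisation are factored; here the kernel is even and the full
  Stokes/anti-Stokes asymmetry is carried by the quantum detailed-balance
  weight B(ω,T) = x/(1−e^(−x)), x = ħω/k_BT (first-moment-preserving
  convention, B(0)=1).  The kernel lives behind a single function
  (`lineshape.dho_kernel`) so an alternative convention is a one-line change;
* the sample temperature entering B is the nominal one (293.15 K gel,
  318.15 K fluid), not a fitted parameter.

Key constants: ħ = 6.582119569×10⁻¹³ meV·s, k_B = 8.617333262×10⁻² meV/K;
a dispersion slope of 1 meV·nm corresponds to 1519.27 m/s.

## Resolution convolution

The RF is a Pseudo-Voigt η·L + (1−η)·G with a common FWHM (default 1.7 meV,
η = 0.5 when a dataset does not specify it).  Because both components reach
half of their own peak at ±FWHM/2, the mixture's FWHM equals the parameter
exactly.

Convolution is performed on an internal uniform grid with step
min(Δω_grid)/2 capped at FWHM/10, padded beyond both ends of the measurement
grid by the kernel half-width, and interpolated back to the (possibly
irregular) measurement grid.  The kernel support is max(5, 159·η)×FWHM: a
Lorentzian carries ~6% of its mass beyond 5×FWHM, so a short kernel would
lose several percent of the zeroth moment; the chosen support truncates
≤ 0.2% and the kernel is renormalised to unit area.  This keeps both moment
conservation and the Lorentzian width-additivity identity
L(a) ⊛ L(b) = L(a+b) accurate to better than 1%.  The kernel FFT is cached
per (grid, RF) so a fit costs one FFT pair per model evaluation.

## Fitting

Free parameters: S(Q,0), bg and (Ω, Γ, I) per mode — 2 + 3n in total, all
bounded below by zero (Γ ≥ 10⁻³ meV, Ω ≤ 1.2·max|ω|).  The objective is the
standard weighted least squares with the per-point 1 s.d. errors; the solver
is scipy's bounded trust-region reflective `least_squares`.  Initialisation:
elastic amplitude from the data peak, background from the median of the outer
10% of energy points, the dominant-mode energy from the largest smoothed
positive residual of an elastic-only model (fallback 8 meV), a 2 meV
transverse candidate, Γ₀ = 2 meV, intensities from the integrated excess over
the elastic-only model.  Each fit runs the base start plus 5 restarts with
log-uniform ×0.5–×2 perturbations of Ω and Γ (seeded; identical spectrum and
seed give bit-identical results).  1σ uncertainties come from the
pseudo-inverse covariance of the linearised problem at the optimum; no χ²
rescaling is applied since the errors are absolute counting errors.

### Mode-count selection

The spectrum is fitted with one and with two modes.  The two-mode fit is also
started from the one-mode optimum with a zero-intensity and with a small
second mode, which guarantees the nested-model property (raw χ²_2 ≤ χ²_1).
Two modes are chosen iff the reduced χ² improves by ≥ 15% (relative) and no
mode has vanished.  A mode counts as vanished only when it has collapsed to
zero: its intensity is below 2× its 1σ error *and* negligible next to its
companion (≤ 5% of the other mode's intensity).  The statistical check alone
is not sufficient: a real mode buried under the resolution line has an
intensity strongly covariant with the elastic amplitude, hence a huge
linearised error, while carrying a large share of the inelastic weight.  The 15% threshold
cleanly separates a dramatic improvement (~50%) from a negligible one (~1%)
while being insensitive to its exact value over a wide range.  The two-hump
residual diagnostic — boxcar-smoothed (5 points) residuals exceeding +1.5σ on
both sides of the elastic region (|ω| > RF HWHM) at mirror positions within
1.5 meV — is recorded as supporting evidence, not used as a selection
criterion.  Within a two-mode fit the lower-Ω mode is labelled transverse and
the higher longitudinal, following the standard branch assignment for these
systems.

## Dispersion and derived observables

* **Sound speed**: weighted least squares of ω = s·Q through the origin
  (an acoustic branch has ω(0) = 0) over present points with
  Q ≤ q_linear_max (default 5 nm⁻¹ for both branches, i.e. the two lowest
  points of the default Q grid).  With a sine-shaped branch the secant slope
  over a finite window is systematically below the true q→0 slope — about
  8–10% for the default window; widening the window to 8 nm⁻¹ raises the bias
  to ~25%, which is why the narrow default was chosen.  The same bias affects
  a measured dispersion, so the estimate is comparable to what experiments
  quote.
* **Zone boundary Q_min**: weighted parabola through the lowest-ω present
  point and up to two neighbours on each side inside a search window (default
  10–20 nm⁻¹); the vertex is the estimate and its error is propagated from
  the ω uncertainties.  Near the minimum the mode is buried under the elastic
  line and its fitted ω is noisy; the five-point parabola makes the vertex
  robust to that middle point (a ±2 meV error moves the vertex by ~0.1 nm⁻¹).
  A minimum at the window edge or a non-convex fit is flagged, not silently
  returned.
* **Area per lipid**: d = 2π/Q_min (Å), A_L = 2.64·(9d/8)²; σ_A = 2A·σ_q/q.
* **Damping ratio**: R = ω/Γ with standard error propagation; a point is
  "critical" when |R−1| ≤ σ_R, otherwise under-/overdamped — exactly one
  class per point.
* **Phononic gap**: the transverse branch's `present` flags (from the per-Q
  mode-count selection) encode where the mode propagates.  The gap edge is
  the midpoint between the largest Q of the contiguous low-Q absent run and
  the first present Q above it; if the branch is present at the lowest
  measured Q there is no gap.  Because the measurement reports a threshold
  region rather than a point, the output carries both the midpoint estimate
  and the interval [2π/Q_first_present, 2π/Q_last_absent] for the cluster
  size d_gap = 2π/Q_gap.

## Synthetic experiment

The generator emulates the measurement protocol: 18 Q values evenly spanning
2.47–27.29 nm⁻¹, 97 energy points on a symmetric ±15 meV grid (the energy
span per scan is a package convention chosen to cover the ~10 meV
longitudinal features with padding), Pseudo-Voigt RF of FWHM 1.7 meV
(η = 0.5) and Poisson counting noise with errors √counts (floor 1).

Scenario truth (gel 20 °C / fluid 45 °C): longitudinal speeds 2532 / 2241
m/s, transverse 582 m/s, zone boundaries 15.4 / 14.2 nm⁻¹, no gap in the gel
and a 5 nm⁻¹ transverse gap edge in the fluid.  Branches follow
ω(q) = ω_max·|sin(πq/Q_min)| with ω_max = s·Q_min/π, so the low-q slope
equals the branch speed and the first minimum falls at the zone boundary;
damping is Γ(q) = γ₀ + γ₁·q with (γ₀, γ₁) = (0.8, 0.25) / (0.25, 0.06) for
the gel longitudinal/transverse and (1.0, 0.25) / (0.8, 0.15) for the fluid —
chosen once so the damping-ratio morphology is realistic for these phases
(gel transverse R peaking ≈ 2.6 at mid-Q, gel longitudinal approaching
critical damping at high Q, fluid transverse scattered about R ≈ 1).
Default statistics: 5000 expected counts at the elastic peak, background 10
counts, integrated mode strengths 0.6×peak counts per branch (inelastic
features comparable to the elastic line, as in clean synchrotron scans);
ensemble studies that specify a different count level (e.g. 10³ peak counts)
override `peak_counts` explicitly.  Seeding: one master seed; the scan at
q-index i uses SeedSequence([seed, i]).

What the generator does **not** emulate: elastic-line anomalies, detector-arm
geometry, multilayer mosaicity, beam damage, optical branches and the ~6 meV
localized mode, or any relaxational (non-DHO) quasi-elastic dynamics.
Passing tests therefore certify the estimator pipeline under the stated
model, not the model's adequacy for real membranes.

A known consequence of the sine dispersion: near the zone boundary both
branches drop far below the 1.7 meV resolution and become undetectable
shoulders, so the two-mode model is (correctly) not selected there and the
transverse branch shows scattered absent flags at mid/high Q.  Gap detection
is unaffected because it only reads the contiguous low-Q absent run.

## Numerical choices and degenerate inputs

* Modes with Ω = 0 carry no inelastic weight in this kernel convention and
  evaluate to zero; fitted intensities and amplitudes may sit exactly on the
  zero bound, where the covariance is rank-deficient — the pseudo-inverse
  then yields large/inf errors and such modes are flagged as vanished.
* `reduced_chi_square` refuses N ≤ n_free; fits refuse under-determined
  spectra; non-convergence after all restarts is flagged, not raised.
* The two-hump diagnostic returns "not fired" on degenerate input rather
  than raising.
* Spectrum files store floats via `repr`, so a write/read round trip is bit
  exact; pipeline outputs contain no timestamps, so a rerun with the same
  config and seed is byte-identical.

## Known limitations

* The DHO normalisation used by specific beamline analysis codes is not
  standardised; absolute intensities are only comparable within this
  package's convention.
* 1σ parameter intervals use the Gaussian (linearised) approximation; their
  empirical coverage on Poisson ensembles is ~60–80%, not the nominal 68%.
* The mean reduced χ² on Poisson data with √counts errors is slightly above
  1 (≈ 1.05–1.08 at 10³ peak counts) because √counts underestimates the
  variance at low counts; this is a property of the error model, not the fit.
* Mode-count selection near the zone boundary and at high Q is conservative:
  heavily overdamped or resolution-buried modes are reported absent.
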