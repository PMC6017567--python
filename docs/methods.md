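# Methods

This note documents the models implemented in `slowbind`, the synthetic-data
generator that stands in for plate-reader measurements, the numerical choices
inside the fitters, and the limits of what the test-suite's recovery results
demonstrate.

## Kinetic models

**Steady-state rate laws.** Velocities follow the Michaelis–Menten law under
the four classical reversible-inhibition modes. Competitive inhibition
multiplies Km by (1 + [I]/Ki); uncompetitive multiplies the [S] term;
noncompetitive divides the whole rate; mixed carries an extra factor α on
the ESI branch (α → ∞ recovers competitive, α = 1 noncompetitive). All modes
reduce exactly to Vmax·S/(Km+S) at [I] = 0, which is enforced as a property
test.

**Slow binding.** A slow-binding progress curve is the closed form
`[P](t) = vs·t + (vi − vs)/kobs·(1 − e^(−kobs·t))`, valid when substrate
depletion is negligible and the inhibitor equilibrates between a fast and a
slow timescale. Under the two-step (isomerisation) mechanism — rapid E·I
formation with apparent constant Kiapp followed by slow E·I ⇌ E*·I with
rates k3/k4 — the observed relaxation rate is
`kobs = k4 + k3·[I]/(Kiapp + [I])`, and the steady-state velocity obeys
`vs = vi·k4/kobs`. The overall steady-state constant `Ki* =
Kiapp·k4/(k3+k4)` is reported alongside the fitted rates. For a competitive
slow binder `Kiapp = Ki·(1 + [S]/Km)`; this relation is exposed as a helper
(`ki_app_competitive`) and used by the simulator, but the fitters never
assume it.

**Dose–response.** Percent inhibition is
`100·(Δcontrol − Δinhibitor)/Δcontrol` from endpoint signal changes; the
dose–response model is the four-parameter log-logistic
`bottom + (top−bottom)/(1 + (IC50/[I])^h)` with the convention that it
returns `bottom` at [I] = 0.

**Units.** Time s, concentrations µM, signal AU, velocities AU/s throughout.
Absorbance is never converted to molar product: the progress-curve model is
linear in signal, so fitting in AU leaves every rate constant and
concentration parameter unchanged.

## Synthetic data generator

The generator emulates a kinetic absorbance read of a tyrosinase/L-tyrosine
type assay: a 20-minute read sampled every 10 s (121 points), substrate
375 µM (50 µL of 1.5 mM into 200 µL), inhibitor series of two-fold dilutions
6.25–100 µM plus an uninhibited control, triplicate wells. Default
full-scale signal is ≈ 0.08 AU (Vmax = 1×10⁻⁴ AU/s), consistent with a
dopachrome-like chromophore (≈ 0.0021 AU/µM at the plate path length); the
conversion is used only to check a substrate-depletion cap (10% by default),
which is recorded as a metadata warning rather than an error because the
generating model itself assumes constant substrate (trace enzyme). The
default Km = 200 µM is a placeholder recorded in every dataset's metadata —
it is a simulator setting, never treated as a known constant by the
inference stages.

Two progress-curve generators are provided and tested against each other:

- **closed form** — evaluates the slow-binding equation per concentration;
- **mechanistic** — integrates the mass-action two-step competitive scheme
  (states: E·I fraction, E*·I fraction, product) with rapid-equilibrium
  substrate binding inside the non-isomerised pool. The fast step uses
  kon = 10 µM⁻¹s⁻¹ with koff = kon·Ki; generation fails loudly if the E·I
  equilibration half-time is not shorter than the first sampling interval,
  because the closed form presupposes a fast first step. Integration uses
  LSODA at rtol 1e-8 (the ms-scale binding step next to 10⁻³–10⁻⁴ s⁻¹
  isomerisation makes the system stiff). The two generators agree pointwise
  to ≈ 3×10⁻⁵ of final signal, far inside the 1%-of-final-signal agreement
  the tests require.

**Noise model.** Progress curves: additive Gaussian with σ equal to
`noise_sd` × that curve's maximal noiseless signal (default 1%). Velocity
grids: multiplicative Gaussian (default 2%). Dose–response: additive
Gaussian in percentage points (default 2). These defaults were chosen to
reproduce the relative scatter typical of triplicate plate-reader assays;
real instruments add correlated drift, plate-edge effects and occasional
outliers that the generator deliberately omits — recovery results here
bound estimator behaviour under well-behaved noise, not under instrument
pathology. All generators are bit-reproducible given the design seed and
write their full generating parameters to a JSON sidecar.

## Inference

**Progress-curve fits.** The closed form is linear in (vi, vs) at fixed
kobs, so kobs is first profiled on a 40-point log grid spanning
0.2–200 / t_max with a linear solve at each candidate, then all three
parameters are refined by trust-region least squares (scipy, tolerances
1e-14, Jacobian-scaled). Standard errors come from the Gauss–Newton
covariance (JᵀJ)⁻¹·rss/(n−k). A straight line is always fit alongside; if
the curved model does not beat it by ΔAICc ≥ 2 the curve is flagged
`kobs_unidentifiable` (this is how an inhibitor with no time dependence is
recognised). `vs > vi` flags `activation`. Replicates at one concentration
are pooled into a single fit rather than averaged afterwards: single-curve
kobs estimates are strongly right-skewed when the transient is slow relative
to the read window, and averaging per-replicate estimates propagates that
skew into the k4 extrapolation, which pooling avoids.

**kobs–[I] fits and mechanism discrimination.** The hyperbola is fit by
weighted least squares (weights 1/se² from the pooled per-concentration
fits) with 5 log-jittered multi-starts under a fixed RNG, because k4 is
weakly identified when k4 ≪ k3. Kiapp beyond 10× the largest tested
concentration, k3 collapsing to its bound, or a singular covariance flags
the fit `poorly_constrained`. One-step vs two-step is decided by AICc
between the straight line and the hyperbola with a ΔAICc < 2 parsimony rule
favouring one-step. Model comparison uses RSS-based AICc with the RSS
floored at (1e-10 × data scale)² per point so that nested models fitting
noiseless data exactly tie and the simpler wins — without the floor the
ranking of two exact fits is decided by round-off. A consequence worth
stating: an *exactly* hyperbolic noiseless series is always called two-step
no matter how locally linear its sampled arc is, because the hyperbola's RSS
hits the floor; the "locally linear at [I] ≪ Kiapp" behaviour appears, as it
should, at any realistic noise level, and is tested that way.

A five-concentration series cannot support two-step detection at realistic
noise: at n = 5 the AICc small-sample penalty difference between the
3-parameter hyperbola and the 2-parameter line is 20, demanding an RSS ratio
below 0.012. The mechanism-discrimination study therefore samples eight
inhibitor concentrations (3.125–100 µM) in triplicate — a design any
kobs-saturation experiment needs — while the two-stage *parameter-recovery*
study keeps the five-point 6.25–100 µM dilution series with triplicate
wells.

**Mode classification.** The four global rate laws are fit to the velocity
grid and ranked by AICc; exact ties and ties within the parsimony margin go
to the model with fewer parameters (so competitive beats mixed on noiseless
competitive data, where both fit exactly). The headline Ki is the global
competitive-fit estimate with its regression SE; the Dixon construction
(1/v vs [I] per substrate, Ki = −mean pairwise intersection abscissa, SEM
over pairs) is reported alongside as the classical plot-based diagnostic,
and the two agree algebraically on noiseless competitive data. Dixon lines
are parallel under uncompetitive inhibition, so near-parallel pairs
(relative slope difference < 1e-6) are excluded and an all-parallel grid
raises an error. A per-inhibitor Lineweaver–Burk regression table with a χ²
test of a common 1/Vmax intercept is attached as the competitive-signature
diagnostic. Both SE flavours for Ki are reported (regression SE from the
global fit; spread-based SEM from Dixon intersections) since assay reports
rarely state which convention they use.

**IC50.** Log-logistic fit with IC50 on a log10 scale; plateaus fixed at
(0, 100) by default because percent inhibition is normalised to an
uninhibited control (freeing them is an option). Hill slope is bounded to
[0.05, 20]. If mean inhibition never reaches 50% the point estimate is
withheld and the result flagged `ic50_above_max_tested` with the largest
tested concentration as a lower bound.

**Orchestration.** `characterize_compound` runs whichever stages its inputs
support and enforces the invariant that two-step rate parameters are present
exactly when the kobs series is classified two-step. Preincubation is
handled purely empirically — the post-preincubation dose–response is fit
like any other; no attempt is made to predict the preincubated IC50 from
k3/k4, which would require substrate-competition assumptions the assay does
not pin down.

## Monte-Carlo study sizes

The recovery studies use 100 seeds (Dixon Ki, IC50, mechanism
discrimination) and 50 seeds (two-stage slow-binding recovery), with child
seeds spawned deterministically from one master seed. These sizes put the
Monte-Carlo error of a median well inside the tolerances checked (10% for
Dixon/IC50, 15% for the slow-binding rates) while keeping a full run in the
low minutes on one core. k4 remains the hardest quantity: its single-seed
IQR spans roughly ±60% of truth at 1% noise because it is an extrapolation
to [I] = 0 from a series whose lowest concentration sits at 2.5×k4 worth of
kobs, and only the median over seeds is claimed to be accurate.

## Known limitations

- No tight-binding (Morrison) depletion correction: inhibitor is assumed in
  large excess over enzyme.
- No substrate-depletion correction in fitting; the simulator only warns
  when its own curves breach the depletion cap.
- The mechanistic simulator implements the competitive two-step scheme
  only; other modes are available solely through the closed-form and
  steady-state generators.
- Dose–response data are taken as percent inhibition already normalised to
  control; raw-signal normalisation is out of scope.
- No stochastic simulation, enzyme inactivation, product inhibition, or
  plate-layout artifacts in the generator.
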