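# Methods

## Scale-space Riccati model

The model treats the degrading fiber system as a fractal object whose
scale-space geodesics satisfy a Riccati equation in scale time,
`dy/dt = a1 y^2 + 2 a2 y + a3` with real constant coefficients. Only the
oscillatory family is implemented: the discriminant `Omega^2 = a1 a3 - a2^2`
must be strictly positive, giving complex-conjugate roots
`tau0, tau0* = -a2/a1 +/- i Omega/a1`. Parameter sets with `Omega^2 <= 0`
(real roots, aperiodic solutions) are rejected with an explicit error
rather than modelled — they lie outside the physical family the model
uses, and silently returning a different solution type would be worse than
failing.

A note on naming: the source formulation overloads one symbol as group
parameter, independent variable and solution. Here the solution is `y(t)`,
`t` is scale time, and `tau_r`/`tau_m` are phase constants; this makes the
exponential in the closed form well defined.

The general solution is the homographic orbit

    y(t) = (tau0 + r e^{2i Omega (t - tau_r)} tau0*) / (1 + r e^{2i Omega (t - tau_r)})

with modulus `0 <= r < 1` and phase `tau_r`. Key identities, all enforced
by tests:

* `|(y - tau0)/(y - tau0*)| = r` for all t (the orbit is a circle in the
  upper half plane when `a1 > 0`);
* period `pi/Omega`;
* the trigonometric form
  `y = -a2/a1 + (Omega/a1) [2r sin(theta) + i(1 - r^2)] / (1 + r^2 + 2r cos(theta))`,
  `theta = 2 Omega (t - tau_r)`, is pointwise identical;
* the morphology field `M = Re(a1 y + a2) = Omega 2r sin(theta) / (1 + r^2 + 2r cos(theta))`
  is independent of `a2`, and its peak is `2 r Omega / (1 - r^2)` at
  `cos(theta*) = -2r/(1 + r^2)`.

The singularity guard raises if the homographic denominator falls below
1e-14 in magnitude; with `r < 1` this is unreachable, so hitting it
signals corrupted inputs rather than a physical pole.

### Harmonic-map parametrisation

The same orbits can be written through the hyperbolic map

    h = -i (cosh Phi - e^{-2i Omega (t - tau_m)} sinh Phi) / (cosh Phi + e^{-2i Omega (t - tau_m)} sinh Phi).

Two conventions deserve care. First, the identification between `Phi` and
the modulus is `r = tanh(Phi)` — the hyperbolic cotangent would put `r >= 1`
outside the oscillatory family, and direct algebra shows the tanh
identification reproduces the trigonometric bracket exactly, with the
imaginary part sign-flipped (`h = conj(bracket)`). Both the flip and the
identification are asserted numerically. Second, `|h|` is *not* bounded by
1: it ranges over `[(1-r)/(1+r), (1+r)/(1-r)]`, equal to 1 only where
`cos(theta) = 0`. The map is pole-free for all real `Phi`.

Numerical note: comparing the two parametrisations to 1e-12 in double
precision is only meaningful where the shared denominator
`1 + r^2 + 2r cos(theta)` is computed in its cancellation-free form
`(1-r)^2 + 4r cos^2(theta/2)` and the orbit magnitude stays moderate; the
verification grid uses `Phi in [0, 1.5]` (`r <= 0.905`), which covers the
modulus range `r = 0.1-0.9` the model is used with. At larger `Phi` the
near-pole magnitudes (~10^2-10^3) make 1e-12 unattainable in double
precision for any algebraically equivalent formula.

### Regime classification

The classifier labels a uniformly sampled morphology trace as
`double_period`, `intermittency`, or `degenerate`. Its design starts from
an observation about the trace family: at fixed modulus `r` the trace is
`Omega f(2 Omega t)` for a fixed shape `f`, so every statistic of the
amplitude distribution — including the quiescent duty fraction and the set
of peak heights, which are all equal within one trace — is invariant under
changes of `Omega`. The only feature that carries the frequency is burst
*timing*. The decision rule therefore uses:

* **burst rate** — peaks of `|trace|` above half the maximum, per unit
  scale time. The trace fires two bursts per period `pi/Omega`, so the
  rate is `~2 Omega/pi`: 0.64-0.70 for `Omega = 1`, 6.4-7.0 for
  `Omega = 10`, across `r in {0.1, 0.5, 0.9}`. The default threshold 2.0
  sits a factor ~3 from both groups. Rates above it label `intermittency`.
* **duty fraction** — fraction of samples with `|value| < 0.1 max`; above
  0.5 also labels `intermittency` (a burst-dominated trace regardless of
  rate).
* **gap alternation** — inter-burst intervals split into short/long
  clusters about their mean; a cluster-mean ratio above 1.05 identifies
  the double-period pattern (bursts in close pairs around `theta = pi`,
  separated by the long quiescent arc through `theta = 0`; measured ratios
  1.29-29 across `r = 0.1-0.9`). With a sub-threshold burst rate this
  labels `double_period`.
* anything else — zero/constant traces, too few peaks — is `degenerate`.

All thresholds are keyword arguments. The preconditions (>= 4 cycles,
>= 64 samples per period) are enforced on the sample count; the sampling
interval `dt` is an explicit argument because burst rate is a rate in
absolute scale time.

## Gravimetric metrics

`mass_loss_percent` and `mes` are the exact algebraic definitions; they
satisfy `MES = -W_loss/100` identically (when mass gain is permitted), and
round-trip to rounding. A measured mass above the initial dry mass is
rejected by default for degradation series — washed-and-dried masses
cannot grow — and allowed with `allow_gain=True` for swelling series.

The pH program is piecewise constant with left-closed segments: media are
replaced instantaneously in the protocol, so the new pH applies from the
replacement instant. The default schedule starts at pH 8.5 (the alkaline
inflammatory stage, the one protocol constant) and steps down
(7.5/7.0/6.5/5.5 at 24/72/120/168 h) consistent with the described
acidic trend through granulation and remodeling; the later values are
configurable placeholders, not measured constants.

The sorption summary reports the maximum uptake across both branches, the
trapezoidal integral of `|down - up|` over the shared RH range (absolute
gap, so the area is zero exactly when the branches coincide pointwise),
and whether the ascending branch is monotone. Washing/lyophilization steps
and medium-refresh events are not modelled; series are taken as
already-corrected masses.

## Log-linear swelling law

`MES(tau) = Mes0 tau + alpha ln tau` is linear in its two coefficients, so
fitting is ordinary least squares on the design `[tau, ln tau]` with no
intercept (optional nonnegative weights supported; no error model beyond
homoscedastic noise is assumed). Reported diagnostics: standard errors
from the unbiased residual variance, and the uncentered R^2 (the model has
no intercept, so centering would be meaningless). Times at `tau = 0` are
dropped with a warning rather than rejected, because experimental tables
start at immersion; negative times and rank-deficient designs are errors
naming the offending rows. A fit-window option restricts the fit, e.g. to
the first hour for compact neat-chitosan fibers where the law holds only
initially; no automatic breakpoint detection is attempted.

The law is not closed under a change of time unit (`ln(c tau)` adds a
constant the model cannot absorb), so a fit records its time unit and
`predict_log_linear` converts input times into that unit; predictions are
then exactly unit-invariant.

`gauge_consistency` checks `ln(tau^b e^{a tau}) = a tau + b ln tau`, the
identity (with the integration constant fixed to zero) that makes the
fitted coefficients `(Mes0, alpha)` the parameters `(a, b)` of the
scale-resolution law `rho(tau) = tau^b e^{a tau}`. The discrepancy is zero
to rounding on any positive grid that avoids overflow.

## Diameter morphometry

Diameters (nm) are histogrammed on bins `[k w, (k+1) w)`; the default
width `w = 20/3 nm` is the grid on which published histogram-mode values
fall. A Gaussian `A exp(-(x-mu)^2/2 sigma^2)` is least-squares fitted to
the bin-center/count pairs — deliberately a fit to the histogram, matching
how such tables are produced, not maximum likelihood on the raw data. If
the optimiser fails, sample moments are reported and the
`gaussian_fit_ok` flag cleared; a converged fit explaining less than 90 %
of the count variance (e.g. a bimodal population) keeps its values but
also clears the flag. The histogram mode is the center of the
most-populated bin, ties broken toward the smaller diameter. All
statistics are in diameter units.

## Synthetic data

The generators define the study conditions the tests run under; they are
seeded, pure functions of their parameters.

* **Degradation**: mean loss
  `q L_leach (1 - e^{-k_leach t}) + L_enz m(pH(t)) (1 - e^{-k_enz t})`,
  the simplest additive two-exponential law reproducing the two-phase
  description — not claimed as mechanism. Defaults: `L_leach = 45 %` at
  full quaternized content and `L_enz = 10 %`, so the asymptote runs from
  10 % (neat chitosan) to 55 % (pure quaternized) across compositions,
  matching the observed 15-55 % blend band; `k_leach = 0.25/h` (leaching
  complete within ~24 h), `k_enz = 0.02/h` (acting over the 7-day
  horizon); pH modifiers 1.0 at pH >= 7 and 1.5 below (abrupt decomposition
  in acidic granulation-stage media); Gaussian noise SD 1 % of initial
  mass. Noise is clipped to keep the loss trajectory non-decreasing — a
  generator convention mirroring the fact that corrected dry masses cannot
  grow.
* **Swelling**: the log-linear law plus Gaussian noise, inverted to masses
  through `wt = w0 (1 + MES)`; MES floored just above -1 to keep masses
  positive under extreme draws.
* **Sorption**: ascending branch `Umax (RH/90)^gamma` with
  `Umax = 30 + 30 q` percent (seeded jitter <= 5 %), `gamma` seeded in
  [1, 2]; the descending branch uses a smaller exponent, which dominates
  the ascending branch pointwise while sharing both endpoints, closing the
  hysteresis loop.
* **Diameters**: Normal(mean, SD) truncated positive by resampling;
  erosion multiplies each fiber by the shrink factor with lognormal-style
  per-fiber jitter (SD 0.02); a shrink factor of 1 reproduces the initial
  population exactly.

What the generators do *not* emulate: enzyme kinetics (no
Michaelis-Menten saturation or activity decay between medium refreshes),
fiber-fusion artifacts that can raise apparent diameters, correlated
measurement error within a vial, and any coupling between degradation and
swelling beyond their shared time axis. Passing tests therefore show that
the pipeline recovers parameters under its own stated statistical
assumptions, not that those assumptions hold for a particular laboratory
system.

## Problem sizes and numerics

Verification runs use 20 random parameter sets for the ODE cross-check
(adaptive RK integration at rtol 1e-10 against the closed form, max error
< 1e-6 over `t in [0, 5]`), 200 Monte-Carlo replicates at n = 50 points
and noise SD 0.2 g/g for fit-recovery checks (bias within 2-3 standard
errors), 1000-2000 diameters for morphometry recovery, and 100 seeds for
generator-band checks — sizes at which the Monte-Carlo standard errors are
small enough to detect real bias while the whole suite runs in seconds.
Classifier traces use 6 periods at 256 samples per period.

## Known limitations

* The mapping between scale time and laboratory time is not specified by
  the model; the fitting module treats them as identical up to the fitted
  constants.
* The real-root Riccati family, fractal-dimension estimation, raw SEM
  image processing, FTIR/TGA analysis, and comparisons against
  Higuchi/Peppas/Weibull release laws are out of scope.
* The regime classifier is a heuristic over peak statistics, tuned to
  separate the canonical trace families by a wide margin; traces outside
  that family (e.g. noisy or aperiodic signals) may land in `degenerate`.
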