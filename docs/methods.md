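# Methods

## Constitutive model

`fibrheo` implements a scalar (shear-only) constitutive model for fibrin
networks — the load-bearing protein scaffold of blood clots — under
oscillatory shear. It extends the Kelvin–Voigt solid,
τ = G γ + η γ̇, with the three nonlinear features such networks display
under large-amplitude oscillatory shear (LAOS):

```
τ  = G00 · x · f(γ) · γ  +  η0 · g(γ) · γ̇
f(γ) = (1 + k1 γ²)^n1          (strain stiffening)
g(γ) = (1 + k2 γ²)^n2          (nonlinear viscous dissipation)
ẋ  = −c_d (x − x_∞)   if x > x_∞   (softening)
     −c_i (x − x_∞)   otherwise    (recovery)
x_∞(γ) = exp(−a |γ|^b)
```

The network state parameter (NSP) `x` is dimensionless, non-negative, and
equals one at the reference state, taken as the start of the first LAOS
sequence. It encodes the deformation history: repeated large cycles soften
the network (fibers lengthen semi-permanently), small-amplitude rest lets it
recover (remodelling, plus continuing factor-XIIIa cross-linking), on a much
slower time scale — hence c_d ≫ c_i.

A modelling convention worth stating explicitly: `x_∞` is a function of the
*instantaneous* strain, so it oscillates within every cycle, returning to 1
at each strain zero crossing. Net cycle-over-cycle softening emerges from
the rate asymmetry, not from an amplitude-level equilibrium. An
amplitude-based variant (x_∞ of the cycle amplitude) would be a different
model; it is noted here but not implemented.

### Parameters

| name | meaning | unit | synthetic-truth default |
|------|---------|------|------------------------|
| G00  | low-strain modulus of the virgin network | Pa | 11.6 |
| eta0 | low-strain viscosity | Pa·s | 0.1 |
| c_d  | softening rate constant | 1/s | 0.1 |
| c_i  | recovery rate constant | 1/s | 1e-3 |
| a    | equilibrium-state amplitude coefficient | – | 1.5 |
| b    | equilibrium-state strain exponent | – | 1.2 |
| k1, n1 | stiffening coefficient / exponent | – | 3.0, 2.0 |
| k2, n2 | viscous coefficient / exponent | – | 4.5, 1.9 |

G00, k2 and n2 are values reported for fibrin networks polymerized for two
hours; eta0 makes the loss modulus (η0·ω ≈ 0.63 Pa at 1 Hz) a small
fraction of the storage modulus, as observed (the networks are
predominantly elastic). The remaining five constants are round values
chosen once so that the simulated ladder looks like a real experiment: peak
stresses of order 10² Pa at unit strain amplitude, softening that levels off
within each 60 s step (time constant 1/c_d = 10 s), recovery over tens of
minutes (1/c_i ≈ 17 min), and x_∞(1) = e^−1.5 ≈ 0.22. They are synthetic
truth, not literature values.

## Deformation protocol

The standard protocol is a stepped amplitude ladder at 1 Hz: seven 60 s
segments at strain amplitudes 0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0. The
0.01 lead-in probes the linear moduli. Optionally a 7200 s small-amplitude
(0.01) recovery segment follows, and optionally the ladder repeats (to test
prediction of a second run from parameters fitted on the first). Every
segment starts at phase zero, so strain is continuous at amplitude steps
while the strain rate jumps; this avoids artificial elastic stress spikes.
The lead-in is assumed to last 60 s like the other steps. The second ladder
starts from the recovery end-state (the state is carried across segments).

## Numerical integration

The state ODE is integrated with a fixed-step explicit midpoint (RK2)
scheme, the softening/recovery branch re-evaluated at every stage by
comparing x with x_∞(γ(t)). Both branches vanish at x = x_∞, so the rate is
continuous across the switch and no event location is needed; branch
switching does limit the formal order locally, but measured convergence is
second order on smooth stretches and the default step keeps the end-state
error below 1e-4. Defaults: dt = 1e-3 s (1000 samples per 1 Hz cycle — this
also sets the feature-extraction resolution), dt = 2e-3 s for sensitivity
sweeps where only cycle-level stress summaries are needed. A configuration
error is raised when dt exceeds 1/(20·f). The state is clipped at zero
(reachable only by rounding).

Long small-amplitude segments (amplitude ≤ 0.02, duration ≥ 300 s) use a
closed-form envelope instead of stepping through ~10⁷ samples: the
branch-switching relaxation is averaged over the oscillation phase, giving
an autonomous drift v(x) = c_i⟨(x_∞−x)⁺⟩ − c_d⟨(x−x_∞)⁺⟩. Below the band
swept by x_∞ the drift is exactly linear (recovery branch only, target
⟨x_∞⟩) and integrates to an exponential; inside the narrow band the drift is
linearized around its zero x*, which sits near x_∞(amplitude) when
c_d ≫ c_i. The simpler alternative — evaluating x_∞ at a single effective
strain such as the mean |γ| — misses exactly this branch asymmetry and was
measured at ~2e-3 absolute error against full integration; the
cycle-averaged form is at ~2e-5. The envelope is switchable
(`saos_envelope=False`).

## Feature extraction

Cycles are delimited by upward zero crossings of the strain within each
segment; partial cycles are discarded. Per cycle:

- γ₀ and τ₀: strain and stress at the strain maximum. The strain rate
  vanishes there, so τ₀ = G00·x·f(γ₀)·γ₀ exactly — a purely elastic reading.
- G₀, the minimal-strain modulus: the two-point slope of the loop's rising
  branch (γ̇ > 0) between γ = −0.05 and +0.05. On that branch the viscous
  offset is identical at the two points and cancels in the slope. The
  rising branch is the one whose stresses are positive near zero strain for
  a predominantly elastic material; at moderate amplitudes it is the only
  branch for which a "positive-stress" reading at γ = −0.05 is even
  defined. For amplitudes ≤ 0.05 the loop never reaches the window and the
  peak secant τ₀/γ₀ is used. The window half-width is configurable; 0.05
  is the default. A least-squares line over the window would average the
  same bias and was not preferred.
- Stresses at γ = 0.5·γ₀ and (√2/2)·γ₀ on the rising and falling branches
  (linear interpolation in strain along each monotone branch) — the strains
  where the viscous contribution is large.
- x_e = G₀/G00 and f_e = τ₀/(G00·x_e·γ₀), the experimental state and
  stiffening readings. x_e is attributed to the cycle midpoint time.

Linear-regime intervals are reduced to storage/loss moduli (G′, G″) by
least-squares projection of the stress onto the in-phase and quadrature
drive components, cycle by cycle.

**Reading bias.** A window reading at strain w measures G00·x·f(w), not
G00·x: every x_e carries the stiffening factor at its reading strain
(≈ 1.5% at w = 0.05 with the default truth). This is within the extraction
tolerance, but it is *systematic*, and because the lead-in and recovery
readings are taken at 0.01 while the ladder readings are taken at 0.05, the
mixed scales bias the fitted softening rate c_d by ~15% if ignored. The
kinetics fit therefore co-estimates a single nuisance scale s = f(w_ref)
with each observation's prediction multiplied by s^((w_i/w_ref)²) — the
small-strain limit of the stiffening law, for which ln f ∝ w². This uses
no quantity from a later fitting step and removes the bias (c_d recovers to
0.2% on noise-free data).

## Staged fitting

Parameters are determined in consecutive steps, each using only quantities
fixed before it:

0. **Linear moduli.** G00 = mean G′ and η0 = mean G″/ω over the
   0.01-amplitude lead-in cycles.
1. **State kinetics (c_d, c_i, a, b).** Weighted least squares between the
   x_e observations (ladder cycles at their midpoints, plus the recovery
   trace as G′/G00) and the integrated state at those times. The recovery
   phase carries a squared weight of 0.01 relative to the ladder after
   normalizing both phases to equal observation counts — the ratio then
   holds regardless of how densely either phase was sampled. Residuals are
   computed on x (dimensionless, comparable across phases) rather than G₀.
2. **Stiffening (k1, n1).** Least squares of f(γ₀) against the per-cycle
   (γ₀, f_e) pairs.
3. **Viscous (k2, n2).** Least squares on the four fraction stresses per
   cycle between model and observation, everything else fixed. Since
   (k2, n2) do not enter the state ODE, the state at the fraction times is
   integrated once and the residual is closed-form.

Every step uses `scipy.optimize.least_squares` (trust-region-reflective)
with bounds and random multistart (default 20 starts; log-uniform draws for
the scale-like parameters c_d, c_i, a, k1, k2, uniform for the exponents),
keeping the lowest-cost converged run. Default bounds: c_d, c_i ∈ [1e-5,
10] s⁻¹, a ∈ [1e-3, 50], b ∈ [0.1, 5], k1, k2 ∈ [0, 1e3], n1, n2 ∈ [0, 10]
— deliberately broad, covering reported fibrin values with a wide margin;
they are surfaced in the API. Fits are fully reproducible given a seed.
Degenerate data paths return flagged solutions instead of optimizing: all
f_e = 1 gives k1 = 0 with n1 unidentifiable; η0 = 0 gives k2 at its lower
bound (a closed loop carries no viscous information). All cycles with valid
fraction stresses enter step 3, not only the largest amplitudes.

Identifiability, measured on synthetic data: G00, η0, a, c_d and the
amplification products (1+k1)^n1, (1+k2)^n2 are well identified (≤ a few
percent noise-free); (k1, n1) and (k2, n2) trade off individually; c_i and
b are weakly identified (~20%) — only six amplitude levels and one recovery
trace constrain them.

## Sensitivity analysis

Three scalar outputs summarize the nonlinear features on the unit-amplitude
interval, simulated warm-started from x = 1 through the preceding ladder
steps (a cold start at γ₀ = 1 is available): O_so, the relative drop of the
cycle-peak stress between the first and last full cycle; O_ss, the first
cycle's peak stress normalized by G00; O_vi, the rising-minus-falling stress
difference at γ = (√2/2)γ₀ on the first full cycle.

Main and total Sobol indices are estimated with Jansen's formulas inside
Saltelli's paired-matrix design: n_base·(k+2) model evaluations for k
parameters (n_base = 5000, k = 8 reproduces the canonical 5·10⁴ runs).
Base points come from a Latin hypercube over the ranges by default; a
scrambled Sobol' sequence is available (`method="sobol"`) and converges
markedly faster — the estimator-validation tests use it. Negative index
estimates (Monte-Carlo noise) are reported as-is, not clipped. Bootstrap
standard errors resample base points. Parameters with zero-width ranges are
held fixed and excluded.

Ranges: `ranges_from_fits` implements the mean ± 2 SD rule over replicate
fitted parameter sets (clipped at zero), mirroring replicate experiments;
`default_ranges` provides symmetric ±50% ranges around a center set when no
replicates exist. Model evaluations are vectorized across the whole sample
matrix (one RK2 step advances all draws at once), which makes 5·10⁴ runs a
matter of minutes on one core.

A caveat established by the test suite: the classic rank pattern — kinetics
parameters dominating O_so, k2 dominating O_vi — depends on the *relative
widths* of the parameter ranges, which in replicate experiments encode
biological between-sample variability. A single-truth synthetic study has
no such variability: replicate-fit ranges reflect only noise-driven fit
scatter (c_i, for instance, is fitted almost noiselessly and gets a
near-degenerate range), and under such ranges the exponents b and n2 —
which have more leverage per relative unit than c_i and k2 — can outrank
them. The stiffening pattern ({k1, n1} dominating O_ss) is robust to this;
the O_so top-three and O_vi top-one orderings are not. See the sensitivity
acceptance test for the exact assertions.

## Synthetic data generator

Emulates the numerical output of a strain-controlled cone–plate rheometer
running the protocol: densely sampled (1 kHz) strain/stress series for the
oscillatory ladders; per-interval (30 s) storage/loss moduli for the
recovery phase, obtained by projecting short noisy stress windows onto the
drive — raw small-amplitude samples are deliberately never emitted, since
at low torque they would be noise-dominated on the real instrument too; and
the noise-free state trajectory as ground truth (written to a sidecar the
fitting CLI never reads).

Noise model: additive Gaussian on stress only (strain is the controlled
variable), SD = noise_floor + noise_rel·|τ| with defaults 0.005 Pa and 1% —
an absolute floor plus a relative term, so signal-to-noise is worst at low
torque. Not emulated: instrument compliance and inertia, evaporation,
drift, transducer resonance, or biological between-sample variability (a
single truth generates all replicates). Passing the recovery tests
therefore demonstrates correctness of the estimation machinery under the
stated noise model, not robustness to instrument artifacts.

## Problem sizes and determinism

Defaults used by the test suite and the acceptance script: full ladder at
1 kHz (4.2·10⁵ samples), recovery by envelope with 240 moduli records,
20-start fits, sensitivity at n_base = 512 (5120 model runs, dt = 2e-3 s)
and estimator validation at n_base = 8192. Every stochastic component
(noise, multistart draws, sampling designs, bootstrap) is driven by an
explicit seed and is bitwise reproducible.

## Known limitations

- Scalar shear only; no tensorial generalization.
- One recovery time constant; real fibrin shows a fast rise followed by a
  slow cross-linking-driven one, so the recovery trace is described only in
  aggregate.
- The staged fit optimizes the experiment as a whole; the resulting set is
  not necessarily the best description of any single cycle.
- Strain-controlled sinusoidal protocols only (the segment abstraction
  would admit ramps, but none are built).
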