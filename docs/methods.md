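# Methods

## The models

### Stochastic Cln3 expression

CLN3 expression is simulated as a two-stage birth–death process in molecule
counts:

* mRNA synthesis at constant rate `a1` (reduced to `r·a1` during early-G1
  suppression, the Ace2 effect in daughter cells), first-order decay `D1·m`;
* protein synthesis at `a2·exp(α·t)·m` — the exponential factor models
  ribosome content growing with cell volume at rate `α` — and first-order
  decay `D2·p`.

The base model works in counts under a constant-nuclear-volume convention,
so counts track nuclear concentration. The simulation starts at the
suppressed deterministic fixed point rounded to integers,
`Int(a1/D1·r)` and `Int(a1·a2/(D1·D2)·r)`, with Int(·) the nearest
integer (ties away from zero — any deterministic tie rule is admissible;
this is the simplest).

**Exactness for the time-varying propensity.** The translation propensity
grows with time, so the plain Gillespie algorithm does not apply directly.
We use thinning: within a look-ahead window of at most 1 min the total
propensity is bounded by evaluating the growing term at the window end;
candidate events drawn from the bound are accepted with probability equal
to the true propensity at the candidate time. Because the rate is monotone
the bound is valid and the method is exact for any `α`; with the default
`α` the bound is within 1% of the true rate, so thinning rejects almost
nothing. Correctness is tested against the deterministic rate equations
(ensemble mean within three standard errors at every checkpoint) and
against the Poisson stationary law of the mRNA marginal.

### Default kinetic parameters

The defaults were chosen once to satisfy, simultaneously, the documented
constraints on this system: a few mRNA copies at steady state, 100–200
protein copies, half-lives of a few minutes for both species, exponential
volume growth on the 1-hour doubling scale, and — because the trigger
thresholds below are fixed at 150 molecules and 1900 molecule·min — a mean
G1 length near 20 min under either trigger rule.

| parameter | value | meaning |
|---|---|---|
| `a1` | 0.693 /min | mRNA synthesis (steady state 3 copies) |
| `D1` | 0.231 /min | mRNA decay (half-life 3 min) |
| `a2` | 10.0 /mRNA/min | translation at t = 0 (protein steady state 130) |
| `D2` | 0.231 /min | protein decay (half-life 3 min) |
| `α` | 0.0115 /min | volume growth (60-min doubling) |
| `r` | 0.4 | early-G1 transcriptional capacity ratio |
| `r_duration` | 0 min | suppression window; by default `r` only sets the initial state, since that is the only place its role is fully determined |

Extrinsic (cell-to-cell) noise draws each targeted parameter independently
from a normal distribution with sd = CV × nominal, truncated by redraw to
the parameter's valid range (positive rates, `r ≤ 1`); the default CV is
20% and applies to all kinetic parameters and to the trigger thresholds.

### Trigger rules

Both rules are evaluated **exactly on the piecewise-constant event trace**:
the instantaneous rule returns the first event time at which the count
reaches the threshold, and the integration rule accumulates the exact
segment integrals and solves for the crossing time inside the crossing
segment, so neither result depends on a sampling grid. Default thresholds
are 150 molecules (instantaneous) and 1900 molecule·min (integration); both
produce a mean G1 length of ~20 min under the default kinetics, which makes
the variability comparison fair. Cells that never trigger within the
horizon (default 300 min) are reported censored and excluded from the CV,
with the censored fraction logged.

The integration rule optionally subtracts a baseline (the critical level of
the integral law) before integrating; the signed integrand is the default,
matching the law's signed integral, with a clipped-at-zero variant
selectable.

In the growing-nucleus variant the nucleus grows as `2.9 fL · exp(α·t)` and
the trace is converted to nM (1 molecule / 2.9 fL = 0.573 nM). The count
thresholds are converted to nM at the initial volume (86 nM, 1088 nM·min)
so that the two variants stay directly comparable for this parameter set;
the variant's role is robustness — the ordering "integration CV <
instantaneous CV" must survive nuclear growth, and does.

### The Whi5 integrator

With Whi5ₚ(T₀) = 0 and saturated phosphatase kinetics, dWhi5ₚ/dt = k₁·Cln3 −
k₂, the time of Start (nuclear Whi5 = Whi5ₜₒₜ − Whi5ₚ dropping to Whi5c) is
the first passage of the signed integral ∫(Cln3 − k₂/k₁)dt at
(Whi5ₜₒₜ − Whi5c)/k₁ — the integral law. The integrator treats its Cln3
input as piecewise-constant between samples and advances each segment in
closed form (linear in saturated mode, exponential relaxation in linear
mode), locating threshold crossings analytically inside the crossing
segment. This replaces a generic ODE solver with an exact method for the
input class the pipeline produces; the closed-form tests hold to 10⁻⁹.
Whi5ₚ is clamped to [0, Whi5ₜₒₜ]: the phosphorylation deficit of a cell
whose Cln3 sits below the critical level is not remembered, which is the
physical behaviour (there is no negative phosphorylation) and has a visible
population consequence discussed under *Known limitations*.

Integrator defaults: k₁ = 0.05, k₂ = 0.75, Whi5ₜₒₜ = 100, Whi5c = 40,
T₀ = 5 min (all in consistent arbitrary units; only ratios matter). They
give A = 1200 molecule·min — G1 lengths of roughly 9–60 min across the
default induction range — and put the critical level Cln3c = k₂/k₁ = 15
molecules well below the default Cln3 operating point (~130 molecules), so
even the lowest titration level sits at three times the vertical asymptote
and marginal sub-critical cells, which would drag the min_Cln3 anchor of
the asymptote search below the true critical level, stay rare.

In the linear-phosphatase regime dWhi5ₚ/dt = k₁·Cln3 − k₂·Whi5ₚ the
accumulated phosphorylation decays with memory length τ = 1/k₂; the
`memory_fit` experiment generates Whi5 nuclear-entry recovery traces
(`Whi5(t) = plateau − amplitude·exp(−t/τ)`) centred on the experimental
scale (13.7 min mothers, 10.6 min daughters) and recovers τ by nonlinear
least squares.

### Start-network model

The multi-site network is a parameterizable stand-in with the structure the
predictions require, not a transcription of any specific published equation
set: Whi5 occupies `n_sites + 1` phosphorylation states (default 4 sites,
identical rates); every state except the fully phosphorylated one is
nuclear; Cln1/2 production is autocatalytic and gated by a decreasing Hill
function of nuclear Whi5 (the SBF de-repression switch), so the loop
ignites when `feedback_strength · act(nuc) > delta`. Start is the Cln1/2
surge itself, which makes the nuclear-Whi5 level at commitment — the
effective Whi5c — an output of the loop gain. This is what produces the
weakened-feedback prediction (smaller gain → ignition at lower nuclear
Whi5 → larger effective A) without hand-setting Whi5c. Effective (A, Cln3c)
are extracted by fitting the inverse law to Start times across constant
Cln3 inputs. All four qualitative perturbation predictions (dosage ↑ → A ↑;
phosphatase ↑ → Cln3c ↑; feedback ↓ → A ↑ and Cln3c ↑; no integrator → no
inverse law) hold at the defaults and are exercised in the tests.

## The synthetic time-lapse generator

The generator emulates the experimental raw material — two-channel
fluorescence traces on a 3-min imaging grid — with known per-cell ground
truth. Design choices that matter:

* **Observed signal is a concentration.** The Cln3 channel (and the
  integrator input) is the volume-normalized concentration
  `counts · exp(−α·t)`, scaled by a reporter gain of 4 a.u. per molecule.
  Fluorescence intensity is a concentration readout, and under this
  convention the G1 Cln3 process is stationary, which is what makes
  ⟨Cln3⟩ a meaningful per-cell covariate for the inverse law. The gain
  puts intensities on the hundreds-of-a.u. scale that the fitting
  procedure's absolute constants (bin width 100 a.u., 200 a.u. search
  range) presuppose.
* **Lineage asymmetry.** Early-G1 CLN3 suppression (`r`) applies to
  daughters only — it models a daughter-specific repressor — and daughters
  carry 1.25× the Whi5 of mothers. Mothers start G1 at full capacity.
* **Cell-to-cell Whi5 variability scales the reserve.** Extrinsic noise on
  the integrator multiplies (Whi5ₜₒₜ − Whi5c), i.e. the integration
  threshold A, rather than Whi5ₜₒₜ alone; perturbing Whi5ₜₒₜ independently
  of Whi5c occasionally collapses the reserve to zero and creates
  unphysical cells that commit instantly.
* **Nuclear entry/export ramps.** The Whi5 channel is the integrator's
  nuclear concentration wrapped in logistic ramps: entry (τ = 1.5 min)
  centred at G1 start, export (τ = 0.75 min) centred 1 min after
  commitment with the nuclear level held at its Start value through the
  export window. With this shape the steepest descent of the noiseless
  signal falls at T_G1, so the derivative-based G1 extraction recovers the
  true G1 length within one frame — the generator's recovery contract.
* **Measurement noise** is multiplicative lognormal, mean 1, default CV
  10% per time point, applied to both channels and to cell area.
* **Default titration** spans induction scales 0.3–1.5× at 120–150 cells
  per level with a 180-min observation horizon. The cap at 1.5× keeps the
  shortest mean G1 a few frames above T₀ (shorter G1 cannot be resolved at
  a 3-min cadence); the 3-hour horizon is a realistic movie length and
  bounds the marginal sub-critical passers discussed below.

Scenario knobs cover whi5Δ (cells pass Start at T₀ + 1 min; their G1
readout is a plateau marker with the same ramps, as there is no Whi5 to
image), a Bck2 bypass cap on G1 (default 29 min), Whi5 dosage, phosphatase
and feedback scaling, and the mother/daughter mix.

What the generator does **not** model: pixel-level imaging artifacts
(the pipeline starts from extracted intensity traces), mRNA localization
control, cell-size feedback on transcription, nutrient-shift transients,
and any correlation structure of measurement noise in time. Passing tests
therefore demonstrate correctness of the *analysis machinery* and internal
consistency of the models on data that embodies the integrator mechanism —
not that real microscopy data meets the generator's assumptions.

## Trace analysis

* **Smoothing**: penalized smoothing spline per channel, stiffness chosen
  by generalized cross-validation by default, fixed override available.
* **G1 extraction**: nuclear entry is the maximum of the smoothed signal's
  first derivative, exit the minimum, searched on a dense grid with two
  frames trimmed at each end. Among descent candidates (local minima of
  the derivative at least a quarter as steep as the steepest descent,
  whose level drops below half the running G1 peak shortly afterwards) the
  **last** is taken: nuclear export at Start is the final strong descent —
  only background follows it — whereas the gradual integrator discharge
  and transient noise dips are followed by further signal. Without this
  disambiguation ~1% of noisy traces yield a mid-G1 exit whose tiny
  ⟨Cln3⟩ then corrupts the min_Cln3-anchored asymptote search below.
  Traces with no qualifying extrema are rejected and counted.
* **Quantification**: Whi5ₜₒₜ = maximum nuclear Whi5 during G1 (a slight
  underestimate of the true total, since the entry ramp suppresses the
  first frames); ⟨Cln3⟩ = trapezoidal time-average over G1; integral A
  estimate = product with T_G1; growth rate by linear fit of log(area),
  rejected when the slope's standard error reaches 0.02 or with ≤ 6 points.
* **Log–log fit**: T₀ fixed at 5 min (Whi5 marker) or 12 min (MCM marker);
  Cln3c grid-searched at 1 a.u. resolution over [min_Cln3 − 200, min_Cln3]
  with min_Cln3 the lowest ⟨Cln3⟩ that passed Start (fixed at 0 for whi5Δ);
  records binned by Cln3 intensity (width 100 a.u.); only bins with more
  than 10 points used; per-bin **medians** fitted by least squares in
  log–log space. Two selection modes for Cln3c: best R², or slope closest
  to −1. The default is *closest to −1*: R²-selection is measurably biased
  toward low Cln3c (and hence steep slopes) because bin medians near the
  vertical asymptote sit above the fitted line by convexity, an effect
  visible even on noiseless data. Both modes agree on clean data and both
  remain available; the fit reports which was used.

## Numerical and procedural choices

* Event-trace first passages, integrator segments and crossing times are
  closed-form; no tolerance enters them. The network ODE uses LSODA with
  rtol 10⁻⁸/atol 10⁻¹⁰ and event detection on the dense output.
* Threshold calibration bisects geometrically (thresholds span decades)
  under common random numbers, so the simulated mean is a monotone
  deterministic function of the threshold; an all-censored candidate is
  treated as mean = horizon, and a target above the horizon reports
  "not bracketed".
* Experiment seeds are spawned from a root `SeedSequence`, so every run is
  a pure function of (config, seed), and paired model comparisons reuse
  the same simulated cells for both trigger rules.
* Problem sizes used by the shipped experiments: 2000 cells for the
  trigger-model comparison, 750 cells across 5 induction levels for the
  inverse-law recovery, 200 traces per lineage for the memory fit — sizes
  at which the reported statistics are stable to well within their stated
  tolerances while a full run stays in the tens of seconds on one core.

## Known limitations

* **Clamped deficit and the asymptote search.** Because Whi5ₚ cannot go
  negative, a cell whose Cln3 hovers below Cln3c accumulates no deficit;
  given a long enough observation window, rare such cells drift across
  Start on fluctuation pulses with a lifetime-average Cln3 *below* the
  asymptote. They are physical, but they drag min_Cln3 — and with it the
  upper edge of the Cln3c search grid — below the true critical level,
  steepening the recovered slope. A 3-hour horizon keeps this negligible
  at the default operating point; analyses of much longer movies should
  treat the min_Cln3 anchor with care.
* The shortest G1 lengths resolvable at a 3-min cadence are ~2 frames
  above T₀; conditions expected to produce shorter G1 (very high Cln3)
  are outside the generator's default range and would bias extraction.
* The Start-network module is a structural stand-in: it reproduces the
  qualitative perturbation directions, not any quantitative fit.
* The whi5Δ scenario's G1 readout is an idealized plateau marker; real
  alternative markers have their own kinetics, captured here only through
  the larger fixed T₀ offered for MCM-marker fits.
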