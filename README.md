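# startint

Models and analysis tools for **time-integrated triggering of the budding-yeast
Start transition** — the G1/S commitment point at which a cell irreversibly
enters a new division cycle.

The upstream G1 cyclin Cln3 is a noisy signal: a few mRNA copies, 100–200
protein copies, and half-lives of a few minutes. How does a cell commit
reliably on such a signal? This package implements and compares the two
competing hypotheses:

* **Instantaneous Model** — Start fires the first time the Cln3 level itself
  crosses a threshold.
* **Integration Model** — Start fires when the *time integral* of Cln3
  crosses a threshold, physically realised by Cln3–Cdk1 activity accumulating
  as phosphorylated Whi5: the repressor Whi5 acts as the signal integrator.

With saturated phosphatase kinetics, dWhi5ₚ/dt = k₁·Cln3 − k₂ together with
Whi5 + Whi5ₚ = Whi5ₜₒₜ yields the **inverse law**

```
T_G1 − T₀ = A / (⟨Cln3⟩ − Cln3c),    A = (Whi5ₜₒₜ − Whi5c)/k₁,   Cln3c = k₂/k₁
```

so G1 length is inversely proportional to the mean Cln3 signal above the
critical level, with a minimum G1 length T₀ and, in the linear-phosphatase
regime, a finite memory window τ = 1/k₂ beyond which accumulated
phosphorylation is erased.

## What is in the package

| module | contents |
|---|---|
| `startint.cln3_stochastic` | exact (thinning) Gillespie simulation of CLN3 mRNA/protein with growth-coupled translation, extrinsic parameter noise, count→nM conversion |
| `startint.trigger_models` | first-passage G1 lengths under both trigger rules, ensemble statistics, threshold calibration, peak-coincidence test |
| `startint.whi5_integrator` | the Whi5ₚ integrator (saturated & linear modes, closed-form per segment), the integral law, memory length, and a multi-site + positive-feedback Start-network ODE |
| `startint.trace_analysis` | spline smoothing, derivative-based G1 extraction, per-cycle quantification (Whi5ₜₒₜ, ⟨Cln3⟩, integral A), growth-rate and memory-length fits, the binned log–log slope fit |
| `startint.synthetic_data` | single-cell time-lapse generator (3-min grid, measurement noise, induction/dosage/phosphatase/feedback/whi5Δ/Bck2 scenarios) with per-cell ground truth |
| `startint.pipeline` | the four canonical experiments as reproducible, seeded runs |

## Worked example

Simulate 300 cells under each trigger rule with both intrinsic (molecular)
and extrinsic (20% cell-to-cell) noise, thresholds at their defaults:

```sh
$ startint simulate-tg1 --model instantaneous --threshold 150 \
      --n-cells 300 --extrinsic-cv 0.2 --seed 7
{
  "model": "instantaneous",
  "threshold": 150.0,
  "n": 300,
  "mean_tg1_min": 18.92,
  "sd_min": 15.96,
  "cv": 0.844,
  ...
}
$ startint simulate-tg1 --model integration --threshold 1900 \
      --n-cells 300 --extrinsic-cv 0.2 --seed 7
{
  "model": "integration",
  "threshold": 1900.0,
  "n": 300,
  "mean_tg1_min": 19.70,
  "sd_min": 7.32,
  "cv": 0.371,
  ...
}
```

Both rules are calibrated to the same ~19–20 min mean G1 length, but the
instantaneous rule's G1 variability (CV ≈ 0.84 here, ≈ 0.92 at n = 2000) is
more than twice the integration rule's (CV ≈ 0.37): integrating the signal
averages its noise away, which is the core argument for Whi5 as an
integrator. The same comparison as a full experiment, including the
growing-nucleus variant and the peak-coincidence test:

```sh
startint run model_comparison --seed 1 --out out/modelcmp
startint run inverse_law      --seed 1 --out out/invlaw
startint run perturbations    --seed 1 --out out/perturb
startint run memory_fit       --seed 1 --out out/memory
```

Each run writes `report.json` (resolved config and seed embedded) and
`records.csv`; identical seeds reproduce identical numbers. The
`inverse_law` report contains the binned log–log fit — on the default
synthetic titration its slope is −1.00 ± 0.02 with Cln3c recovered within a
few a.u. of the generator's value — and `perturbations` checks the model's
qualitative predictions (integration threshold A rises with Whi5 dosage and
with weakened Cln1/2 feedback, Cln3c rises with phosphatase activity, whi5Δ
destroys the inverse proportionality, Bck2 caps G1 at low Cln3).

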