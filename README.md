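# slowbind

Analysis of reversible and slow-binding (time-dependent) enzyme inhibition
from plate-reader assays, built around the workflow used to characterise
small-molecule tyrosinase inhibitors: percent-inhibition and IC50
dose–response analysis, inhibition-mode classification with Lineweaver–Burk
and Dixon diagnostics, and slow-binding progress-curve analysis resolving the
two-step (isomerisation) binding mechanism. A synthetic assay-data generator
with matched statistical structure makes every stage testable without
laboratory data.

## The kinetics

For a reversible inhibitor the steady-state velocity follows the
Michaelis–Menten law under one of the classical modes; competitive
inhibition scales the apparent Michaelis constant:

    v = Vmax·[S] / (Km·(1 + [I]/Ki) + [S])

A slow-binding inhibitor produces curved progress curves: product signal

    [P](t) = vs·t + (vi − vs)/kobs · (1 − exp(−kobs·t))

relaxes from the initial velocity `vi` to the steady-state velocity `vs`
with first-order rate `kobs`. If binding is a single slow step, `kobs` rises
linearly with `[I]`; if a rapid encounter complex E·I (apparent constant
`Kiapp`) isomerises slowly to a tighter complex E*·I (forward `k3`, reverse
`k4`), `kobs` saturates hyperbolically:

    kobs = k4 + k3·[I] / (Kiapp + [I])

The package fits the progress-curve model per curve, fits the `kobs`–`[I]`
relation, discriminates one-step from two-step binding by AICc, classifies
the inhibition mode by global rate-law fits (with Lineweaver–Burk
common-intercept and Dixon-intersection diagnostics), and fits log-logistic
dose–response curves for IC50, including the preincubation variant used to
expose slow binding. Units package-wide: time s, concentration µM, signal AU.

## Worked example

Characterise a synthetic slow-binding competitive inhibitor end to end
(generating truths: Ki = 10.3 µM, IC50 = 39.7 µM, preincubated IC50 =
13.2 µM, k3 = 0.0041 s⁻¹, k4 = 0.0004 s⁻¹, Kiapp = 35.8 µM):

```python
import slowbind as sb

truth = sb.TwoStepBindingParams(k3=0.0041, k4=0.0004, Kiapp=35.8)
mech = sb.mechanism_from_kiapp(truth)
progress = sb.simulate_progress_mechanistic(
    sb.AssayDesign(inhibitor_concs=(0, 3.125, 6.25, 12.5, 25, 37.5, 50, 75, 100),
                   replicates=3, noise_sd=0.01, seed=1), mech)
grid = sb.simulate_steady_state(
    sb.AssayDesign(inhibitor_concs=(0, 12.5, 25, 50),
                   substrate_concs=(93.75, 187.5, 375, 750),
                   replicates=3, noise_sd=0.02, seed=2),
    sb.MechanismSpec(inh=sb.InhibitionModel("competitive", 10.3)))
dose = sb.simulate_dose_response(
    sb.AssayDesign(inhibitor_concs=(6.25, 12.5, 25, 50, 100), replicates=3, seed=3),
    sb.DoseResponseParams(ic50=39.7))
dose_pre = sb.simulate_dose_response(
    sb.AssayDesign(inhibitor_concs=(6.25, 12.5, 25, 50, 100), replicates=3, seed=4),
    sb.DoseResponseParams(ic50=13.2))

result = sb.characterize_compound("compound-A", progress=progress,
                                  steady_state=grid, dose=dose,
                                  dose_preincubated=dose_pre)
print(result.summary())
```

prints

```
compound: compound-A
  inhibition mode : competitive (Ki = 10.3 ± 0.23 µM)
  Dixon Ki        : 10.3 µM
  IC50            : 40.3 µM
  IC50 (preincubated): 13.3 µM
  binding kinetics: two_step
    k3 = 0.00412 s⁻¹, k4 = 0.000621 s⁻¹, Kiapp = 45.5 µM
```

The mode is called competitive with the global-fit Ki (± its regression SE)
agreeing with the Dixon-plot estimate; both IC50s are recovered within the
noise; the kobs–[I] series is classified as two-step isomerisation. The rate
constants of the slow step illustrate single-experiment spread at 1% signal
noise — `k3` is tight while `k4` and `Kiapp` (set by extrapolation and
curvature of a five-to-eight-point series) scatter more; the Monte-Carlo
studies below quantify this.

The same pipeline is scriptable from a shell:

```
slowbind simulate --kind progress --seed 1 --out-dir runs/demo
slowbind fit progress runs/demo/data.csv --out runs/demo/fits.json
slowbind fit characterize --progress runs/demo/data.csv --out runs/demo/report.json
```

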