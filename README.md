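# growthdeath

Drug response is almost always summarized by viability — live-cell number
relative to an untreated control. But a compound that halts division and a
compound that kills cells can produce *identical* viability curves while
doing very different things to a tumor: cytostatic arrest leaves a persister
population behind, and the route of cell death (apoptotic or not) shapes the
immune response. `growthdeath` separates these phenotypes. It is built for
scientists analyzing time-lapse imaging experiments in which three percent-of-
image-area channels are recorded per well: phase confluence (all cells),
Annexin V (apoptotic cells), and YOYO-3 (membrane-permeabilized cells).

## The model

A population is tracked per starting cell in four compartments — live (L),
early apoptotic (E), late apoptotic (D_a), non-apoptotic dead (D_n):

    dL/dt   = (R_g − R_d) L
    dE/dt   = R_d f L − τ E
    dD_a/dt = τ E
    dD_n/dt = R_d (1 − f) L

with division rate `div` (R_g), death rate `deathRate` (R_d), apoptotic
fraction `apopfrac` (f), and early→late apoptosis transition rate `d` (τ),
all per hour. Death moves cells between compartments without removing them,
so confluence tracks `L+E+D_a+D_n`, Annexin V tracks `E+D_a`, and YOYO-3
tracks `D_a+D_n`. The system has an exact solution (certified against
adaptive numerical integration to <1e−8), and the model is fit to whole
experiments by ensemble MCMC with per-condition rates, shared channel
conversions/backgrounds/noise, and literature-standard priors. Dose–response
couples through Hill curves with shared EC50/slope and separate maximal
effects for growth inhibition and death.

Three analyses sit on top:

* **identifiability** — fit the same growth+death model to viability-only
  dose–response data and quantify how badly growth and death are confounded
  (the net rate γ = R_g − R_d is all viability can see);
* **interaction** — compare classical Bliss independence on viability with a
  growth/death-aware additive null (growth-rate reductions add, death rates
  add) on two-compound dose grids, exposing spurious interaction calls;
* **synthetic_data** — seeded generators for every experiment type, so the
  whole pipeline is testable end to end without downloads.

## Worked example

Fit a synthetic doxorubicin-like experiment (5 doses × 3 replicates × 25
scans over 72 h) and read off the rates at the top dose:

```python
import growthdeath as gd
from growthdeath.synthetic import fixture_truth, generate_single_agent

truth = fixture_truth("DOX-like", seed=0)
table = generate_single_agent(truth)          # tidy three-channel table
post = gd.fit_experiment(table, seed=1)
print(post.summary())
```

The top-dose rows of the posterior summary:

```
              parameter   mean     sd    q05    q50    q95      ess
      div[DOX-like@160] 0.0058 0.0003 0.0053 0.0058 0.0063 867.6
deathRate[DOX-like@160] 0.0051 0.0008 0.0039 0.0051 0.0065 830.2
 apopFrac[DOX-like@160] 0.7249 0.0913 0.5836 0.7215 0.8834 838.3
        d[DOX-like@160] 0.0166 0.0125 0.0034 0.0134 0.0409 809.2
```

The generating truth at 160 nM was div = 0.0059, deathRate = 0.0038,
apopFrac = 0.85, d = 0.035 1/h: division is pinned to two significant
figures, death to the right scale, and the apoptosis parameters are
recovered with honest, wider uncertainty. For the motivating confounding
result, ask what a *fixed* 75% viability drop at 72 h implies:

```python
print(gd.viability_tradeoff(0.25, 0.0315, 72.0, [0.0, 0.5, 1.0]))
```

```
 split    div  death_rate  divisions  deaths
   0.0 0.0122      0.0000     1.4150  0.0000
   1.0 0.0315      0.0193     3.6398  2.2248
```

A purely cytostatic and a purely cytotoxic explanation of the same viability
differ by 2.2 dead cells per starting cell — viability alone cannot tell
them apart.

A command-line interface wraps the same library:

```sh
growthdeath simulate --fixture NVB-like --seed 3 --out sim/
growthdeath fit-kinetic --input sim/experiment.csv --out fit/ --seed 4
growthdeath fit-combination --input grid.csv --out combo/ --plot
growthdeath diagnose --run fit/posterior_draws.npz --run fit2/posterior_draws.npz
```

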