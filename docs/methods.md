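# Methods

## Compartment model

Cells occupy four states per starting cell: live `L`, early apoptotic `E`,
late apoptotic `Da`, non-apoptotic dead `Dn`. Live cells divide at `div`
(R_g, 1/h) and die at `deathRate` (R_d, 1/h); a fraction `apopFrac` (f) of
deaths enters early apoptosis and converts to late apoptosis at rate `d`
(τ, 1/h), the rest permeabilize immediately. Death never removes cells from
the dish (no clearance or detachment), so the total population obeys
d(total)/dt = R_g·L. With γ = R_g − R_d and φ(x) = (e^x − 1)/x, the exact
solution from (1, 0, 0, 0) is

    L(t)      = e^{γt}
    deaths(t) = R_d t φ(γt)                    (cumulative dead cells)
    E(t)      = R_d f t e^{−τt} φ((γ + τ)t)
    Da(t)     = f·deaths(t) − E(t)
    Dn(t)     = (1 − f)·deaths(t)

This form makes the bookkeeping identities explicit — total = 1 + divisions,
deaths = E + Da + Dn — and is continuous through the degenerate denominators
γ → 0 and γ → −τ, handled by a series expansion of φ below |x| < 1e−9.
The closed form is certified against adaptive Runge–Kutta integration
(DOP853, rtol 1e−12) over a 500-point random parameter grid that includes
both degeneracies; agreement is ~1e−11 in absolute state units. The
certification grid spans division rates to 0.05/h and death rates to 0.1/h:
beyond that the state magnitude e^{γt} makes a fixed absolute tolerance
meaningless in double precision, and no condition in scope grows faster than
a 14-hour doubling.

Cumulative divisions and deaths are the integrals of R_g·L and R_d·L,
i.e. R·t·φ(γt), with the γ → 0 limit R·t. `viability_tradeoff` apportions a
fixed viability drop between growth inhibition and death (split s: the total
rate effect Δ = −ln(V)/t is divided as R_d = sΔ, R_g = g0 − (1−s)Δ) and
reports the resulting turnover; rows where the growth share would drive
R_g < 0 are flagged infeasible.

## Observation model

Channels are percent of image area: confluence counts every compartment,
Annexin V counts E + Da, YOYO-3 counts Da + Dn. Each channel has a
conversion factor (percent area per starting-cell unit), a background
offset, and an additive Gaussian noise scale. Default conversions are
(5, 2, 2) % per cell unit — a 1.5e3-cell seeding is about 5% initial
confluence, and drug-free wells then reach ~48% at 72 h, keeping every
channel inside [0, 100]. Default noise is 0.5% (phase) and 0.2%
(fluorescence) absolute; backgrounds default to 0.1%. Percent areas live on
[0, 100], so the fitting likelihood treats observations at the floor or
ceiling as left/right-censored Gaussians (exactly matching how the
generators truncate their noise); fluorescence readings near background are
frequently at the floor, and ignoring the censoring measurably biases the
death-rate posterior.

## Inference

Whole experiments are fit jointly: four rates per drug condition plus one
shared set of conversions, backgrounds and per-channel noise scales. Priors:
div ~ Uniform(0, 0.35)/h; deathRate and d ~ log-normal with natural-scale
median 0.01/h and sd 0.5 in log10 units (the only self-consistent reading of
a "mean" stated with a log10-scale sd); apopFrac ~ Uniform(0, 1) (no prior
is stated for it anywhere, and Beta(1,1) is the neutral choice);
backgrounds ~ log-normal median 0.1%, sd 0.1 log10; conversions ~ log-normal
centered on the calibration values with sd 0.05 log10 (counting ~100 cells
in a calibration field pins the conversion to ~10%; pairwise channel-overlap
calibration is treated as folded into these conversions rather than modeled
separately); noise sd ~ half-normal(1.0%).

Sampling uses an affine-invariant ensemble (emcee) in an unconstrained
parameterization (logit for bounded, log for positive parameters), with
differential-evolution moves — the posterior has pronounced ridges
(f ↔ conversion, d ↔ f at late times) along which stretch moves mix poorly.
Walkers start in a small ball around an approximate posterior mode found by
simplex polishing from moment estimates (per-condition rate guesses read off
the replicate-mean channels at the final scan, plus a coarse likelihood scan
over candidate d values — d is the least identified direction and the one
prone to local optima). Defaults: 64 walkers, 1500 tuning steps, 500 kept
steps (32,000 draws). Effective sample sizes come from the ensemble's
integrated autocorrelation time; the convergence gate requires ESS > 200 for
every gated parameter, retries once with doubled tuning, and otherwise
returns the posterior flagged unconverged rather than failing silently.
`diagnostics` compares ≥2 independent runs: per-parameter ESS, Geweke
first-vs-second-half z-scores, and between-run mean-difference z-scores;
the pass/fail gate is the ESS threshold.

End-point mode applies the identical model to the first and last scan of
each condition. Per condition this leaves three informative channel values
for four rates, so the (f, d) pair is under-determined and the posterior
blends toward the d prior; division and death rates remain accurate when the
truth's d is near the prior's center and the death-rate estimate degrades
smoothly as it moves away (measured ~1%/10%/30% deviation from the kinetic
fit at true d = 0.01/0.02/0.04 per hour). This is the price of end-point
throughput and is why the kinetic mode is the reference.

## Viability-only identifiability analysis

The Fig.-1-style analysis fixes the drug-free growth rate (0.0315 1/h,
measured) and zero drug-free death, then fits viability
V(c) = exp(−[(g0 − g_min) + d_max]·h(c)·t) with a shared Hill curve h(c).
Only the sum of the growth effect and the death effect enters, so the
likelihood is exactly blind to the split — the structural confounding the
package exists to demonstrate. Priors: minimum growth rate uniform on
(0, g0); maximal death rate log-normal median 0.01/h, sd 2.0 log10; Hill
slope log-normal median 1, sd 1 log10; EC50 log-uniform over the assayed
range padded a decade each side (no EC50 prior is stated in the source
analysis); residual sd half-normal(0.1). The reference synthetic assay is a
12-point 2-fold dilution series reaching 32× EC50, N = 3, 2% viability
noise — a standard plate design whose wide top keeps the plateau pinned.
`effect_correlation` reports the correlation of the implied growth and
death *rates* at a reference dose, which the confounding ridge drives
toward +1; the maximal effect sizes are anticorrelated along the same ridge.

## Drug combinations

The interaction null combines growth-rate reductions additively
(div = g0·max(0, 1 − I_A − I_B)) and death rates by summation. Additive rate
effects add in the exponent of L(t), so live-cell viabilities multiply —
this null *is* Bliss independence at the viability level, which is why it is
the right mechanistic reading of "Bliss additivity for the growth rate". An
independence combination of the inhibition fractions
(I = I_A + I_B − I_A·I_B) is available as an option; it predicts less
combined inhibition and makes even two purely cytostatic compounds deviate
from viability-Bliss by 4–8 percentage points at realistic maximal effects.

Bliss-on-viability is evaluated exactly as a screening analysis would:
proportional decrease in confluence relative to the in-grid control,
single-agent decreases read off the grid edges, predicted combined decrease
a + b − ab, deviation = observed − predicted (synergy positive). Because
dead cells keep occupying image area, an additive cytostatic + cytotoxic
pair *necessarily* deviates from confluence-Bliss — one can show
dev·e^{g0t} = R_d·t·[e^{−v}φ(u) − φ(u − v)] < 0 for any growth effect v > 0,
so within this model family the artifact appears as spurious *antagonism*
of magnitude up to ~0.08, while the rate-aware model explains the same grid
with deviations under 0.02. Positive (synergistic) Bliss deviations of real
confluence data additionally involve effects outside this model, e.g.
control-well saturation: if the control saturates by a factor c, the Bliss
map gains a positive term ≈ (1 − 1/c)·dec_A·dec_B. The point either way is
that the viability-level analysis reports an interaction where the rates are
strictly additive. Deviation maps average the per-scan map over the three
scans nearest the requested time: the systematic deviation drifts slowly
while read noise is independent per scan, and single-scan triplicate maps
carry ~±0.01 noise per cell, which would swamp the quiet-map comparisons.

The combination fit shares one apopFrac and one d across the grid (as the
source analysis does), gives each compound its own EC50 (log-uniform over
its dose range), Hill slope (log-normal median 1, sd 1 log10), maximal
growth inhibition (Beta(1,1)) and maximal death rate (log-normal median
0.01/h, sd 0.5 log10), and fits the drug-free growth rate with a log-normal
prior median 10^−1.5/h, sd 0.1 log10, with zero drug-free death.

## Synthetic data

Generators emulate IncuCyte-style experiments: triplicate wells scanned
every 3 h over 72 h, multi-dose single agents, dose-grid combinations with a
0-dose edge and control, and end-point viability assays (live-cell ratio
plus 2% Gaussian noise, floored at a small positive value). All generators
are deterministic given the TruthSpec seed. Named fixtures ("DOX-like",
"NVB-like", "OSI-906-like", "binimetinib-like", "LCL161-like",
"PIM447-like") are phenotype archetypes — growth-dominant, death-dominant,
growth-only, death-only, mixed — with magnitudes chosen to be realistic for
a 72-h assay (control growth 0.0315/h; maximal death rates 0.004–0.03/h;
EC50s in the nM–µM range); they are design choices, not measurements of the
eponymous compounds.

`generate_recovery_experiment` implements simulation-based calibration for
the kinetic fit: every weakly identified parameter the fit estimates
(per-condition death rate, apopFrac, d; conversions; backgrounds) is drawn
from its inference prior, division rates follow a Hill curve across five
doses, and the generating rates are returned with the table. Under this
design posterior credible intervals are calibrated by construction, so
repeated fits measure the implementation rather than the luck of a fixed
truth; empirical 95%-interval coverage across 20 independent experiments is
85–95% per parameter with near-uniform posterior ranks.
`prior_central_truth` provides the complementary single benchmark truth with
all weakly identified parameters at their prior centers, used to compare
fitting modes against each other.

What passing on synthetic data does not show: real images bring segmentation
error, dead-cell shrinkage and detachment, confluence saturation near 100%,
heteroscedastic and temporally correlated noise, and drifting backgrounds —
none of which are in the generator. Results on real plates therefore inherit
the model's assumptions, most visibly the no-clearance assumption behind the
confluence mapping.

## Numerical choices and limitations

* Time unit is hours throughout; per-day reporting is a ×24 display option.
* Equal-tailed posterior quantile intervals everywhere.
* φ uses a second-order series below |x| < 1e−9; exponent overflow in
  far prior tails is mapped to −inf log-posterior.
* The Nelder–Mead mode search is approximate by design; the ensemble
  corrects it during tuning. The ESS gate is the guard against the rare
  failure of that assumption.
* No cell-cycle or age structure, no delayed death, no dead-cell clearance,
  no hierarchical pooling across cell lines, no Loewe/Chou–Talalay/ZIP
  synergy scores (Bliss variants only).
* Wide plate exports are supported through the `reshape` subcommand with an
  explicit platemap; the tidy CSV schema is the single interchange format.
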