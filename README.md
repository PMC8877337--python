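# camdensity

Abundance and density estimation for **unmarked species** from camera-trap
data, built around the method-comparison problem that wildlife ecologists
face with species like the dhole (*Cuon alpinus*): no pelage patterns, no
individual identification, and therefore no conventional capture–recapture.
The package implements four estimators over one deployment/detection data
model, a seeded synthetic-data generator for each, and a scenario runner
that produces method-comparison tables — so each estimator can be validated
by parameter recovery and their failure modes compared on a common design.

## The estimators

**Space-to-event (STE).** At an instantaneous snapshot (1-s ticks), scan
the camera stations in random order and record the cumulative viewshed area
*S* until the first station containing an animal. Under random placement,
*S* ~ Exponential(λ) with λ the density (animals/m²); snapshots with no
animal are censored at the total active area *A*. The censored-exponential
MLE is closed form:

    λ̂ = n_events / (Σ s_j + Σ_censored A),   SE(λ̂) = λ̂/√n_events

with a log-scale Wald 95% CI, N̂ = λ̂ × study area, density per 100 km².

**Time-to-event (TTE).** One-hour occasions every two hours, subdivided
into periods of length (viewshed crossing distance)/(movement rate); the
period *T* of first detection at a station with area *a* has hazard λ·a per
period, censored at *J* periods. λ̂ = n_uncensored / Σ a_j T*_ij. Unlike
STE, TTE inherits movement-rate error and trail-placement bias.

**Site-based abundance (SBA).** The beta-binomial/Poisson mixture for
site × occasion counts: N_i ~ Poisson(λ), C_ij ~ Binomial(N_i, p_ij),
p_ij ~ Beta(α, β), with derived correlation ρ = 1/(α+β+1) and mean
detection p_ab = α/(α+β). Fitted by a Metropolis-within-Gibbs sampler
(detection probabilities integrated out analytically; 10,000 iterations ×
5 chains, burn-in 2,000 by default) under three gamma priors on λ —
uninformed (0.01, 0.01), partially informed (5, 3), constrained (20, 15) —
with split-chain R-hat convergence diagnostics.

**SECR.** For the individually identifiable control species: likelihood
spatially explicit capture–recapture with a half-normal detection function
λ(d) = λ₀ exp(−d²/2σ²), Poisson count detectors, and activity centers
integrated over a habitat mask (buffer 4σ, iterated from a pilot fit).

Plus **direct counts** (minimum known alive: distinct individuals, or
summed distinct pack sizes) as the model-free floor.

## Worked example

Generate the study-mimicking dataset (27 paired-camera stations, three
16–18-day blocks, a pack-living species and a solitary marked species) and
run the comparison:

```sh
python analysis/01_simulate_study.py
python analysis/02_fit_event_models.py
python analysis/03_fit_sba.py
python analysis/04_fit_secr.py
python analysis/05_compare_methods.py
```

which prints (seed 42):

```
        largest: N =    75.6 ±   6.0  D =  21.53/100 km²
    largest+10%: N =    68.7 ±   5.4  D =  19.57/100 km²
    largest+20%: N =    63.0 ±   5.0  D =  17.94/100 km²
TTE spread across rates/scenarios: N 907–3260 (trail-biased, inflated as expected)
   uninformed: N_tot =  221.6 [206, 242]  p_ab = 0.105  rho = 0.818  max R-hat = 1.010
SECR: D = 1.98 ± 0.72 /100 km², sigma = 2661 m, lam0 = 0.149
direct counts: 26 grouped animals (pack sums), 8 solitary individuals
```

The true simulated population is 26 grouped animals. STE is the least
biased unmarked-species estimator (enlarging the assumed viewshed lowers
the estimate, as the scenario rows show); TTE explodes because the
simulated cameras sit on trails the animals preferentially use, inflating
the encounter hazard; SBA overstates total abundance by ~8× because sparse,
within-pack-correlated group counts violate its independence assumptions;
SECR tracks the solitary species using the spatial information in its
recaptures.

The same fits are available per method from the command line, e.g.

```sh
camdensity ste --deployments results/study_sim/deployments.csv \
  --detections results/study_sim/detections.csv \
  --species dhole --viewshed largest --area-km2 351 --seed 42
```

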