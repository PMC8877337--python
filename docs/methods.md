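# Methods

This note documents the statistical models, the numerical choices, and
what the synthetic-data experiments do and do not demonstrate.

## Data model and occasion construction

Deployments are camera stations with projected coordinates, half-open
active windows `[start, end)` at 1-second resolution (timezone-naive; all
instruments assumed on one clock), and two trapezoidal camera viewsheds
per station (near width, far width, depth, in meters; area =
(near+far)/2 × depth). The station-level area is the larger of the two
camera areas, optionally inflated by +10% or +20% scenario multipliers to
probe sensitivity to viewshed measurement error. A station that was stolen
or failed simply lacks an active window over the lost span — missing
effort is never recorded as zero counts.

Detections outside every active window of their station (or at unknown
stations) are flagged and excluded, never silently used; every builder
conserves detections between its used and flagged bins.

**Snapshot (STE) occasions.** Ticks are laid every `freq_s` seconds
(default 1 s, with a 1-s sampling length) from the earliest window start.
Ticks with at least one detection are materialized: stations active at the
tick are scanned in a fresh seeded random permutation, and the
area-to-event is the cumulative station area up to and including the first
detecting station. Ticks with no detection are only counted, grouped by
the active-station configuration (which changes only at window
boundaries), each contributing a censoring term at the configuration's
total area. A survey of millions of ticks therefore costs memory
proportional to the number of detections, and (events + censored) equals
the exact tick count by construction. When several stations detect in the
same second, the permutation decides which is "first"; group counts are
ignored by STE/TTE (the event is "at least one animal present"), which for
pack-living species under-uses information and is one reason densities of
*individuals* are better-identified than pack structure.

**TTE occasions.** Occasions of 1 h are anchored every 2 h from each
window start; occasions that would extend past the window are not formed.
The period length is crossing distance / movement rate; the crossing
distance defaults to the station's mean camera viewshed depth (the
measured dimension closest to "distance an animal must travel to cross
the monitored patch") and is configurable, since the appropriate dimension
depends on camera geometry. J = floor(occasion/period) with a floor of 1
(a period longer than the occasion clamps J to 1 with a warning).

**Counts (SBA).** Daily site × occasion counts; the default rule takes the
largest group count among the day's events (`max_group`), so repeated
photographs of one pack do not inflate the count; an event-count rule is
provided for contrast. The day-long occasion is a package decision —
exposed as a flag — because count-based mixtures need an occasion long
enough to make repeat visits plausible but short enough for many
occasions.

**SECR histories.** Individual × trap × daily-occasion counts with a
trap × occasion usage matrix from the active windows; detections lacking
an individual id are excluded with a reported count.

## Censored-exponential estimators (STE, TTE)

Both models reduce to a censored exponential. With n events and total
exposure E (summed areas for STE; summed area × periods for TTE), the MLE
is λ̂ = n/E, with Fisher-information standard error λ̂/√n (censored
occasions contribute exposure but no information beyond it) and a Wald
interval on log λ, λ̂·exp(±1.96/√n), which keeps the interval positive and
matches the skew of a small-n rate estimate. Zero events yields an
explicit boundary result (N̂ = 0, CI undefined) with a warning rather than
a silent zero. Abundance multiplies λ̂ by a user-supplied reference area:
the package never guesses the effective sampled area, because converting a
density to an abundance is a reporting decision, not an estimation one.

Correctness is anchored by oracle tests: the closed forms are checked
against exhaustive grid maximization of the stated log-likelihoods
(200,000-point log-spaced grids), and scale equivariance, monotonicity in
the viewshed scenario, and boundary behavior are property-tested.

## SBA sampler

The detection probabilities p_ij are integrated out analytically, giving
each observed cell a beta-binomial likelihood; this leaves (λ, α, β,
N_1..N_M) to sample. λ|N is conjugate gamma(shape+ΣN_i, rate+M). Each N_i
takes a symmetric ±1 random-walk step floored at max_j C_ij (the hard
support constraint, which holds in every retained draw). (ln α, ln β) take
a bivariate Gaussian random-walk step with gamma(0.1, 0.1) hyperpriors —
weakly informative, chosen because the data often carry little information
about the beta shape; a sensitivity flag exposes them. The proposal scale
adapts toward 20–50% acceptance during burn-in only and is frozen
afterwards, preserving the correct stationary distribution. Missing cells
(inactive cameras) contribute nothing to the likelihood.

The gamma priors named `uninformed` (0.01, 0.01), `partial` (5, 3) and
`constrained` (20, 15) are placed on λ, the Poisson mean: a gamma prior on
the discrete N itself would be ill-posed, and gamma–Poisson is the
standard construction. Defaults are 10,000 iterations × 5 chains with
burn-in 2,000 and thinning 1. Convergence is diagnosed with the
split-chain potential scale reduction factor (R-hat), defined as 1 for
constant chains; any parameter above 1.1 flags (not suppresses) the
result.

Sampler validation is three-fold: the conjugate λ step is checked
distributionally; a likelihood-free run on an all-missing count matrix
must reproduce the prior's moments within 3 Monte-Carlo standard errors
(effective sample size via arviz); and on data generated from the model at
high detection (M=50, J=20, p_ab≈0.9) the posterior mean of ΣN_i recovers
the simulated total within 10%.

On *misspecified* data — sparse, within-pack-correlated group counts from
the study-like generator — the posterior total overshoots the true number
of animals several-fold at mean detection below 0.1. This is the
documented failure mode for group-living species, and it is a property of
the data-model mismatch, not a sampler defect: on the model's own
generative draws at the same low detection the posterior is roughly
calibrated, just very wide.

## SECR

Full Poisson-n likelihood with half-normal encounter rate and Poisson
count detectors (binary proximity offered as a flag), activity centers
integrated over a rectangular grid mask. Optimization is L-BFGS-B on
(ln D, ln λ₀, ln σ) from moment starts (σ from the RMS spread of each
individual's detections about its detection centroid), inside a generous
±12 log-unit box that prevents floating-point under/overflow; standard
errors come from the central-difference Hessian by the delta method. The
default mask buffer is 4σ with spacing buffer/32, iterated once if the
fitted σ disagrees with the pilot by more than 20%; a test verifies that
doubling the buffer moves D̂ by under 1%. The vectorized likelihood is
checked to 1e-8 against an independent all-loops implementation, and is
translation-invariant and exchangeable over individual labels by
construction (also tested). Individuals detected at a single
trap-occasion leave σ weakly identified; such fits carry explicit
warnings.

## Synthetic data

Each estimator has a generator matching its assumptions exactly
(`sim_snapshot_stream`, `sim_tte_stream`, `sim_sba_counts`, `sim_secr`),
used for the recovery experiments; every generator is seed-deterministic
and stores its generating truth.

`make_study_like_dataset` emulates the target field design: 27
paired-camera stations on a jittered 2-km lattice, three blocks of
16/17/18 days (April–May), trapezoid viewsheds for 1.5–2 m trail
crossings (near width 1.5–2 m, far width up to ~4.5 m, depth 5–8 m). The
grouped species has three packs of 6–12 animals with 4-km home-range
kernels; pack *visits* to a station are a Poisson process (0.12/day at the
home-range center, decaying with distance) and each visit yields a short
burst of photographs sharing the pack id and a group count near pack size
— producing the within-pack correlation and overdispersion the
beta-binomial layer is meant to absorb, and the trail-use inflation that
biases event models. The solitary species has ~8 individuals with
half-normal encounter rates (0.15/day at center, σ = 2.5 km) and
individual ids. These rates are field-plausible for sparse large
carnivores and are deliberately *not* the event-model generative process:
passing recovery tests on the model-faithful generators shows the
estimators are correct; the study-like dataset shows what trail placement,
motion triggers and sociality do to them. Real data differ further in ways
the generator does not emulate (diel activity cycles, camera failure
modes, imperfect detection within the viewshed, pack fission–fusion), so
recovery here bounds implementation error, not field error.

## Problem sizes

The validation experiments are sized to desk-scale compute: STE coverage
uses 500 replicate surveys of 27 stations × 10⁵ one-second ticks at
density 10⁻⁶/m² (≈40 events each); TTE recovery uses density
5 × 10⁻⁶/m² over 16 days (≈16 events — enough information that a 2-SE
check reflects estimator correctness rather than small-sample skew); SECR
recovery uses 200 replicates of a 6×6 trap grid at spacing σ = 2 km,
λ₀ = 0.5, D = 5/100 km², K = 10 occasions; SBA uses the full production
sampler settings throughout.

## Known limitations

- No imperfect detection inside the viewshed (detection is assumed
  certain once an animal is in the monitored patch).
- No covariates on density or detection, no trap-response or mixture
  detection in SECR, no spatial thinning of correlated sites.
- Movement rates for TTE are inputs, not estimated.
- The effective area for converting density to abundance is a required
  user input.
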