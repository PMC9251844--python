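# cyclecmr

Demographic analysis of cyclic small-mammal populations from robust-design
live-trapping data: spatially explicit capture–recapture (SECR) densities,
bootstrap sex/age composition, error-propagating robust regressions of
demographic rates on density, Cormack–Jolly–Seber (CJS) apparent survival
with unequal intervals, and movement/reproduction/body-condition models —
validated end-to-end against a built-in cyclic-population simulator.

## The problem

Arctic lemming populations cycle over ~100-fold amplitude with a 3–4-year
period, and the prolonged low phase is the hardest part of the cycle to
explain. Long-term capture–mark–recapture grids (a few hectares, single-capture
live traps at 30-m spacing, 3–4 primary trapping periods per summer with up
to 10 secondary occasions each) let one ask which summer demographic
parameters — population structure, survival, movement, reproduction, body
condition — are density-dependent, and in which direction. `cyclecmr` is for
quantitative ecologists who need that full chain as tested, reusable code,
with a synthetic generator so every estimator has a parameter-recovery
benchmark.

## The models

**Density.** Detection of an animal with activity centre *x* by a trap at
distance *d* follows a half-normal, g(d) = g₀·exp(−d²/2σ²), with competing
trap hazards within an occasion (multi-catch). Detection parameters maximise
the likelihood conditional on the n animals detected; density is the
Horvitz–Thompson estimator D̂ = Σᵢ 1/aᵢ(θ̂), where aᵢ is the effective
sampling area — the habitat-mask integral (grid + 100-m buffer) of the
probability of being caught at least once.

**Composition.** Class proportions are ratios of SECR densities,
pₖ = Dₖ/ΣD. Their SEs come from resampling whole individual capture
histories with replacement (200 replicates) and refitting.

**Density dependence with errors on both axes.** Responses (proportions,
survival) and densities both carry error, so regressions resample
(x, y) pairs, perturb each replicate on the link scale — Normal(logit y,
se_logit) and Normal(log x, se_log) — back-transform, and fit a Huber
M-estimator (c = 1.345, IRLS with MAD scale) to each of B = 2000 datasets;
coefficients are replicate means with 2.5%/97.5% quantile intervals.

**Survival.** A CJS likelihood on presence/absence across a summer's primary
periods, conditioned on first capture, with interval survival
φ_Δt = φ_monthly^(Δt/30) so the 20-day (early years) and 30-day schedules are
comparable. Candidate structures over sex-age group, primary period, year
and grid are ranked by AICc; the selected model is the simplest within 2
units of the best.

**Behaviour.** Movement: max/mean distance from first capture, negative
binomial with a log(captures) offset. Reproduction: binomial mixed model
with individual random intercepts (Gauss–Hermite marginal likelihood). Body
condition: daily mass change between consecutive primaries, linear mixed
models always containing initial mass.

## Worked example

`examples/02_density_estimation.py` simulates one closed trapping session at
a known density of 5 animals/ha (g₀ = 0.3, σ = 15 m, 12×12 grid, 6
occasions) and fits it:

```
true density        : 5.00 animals/ha (121 animals on 28.1 ha)
animals detected    : 70
g0-hat              : 0.254   (truth 0.30; per-occasion capture prob at the centre)
sigma-hat           : 15.7 m (truth 15; half-normal movement scale)
effective sampl.area: 13.39 ha (mask integral of the detection prob)
D-hat               : 5.23 /ha, 95% CI [4.11, 6.64]
```

The effective sampling area (13.4 ha) says each detected animal represents
1/13.4 animals per hectare; 70 detections give D̂ = 5.23/ha, and the interval
covers the truth. `examples/04_survival.py` fits the survival model set on
simulated histories (truth φ: adult F 0.46, adult M 0.29):

```
  adult_female     0.518 [0.444, 0.591]  (0.46)
  adult_male       0.289 [0.229, 0.356]  (0.29)
```

The other examples cover the composition regression
(03), the full behavioural suite (05) and the end-to-end pipeline with its
markdown report (06). The pipeline is also scriptable from the shell:

```bash
cyclecmr run --seed 4 --out run_dir
cyclecmr report run_dir
```

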