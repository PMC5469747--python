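# finmove

Movement analysis for fin-whale Argos satellite telemetry: a Bayesian
switching state-space model that separates **transiting** from
**area-restricted search (ARS, a foraging proxy)**, kernel **home ranges**,
**chlorophyll-front habitat** proximity, and home-range × **shipping
traffic** overlap — the analysis chain used to ask where Mediterranean fin
whales feed and where that space use intersects dense vessel traffic.
Because real Argos tracks, satellite chl-a and traffic rasters are
proprietary, the package ships a first-class synthetic-data generator with
known ground truth, and every stage is exercised end-to-end against it.

## The model

Argos fixes are irregular in time and carry class-dependent, heavy-tailed
position errors. On a regular 12-h grid the latent track x_t follows a
two-state switching first-difference correlated random walk,

    x_{t+1} = x_t + γ_b T(θ_b)(x_t − x_{t−1}) + ε_t,   ε_t ~ N₂(0, Σ)

where b_t ∈ {transit, ARS} is a two-state Markov chain (α_k = Pr(b_t = 1 |
b_{t−1} = k)), transit has high persistence γ₁ and weak turning θ₁ ≈ 0, and
ARS has low γ₂ and strong turning θ₂ near π. A fix at fractional position j
in grid interval t observes (1−j)x_t + j x_{t+1} plus per-coordinate
Student-t noise with class-specific scale τ and df ν. A Metropolis-within-
Gibbs sampler (pure numpy, bit-reproducible under a seed) pools the
movement parameters across all track segments and samples latent locations
and states per segment. Posterior mean states b̂_t ∈ [1, 2] are labelled
with conservative cut-offs: < 1.25 transit, > 1.75 ARS, otherwise
uncertain.

Downstream, positions feed a Gaussian-kernel utilisation distribution in an
equal-area projection (barrier-masked and renormalised); the 50% and 90%
superlevel sets give the core (CHR) and total (THR) home ranges; daily
habitat masks combine a chl-a front detector, a 0.05–0.5 mg m⁻³ chl-a
window and a 200-m minimum depth; and high-traffic cells (≥ 90th percentile
inside the minimum bounding geometry) are intersected with CHR/THR.
See `docs/methods.md` for the full specification of priors, numerics and
design choices.

## Worked example

```sh
python analysis/01_simulate_tracks_and_scene.py
python analysis/02_fit_and_classify.py
python analysis/03_space_use_and_risk.py
```

The first script simulates three platforms (150 twelve-hour steps each,
sticky transit / strongly turning ARS), observes them through the Argos
error process and ingests them (`platforms simulated: 3; analysis-ready
fixes: 646`). The second fits the pooled model and prints the posterior
summary — with the generating values γ₁ = 0.85, γ₂ = 0.15, α₁ = 0.9,
σ ≈ 0.15°, a desk-scale run gives

```
parameter   mean    sd     q5   q95  rhat
   gamma1  0.840 0.035  0.781 0.893 1.003
   gamma2  0.185 0.130  0.012 0.425 1.093
   alpha1  0.901 0.040  0.834 0.962 1.016
sigma_lon  0.134 0.010  0.118 0.150 1.040
```

i.e. the pooled posteriors concentrate around the truth — followed by the
per-tag table of transit/ARS/uncertain percentages (integer rows summing
to 100). A large uncertain share is expected: class-B Argos errors
(τ = 0.25°) rival the 12-h displacement scale, so many true-ARS steps
cannot be called confidently — the same effect field analyses report. The
third script prints the home-range areas and attained isopleth masses
(`CHR … mass 0.500`, `THR … mass 0.900`), the fraction of daily positions
within 7 km of suitable habitat, and the percentage of THR/CHR covered by
high-traffic cells, writing all tables under `results/run/`.

The same pipeline is scriptable via the `finmove` CLI (`finmove run-all
--seed 1 --outdir runs/demo`, plus per-stage subcommands and `finmove
report`).

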