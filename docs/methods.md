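# Methods

`finmove` re-implements, as a tested pipeline over synthetic data, the
movement analysis used in Mediterranean fin-whale satellite-tagging work:
ingesting Argos location tables, fitting a Bayesian switching state-space
model that separates transiting from area-restricted search (ARS), kernel
home-range estimation, chlorophyll-front habitat proximity, and
home-range × shipping-traffic overlap. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Track ingestion

Fixes carry an Argos location class (lc) in {3, 2, 1, 0, A, B}; class Z
(invalid) is rejected at parse time. Tracks are assembled per platform,
time-sorted; equal-time duplicates keep the best class (3 > 2 > 1 > 0 > A
> B) — the most precise observation is retained. Segments are split where
the gap between consecutive fixes *strictly exceeds* 4 days ("longer than
four days"), labelled a, b, … in temporal order. Platforms with zero
location fixes are excluded (`no_locations`); platforms with under 3
tracked days or under 10 fixes are excluded (`too_short`). The 3-day /
10-fix cut-offs are this package's own defaults (the source analyses
excluded a ~2-day tag without stating a numeric rule); both are
config-exposed. Timestamps are treated as UTC throughout.

## The switching state-space model

On a regular grid with step Δ (default 12 h, config-exposed), latent
locations x_t (planar degrees) follow a first-difference correlated random
walk whose persistence and turning switch with a two-state Markov
behavioural process b_t:

    x_{t+1} = x_t + γ_{b} T(θ_{b}) (x_t − x_{t−1}) + ε_t,  ε_t ~ N₂(0, Σ)

with T(θ) the rotation matrix, γ ∈ (0,1) move persistence, θ mean turning.
State 1 is transit (high γ, θ near 0), state 2 ARS (low γ, strong turning).
The behavioural chain has α_k = Pr(b_t = 1 | b_{t−1} = k). An Argos fix at
fractional position j inside grid interval t observes
(1−j)·x_t + j·x_{t+1} with independent per-coordinate Student-t errors
whose scale τ and degrees of freedom ν depend on the location class —
heavy tails absorb the occasional gross Argos outlier, which is why no
speed/angle prefilter is applied.

Working in planar degrees is acceptable at Mediterranean scale
(≤ ~5% longitude-compression anisotropy around 42° N relative to the
fitted covariance; the model's Σ is free to be anisotropic anyway).

### Priors and identifiability

* γ_k ~ Uniform(0,1) jointly truncated to γ₁ > γ₂ (transit is the more
  persistent state).
* θ₁ ~ Uniform(−π/4, π/4): transit turns weakly.
* θ₂: uniform on the *reversal half-circle*, cos θ₂ ≤ 0. An unrestricted
  circular prior admits a reflected posterior mode in which a track with
  no ARS at all is relabelled entirely ARS (θ₂ ≈ 0, γ₂ ≈ the data's
  persistence); confining θ₂ to elevated turning encodes what ARS *means*
  and removes that mode. `Priors.theta2_cos_max` restores the
  unrestricted prior.
* α_k ~ Beta(1,1); conjugately updated from pooled transition counts.
* Σ via per-axis half-Normal(1°) scales and Uniform(−1,1) correlation.
* τ, ν are fixed per class from the configuration. Defaults equal the
  synthetic generator's error table, closing the loop in tests; analyses
  of real Argos data should substitute literature values.

### Sampler

A self-contained Metropolis-within-Gibbs sampler (pure numpy, bit
reproducible under a seed): exact two-point full-conditional draws for b_t
on an even/odd checkerboard; random-walk Metropolis for x_t in three
interleaved colour classes (nodes three apart share no innovation term)
with per-node scales adapted toward 0.44 acceptance during burn-in only;
adaptive scalar random-walk blocks for γ, θ and (log s₁, log s₂, ρ);
conjugate Beta draws for α. Movement parameters are pooled across all
segments — the hierarchical sharing that lets long tracks inform short
ones. Defaults: 2 chains, 10,000 iterations with 5,000 burn-in, thinned
by 10; convergence flagged at R̂ < 1.1 (R̂/ESS via arviz). Desk-scale
analyses in this repository shorten chains (stated per script/test); real
analyses should lengthen them via the configuration.

### Behavioural classification

b̂_t is the posterior mean of b_t over retained draws of all chains.
Labels use the conservative cut-offs (1.25, 1.75): below → transit, above
→ ARS, between (boundaries included) → uncertain. Table-style reports
convert label counts to integer percentages with largest-remainder
rounding (ties broken transit → ARS → uncertain), so rows always sum to
100. Region-level ARS rates pool locations across segments rather than
averaging per-segment percentages, matching a "percentage of locations"
definition.

## Synthetic data

The generator is the model's own generative process plus an observation
layer and an environmental scene; every generator is a pure function of
(spec, seed).

* Reference movement regime: γ = (0.85, 0.15), θ = (0, π),
  α = (0.9, 0.3), Σ = diag(0.15°²). At Δ = 12 h the implied transit speed
  is ~2.5–3 km h⁻¹, a realistic fin-whale travel rate; ARS dwell time
  averages ~1/0.3 ≈ 3 steps.
* Observation: Poisson times (default 3 fixes/day — irregular Argos duty
  cycles), endpoints always observed; classes drawn from a frequency
  table dominated by the poor classes (B 35%, A 25%), as in marine Argos
  practice; per-class Student-t noise with τ from 0.01° (class 3) to
  0.25° (class B), ν = 4 — declared test constants, not published values.
* Scene: chl-a transitions between two plateaus through a logistic band
  (analytic gradient → oracle tests), optionally drifting; bathymetry
  deepens linearly away from a northern coast; traffic lanes are
  polylines rasterised with a width and an integer value, clipped to the
  source product's [0, 409] range.

What the synthetic data do **not** emulate: spatially correlated chl-a
noise, clouds/data gaps, tag-failure processes, coastline-constrained
movement, or AIS-like traffic structure. Passing tests therefore
establish the *correctness of the computations*, not field performance on
real tracks.

## Self-consistency (calibration) study

`finmove.calibration` simulates 3 segments × 150 steps at the reference
regime, refits with 2 chains × 5,000 post-burn-in iterations (thin 5) and
scores (i) 90% credible-interval coverage of γ₁, γ₂, α₁, α₂ and (ii) the
fraction of interior steps whose classified state matches the simulated
truth among non-uncertain calls. Ten replicates run in ~5 minutes on one
CPU; these sizes are the package's chosen desk-scale study conditions.
Expected behaviour: coverage in ≥ 8/10 replicates per parameter and ≥ 80%
decoding agreement. A large share of true-ARS steps is classified
*uncertain* rather than ARS — the same phenomenon the field analyses
report when Argos error is large relative to the displacement scale.

## Home ranges

Positions (state-space estimates, pooled across whales by default) are
projected into a Lambert azimuthal equal-area plane centred on their
centroid (km), so masses and areas are area-true. The minimum bounding
geometry is the convex hull (config-replaceable by envelope). The
utilisation distribution is a Gaussian product-kernel density with
per-axis reference-rule bandwidths h_j = σ̂_j n^{−1/6} (config override)
evaluated on a regular grid (default ~200 cells across, margin 4
bandwidths); barrier cells are zeroed and the field renormalised to unit
mass over sea — mass-preserving and testable, if cruder than full
barrier-aware kernels. Isopleths are smallest superlevel sets: cells
ranked by density (ties broken by flat cell index for determinism),
accumulated until the target mass (0.5 → CHR, 0.9 → THR) is reached;
polygons are unions of cell rectangles, areas are cell counts × cell
area. CHR ⊆ THR holds by construction; halving the cell size moves areas
by < 5% on smooth densities.

## Habitat and proximity

Daily potential feeding habitat = front-adjacent ∧ chl-a in
[0.05, 0.5] mg m⁻³ ∧ depth ≥ 200 m ∧ sea. The 0.5 upper bound is the
published "low chlorophyll" criterion; the 0.05 lower bound and the front
detector's parameters are this package's declared defaults. The front
proxy thresholds |∇ ln chl-a| (centred differences on metric distances,
default 0.5 per 100 km) and dilates by 2 cells; it is deliberately
simpler than the published multi-scale detector. Daily positions are
per-platform daily means of the estimated locations (config-switchable
to nearest-noon). Distance to habitat is the haversine distance
(R = 6371 km) to the nearest suitable cell centre of the same day — 0
when the position's own cell is suitable; days with an empty mask are
excluded from the summary fraction but counted. "Within" is strict
(< threshold, default 7 km).

## Traffic overlap

High-traffic cells are those inside the MBG whose value reaches the 90th
percentile of the nonzero in-MBG values (an absolute-threshold alternative
is provided); they are vectorised to polygons. Overlap percentages are
area(THR ∩ high-traffic)/area(THR) (and likewise CHR), all geometry
clipped to the MBG in the equal-area plane; the denominator is the home
range, not the MBG. A raster (cell-counting) route cross-checks the
polygon route to within boundary-cell error.

## Degenerate inputs and tie-breaks (summary)

Empty tracks, sub-2Δ segments, all-barrier positions, empty day windows,
non-intersecting geometries and zero-area home ranges raise errors naming
the offending object. Deterministic tie-breaks: equal-time fixes → best
class; equal-density cells → flat index; percentage rounding → label
order. All stochastic code takes explicit seeds; a pipeline re-run with
identical config and seed is byte-identical.

## Known limitations

* The observation-error table must be supplied for real data; defaults
  are test constants.
* Planar-degree dynamics mildly distort anisotropy at high latitudes;
  the optional cos-latitude longitude correction is off by default.
* The mask-and-renormalise barrier treatment lets kernel mass "jump"
  narrow peninsulas.
* The front detector is a single-scale proxy; published habitat-area
  percentages for the western Mediterranean depend on real satellite
  fields and are out of scope.
* With ≤ 2 behavioural states and pooled parameters, tracks mixing more
  regimes (e.g. migration vs. local search vs. rest) will fold extra
  structure into the uncertain class.
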