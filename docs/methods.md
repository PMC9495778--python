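# Methods

## Model structure and assumptions

The hidden process is a deterministic matrix population model on a
lattice, extended with dispersal and density dependence. Its assumptions,
in the order they bite:

* **Discrete annual steps, ages 1..K.** K defaults to 50 (a deliberately
  optimistic maximum age for a woody shrub); the desk-scale synthetic
  scenario uses K = 20 to keep simulations fast without changing the
  dynamics, since mortality removes almost all plants long before age 20.
* **Age-independent mortality ρ.** Survival to age *a* is geometric,
  `(1 − ρ)^(a−1)`. Rounding to whole plants at every step means cohorts
  can go extinct exactly, which is intended: fractions of a plant do not
  reproduce.
* **Fecundity** `f(k) = floor(M·k^θ / (k̂^θ + k^θ))` rises sigmoidally at
  the maturity age k̂ and saturates at M. The floor alone does not force
  `f(k) = 0` below k̂ when M is large, so by default fecundity is clamped
  to zero below maturity (`strict_maturity=True`); the literal
  floor-only variant remains available for sensitivity analysis.
* **Stratified dispersal.** Each kernel column (source cell) distributes
  the reference share `1/D` locally, `ds/D` to each Moore neighbour and
  `dl·a/D` to every other cell, `a` being the source's urban cover. The
  column-normalisation `D = (C−1−|Neig|)·dl·a + |Neig|·ds + 1` conserves
  seeds exactly, border cells included. Long-distance transport is
  spatially uniform — a deliberate simplification of human-mediated
  movement. The kernel is rebuilt from each year's urban surface (and
  cached when the surface does not change between years).
* **Recruitment** multiplies arriving seeds by the self-regulation ratio
  `c` and the logistic suitability `p`. `c` compares free slots
  (capacity `p·A·φ` minus survivors) to seed supply and is defined as 0
  in the 0/0 case of no capacity and no seeds. Total cell population can
  exceed capacity by at most one plant (rounding slack), a bound the
  test suite asserts on every simulated trajectory.
* **Initial populations** put a binomial(K, ageRatio) age profile of
  total size popIni in each introduction cell. The profile is evaluated
  literally on k = 1..K; the k = 0 binomial mass is dropped without
  renormalisation, so the realised total is marginally below popIni for
  young populations. Mean age is K·ageRatio.
* **No seed bank, no stochastic demography, no vegetative reproduction,
  no age-dependent mortality.**

Rounding is half-away-from-zero throughout, avoiding the parity
artifacts of banker's rounding in long deterministic simulations.

A closed-form check anchors the simulator: in a propagule-saturated,
constant environment the one-step change of total population is
`p·φ′ − (p + ρ − p·ρ)·N_t` with `φ′ = p·A·φ`, and the simulator matches
it within one rounding unit per cell. A second anchor is exact
state-by-state equality with an independent straight-loop
reimplementation on a 3×3 grid over 10 years.

## Observation model

Weighted record counts are Poisson with mean `n_total · p_detec[d] ·
N_tg`, the small-probability limit of each plant being reported
independently (total-variation distance to the exact binomial is below
0.01 at n = 100, o = 0.005, which the suite verifies by enumerating both
pmfs). Records disaggregated from coarser grids carry fractional
weights, so the log-likelihood uses the gamma-function continuous
extension of the Poisson log-pmf; whether to floor weighted counts
instead was genuinely open, and the continuous treatment was chosen
because it preserves the total weight of every source record. A cell
with zero predicted rate but a positive observed count contributes a
large negative sentinel (−1e10) rather than −∞, keeping MCMC arithmetic
finite while auto-rejecting such proposals.

Target-group selection is greedy and deterministic: starting from the
focal species (which guarantees `y = 0` wherever effort is zero),
Phase A adds the species covering the most new (cell, year) volumes
(ties broken lexicographically), and Phase B adds species that strictly
increase the Shannon entropy of TG richness across volumes. "Entropy of
the richness distribution" admits two readings; the default treats
richness as a mass distribution over volumes (`r_v / Σr`), which rewards
spatial evenness — the stated purpose of the heuristic; the histogram
reading (frequencies of distinct richness values) is available behind
`entropy_variant="histogram"`. Natural logarithms throughout.

## Priors, parameterisation, sampling

The parameter vector is laid out as (popIni and ageRatio per
introduction cell | ρ, φ, k̂, θ, M, ds, dl, β | p_detec per dataset).
Sampling runs on log scales for positive parameters and logit scales for
probabilities, with transform Jacobians in the target density. The
maturity age k̂ is proposed on a continuous latent and floored (minimum
1) at model evaluation, so one Metropolis kernel covers the single
integer-like parameter.

Default priors are weakly informative and all overridable: Beta(2,2) on
ρ, log-normals on φ, θ, M and popIni, a log-normal on k̂ with mode
slightly below 3 years, half-normals shrinking ds and dl toward zero,
diffuse normals on β, Beta(2,6) on ageRatio, and a log-normal on
p_detec. The detection-rate/abundance confounding inherent to
presence-only data (doubling all populations and halving all detection
rates leaves the likelihood almost unchanged) is mitigated only by the
priors on φ and p_detec; the synthetic module ships a
`confound_effort=True` stress scenario that makes the confounding
visible by tying effort to population.

The sampler is a random-scan block Gaussian random-walk
Metropolis–Hastings: each iteration perturbs one parameter block.
Multi-session fitting (default protocol: three sessions, nine chains,
100,000 iterations, burn-in 15,000, thinning 450 — every field
configurable) restarts all chains of a session from the best draw of the
previous session, a cheap simulated-annealing-like climb that matters on
this likelihood surface, which is discontinuous in the parameters
through the rounding steps. Only the final session is burned in and
thinned; the retained count is exactly
`n_chains · floor((n_iter − burnin)/thin)`.

Convergence: univariate PSRFs use the Brooks–Gelman
degrees-of-freedom-corrected estimator and match R's `coda::gelman.diag`
to the printed precision (a frozen cross-checked example lives in the
tests). The multivariate factor is computed from the published formula
`sqrt((n−1)/n + (m+1)/m · λ₁)` with λ₁ the leading eigenvalue of
`W⁻¹B/n`; note `coda` multiplies λ₁ by `(1 + 1/n_vars)` instead, so the
two disagree when the number of variables differs from the number of
chains.

## Synthetic studies

The generator emulates the structure of a regional invasion dataset:

* a rectangular lattice (default 10×10, terrestrial fractions drawn in
  [0.8, 1]) with two smooth standardised suitability covariates
  (Gaussian-filtered noise, correlation length 2 cells) and urban cover
  decaying exponentially from a few "city" cells;
* introduction cells placed in the cities (as herbarium-era records of
  cultivated plants would be), with young founder populations —
  mean ages below the maturity age, producing a lag phase;
* three datasets with the archetypal temporal profiles of real sources:
  an early sparse "herbarium" window, a mid-period "monitoring" window,
  and a late, dense, upward-trending "crowdsourcing" window, each with a
  spatially autocorrelated log-normal intensity surface realised as
  Poisson counts;
* default true parameters (ρ = 0.3, φ = 300, k̂ = 3, θ = 6, M = 50,
  ds = 0.2, dl = 0.01, β = (0, 1, −0.5), p_detec = (3, 5, 8)·10⁻⁴)
  chosen once so the desk scenario reproduces the qualitative dynamics
  the method is meant to resolve: an early urban-seeded long-distance
  wave of pioneer populations, local growth to a global equilibrium
  (~×160 over nine years), and a few hundred weighted records overall.

What the generator does **not** emulate: real geography and geodesic
cell areas, taxonomy of the target groups, non-detection biases that are
correlated with abundance (other than the explicit `confound_effort`
stress case), observer misidentification, and temporal autocorrelation
of effort beyond the windowed trends. Passing recovery tests therefore
show the estimator is consistent with its own assumptions at realistic
signal levels — not that those assumptions hold for any particular real
archive.

## Post-fit analyses

All analyses re-simulate the deterministic trajectory per retained draw.
Percentile maps pool, per draw, all (cell, year) total populations
(zeros included — the pool definition was open and this is the choice)
and cut at that draw's own 40th/70th/90th percentiles; a couple keeps a
bin only when at least two-thirds of draws agree (inclusive threshold,
asserted at the boundary in tests). Invasion syndromes combine growth /
decline (strict inequalities on the cell total) with a dispersal status:
a cell "disperses" in a year when its exported seeds are expected to
establish at least one plant elsewhere,
`out_i′ · Σ_{i≠i′} disp[i,i′]·c_i·p_i ≥ 1` — an expected-recruit rule;
a realised-recruit variant would require attributing integer recruits to
sources, which the rounding makes non-identifiable. Long-distance
recruit series apportion each cell's recruits by the long-distance share
of its seed rain.

Ablations re-simulate each draw with `dl = 0` or `ds = 0`, everything
else unchanged, and report (ablated − full)/full per year with a 90%
band. Setting a rate to zero changes the kernel normalisation `D`, so
seeds formerly spread (below the recruitment-rounding threshold) over
distant cells are redirected locally; small positive excursions of the
relative difference in the first transition years are therefore genuine
model behaviour, not a bug — the suppression of the expansion wave
dominates from then on. `ds = 0` lies outside the fitting support and is
allowed only through an unchecked constructor used by the
counterfactuals.

Data-deprivation validation refits on observations truncated at a
cutoff year (effort tensors zeroed after it too) and ranks cells by
posterior-mean predicted population over an evaluation window; the AUC
is the fraction of (detection, non-detection) cell pairs ranked
concordantly, ties counting one half. Windows without detections (or
without non-detections) are reported as NaN rather than guessed.

## Problem sizes and runtime

The default test suite runs in a few minutes on one CPU. The
parameter-recovery acceptance experiment is the scaled-down version of a
cluster-scale protocol: five replicate desk studies, each fit with two
sessions of two chains × 3,000 iterations (burn-in 500, thinning 25,
~200 retained draws), sampling ρ, ds and k̂ with the remaining
parameters held at their generating values. Coverage of the 90%
credible intervals must reach 80% of replicates per parameter; at this
scale the observed coverage is 100%. The acceptance script uses the same
protocol plus a mid-period validation cutoff; a full-size preset
(19×43 = 817 cells, 42 years, K = 50, 24 introduction cells) exists for
long runs but is not part of any automated check.

## Known limitations

* The Poisson likelihood treats fractional weighted counts continuously;
  a floored-count variant is not implemented (flagged for sensitivity
  testing).
* The sampler has no adaptation during sampling; proposal scales are
  fixed per block and must be chosen by the user (acceptance rates are
  logged to support this).
* MPSRF follows the published formula, not `coda`'s variant (see above).
* The expected-recruit dispersal attribution and the percentile-pool
  definition are documented choices among several defensible ones; both
  alternatives would change map labels near thresholds, not the global
  metrics.
* Desk-scale fits hold nuisance parameters fixed in the automated
  recovery checks; joint identifiability of all 20+ parameters at
  desk-scale data volumes is not claimed — the confounded-effort
  scenario exists precisely to demonstrate where identification fails.
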