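# Methods

## Model and assumptions

`volescr` fits a closed-population spatial capture-recapture (SCR) model
to multi-occasion live-trapping data by Bayesian data augmentation.  The
population is closed within a session (no births, immigration or
natural mortality between occasions; the only removals are deaths in
traps, handled explicitly).  Activity centres are fixed within a
session and uniform over the state space; detection declines with
distance from the centre as a half-normal with scale σ, optionally
sex-specific.  The encounter distribution per individual-occasion is
multinomial over traps plus a no-capture cell.

Two link formulations are implemented for turning the trap hazards
`h_j = exp(lp)·exp(−d_j²/2σ²)` into cell probabilities:

* **multinomial-logit** (default): `p_j = h_j/(1+Σh)`, no-capture
  `1/(1+Σh)`.  For one trap at distance zero this collapses to
  `p = logit⁻¹(lp)`, which makes `lp` interpretable as logit of the
  baseline detection probability p₀ — the scale on which the covariate
  model is written.
* **competing-hazard** (option): `p_j = (h_j/Σh)(1−e^{−Σh})`,
  no-capture `e^{−Σh}`.  The two differ only at high hazard.

Multinomial likelihoods are an approximation for single-catch traps;
simulation work in the SCR literature shows the approximation is
adequate when per-occasion trap saturation stays below ~86%, far above
anything the generator or the field protocol produces (tens of percent
at most).

## Parameters

| parameter | meaning | unit / scale | prior (default) |
|---|---|---|---|
| α0 (by sex) | baseline detection logit at the activity centre | logit | N(0, slab σ²=10) |
| α_t | slope on standardized occasion number | logit / SD | N(0, slab) |
| α_b | prior-capture (behavioural) effect | logit | N(0, slab) |
| σ_f, σ_m | half-normal movement scale | metres | Uniform(0, 25) |
| ψ | inclusion probability of an augmented individual | — | Beta(1, 1) |
| π | male proportion | — | Beta(1, 1) |
| s_i | activity centre | metres | Uniform(state space) |
| w_t, w_b, w_s | covariate selection indicators | {0,1} | Bernoulli(0.5) |

The time covariate is the occasion index 1..K standardized to mean 0,
variance 1 — the coding is a package choice; the α_t magnitudes it
produces are consistent with reported fits.  Sex is coded female = 0,
male = 1 and is latent (Gibbs-imputed) when unknown.  The σ prior upper
bound of 25 m is more than 3× the largest movement scale reported for
this system.  The slab variance σ² ∈ {10, 100} is run both ways when
assessing selection sensitivity.

Augmentation size defaults to `max(3n, ⌈1.5·area_ha·200⌉)` so the
posterior of ψ stays well below 1; a warning is emitted if the
posterior mean of ψ exceeds 0.8 (M likely truncating N).

Derived quantities: density `D = N/area` (per ha), sex-specific
densities `D_f = D(1−π)`, `D_m = Dπ` (draw-wise, so they sum exactly),
and circular home-range area `π·q·σ²` with q = 5.99, the 95% quantile
of a χ²₂ — a radius of √5.99 ≈ 2.45σ.  The commonly quoted "2.5σ
radius" is treated as a rounding of this; using literal 2.5 would
inflate the reported areas by ~4%.

## Sampler

Metropolis-within-Gibbs over: detection coefficients and log-σ
(random-walk Metropolis, proposal scales adapted to 25–45% acceptance
during burn-in then frozen; the uniform σ prior contributes a log-scale
Jacobian), activity centres (bivariate random walk restricted to the
state space for z = 1; a uniform prior redraw for z = 0), inclusion
flags z (Bernoulli full conditional from ψ and the all-empty-history
probability), ψ and π (conjugate Beta), latent sexes (two-category full
conditional), and Kuo–Mallick indicators (Gibbs on the likelihood ratio
with the Bernoulli(0.5) prior; a switched-off coefficient is refreshed
from its slab prior so the chain traverses models).  Dead individuals
contribute nothing after their removal occasion anywhere in the
sampler.

The implementation is vectorised numpy over all M individuals, with
per-individual caches of trap distances and kernel sums that are
updated row-wise on acceptance; a full likelihood evaluation is O(M·K)
given the caches, and centre/σ updates are O(M·J).  Production settings
(3 chains × 150 000 iterations, burn-in 5 000, thin 1) are defaults;
every analysis here runs desk-scale chains (thousands of iterations,
M = 250–800), which the validation below shows is sufficient at these
data sizes.  All randomness flows from one integer seed per run; equal
seeds give bit-identical chains.

An optional *discrete* centre grid replaces the random-walk update with
exact Gibbs over the grid.  Its purpose is validation: on an instance
small enough to enumerate (M = 3, J = 2, K = 2, 3 × 3 centre grid,
detection parameters held fixed) the sampler's posterior over N is
compared against brute-force enumeration of the joint posterior with ψ
integrated analytically under its Beta(1,1) prior; agreement is within
0.02 in probability.

Convergence is monitored with the classic Gelman–Rubin
between/within-chain R-hat (threshold 1.1).  Runs with any R-hat ≥ 1.1
are completed and flagged NOT CONVERGED rather than suppressed.

## Synthetic data generator

The generator emulates the field design: the May grid (7 × 10 node
lattice, 12 m × 15 m spacing, two paired traps per node = 140
detectors) and the June grid (one trap per node plus the 54 interior
cell centres = 124 detectors, minimum spacing √(6² + 7.5²) = 9.6 m).
This layout is a reconstruction from the published counts, extents and
spacing values, all of which it matches exactly.  Populations are
Poisson (or fixed-N) with uniform centres and Bernoulli(π) sexes;
capture histories add, in order: the time-increasing detection logit, an
optional behavioural effect via the prior-capture matrix, single-catch
competition, and per-capture trap mortality (default 3%, matching the
observed rate).

Single-catch competition uses competing exponential arrival times
within an occasion, at the level of trapping *nodes*: an animal's
arrival rate at a node is the half-normal hazard of one trap there, it
commits to its earliest-arriving node (unit horizon), a node captures
its earliest arrivals up to its detector count, and losers are released
uncaptured.  Co-located paired detectors therefore share one encounter
process and contribute capture capacity only — which is what pairing
traps at a point is for in the field (avoiding saturation).  The
alternative of giving every detector an independent hazard would make a
second box at the same point double the point's attractiveness; under
that semantics the densified single-trap grid shows no precision
advantage for the female movement scale, contradicting both intuition
and the reported design comparison, so it was rejected.  Discrete
first-come schemes were likewise rejected because they need an
arbitrary ordering rule.  For one-detector nodes the mechanism is plain
earliest-arrival competition, and at low per-occasion hazard it is
statistically indistinguishable from independent multinomial draws
(verified by a rank test in the suite).  In multinomial mode co-located
detectors remain independent cells — that is the fitted model's own
assumption, and the mode exists to validate the estimator against its
own sampling distribution.

At the fitted June truth (168.25 voles/ha, π = 0.25, σ = 4.1/8.12 m,
time-increasing detection) the generator yields ~145 observed
individuals and ~230 captures per session — the same order as the real
June session — with per-occasion saturation in the tens of percent.
What the generator does *not* emulate: between-occasion movement of
activity centres, open-population dynamics (the May→June change is not
modelled), trap-level covariates, non-Euclidean distance, and
within-occasion twice-daily trap checks (a physical field trap could
hold two animals per daily occasion, so real per-check occupancy runs
lower than the generator's one-capture-per-trap-occasion saturation).
Passing tests therefore validate the estimator under the model's own
sampling assumptions plus single-catch competition — not robustness to
every field artefact.

## Numerical choices and degenerate inputs

* Distances are exact Euclidean; paired detectors at one node are
  distinct multinomial cells with identical coordinates.
* The pixel grid shrinks the requested pixel side per axis so pixels
  tile the state space exactly and the density surface integrates to
  the posterior mean N of the saved draws (exact identity).
* Indicator Gibbs uses a numerically stable sigmoid of the
  log-likelihood ratio; sex Gibbs subtracts the row-wise max before
  exponentiating.
* Proposals outside the state space or σ outside (0, upper) are
  rejected outright (prior mass zero).
* Degenerate inputs error early: duplicate detector ids, captures after
  a death flag, empty capture files, all-coincident trap arrays,
  non-positive radii/σ, M < n.
* R-hat returns exactly 1 for constant chains (zero within-variance).

## Design study

Grid designs are scored by RMSE of the posterior-mean estimates of N
and σ against the realized simulated truth (realized N, not the Poisson
expectation, since a fit sees one realization), per sex, with shared
population seeds across grids within a replicate so differences are
attributable to geometry alone.  The posterior mean is the scored point
estimate.  Replicates with fewer than 2 captured individuals are
recorded as failed and excluded with counts reported.  Production
protocol: 100 replicates per sex × grid at 5000 iterations / 1000
burn-in; the analysis scripts and tests run 6–10 replicates at 2000
iterations, which already reproduces the directional result (the
densified June grid lowers female-σ RMSE and roughly doubles spatial
recaptures).

## Known limitations

* The sampler is single-threaded; production-length runs (150 000 × 3
  chains at M ≈ 800) take hours, not minutes.
* Model weights for structurally unidentifiable combinations (e.g. a
  behaviour effect with almost no recaptures) can mix slowly; the
  two-slab sensitivity run is the guard.
* The competing-hazard link is available but the selection machinery
  is only exercised under the default multinomial-logit link.
* Closed-population assumption within a session; no movement of
  centres between occasions.
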