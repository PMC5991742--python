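# volescr

Bayesian spatial capture-recapture (SCR) for small-mammal live-trapping
studies, built around a field study of common voles (*Microtus arvalis*)
trapped on a 72 × 135 m grid over two monthly sessions of K = 8
occasions.  The package estimates population density, sex ratio and
movement from single-catch trap capture histories, selects detection
covariates with Bayesian indicator variables, and evaluates trap-grid
designs by simulation.

## The model

Each of M potential individuals (data augmentation: the n observed
capture histories padded with M − n all-empty ones) has

* an inclusion flag `z_i ~ Bernoulli(ψ)`; population size is `N = Σ z_i`
  and density `D = N / |S|` on the state space S, the trap bounding box
  buffered by ≥ 2.5σ (30 m here);
* a latent activity centre `s_i ~ Uniform(S)`;
* a sex `~ Bernoulli(π)` (π is the male proportion);
* a multinomial encounter per occasion over the J traps plus a
  "not captured" cell.  With distance `d_ij = ‖s_i − x_j‖`, trap hazard

  `h_ij = exp(lp_ik) · exp(−d_ij² / 2σ²_sex)`

  and cell probabilities `h_ij / (1 + Σ_j h_ij)`, so that for a single
  trap at distance 0 the capture probability is `logit⁻¹(lp)`.  The
  baseline detection logit is

  `lp_ik = α0(sex) + w_t·α_t·z(k) + w_b·α_b·C_ik`

  with z(k) the standardized occasion number, C the prior-capture
  indicator, and w ∈ {0,1} Kuo–Mallick selection indicators with
  Bernoulli(0.5) priors and a N(0, σ²∈{10,100}) slab on coefficients.
  Posterior indicator frequencies are model weights.

Voles that die in a trap (~3% of captures) are excluded from the
likelihood after their removal occasion.  σ is sex-specific when the
sex-σ structure is on; a circular home range is derived as
`π·5.99·σ²` (the 95% bivariate-normal quantile, radius ≈ 2.45σ).

Inference is by a bespoke Metropolis-within-Gibbs sampler
(`volescr.sampler`); convergence is checked with the Gelman–Rubin R-hat
(< 1.1).  The synthetic-data generator (`volescr.simulate`) reconstructs
the two field grids — 140 paired traps at 70 nodes (May) and 124 single
traps at 9.6 m minimum spacing (June) — and simulates capture histories
with single-catch trap competition via competing exponential arrival
times.

## Worked example

```python
import volescr as v

traps = v.june_grid()                       # 124 traps, 9.6 m spacing
space = v.build_state_space(traps, buffer=30.0)
print(space.area)                           # 25740.0 (m^2)

par = v.DetectionParams(alpha0_f=-1.92, alpha0_m=-2.74, alpha_time=0.28,
                        sigma_f=4.1, sigma_m=8.12)
cfg = v.IndicatorConfig(w_time=1, w_sex=1, sex_sigma=1)
pop = v.simulate_population(space, 168.25, 0.25, par, seed=1, cfg=cfg)
data = v.simulate_captures(pop, traps, v.SimOptions(K=8, seed=2))
print(pop.N, data.n, data.n_captures)       # 434 156 236

spec = v.ScrModelSpec(M=800, cfg=cfg, n_chains=1,
                      n_iter=6000, burn_in=1500, seed=3)
chains = v.run_mcmc(data, traps, space, spec)
print(v.summarize(chains, ["D", "sigma_f", "sigma_m", "pi"]).round(2))
```

prints (4500 retained draws; the realized truth is D = 168.6 voles/ha,
σ_f = 4.1, σ_m = 8.12, π = 0.25):

```
             Mean     SD   2.50%     50%  97.50%  Rhat
parameter
D          190.19  17.35  157.34  189.59  223.78   NaN
sigma_f      4.21   0.33    3.59    4.19    4.85   NaN
sigma_m      8.51   0.91    6.95    8.45   10.23   NaN
pi           0.20   0.03    0.14    0.20    0.28   NaN
```

i.e. the fitted density, movement scales and sex ratio recover the
simulated truth within their 95% credible intervals (R-hat needs ≥ 2
chains, hence NaN here).  `v.home_range_area` converts σ to home-range
area (`8.12 → 1240 m²`, `4.10 → 316 m²`).

The numbered scripts under `analysis/` run the full workflow:
descriptive statistics (`01`), synthetic session generation (`02`),
fitting with covariate selection and a density surface (`03`), and the
May-vs-June grid-design comparison (`04`).  A `scr` command-line tool
(`scr describe|simulate|fit|design --config cfg.yaml`) wraps the same
stages for file-based runs.

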