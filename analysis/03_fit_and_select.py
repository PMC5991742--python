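"""Fit the SCR model to the synthetic session with covariate selection.

Two-stage workflow mirroring the field analysis: sex-specific sigma is
retained (stage 1), then Kuo-Mallick indicator selection chooses among
the time / behaviour / sex detection covariates under both slab priors
(N(0,10) and N(0,100)).  Finally the selected model is refitted with 3
chains and summarized with R-hat, and the posterior density surface is
exported.  Chain lengths here are desk-scale (thousands, not the
150,000-iteration production runs); pass a seed as argv[1].

Requires the session from 02_simulate_session.py.
"""

import sys
from pathlib import Path

from volescr import (ScrModelSpec, build_state_space, density_surface,
                     model_weights, read_captures, read_traps, run_mcmc,
                     summarize)
from volescr.detection import IndicatorConfig

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1] / "results"
SESSION = ROOT / "session"
OUT = ROOT / "fit"
OUT.mkdir(parents=True, exist_ok=True)

traps = read_traps(SESSION / "traps.csv")
data = read_captures(SESSION / "captures.csv", traps, K=8)
space = build_state_space(traps, buffer=30.0)

# stage 2: Kuo-Mallick selection under the two slab priors
weights = {}
for slab in (10.0, 100.0):
    spec = ScrModelSpec(M=1000, cfg="select", select_sex_sigma=1,
                        slab_variance=slab, n_chains=1, n_iter=6000,
                        burn_in=1500, seed=SEED, save_centres_every=10 ** 9)
    w = model_weights(run_mcmc(data, traps, space, spec))
    weights[slab] = w
    w.to_csv(OUT / f"model_weights_slab{int(slab)}.csv", index=False)
    top = w.iloc[0]
    print(f"slab variance {slab}: top model "
          f"(t={int(top.w_time)}, b={int(top.w_behav)}, "
          f"s={int(top.w_sex)}) weight {top.weight:.3f}")

# refit the top model under the sigma^2=10 prior with 3 chains
top = weights[10.0].iloc[0]
cfg = IndicatorConfig(w_time=int(top.w_time), w_behav=int(top.w_behav),
                      w_sex=int(top.w_sex), sex_sigma=1)
spec = ScrModelSpec(M=1000, cfg=cfg, n_chains=3, n_iter=6000, burn_in=1500,
                    seed=SEED + 7, save_centres_every=20)
chains = run_mcmc(data, traps, space, spec)
table = summarize(chains)
table.round(4).to_csv(OUT / "posterior_summary.csv")
print()
print(table.round(3).to_string())
if (table["Rhat"].dropna() >= 1.1).any():
    print("NOT CONVERGED at this chain length (some R-hat >= 1.1)")

surf = density_surface(chains, space)
surf.to_csv(OUT / "density_surface.csv", index=False)
print(f"\nfit artifacts in {OUT}")
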