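"""Generate one synthetic June-like trapping session and describe it.

The generator is parameterized at the fitted June model (density
168.25 voles/ha, male fraction 0.25, sex-specific sigma 4.1 / 8.12 m,
time-increasing baseline detection) with single-catch competition and 3%
trap mortality.  Writes the session files and the naive summaries under
results/session/.
"""

import sys
from pathlib import Path

import pandas as pd

from volescr import (SimOptions, build_state_space, capture_frequency,
                     captures_per_individual, count_spatial_recaptures,
                     june_grid, simulate_captures, simulate_population,
                     trap_saturation, write_captures, write_traps)
from volescr.detection import DetectionParams
from volescr.simulate import write_truth

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "session"
OUT.mkdir(parents=True, exist_ok=True)

traps = june_grid()
space = build_state_space(traps, buffer=30.0)
params = DetectionParams(alpha0_f=-1.92, alpha0_m=-2.74, alpha_time=0.28,
                         sigma_f=4.1, sigma_m=8.12)
pop = simulate_population(space, density_per_ha=168.25, pi_male=0.25,
                          params=params, seed=SEED)
data, captured = simulate_captures(
    pop, traps, SimOptions(K=8, death_prob=0.03, seed=SEED + 1),
    return_truth=True)

write_traps(traps, OUT / "traps.csv")
write_captures(data, traps, OUT / "captures.csv")
write_truth(pop, captured, OUT / "truth.csv")

freq = capture_frequency(data)
sat = trap_saturation(data, traps)
summary = pd.DataFrame([
    ("true_N", pop.N),
    ("observed_n", data.n),
    ("captures", data.n_captures),
    ("captures_per_individual", round(captures_per_individual(freq), 2)),
    ("spatial_recaptures", count_spatial_recaptures(data, traps)),
    ("deaths_in_trap", int((data.removal_occasion >= 0).sum())),
    ("saturation_min_pct", round(float(sat.global_pct.min()), 2)),
    ("saturation_max_pct", round(float(sat.global_pct.max()), 2)),
], columns=["statistic", "value"])
summary.to_csv(OUT / "summary.csv", index=False)
print(summary.to_string(index=False))
print(f"\nsession files in {OUT}")
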