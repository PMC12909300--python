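"""Associate a bin-gated trait with mortality in a time-varying Cox model.

Animals carry a per-age-bin covariate (here a synthetic decline-occupancy-like
score, in percentage points); deaths are piecewise-exponential with true
log-hazard 0.065 per unit. The fit recovers the effect, and the translation
helpers turn it into a percent change in the risk of death.
"""

import numpy as np
import pandas as pd

from bwdyn import survival
from bwdyn.simulate import SimConfig, simulate_survival

beta_true = 0.065
cfg = SimConfig(baseline_hazard=4e-4, hazard_coefs={"x": beta_true},
                hazard_bin_days=360.0, max_age=780.0)
rng = np.random.default_rng(1)
rows = []
for i in range(300):
    x = {0: rng.normal(0, 10.0), 1: rng.normal(0, 10.0)}
    death = simulate_survival(x, cfg, seed=1000 + i, feature_name="x")
    end = death if death is not None else cfg.max_age
    rows.append({"animal_id": i, "start": 60.0, "stop": min(end, 420.0),
                 "event": int(death is not None and end <= 420.0),
                 "x_bin0": x[0], "x_bin1": 0.0})
    if end > 420.0:
        rows.append({"animal_id": i, "start": 420.0, "stop": end,
                     "event": int(death is not None),
                     "x_bin0": 0.0, "x_bin1": x[1]})
episodes = pd.DataFrame(rows)

best_pen, table = survival.select_penalty(episodes, grid=[0.0, 0.01, 0.1], seed=0)
fit = survival.fit_tv_cox(episodes, penalty=best_pen)
b = fit.beta["x_bin0"]
print(f"penalty grid search: {table.to_dict('records')} -> chosen {best_pen}")
print(f"log hazard per unit in bin 0: {b:.4f} (truth {beta_true}), "
      f"se {fit.se['x_bin0']:.4f}, Wald p {fit.wald_p['x_bin0']:.2e}")
print(f"=> each unit raises the hazard by {survival.hazard_percent_change(b):.1f}% "
      f"(ratio {survival.hazard_ratio(b):.4f}); c-index {fit.c_index:.3f}")
# With the true 0.065 the translation is a 6.7% hazard increase per unit.
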