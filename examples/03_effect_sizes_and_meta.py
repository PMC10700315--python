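"""Paired effect sizes pooled with a random-effects meta-regression.

Each simulated landscape contributes a Hedges' g comparing removal under
low- vs high-intensity grazing (positive g = more removal under low
intensity).  A moderator (here the known diversity gradient) explains
part of the between-site heterogeneity; the rest stays in T^2.
"""

import pandas as pd

from dungbef.effect_meta import heterogeneity, meta_regression, random_effects_fit
from dungbef.synthetic_data import simulate_effect_sizes

# 150 landscapes so the moderator slope is estimated precisely; the field
# design's n = 38 gives the same estimator with a wider standard error
effects, x = simulate_effect_sizes(n=150, gamma0=0.0, gamma1=0.4, tau=1.4,
                                   seed=123)
pooled = random_effects_fit(effects)
het = heterogeneity(effects)
print(f"pooled Hedges' g = {pooled.mu:+.3f} "
      f"(t = {pooled.t:.2f}, df = {pooled.df}, p = {pooled.p:.3f})")
print(f"T^2 = {het['tau2']:.3f}, Q = {het['Q']:.1f} (df {het['df']}), "
      f"I^2 = {het['I2']:.3f}")
print("-> no overall shift between regimes, but strong between-site "
      "heterogeneity to explain.\n")

fit = meta_regression(effects, pd.DataFrame({"diversity_diff": x.to_numpy()}))
print(fit.table.round(3).to_string(index=False))
print(f"\nomnibus F{fit.F_df} = {fit.F:.2f} (p = {fit.F_p:.4f}); "
      f"pseudo-R^2 = {fit.pseudo_R2:.3f}")
print("-> the diversity moderator absorbs part of T^2: sites whose "
      "low-intensity pasture is more functionally diverse remove more dung "
      "there (true slope 0.4).")
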