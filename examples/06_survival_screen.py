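"""Gene-family survival screen on simulated cohorts.

One gene carries a true log-linear hazard effect; the rest are noise.
Each gene is median-dichotomized, tested by log-rank, and given a
high-vs-low hazard ratio from a binary Cox fit; the screen ranks by HR.
"""

import numpy as np

from kdsig import simulate_survival, screen_genes, summarize_screen
from kdsig.simulate import SimSurvivalConfig

rng = np.random.default_rng(0)
cohort = simulate_survival(SimSurvivalConfig(
    n_subjects=1000, baseline_hazard=0.03, log_hr_per_unit=np.log(2),
    censor_rate=0.01, seed=0), gene="HIT")
for k in range(9):
    cohort[f"NULL{k}"] = rng.normal(size=len(cohort))

genes = ["HIT"] + [f"NULL{k}" for k in range(9)]
screen = screen_genes(cohort, genes, method="median")
print(screen[["gene", "hr", "ci_low", "ci_high", "logrank_p", "n_high", "n_low"]]
      .round(4).to_string(index=False))
print("\nsummary:", summarize_screen(screen))
print("\nHIT (true per-unit HR 2) tops the ranking with a wide margin; "
      "the null genes scatter around HR 1.")
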