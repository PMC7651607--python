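"""Simulate one dose-finding trial and check its variance structure.

Builds the reference 16-week design (placebo + 3/10/30/100 mg, 39
subjects per arm, 9 post-baseline visits) and simulates one replicate of
log-scale change from baseline in UACR under a linear drug-effect
time-course with ED50 = 32 mg.
"""

import numpy as np

from drmmrm import Design, Scenario, simulate_trial

design = Design()
scenario = Scenario(ed50_true=32.0, timecourse="linear", n_reps=1, seed=2024)
trial = simulate_trial(scenario, design, rep=0)

print(trial.head(9).to_string(index=False))
print(f"\nrows: {len(trial)} (= 5 arms x 39 subjects x 9 visits)")

plc = trial[trial.dose == 0].pivot(index="subject", columns="week", values="duacr")
print(f"placebo per-visit variance: {plc.var().mean():.3f} "
      f"(population value omega^2 + sigma^2 = {0.3716**2 + 0.5**2:.3f})")
resid = plc - plc.mean()
lag1 = (resid.to_numpy()[:, 1:] * resid.to_numpy()[:, :-1]).mean() / resid.to_numpy().var()
print(f"lag-1 serial correlation: {lag1:.3f} "
      "(subject heterogeneity plus AR(1) residuals make this larger than rho = 0.226)")
print("\nEach subject's trajectory = true drug effect + random intercept "
      "(SD omega) + AR(1) noise (SD sigma, correlation rho per visit).")
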