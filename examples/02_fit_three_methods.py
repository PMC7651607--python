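"""Fit all three analysis methods to one simulated trial.

Compares the placebo-adjusted end-of-study estimates (ddUACR, log scale)
of conventional MMRM, the end-of-study Emax fit (DR-EOS) and the
dose-response MMRM (DR-MMRM) on the same data, against the simulated
truth.  The dose-response methods borrow strength across arms (and, for
DR-MMRM, across visits), which shows up as smaller standard errors at
the lower doses.
"""

import pandas as pd

from drmmrm import (
    Design, Scenario, TruthParams, fit_dreos, fit_drmmrm, fit_mmrm,
    simulate_trial, true_effect,
)

design = Design()
scenario = Scenario(ed50_true=32.0, timecourse="linear", n_reps=1, seed=2024)
trial = simulate_trial(scenario, design, rep=0)
params = TruthParams(ed50=32.0, timecourse="linear")

rows = []
for fit in (fit_mmrm(trial), fit_dreos(trial), fit_drmmrm(trial)):
    last = fit.estimates[fit.estimates.week == 16.0]
    for r in last.itertuples():
        rows.append((fit.method, r.dose, r.estimate, r.se,
                     true_effect(params, r.dose, 16.0)))
table = pd.DataFrame(rows, columns=["method", "dose_mg", "ddUACR", "se", "truth"])
print(table.pivot(index="dose_mg", columns="method",
                  values=["ddUACR", "se"]).round(3).to_string())
print("\ntruth at week 16:",
      {d: round(true_effect(params, d, 16.0), 3) for d in (3, 10, 30, 100)})

eos, drm = fit_dreos(trial), fit_drmmrm(trial)
print(f"\nED50 estimates — DR-EOS: {eos.dose_response.ed50_hat:.1f} mg, "
      f"DR-MMRM: {drm.dose_response.ed50_hat:.1f} mg (true 32 mg)")
print("A ddUACR of -0.51 log(mg/g) is a 40% reduction in UACR; standard "
      "errors shrink from MMRM to DR-EOS to DR-MMRM at the lower doses.")
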