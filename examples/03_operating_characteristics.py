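"""A small Monte-Carlo study of estimator operating characteristics.

Runs 40 replicate trials for two scenarios and summarizes bias,
precision (SD) and RMSE of the last-visit placebo-adjusted estimate for
each method — a desk-scale version of the full 21-scenario x 1000-rep
study (reachable via `drmmrm study` or `run_study`).
"""

from drmmrm import Design, Scenario, run_study, summarize, theoretical_rmse

design = Design()
scenarios = [
    Scenario(ed50_true=8.0, timecourse="direct", n_reps=40, seed=11, index=0),
    Scenario(ed50_true=64.0, timecourse="linear", n_reps=40, seed=12, index=1),
]
raw = run_study(scenarios, design)
summary = summarize(raw, design)

cols = ["timecourse", "ed50_true", "dose", "method", "bias",
        "relative_bias_pct", "sd", "rmse"]
print(summary.estimates[cols].round(3).to_string(index=False))
print(f"\ntheoretical RMSE of an unbiased end-of-study contrast: "
      f"{theoretical_rmse(design.omega, design.sigma, design.n_per_arm):.3f} log(mg/g)")
print("MMRM sits at the theoretical RMSE; DR-MMRM beats it in every cell "
      "because sharing the Emax shape across visits buys precision. "
      "Relative bias is in % of the maximal (40%) effect.")

dr = summary.dose_response
print("\nED50 medians [2.5th, 97.5th percentiles]:")
for r in dr.itertuples():
    print(f"  {r.method:8s} true={r.ed50_true:5.0f}  "
          f"median={r.ed50_median:7.1f}  [{r.ed50_p2_5:6.1f}, {r.ed50_p97_5:8.1f}]")
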