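"""All-cause mortality: two-group Cox model on the matched cohort.

The package fits the partial likelihood by Newton-Raphson with Efron tie
handling.  The large-sample demonstration draws from the generator's
mortality submodel alone (50,000 pairs, true hazard ratio 2.2) where the
fitted HR recovers the truth within sampling error.
"""

import math

import mddburden as mb

records = mb.simulate_survival(50_000, log_hr=math.log(2.2), seed=1)
fit = mb.fit_cox(records)
print(f"true HR 2.20 -> fitted {fit.hr:.2f} "
      f"(95% CI {fit.ci95[0]:.2f}-{fit.ci95[1]:.2f}), "
      f"{fit.n_events} deaths among {fit.n:,} individuals")
print(f"death rate: {mb.mortality_rate(records):.1f} per 1000 person-years "
      "(pooled; configured to ~8.6)")

# the same fit on a full simulated registry cohort (fewer deaths, wider CI)
tables, _ = mb.generate(mb.SimConfig(seed=6, n_persons=15000))
codebook = mb.default_codebook()
cohort = mb.build_cohort(tables, codebook, ("2012-01-01", "2019-01-01"),
                         "2018-12-31", seed=6)
out = mb.mortality_analysis(cohort)
print(f"\nfull-pipeline cohort: HR {out['hr']:.2f} "
      f"(95% CI {out['ci95'][0]:.2f}-{out['ci95'][1]:.2f}), "
      f"{out['n_events']} deaths among {out['n']} matched individuals")
print("rates per 1000 py:", {k: round(v, 1) for k, v in
                             out["rate_per_1000py_by_group"].items()})
print("\nAt desk scale the cohort fit is noisy; the submodel run shows the")
print("estimator is unbiased at registry scale.")
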