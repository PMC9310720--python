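"""Stitch depressive events into treatment episodes; estimate duration.

Consecutive depression-related events (diagnoses, antidepressant or add-on
fills, ECT/rTMS/psychotherapy) no more than 365 days apart form one episode;
a terminal dispensation extends the end by up to 100 days of supply.  The
sensitivity variant tightens the gap to 180 days.  Durations of the incident
episode go into a Kaplan-Meier fit (persons with <1 year follow-up excluded;
open episodes censored).
"""

import mddburden as mb
from mddburden.pipeline import _km_input

tables, truth = mb.generate(mb.SimConfig(seed=3, n_persons=15000))
codebook = mb.default_codebook()
cohort = mb.build_cohort(tables, codebook, ("2012-01-01", "2019-01-01"),
                         "2018-12-31", seed=3)
events = mb.depressive_events_all(tables, codebook)

for gap in (365, 180):
    eps = mb.cohort_episodes(events, cohort, mb.EpisodeParams(gap_days=gap),
                             "2018-12-31")
    km_in = _km_input(eps, cohort)
    km = mb.km_fit(km_in["duration"], km_in["observed"])
    print(f"gap rule {gap} d: {len(eps)} episodes, KM median duration "
          f"{km.median:.0f} d (95% CI {km.median_ci[0]:.0f}-{km.median_ci[1]:.0f}, "
          f"n={km.n})")

print("\nThe 180-day rule splits the same event streams into more, shorter")
print("episodes, so its median lies below the 365-day one; the generator's")
print("true episode median is 398 days (episode ends clipped at the data end).")
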