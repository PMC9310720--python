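"""Care-level states at 0/3/6/9/12 months and the mobility flow table.

Each case is classified by the care level of its most recent depression
event at each quarterly timepoint; the flow table counts transitions between
consecutive timepoints (the numbers behind an alluvial diagram).
"""

import mddburden as mb

tables, _ = mb.generate(mb.SimConfig(seed=2, n_persons=10000))
codebook = mb.default_codebook()
cohort = mb.build_cohort(tables, codebook, ("2012-01-01", "2019-01-01"),
                         "2018-12-31", seed=2)
events = mb.depressive_events_all(tables, codebook)

summary = mb.referral_summary(cohort, events)
states = summary["states"]
print("state distribution by timepoint:")
for tp in (0, 3, 6, 9, 12):
    counts = states[f"m{tp}"].value_counts().to_dict()
    print(f"  month {tp:>2}: {counts}")

flows = summary["flows"]
moves = flows[(flows.state_from != flows.state_to) & (flows.n > 0)]
print(f"\noff-diagonal transitions: {moves.n.sum()} of {len(states) * 4}")
print(f"primary-onset cases reaching psychiatric care within a year: "
      f"{100 * summary['primary_to_psychiatric_share']:.1f}% "
      "(generator configured at 13.8%)")
print("\nMost cases stay at the care level where they were first diagnosed,")
print("mirroring the low mobility between healthcare levels in registry data.")
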