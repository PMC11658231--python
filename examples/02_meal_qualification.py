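"""Reconstruct meal records from EMA responses and apply the inclusion rules.

A meal enters the analysis when CGM readings cover its pre- and
postprandial windows, no other reported intake falls within the prior
2.5 h, and it was eaten between 06:00 and 24:00; participants need at
least three qualifying meals.
"""

import ppgr
from ppgr.meals import build_meal_records, filter_participants, qualify_meals

bundle = ppgr.generate_cohort(ppgr.SimConfig(n_participants=20, seed=2))
meals, parse_errors = build_meal_records(bundle.ema)
qual = qualify_meals(meals, bundle.traces)

print(f"reported meals: {len(meals)} ({len(parse_errors)} parse errors)")
print(f"qualified: {qual['qualified'].sum()} "
      f"({100 * qual['qualified'].mean():.1f}%)")
reasons = qual.loc[~qual["qualified"], "failure_reasons"].str.split(";").explode()
print("failure reasons:")
print(reasons.value_counts().to_string())

retained = filter_participants(qual, min_meals=3)
print(f"\nretained participants (>=3 qualifying meals): {len(retained)} / 20")
# Each failure reason is independent, so one meal can fail several rules;
# the audit table keeps every reason for the filter ledger.
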