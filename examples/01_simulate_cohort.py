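"""Generate a small synthetic free-living cohort and look at its streams.

The generator emulates a nine-day protocol: EMA meal surveys in six daily
windows, 15-min CGM, 5-s wrist ENMO epochs and nightly sleep windows,
with every meal's 2-h glucose iAUC driven by a known linear model.
"""

import ppgr

bundle = ppgr.generate_cohort(ppgr.SimConfig(n_participants=5, seed=1))

print(f"participants: {len(bundle.participants)}")
print(bundle.participants[["participant_id", "age", "sex", "bmi",
                           "prediabetes"]].to_string(index=False))
print(f"\nEMA meal reports: {len(bundle.ema)}")
print(bundle.ema[["participant_id", "response_timestamp", "occasion",
                  "reported_clock_time", "satiety"]].head(5).to_string(index=False))

pid = bundle.participants["participant_id"].iloc[0]
trace = bundle.traces[pid]
print(f"\nCGM trace for {pid}: {trace.times.size} readings "
      f"({(trace.span[1]-trace.span[0])/86400:.1f} days)")
print(f"epoch series for {pid}: {bundle.epochs[pid].enmo.size} five-second epochs")

mt = bundle.meal_truth
print(f"\nhidden truth: {len(mt)} meals, mean intended iAUC "
      f"{mt['intended_iauc'].mean():.1f} mmol/l*min")
# The intended iAUC is what the glucose trace was built to carry for each
# meal; downstream stages must recover it from the raw streams alone.
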