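"""Split exposures into within- and between-person parts; quantify ICC.

Person-mean centering separates each repeated measure into a habitual
(between-person) level and an occasion-to-occasion (within-person)
deviation.  The intraclass correlation from an intercept-only
random-intercept model gives the between-person share of total variance;
1 - ICC is the within share.
"""

import ppgr
from ppgr.centering import person_center, variance_contribution_table

bundle = ppgr.generate_cohort(ppgr.SimConfig(n_participants=60, seed=4))
mt = bundle.meal_truth
day = mt[mt["time_category"].notna()].rename(
    columns={"intended_iauc": "iauc_2h"})

centered = person_center(day, ["satiety", "sleep_h"])
one = centered[centered["participant_id"] == "P0000"]
print("participant P0000, sleep the night before (h):")
print(one[["sleep_h", "sleep_h_within", "sleep_h_between"]]
      .head(5).round(2).to_string(index=False))

tab = variance_contribution_table(
    day, continuous=["iauc_2h", "satiety", "pp_lpa_h", "daily_mvpa_h",
                     "sleep_h"],
    binary=["refined_grains", "whole_grains"])
print("\nvariance contributions (% of total):")
print(tab[["measure", "scale", "within_pct", "between_pct"]]
      .round(1).to_string(index=False))
# Glucose responses and most lifestyle measures vary more within than
# between persons - the situational component dominates the habitual one.
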