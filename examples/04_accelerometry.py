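"""From 15-s accelerometer epochs to habitual MVPA.

Epoch counts are screened for non-wear (≥ 30 min of consecutive zeros),
epochs at or above the 2298 counts-per-minute cut-off count as
moderate-to-vigorous activity, days need ≥ 8 h of weartime to be valid,
and a child enters the analysis only with ≥ 3 consecutive valid days
including a weekend day.
"""

import moveability as mv

# a child wearing the device Thursday through Sunday, 60 min MVPA per day,
# with a 45-min non-wear bout injected each day
series = mv.generate_epoch_counts("demo_child", habitual_mvpa_min_per_day=60.0,
                                  n_days=4, config=mv.EpochConfig(seed=1))
days, habitual = mv.process_series(series)

print(days[["date", "weartime_h", "mvpa_min", "is_weekend",
            "is_valid"]].to_string(index=False))
print(f"\nhabitual MVPA : {habitual.mvpa_min_per_day:.2f} min/day "
      f"over {habitual.n_valid_days} valid days")
print(f"mean weartime : {habitual.mean_valid_weartime_h:.2f} h")
print(f"included      : {habitual.included} "
      "(>= 3 consecutive valid days incl. a weekend day)")

# Only two days of wear fails the inclusion rule:
short = mv.generate_epoch_counts("short_child", 60.0, n_days=2)
_, hab2 = mv.process_series(short)
print(f"\n2-day child included: {hab2.included}")
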