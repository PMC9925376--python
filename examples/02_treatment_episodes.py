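"""Reconstruct treatment episodes from a pharmacy dispense series.

A refill gap longer than 122 days (4 months) splits an episode; each
episode ends at its last dispense plus the dispensed days of supply
(DDD count), capped at 90 days.
"""
import pandas as pd

from pgxreg import build_episodes, mg_to_ddd

dates = pd.to_datetime(["2008-01-01", "2008-03-15", "2008-06-01",
                        "2009-02-01", "2009-04-01"])
n_ddd = [100, 100, 100, 100, 120]

for e in build_episodes(dates, n_ddd):
    print(f"episode {e.start_date.date()} → {e.end_date.date()} "
          f"({e.n_dispenses} dispenses, {e.duration_days} days)")
# The 245-day gap between 2008-06-01 and 2009-02-01 exceeds 122 days, so two
# episodes result; the second ends 90 days (the tail cap, not 120) after its
# last dispense.

print(f"\n5000 mg sertraline = {mg_to_ddd('sertraline', 5000):.0f} DDD "
      "(50 mg/day defined daily dose)")
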