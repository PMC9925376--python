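"""Sample-size planning for a two-group Cox comparison (Schoenfeld formula).

Required events E = (z_{1-a/2} + z_power)^2 / (p (1-p) (ln HR)^2); the total
sample inflates E by the overall event rate.
"""
from pgxreg import cox_sample_size, schoenfeld_events

for hr in (1.2, 1.5):
    n = cox_sample_size(hr, exposed_proportion=0.036, event_rate=0.5,
                        power=0.8, alpha=0.05)
    e = schoenfeld_events(hr, 0.036, power=0.8, alpha=0.05)
    print(f"HR {hr}: {e:8.0f} events → total n = {n:6d} "
          "(minor group 3.6%, event rate 50%)")
# Detecting modest hazard ratios against a 3.6%-prevalence exposure group
# requires cohorts in the thousands — rare-phenotype pharmacogenetic safety
# signals need very large samples.
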