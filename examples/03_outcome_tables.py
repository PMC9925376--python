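"""Derive the four analysis-ready outcome tables from a synthetic registry.

Simulates a small cohort, rebuilds episodes, and prints event counts for
early non-persistence, discontinuation, switching, and 91-day mania.
"""
from pgxreg.pipeline import RunConfig, StudyData, make_fixture

_, tables = make_fixture("null", seed=11)
data = StudyData(tables, RunConfig(input_dir="synthetic"))

for outcome in ("nonpersistence", "discontinuation", "switch", "mania"):
    recs = data.records("sertraline", outcome)
    line = (f"{outcome:16s} records={len(recs):5d} "
            f"events={int(recs['event'].sum()):4d}")
    if "time_days" in recs:
        line += f"  median follow-up={recs['time_days'].median():6.1f} d"
    print(line)
# Each record is one treatment episode (or new-user index dispense for the
# switch outcome) with its event indicator, follow-up time, demographics,
# phenotype, and co-medication flags — ready for the model layer.
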