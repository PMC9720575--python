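"""Recode KABCO severities, split by residency, and tabulate an attribute.

Builds a tiny hand-written crash table, loads it through the data
dictionary, and prints the in-state count/percent table for the primary
contributing factor.  The percent columns are row shares: of all crashes
with that factor, what fraction ended in severe (SI), minor (MIN) or no
injury (NI).
"""

import pandas as pd

import crashmix as cm
from crashmix.schema import records_from_frame

raw = pd.DataFrame({
    "severity_kabco": ["K", "A", "B", "O", "O", "C", "O", "B"],
    "license_state": ["AL", "AL", "AL", "AL", "GA", "GA", "AL", "AL"],
    "factor": ["Fatigue", "Fatigue", "Speeding", "Fatigue", "Speeding",
               "Fatigue", "Speeding", "Fatigue"],
})
dictionary = cm.DataDictionary(attributes={"factor": ("Fatigue", "Speeding")},
                               year_column=None)
records, report = records_from_frame(raw, dictionary)
print(f"loaded {report.n_accepted} records, quarantined {report.n_rejected}")

part = cm.partition_residency(records, home_state="AL")
print(f"in-state: {len(part.in_state)}, out-of-state: {len(part.out_state)}")

table = cm.descriptive_table(part.in_state, "factor", dictionary)
print(table.to_text())
print("Each row: crashes with that factor, split across severity outcomes;")
print("percents are row shares and sum to 100.")
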