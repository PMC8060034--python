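"""Simulate a MOM session and summarise the behavioural vigilance decrement.

Builds the full published design (30 blocks of 64 dots, 2 vs 16 targets
among the 32 cued-colour dots) for one subject, fills outcomes from the
default behaviour model, and prints per-block miss rates.  Expect Active
miss rates to fall toward a ~17% plateau while Monitoring rates climb —
the behavioural signature of a vigilance decrement.
"""

import numpy as np

import momdecode as m

schedule = m.generate_schedule(m.TaskConfig(), seed=1)
schedule = m.simulate_behaviour(schedule, m.BehaviourModel(), seed=2)

df = m.schedule_to_frame(schedule)
print(f"dots simulated: {len(df)} over {df['block_index'].nunique()} blocks")

summary = m.summarize_behaviour(schedule)
table = summary.pivot_table(
    index="block_in_condition", columns="condition", values="miss_rate"
)
print("\nper-block miss rate (1 subject; Monitoring rests on only 2 targets/block):")
print(table.round(2).to_string())

hits = df[df["outcome"] == "hit"]
print(f"\nmean correct RT: {hits['rt_ms'].mean():.0f} ms over {len(hits)} hits")
print(f"misses: {(df['outcome'] == 'miss').sum()}, "
      f"false alarms: {df['outcome'].str.startswith('false_alarm').sum()}")
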