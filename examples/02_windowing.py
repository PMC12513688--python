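"""Turn timestamped hospitalization records into decision-step trajectories.

Shows the windowing rule (24 h first window, second window ending at the
next 6 AM, 6 AM-to-6 AM afterwards, truncation at 8 days) and the decision-
timing shift that pairs each window's state with the action taken in the
following window.
"""
import pandas as pd

from proprl.windows import build_cohort, decision_view

T = pd.Timestamp

events = pd.DataFrame(
    {
        "stay_id": ["A"] * 3,
        "timestamp": [T("2023-01-01 23:00"), T("2023-01-02 23:30"), T("2023-01-03 07:00")],
        "sofa": [4.0, 6.0, 5.0],
        "bnp": [310.0, 450.0, 420.0],
    }
)
actions = pd.DataFrame({"stay_id": ["A"], "timestamp": [T("2023-01-02 23:00")]})
outcomes = pd.DataFrame(
    {
        "stay_id": ["A"],
        "admit_time": [T("2023-01-01 22:00")],
        "end_time": [T("2023-01-03 09:00")],
        "outcome": ["alive"],
    }
)

window_table, excluded = build_cohort(events, actions, outcomes)
print("window-level table (one row per decision window):")
print(window_table[["stay_id", "t", "start", "end", "sofa", "action", "reward"]])
print()
decisions = decision_view(window_table.drop(columns=["start", "end"]))
print("decision-step view (state of window t paired with action of window t+1,")
print("terminal +100 attached to the final decision step):")
print(decisions)
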