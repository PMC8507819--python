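"""Score a single joint-angle recording frame by frame.

Builds a one-minute synthetic recording of a typical close-work dental
posture, scores every frame through the RULA worksheet, and prints the
step scores and the grand score of the first frame plus the recording's
time-in-score distribution.
"""

import numpy as np

from rulatime import score_recording, time_distribution
from rulatime.synthetic_data import default_states, generate_recording

# one posture state held statically for a minute
state = default_states()[0]  # close intraoral work
rec = generate_recording([state], [[1.0]], duration_s=60.0, rate=24.0, seed=1)

scores = score_recording(rec)
first = {c: int(scores[c].iloc[0]) for c in scores.columns if c != "t_s"}
print("first frame, right side:")
print(f"  upper arm {first['upper_arm_r']}, lower arm {first['lower_arm_r']}, "
      f"wrist {first['wrist_combined_r']} (posture {first['wrist_posture_r']} + "
      f"twist {first['wrist_twist_r']})")
print(f"  neck {first['neck']}, trunk {first['trunk']}, legs {first['legs']}")
print(f"  posture tables: A={first['table_a_r']}, B={first['table_b']} "
      f"-> final {first['final']}")

dist = time_distribution(scores["final"].to_numpy(), max_score=7)
print("\ntime in each final score over the minute:")
for value, frac in sorted(dist.rel_time.items()):
    print(f"  score {value}: {frac:.1%}")
print("\nA grand score of 7 means the worksheet calls for investigating and")
print("changing the working situation immediately; the distribution shows")
print("how much of the minute was spent there.")
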