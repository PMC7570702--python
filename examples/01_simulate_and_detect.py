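"""Simulate one walking session and detect its turns.

Builds a synthetic five-IMU session (three ~180 degree turns between
straight walking bouts), estimates yaw per location, and runs the
zero-crossing turn detector. Prints detected lower-back turns next to the
generated ground truth: start/end times in seconds, signed angle in
degrees (negative = left turn), and how far each boundary landed from the
truth.
"""

import turnkit as tk

session, truth = tk.simulate_session(tk.control_like(seed=42), subject_id="demo")
analysis = tk.analyze_session(session)

print(f"{'':>10} {'start':>8} {'end':>8} {'angle':>8}  direction")
for det, true in zip(analysis.l5_turns, truth.l5_turns):
    print(f"{'detected':>10} {det.start_s:8.2f} {det.end_s:8.2f} "
          f"{det.angle_deg:8.1f}  {det.direction.value}")
    print(f"{'truth':>10} {true.start_s:8.2f} {true.end_s:8.2f} "
          f"{true.angle_deg:8.1f}  {true.direction.value}")
    print(f"{'error':>10} {abs(det.start_s - true.start_s):8.3f} "
          f"{abs(det.end_s - true.end_s):8.3f}   (seconds)")

for turn, steps in zip(analysis.l5_turns, analysis.steps_by_turn):
    print(f"turn at {turn.start_s:6.2f}s: {len(steps['inner'])} inner / "
          f"{len(steps['outer'])} outer ankle steps")
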