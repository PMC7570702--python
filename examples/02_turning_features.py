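"""Extract the 425 turning characteristics from one session.

The feature schema is pinned: 109 characteristics per upper-body location
(21 spatiotemporal + 88 signal-based for head, neck, lower back) and 49
per ankle role (inner/outer relative to each turn's direction), 425 in
total. Prints the schema bookkeeping and a few interpretable values:
turn duration (s), angular velocity theta/T (deg/s), and RMS of the
vertical angular velocity (rad/s).
"""

import turnkit as tk
from turnkit.features import feature_manifest

session, _ = tk.simulate_session(tk.control_like(seed=7), subject_id="demo")
fv = tk.extract_session_features(session)

manifest = feature_manifest()
counts = manifest.counts()
print(f"total features: {len(fv.values)}")
for loc, c in counts.items():
    print(f"  {loc:>6}: {c['spatiotemporal']:2d} spatiotemporal "
          f"+ {c['signal']:2d} signal-based")

print(f"\nturns used: {fv.n_turns_used}")
for fid in ("L5_turn_time_mean", "L5_angular_velocity_mean",
            "L5_gyr_rms_VT_overall", "inner_steps_per_turn_mean",
            "HD_jerk_rms_R_overall"):
    print(f"  {fid:30s} {fv.values[fid]:10.3f}")
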