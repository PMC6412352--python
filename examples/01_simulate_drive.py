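"""Simulate a drive and show the planted awake/drowsy steering signature.

Generates a 5-minute synthetic drive whose KSS trace ramps from alert to
drowsy, windows it, and compares the zero-crossing rate of the detrended
steering angle between the two regimes.
"""

import numpy as np

from steerwake import ScenarioConfig, WindowSpec, generate_trace, slide_windows
from steerwake.features import zero_crossing_rate

cfg = ScenarioConfig(duration_s=300.0, seed=1)
trace = generate_trace(cfg)
print(f"simulated {len(trace)} samples at {cfg.fs:g} Hz, "
      f"KSS {trace.kss.min()}..{trace.kss.max()}")

segments = slide_windows(trace, WindowSpec())
zcr = {0: [], 1: []}
for seg in segments:
    if seg.label in zcr:
        zcr[seg.label].append(zero_crossing_rate(seg.angle_detrended, cfg.fs))

print(f"windows: {len(segments)} total, {len(zcr[0])} awake, {len(zcr[1])} drowsy")
print(f"mean steering ZCR  awake: {np.mean(zcr[0]):.2f}/s   drowsy: {np.mean(zcr[1]):.2f}/s")
print("the drowsy regime steers in sparse large corrections, so its")
print("detrended angle changes sign far less often than the alert regime's")
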