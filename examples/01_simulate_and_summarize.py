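"""Simulate one drift dive and summarize it with the broken-stick algorithm.

A drift dive has three phases: an active descent, a passive drift whose
vertical rate is the seal's buoyancy, and an active ascent.  The on-board
summarizer keeps the start, the end, and the four samples that best
explain the profile; the selection order and residuals are recorded.
"""

import numpy as np

import driftdive as dd

profile, label = dd.simulate_dive(
    "drift", {"drift_rate": -0.25, "drift_duration": 900.0}, seed=42
)
print(f"high-resolution dive: {profile.n_samples} samples at 30 s, "
      f"max depth {profile.max_depth:.0f} m, duration {profile.duration:.0f} s")

res = dd.bsa_summarize(profile)
print("\nsix-point summary (time s, depth m):")
for t, z in res.summarized.points:
    print(f"  {t:7.1f}  {z:7.1f}")
print(f"\nselection order (time-sorted indices): {res.selection_order}")
print(f"residuals in selection order (m): {np.round(res.residuals, 2)}")
print("\nThe first selected point is the deepest sample; the last residual "
      "tells how much vertical activity the summary failed to capture.")
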