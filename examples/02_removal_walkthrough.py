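"""Trace the rarest-first removal walkthrough on a ten-species plot.

The plot has abundances {1, 2, 3, 4, 4, 7, 9, 14, 33, 89}; expressed as
relative abundances rounded to two decimals, each 5% step consumes species
from the rare end, splitting a species across steps when needed.
"""

import numpy as np
import pandas as pd

import fdrobust as fr

x = np.array([1, 2, 3, 4, 4, 7, 9, 14, 33, 89], dtype=float)
species = [f"s{i:02d}" for i in range(1, 11)]
cm = fr.CommunityMatrix(pd.DataFrame([x], index=["plot1"], columns=species))

p = fr.round_relative(fr.relative_abundances(x))
print("relative abundances (2 dp):", p)

schedule = fr.removal_schedule_plotwise(cm, step_size=0.05, floor=0.5,
                                        round_digits=2)
for step in (1, 2):
    removed = schedule.removed_amount(step)[0]
    prev = schedule.removed_amount(step - 1)[0]
    delta = np.round(removed - prev, 3).tolist()
    print(f"\nstep {step}: removes",
          {sp: amt for sp, amt in zip(species, delta) if amt > 0})
    print(f"  fully removed so far: {int(schedule.n_fully_removed(step)[0])} species,"
          f" remaining share {schedule.remaining_share(step)[0]:.3f}")

print("\nStep 1 removes the three rarest species entirely plus 0.01 of the")
print("fourth; step 2 finishes the fourth, takes the fifth, and 0.02 of the")
print("sixth — each step trims exactly 5% of relative abundance.")
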