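"""Grid an irregularly sampled body-weight record and split it at the intervention.

Raw weighings arrive every 7-10 days; the pipeline snaps them to a 10-day grid
(averaging collisions, interpolating interior gaps) and partitions the trace at
the 6-month dietary-intervention boundary.
"""

import numpy as np

from bwdyn.preprocess import RawTrace, filter_cohort, grid_trace, split_phases

rng = np.random.default_rng(0)
times = np.cumsum(rng.integers(7, 11, size=30)) + 60.0  # weighing every 7-10 d
weights = 22 + 0.05 * (times - 60) + rng.normal(0, 0.4, times.size)
raw = RawTrace(animal_id="demo", times=times, weights=weights, diet="1D")

kept = filter_cohort([raw], min_measurements=7)
print(f"animals kept after the 7-measurement filter: {len(kept)}")

g = grid_trace(kept[0])
print(f"grid: {g.grid_times[0]:.0f}..{g.grid_times[-1]:.0f} d, "
      f"{len(g)} points, {int(g.interpolated_mask.sum())} interpolated")

pre, post = split_phases(g)
print(f"pre-intervention points: {len(pre)}  post-intervention points: {len(post)}")
# The interpolated count shows how many 10-day slots had no weighing; the
# pre/post split is where the dietary intervention starts (day 180).
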