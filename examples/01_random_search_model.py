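"""Simulate the looping random-search null model (Models S and R).

A released forager with no useful landscape memory is modeled as a
unit-step random walk whose heading noise is low-pass filtered and which
is folded back by 180° whenever it strays beyond a growing excursion
envelope (1 + k/10 unit lengths in loop k) or re-enters a small inner
disk at the release site.  Model S is the full path; Model R discards
fixes the harmonic radar cannot see (beyond 900 m or inside the 150°
blanking sector).
"""

import numpy as np

from beesearch import SimulatorConfig, apply_radar_mask, make_fixture, simulate_random_bee
from beesearch.simulator import simulate_raw

landscape = make_fixture("test-area")
config = SimulatorConfig()  # 10 000 unit steps, unit length 2.22 m

raw, info = simulate_raw(config, seed=1)
bee_s = simulate_random_bee(config, landscape, bee_id="S01", group="S", seed=1)
bee_r = apply_radar_mask(bee_s, landscape.radar)

d = np.hypot(bee_s.x, bee_s.y)
print(f"Model S: {bee_s.n_fixes} fixes, {info['inner_returns']} returns to the release site,")
print(f"         final loop index k = {info['loop_index']}")
print(f"         median / max distance from release: {np.median(d):.1f} m / {d.max():.1f} m")
print(f"Model R: {bee_r.n_fixes} fixes survive the radar mask "
      f"({bee_s.n_fixes - bee_r.n_fixes} removed)")

# The number of returns shows the walk loops back to the release site
# rather than diffusing away; the median distance is the quantity the
# unit length is calibrated against.
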