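"""Three-phase release curves for the three particle size classes.

Each curve bursts to 13% of payload in 24 h, adds a size-dependent
increment by 96 h (smaller particles release more), then settles into a
0.4%/day zero-order phase.
"""

import numpy as np

from depotpk import ReleaseModel, cumulative_release, default_release_params, release_rate

for size in ("10.6 um", "6.5 um", "3.9 um"):
    m = ReleaseModel(default_release_params(size))
    f24 = cumulative_release(m, 24.0)
    f96 = cumulative_release(m, 96.0)
    f672 = cumulative_release(m, 672.0)
    rate = release_rate(m, 240.0) * 24  # per day
    print(
        f"{size:>8}: 24 h {100*f24:.0f}%  96 h {100*f96:.0f}%  "
        f"day 28 {100*f672:.1f}%  sustained {100*rate:.2f}%/day"
    )
print("day-28 totals stay well below 100%: the depot outlasts the study window")
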