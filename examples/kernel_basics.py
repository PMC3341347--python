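"""The 2D-t dispersal kernel: density, mean distance, and sampling.

Run:  python examples/kernel_basics.py
"""

import numpy as np

from seedshadow import kernels

# The kernel parameter u (m^2) sets the scale of dispersal.  A few values
# of record: 253 and 2000 are the seed/pollen prior means; 92 and 6300 are
# posterior means for a low- and a high-dispersal oak stand.
for u in (253.0, 2000.0, 92.0, 6300.0):
    d = kernels.expected_distance(u)
    print(f"u = {u:7.0f} m^2  ->  mean dispersal distance {d:6.1f} m")

# param_from_distance inverts the transform: the prior truncation bounds,
# stated as 5 m and 157 m, become bounds on u.
lo, hi = kernels.param_from_distance(5.0), kernels.param_from_distance(157.0)
print(f"\nseed-prior truncation: u in [{lo:.1f}, {hi:.0f}] m^2")

# Random distances follow the radial law 2 pi r K(r); the sample mean
# converges to (pi/2) sqrt(u) despite the fat tail.
rng = np.random.default_rng(0)
r = kernels.sample_distances(800.0, 100_000, rng)
print(f"\nu = 800: sample mean {r.mean():.1f} m vs analytic "
      f"{kernels.expected_distance(800.0):.1f} m; "
      f"median {np.median(r):.1f} m (right-skewed: median < mean)")
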