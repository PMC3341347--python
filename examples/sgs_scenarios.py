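"""Site-history scenarios and their spatial-genetic-structure signatures.

Compares relatedness-by-distance profiles for a stand recolonized from
distant source populations (weak, flat structure) versus one regenerating
from scattered local source trees (strong short-range structure, steeper
for shorter dispersal).

Run:  python examples/sgs_scenarios.py
"""

import numpy as np

from seedshadow.sgs_sim import Scenario, run_scenario, synthetic_cohorts
from seedshadow.simulate import default_polygon

poly = default_polygon(7.5)
cohorts = synthetic_cohorts(poly, [100], np.random.default_rng(0))

for kind, extra in (("distant", {}), ("scattered", {"density_ha": 1.5})):
    sc = Scenario(kind=kind, u_s_values=(20.0, 7000.0), n_replicates=50, **extra)
    prof = run_scenario(sc, poly, cohorts, seed=1, generations=[1])
    print(f"\nscenario: {kind} sources  (generation 1, 50 replicates)")
    for u in sc.u_s_values:
        rows = prof[prof.u_s == u].head(5)
        classes = ", ".join(
            f"{lo:.0f}-{hi:.0f}m: {m:.3f}" if np.isfinite(m) else "n/a"
            for lo, hi, m in zip(rows.class_lo, rows.class_hi, rows["mean"])
        )
        print(f"  u_s={u:6.0f}  mean relatedness  {classes}")

print(
    "\nReading: distant-source recolonization leaves almost no spatial "
    "structure at any dispersal scale, while scattered in-plot sources "
    "produce elevated relatedness below ~20 m that fades faster when "
    "seed dispersal is short (u_s = 20 vs 7000)."
)
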