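"""Open-set identification: rejecting queries whose owner is not enrolled.

Sweeps the rejection threshold and reports the TP ratio (owner present,
assigned correctly below threshold) and TN ratio (owner's references
removed, query rejected) across the grid.
"""

import numpy as np

from skinid import EvalConfig, open_set_threshold_sweep, to_relative_abundance
from skinid.simulate import default_cohort_config, generate_cohort

table, _ = generate_cohort(default_cohort_config(seed=0))
rel = to_relative_abundance(table)

# scale the grid to the observed mean distances
probe = open_set_threshold_sweep(rel, [1e9], EvalConfig(seed=0))
dmax = 1.2 * max(r["absent_min_distance"] for r in probe.rows)
grid = np.linspace(1.0, dmax, 41)

report = open_set_threshold_sweep(rel, grid, EvalConfig(seed=0))
crossing = min(report.conditions, key=lambda c: abs(c["tp_ratio"] - c["tn_ratio"]))
print(f"threshold grid: {grid[0]:.0f} .. {grid[-1]:.0f} ({len(grid)} points)")
print(f"near the curves' crossing (threshold {crossing['value']:.1f}):")
print(f"  TP ratio {crossing['tp_ratio']:.3f}  TN ratio {crossing['tn_ratio']:.3f}")
# Raising the threshold accepts more genuine owners (TP up) but also more
# impostors (TN down); the crossing is the balanced operating point.
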