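#!/usr/bin/env python
"""Calibrate the hierarchical bootstrap before trusting any of its verdicts.

Simulates two-level null datasets (5 imaging sites x 40 neurons, site-effect
SD tau in {0, 0.5, 1} x neuron SD) and measures the two-sided rejection rate
at alpha = 0.05, next to a flat neuron-level bootstrap that ignores the site
structure, plus power at three planted effect sizes.

Finding: the hierarchical test stays roughly calibrated (conservative at
tau = 0, mildly liberal at tau = sigma with only 5 sites), while the flat
bootstrap rejects more than half of all null datasets at tau = sigma —
ignoring the nesting is not an option.
"""

import argparse
import json
from pathlib import Path

from mmpipe.calibration import calibration_table

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--n-datasets", type=int, default=300)
args = ap.parse_args()

table = calibration_table(n_datasets=args.n_datasets, n_boot=1000,
                          seed=args.seed)
out = Path("results/calibration.json")
out.parent.mkdir(exist_ok=True)
out.write_text(json.dumps(table, indent=2, sort_keys=True))

print(f"type-I error at alpha=0.05 ({args.n_datasets} null datasets each):")
for k, v in sorted(table["type_one"].items()):
    print(f"  hierarchical, {k}: {v:.3f}")
print(f"  flat bootstrap, tau=max: {table['type_one_flat_tau_max']:.3f}"
      "  <- inflated by the ignored site level")
print("power (effect in units of neuron SD, tau=0.5):")
for k, v in sorted(table["power"].items()):
    print(f"  {k}: {v:.3f}")
print(f"table written to {out}")
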