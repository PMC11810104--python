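#!/usr/bin/env python
"""Concurrent [AM+VM] mismatch vs the linear sum of unimodal mismatches.

Three closed-loop paradigms (AM, VM, AVM coupling) are simulated for one
shared population whose multimodal units carry an interaction gain g applied
when both halts co-occur.  The driver measures the population
concurrent/linear-sum ratio at g=2 and g=1 (parameter recovery), and
classifies per-neuron selectivity on a separate population with 15% planted
concurrent-selective units.
"""

import argparse

from mmpipe.pipeline import RunConfig, run_preset
from mmpipe.synthgen import SimConfig

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

sim = SimConfig(n_sites=10, neurons_per_site=50, session_length_s=600)
mm = {"multimodal_selective": 0.6, "motor": 0.1, "silent": 0.3}
for g in (2.0, 1.0):
    s = run_preset(RunConfig(
        preset="fig4_avm", seed=args.seed, n_boot=1000, sim=sim,
        interaction_gain=g, class_fractions=mm,
        class_overrides={"multimodal_selective":
                         {"mm_amp_am": 1.5, "mm_amp_vm": 1.5, "g": g}},
        out_dir=f"results/supralinearity_g{g:g}"))
    print(f"g={g:g}: concurrent/linear-sum ratio "
          f"{s['ratio_concurrent_over_sum']:.2f}, "
          f"concurrent > sum p = {s['p_concurrent_gt_sum']:.3f}")

sel = run_preset(RunConfig(
    preset="fig4_avm", seed=args.seed + 1, n_boot=1000,
    sim=SimConfig(n_sites=5, neurons_per_site=40, session_length_s=600),
    class_fractions={"multimodal_selective": 0.15, "motor": 0.15,
                     "silent": 0.70},
    out_dir="results/supralinearity_selectivity"))
fr = sel["selectivity_fractions"]
print(f"selectivity: planted {sel['gt_fraction_multimodal']:.0%} "
      f"concurrent-selective units, recovered {fr['concurrent_only']:.1%} "
      f"(sum-only {fr['sum_only']:.1%}, both {fr['both']:.1%}, "
      f"neither {fr['neither']:.1%})")
print("stats written under results/supralinearity_*")
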