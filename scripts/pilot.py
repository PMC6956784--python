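#!/usr/bin/env python
"""Pilot run used to freeze the simulation thresholds in the test suite.

Prints, for each frozen-threshold criterion, the observed values so the
margins can be re-checked after changes to the simulator or learner.
"""

import numpy as np

from ensaff.simulate import (
    preset_low_noise,
    preset_noise_free,
    preset_structure_dominant,
    recovery_experiment,
)


def main() -> None:
    rps = [recovery_experiment(preset_low_noise(n_ligands=400, seed=s), n_trees=200)[0].rP
           for s in range(5)]
    nulls = [recovery_experiment(preset_low_noise(n_ligands=400, seed=s), n_trees=200,
                                 permute_labels=True)[0].rP
             for s in range(5)]
    print(f"low-noise mean rP        = {np.mean(rps):.4f}   (threshold >= 0.90)")
    print(f"permuted mean |rP|       = {np.mean(np.abs(nulls)):.4f}   (threshold <= 0.15)")

    wins_s = wins_c = 0
    for seed in range(10):
        cfg = preset_structure_dominant(n_ligands=300, seed=seed)
        rp = {m: recovery_experiment(cfg, mode=m, n_trees=150)[0].rP
              for m in ("structure_only", "ligand_only", "combined")}
        wins_s += rp["structure_only"] > rp["ligand_only"]
        wins_c += rp["combined"] > rp["ligand_only"]
    print(f"structure > ligand wins  = {wins_s}/10   (threshold >= 8)")
    print(f"combined  > ligand wins  = {wins_c}/10   (threshold >= 8)")

    rep, _ = recovery_experiment(preset_noise_free(n_ligands=600, seed=0), n_trees=300)
    print(f"noise-free held-out RMSE = {rep.RMSE:.4f}   (threshold < 0.05)")


if __name__ == "__main__":
    main()
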