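#!/usr/bin/env python
"""Recent effective population size from linkage disequilibrium:
constant-Ne recovery on coalescent (Wright-Fisher) genotypes, and
slope-change detection on a trajectory with an injected accelerated
decline at t = 110 generations."""

import os

import numpy as np
import pandas as pd

from admixkit import demography, simdata

os.makedirs("results", exist_ok=True)
R = 1.82e-8

pos, dos = simdata.simulate_wf_genotypes(24, 1000, 5e7, R, 1e-8, seed=1)
traj = demography.ldne_trajectory(
    dos, pos, np.full(len(pos), "chr1"), R, bin_edges=np.geomspace(5e4, 2e6, 16)
)
traj.table.to_csv("results/06_ne_trajectory.tsv", sep="\t", index=False)
print(
    f"LD-based Ne from {len(pos)} coalescent SNPs (truth Ne = 1000): "
    f"median over bins = {np.nanmedian(traj.table['ne']):.0f}"
)

edges = np.geomspace(5e4, 2e6, 31)
mid = 0.5 * (edges[:-1] + edges[1:])
c = mid * R / (1 + mid * R)
t = np.sort(1 / (2 * c))[::-1]
ne = 20.0 * t + 500.0
k = int(np.argmin(np.abs(t - 110.0)))
ne[k:] -= 800.0
dev = demography.nes_slopes(pd.DataFrame({"t": t, "ne": ne}))
dev.to_csv("results/06_nes_slope_deviations.tsv", sep="\t", index=False)
knee = dev.loc[dev["slope_dev"].idxmin(), "t_mid"]
print(
    f"Slope-change series localizes the injected accelerated decline at "
    f"t = {knee:.1f} generations (injected at ~110)."
)
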