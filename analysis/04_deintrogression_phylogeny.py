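#!/usr/bin/env python
"""De-introgression and its effect on the SNP phylogeny: NJ trees from
250-bp-thinned SNPs before and after masking inferred donor tracts in
the admixed samples, plus the quartet-topology tally."""

import os

from admixkit import ancestry, genomio, phylo, simdata

os.makedirs("results", exist_ok=True)

cfg = simdata.SimConfig(seed=1)
panels = simdata.simulate_panels(cfg)
data, truth = simdata.simulate_admixed_cohort(cfg, panels)
table = genomio.polarize_and_filter(data, "outgroup")
aims = ancestry.select_aims(table, "ancA", "ancB")
model, post = ancestry.pulse_hmm_fit(data, aims, cfg.r, n_bootstrap=50, block_size_aims=250, seed=1)
tracts = ancestry.call_tracts(post, chrom_lengths=data.chrom_lengths)
masked, mask_df = ancestry.mask_introgressed(data, tracts)
mask_df.to_csv("results/04_mask_intervals.tsv", sep="\t", index=False)

keep = genomio.thin_snps(data.chrom, data.pos, 250)[:5000]
names = [s for s in data.samples if data.pops[s] in ("ancA", "ancB", "admixed")]
native = frozenset(s for s in names if data.pops[s] in ("ancA", "admixed"))
split = frozenset({native, frozenset(names) - native})

for label, dataset in [("before", data), ("after", masked)]:
    sub = dataset.subset_sites(keep)
    tree, support = phylo.nj_tree(sub, names, n_bootstrap=100, seed=0)
    tree.write(f"results/04_nj_{label}_masking.nwk")
    dm = phylo.p_distance_matrix(sub, names)
    adm = [s for s in names if data.pops[s] == "admixed"]
    d_native = dm.loc[adm, [s for s in names if data.pops[s] == "ancA"]].mean().mean()
    d_donor = dm.loc[adm, [s for s in names if data.pops[s] == "ancB"]].mean().mean()
    print(
        f"NJ {label} masking: admixed+native clade support = {support.get(split, 0.0):.0f}%; "
        f"mean P-distance admixed->native {d_native:.4f}, ->donor {d_donor:.4f}"
    )

props, _ = phylo.quartet_ils(
    data, {"A": "admixed", "B": "ancA", "C": "ancB", "D": "outgroup"}, window=1_000_000
)
props.rename("proportion").to_csv("results/04_quartet_proportions.tsv", sep="\t")
print("Quartet topology proportions (A=admixed, B=native, C=donor, D=outgroup):")
print(props.to_string())
print("Donor-pairing minor topology exceeding the other indicates admixture, not ILS.")
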