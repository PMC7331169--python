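"""Local-ancestry HMM: AIM selection rules, forward algorithm against a
hand-computed oracle, posterior properties, parameter recovery, tract
calling and dating, proportions, and de-introgression masking."""

import numpy as np
import pandas as pd
import pytest

from admixkit import ancestry, genomio, simdata
from conftest import make_site_table


def _panel_table(pA, pB, pos=None, chrom=None, nA=16, nB=16):
    n = len(pA)
    return pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["chr1"] * n,
            "pos": pos if pos is not None else (np.arange(n) + 1) * 20_000,
            "p_ancA": pA,
            "n_ancA": nA,
            "p_ancB": pB,
            "n_ancB": nB,
            "pO": 0.0,
            "nO": 8,
        }
    )


# ---------------------------------------------------------------------------
# AIM selection


def test_select_aims_spacing_rule():
    t = _panel_table([0.1, 0.1], [0.7, 0.7], pos=[1000, 6000])
    aims = ancestry.select_aims(t, "ancA", "ancB")
    assert len(aims) == 1
    assert aims.sites["pos"].iloc[0] == 1000
    assert aims.n_removed["spacing"] == 1


def test_select_aims_frequency_rule():
    t = _panel_table([0.0, 0.0], [0.49, 0.51], pos=[1000, 20_000])
    aims = ancestry.select_aims(t, "ancA", "ancB")
    assert len(aims) == 1
    assert aims.sites["pos"].iloc[0] == 20_000
    with pytest.raises(ValueError, match="divergence"):
        ancestry.select_aims(_panel_table([0.5], [0.6]), "ancA", "ancB")


def test_select_aims_matches_brute_force_filter(table_std):
    aims = ancestry.select_aims(table_std, "ancA", "ancB", smooth=False)
    # independent scan: frequency filter then greedy spacing per chromosome
    expected = 0
    ok = np.abs(table_std["p_ancA"] - table_std["p_ancB"]) >= 0.5
    for _, grp in table_std[ok].groupby("chrom"):
        last = -1e18
        for p in grp["pos"]:
            if p - last >= 10_000:
                expected += 1
                last = p
    assert len(aims) == expected


# ---------------------------------------------------------------------------
# HMM oracle and posterior properties


def _hand_forward(emit, gaps, rt, m):
    """Explicit 3-state matrix-product forward likelihood (oracle)."""
    s_list = np.exp(-rt * np.asarray(gaps))
    pi = np.array([(1 - m) ** 2, 2 * m * (1 - m), m**2])
    like = pi * emit[0]
    for i in range(1, len(gaps)):
        s = s_list[i]
        H = np.array([[s + (1 - s) * (1 - m), (1 - s) * m], [(1 - s) * (1 - m), s + (1 - s) * m]])
        T = np.empty((3, 3))
        T[0] = [H[0, 0] ** 2, 2 * H[0, 0] * H[0, 1], H[0, 1] ** 2]
        T[1] = [H[0, 0] * H[1, 0], H[0, 0] * H[1, 1] + H[0, 1] * H[1, 0], H[0, 1] * H[1, 1]]
        T[2] = [H[1, 0] ** 2, 2 * H[1, 0] * H[1, 1], H[1, 1] ** 2]
        like = (like @ T) * emit[i]
    return np.log(like.sum())


def test_forward_matches_hand_computed_matrix_product():
    emit = np.array([[0.7, 0.2, 0.1], [0.05, 0.15, 0.8]])
    gaps = np.array([0.0, 37_000.0])
    rt, m = 1.82e-8 * 120, 0.36
    got = ancestry._forward_block(emit[:, None, :], gaps, rt, m)
    assert got == pytest.approx(_hand_forward(emit, gaps, rt, m), abs=1e-10)
    # longer chain, different parameters
    rng = np.random.default_rng(0)
    emit5 = rng.random((5, 3)) + 0.01
    gaps5 = np.concatenate([[0], rng.uniform(5e3, 5e4, 4)])
    got5 = ancestry._forward_block(emit5[:, None, :], gaps5, 2e-6, 0.1)
    assert got5 == pytest.approx(_hand_forward(emit5, gaps5, 2e-6, 0.1), abs=1e-10)


def test_posteriors_sum_to_one_and_recover_perfect_information(cohort_small):
    """Fully diagnostic AIMs decoded in genotype mode recover the true
    dosage with near-certain posteriors."""
    cfg = simdata.SimConfig(seed=9, n_chrom=1, chrom_length=5_000_000,
                            n_sites_per_chrom=600, divergence=(0.0, 0.0))
    panels = simdata.simulate_panels(cfg)
    panels["pA"] = 0.0
    panels["pB"] = 1.0  # |pA - pB| = 1 everywhere
    data, truth = simdata.simulate_admixed_cohort(cfg, panels)
    table = _panel_table(
        panels["pA"], panels["pB"], pos=panels["pos"].to_numpy(), chrom=panels["chrom"]
    )
    aims = ancestry.select_aims(table, "ancA", "ancB", smooth=False)
    model, post = ancestry.pulse_hmm_fit(
        data, aims, cfg.r, mode="genotypes", n_bootstrap=10, block_size_aims=200, seed=0
    )
    assert np.allclose(post[["p0", "p1", "p2"]].sum(axis=1), 1.0, atol=1e-9)
    # true dosage at AIMs from truth tracts
    hits = total = 0
    for sample, grp in post.groupby("sample"):
        tr = truth.tracts[truth.tracts["sample"] == sample]
        for hap in (0, 1):
            sub = tr[tr["hap"] == hap].sort_values("start")
            ends = sub["end"].to_numpy()
            donor = (sub["ancestry"] == "donor").to_numpy()
            idx = np.searchsorted(ends, grp["pos"].to_numpy() - 1, side="right")
            if hap == 0:
                dose = donor[idx].astype(int)
            else:
                dose = dose + donor[idx].astype(int)
        called = np.argmax(grp[["p0", "p1", "p2"]].to_numpy(), axis=1)
        hits += (called == dose).sum()
        total += len(dose)
        top = grp[["p0", "p1", "p2"]].to_numpy()[np.arange(len(dose)), dose]
        assert (top >= 0.999).mean() > 0.99
    assert hits / total > 0.999


def test_likelihood_invariant_to_chromosome_order(cohort_small, table_small):
    _, _, data, _ = cohort_small
    aims = ancestry.select_aims(table_small, "ancA", "ancB")
    sample_idx = data.sample_indices("admixed")
    key = pd.MultiIndex.from_arrays([data.chrom, data.pos])
    rows = key.get_indexer(pd.MultiIndex.from_arrays([aims.sites["chrom"], aims.sites["pos"]]))
    emit = ancestry.build_emissions(
        data, rows, sample_idx, aims.sites["pA"].to_numpy(), aims.sites["pB"].to_numpy()
    )
    chains = ancestry._chains(aims)
    rt, m = 1.82e-8 * 120, 0.36
    ll_fwd = sum(ancestry._forward_block(emit[r], g, rt, m) for r, g in chains)
    ll_rev = sum(ancestry._forward_block(emit[r], g, rt, m) for r, g in reversed(chains))
    assert ll_fwd == pytest.approx(ll_rev, abs=1e-8)


def test_parameter_recovery_single_seed(cohort_std, table_std):
    cfg, _, data, truth = cohort_std
    aims = ancestry.select_aims(table_std, "ancA", "ancB")
    model, post = ancestry.pulse_hmm_fit(
        data, aims, cfg.r, n_bootstrap=500, block_size_aims=250, seed=1
    )
    assert 0.33 <= model.m <= 0.39
    assert model.ci_t[0] <= cfg.t <= model.ci_t[1]
    props = ancestry.ancestry_proportions(post)
    assert props.mean() == pytest.approx(model.m, abs=0.02)
    # per-sample estimates track each sample's realized donor fraction
    tr = truth.tracts
    lengths = tr["end"] - tr["start"]
    realized = lengths.where(tr["ancestry"] == "donor", 0).groupby(tr["sample"]).sum() / (
        2 * cfg.n_chrom * cfg.chrom_length
    )
    assert np.allclose(props.sort_index(), realized.sort_index(), atol=0.03)
    assert props.mean() == pytest.approx(cfg.m, abs=0.04)
    tracts = ancestry.call_tracts(post, chrom_lengths=data.chrom_lengths)
    t_tr = ancestry.tract_time(tracts, cfg.r, model.m)
    assert t_tr == pytest.approx(cfg.t, rel=0.15)
    # decoded donor bp agree with truth at >= 90 % base-pair recall
    truth_donor = truth.tracts[truth.tracts["ancestry"] == "donor"]
    recall_num = recall_den = 0
    for sample in props.index:
        td = truth_donor[truth_donor["sample"] == sample]
        cd = tracts[tracts["sample"] == sample]
        for chrom in cfg.chrom_names:
            t_iv = td[td["chrom"] == chrom][["start", "end"]].to_numpy()
            c_iv = cd[cd["chrom"] == chrom][["start", "end"]].to_numpy()
            for ts_, te in t_iv:
                recall_den += te - ts_
                for cs, ce in c_iv:
                    lo, hi = max(ts_, cs), min(te, ce)
                    if hi > lo:
                        recall_num += hi - lo
    assert recall_num / recall_den >= 0.90


def test_ancestry_proportions_edge_cases():
    post = pd.DataFrame(
        {"chrom": "c", "pos": [1, 2], "sample": "s", "p0": [0.0, 0.0], "p1": [0.0, 0.0], "p2": [1.0, 1.0]}
    )
    assert ancestry.ancestry_proportions(post).iloc[0] == 1.0
    post0 = post.assign(p0=1.0, p2=0.0)
    assert ancestry.ancestry_proportions(post0).iloc[0] == 0.0


# ---------------------------------------------------------------------------
# tract calling and dating


def _post_frame(p_donor, pos=None, chrom="c", sample="s"):
    p = np.asarray(p_donor, dtype=float)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos if pos is not None else (np.arange(len(p)) + 1) * 1000,
            "sample": sample,
            "p0": 1 - p,
            "p1": p,
            "p2": 0.0,
        }
    )


def test_call_tracts_whole_chromosome_run():
    post = _post_frame([0.95] * 10)
    tr = ancestry.call_tracts(post, chrom_lengths={"c": 20_000})
    assert len(tr) == 1
    assert tr["start"].iloc[0] == 0 and tr["end"].iloc[0] == 20_000
    assert tr["censored"].iloc[0]


def test_call_tracts_alternating_runs_and_midpoints():
    post = _post_frame([0.9, 0.1, 0.9, 0.1, 0.9], pos=[1000, 2000, 3000, 4000, 5000])
    tr = ancestry.call_tracts(post).sort_values("start").reset_index(drop=True)
    assert len(tr) == 3
    assert tr.loc[1, "start"] == 2500 and tr.loc[1, "end"] == 3500
    assert not tr.loc[1, "censored"]


def test_tract_time_closed_form_and_scaling():
    tr = pd.DataFrame(
        {"chrom": "c", "start": 0, "end": [708_616] * 40, "sample": "s",
         "dosage_class": 1, "mean_posterior": 0.9, "censored": False}
    )
    t = ancestry.tract_time(tr, r=1.82e-8, m=0.36, ploidy="haploid")
    assert t == pytest.approx(121.2, abs=0.1)
    tr2 = tr.assign(end=tr["end"] * 2)
    assert ancestry.tract_time(tr2, 1.82e-8, 0.36, ploidy="haploid") == pytest.approx(t / 2)
    with pytest.raises(ValueError):
        ancestry.tract_time(tr.assign(censored=True), 1.82e-8, 0.36)


# ---------------------------------------------------------------------------
# masking


def test_merge_mask_flags_reconnect_semantics():
    # two masked runs separated by two clean sites: gap absorbed
    flags = np.array([1, 1, 0, 0, 1, 1], dtype=bool)
    assert ancestry.merge_mask_flags(flags, 3).all()
    # three clean sites: flanks reconnect, gap survives
    flags3 = np.array([1, 1, 0, 0, 0, 1, 1], dtype=bool)
    out = ancestry.merge_mask_flags(flags3, 3)
    assert list(out) == [1, 1, 0, 0, 0, 1, 1]
    # no tracts -> identity
    clean = np.zeros(5, dtype=bool)
    assert not ancestry.merge_mask_flags(clean, 3).any()


def test_mask_introgressed_site_counts():
    gt = np.zeros((20, 2, 2), dtype=np.int8)
    data = genomio.GenotypeData(
        chrom=np.array(["c"] * 20, dtype=object),
        pos=np.arange(1, 21, dtype=np.int64),
        ref=np.array(["A"] * 20, dtype=object),
        alt=np.array(["T"] * 20, dtype=object),
        samples=["s0", "s1"],
        pops={"s0": "admixed", "s1": "ancA"},
        gt=gt,
        chrom_lengths={"c": 30},
    )
    tracts = pd.DataFrame(
        {"chrom": "c", "start": [4], "end": [10], "sample": "s0",
         "dosage_class": 1, "mean_posterior": 0.9, "censored": False}
    )
    masked, mask_df = ancestry.mask_introgressed(data, tracts)
    # sites at pos 5..10 (0-based 4..9) masked for s0 only
    assert (masked.gt[4:10, 0] == -1).all()
    assert (masked.gt[:4, 0] == 0).all() and (masked.gt[10:, 0] == 0).all()
    assert (masked.gt[:, 1] == 0).all()
    assert len(mask_df) == 1
    assert (masked.gt[:, 0] >= 0).sum() == 2 * 14
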