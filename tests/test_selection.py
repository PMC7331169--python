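"""Selection-scan statistics against independent brute-force oracles:
Weir-Cockerham components, pairwise-difference diversity, the EHH/iHH
trapezoid, the region-merge rule, and sweep localization."""

import itertools

import numpy as np
import pandas as pd
import pytest

from admixkit import genomio, selection, simdata


def _two_pop_data(g1, g2):
    """GenotypeData from per-population genotype matrices (sites, n, 2)."""
    g = np.concatenate([g1, g2], axis=1).astype(np.int8)
    n_sites = g.shape[0]
    samples = [f"a{i}" for i in range(g1.shape[1])] + [f"b{i}" for i in range(g2.shape[1])]
    pops = {s: ("p1" if s.startswith("a") else "p2") for s in samples}
    return genomio.GenotypeData(
        chrom=np.array(["c"] * n_sites, dtype=object),
        pos=(np.arange(n_sites, dtype=np.int64) + 1) * 100,
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        samples=samples,
        pops=pops,
        gt=g,
        chrom_lengths={"c": n_sites * 100 + 100},
    )


def _genotypes_for_counts(n_dip, n_alt):
    """Deterministic diploid genotypes realizing an allele count (all
    heterozygotes spread first, then homozygotes)."""
    g = np.zeros((n_dip, 2), dtype=np.int8)
    full, rem = divmod(n_alt, 2)
    g[:full] = 1
    if rem:
        g[full, 0] = 1
    return g


def _wc_oracle(g1, g2):
    """Independent Weir-Cockerham (1984) implementation from first
    principles for one site, two populations of diploids."""
    def summarize(g):
        n = g.shape[0]
        p = g.sum() / (2 * n)
        h = (g.sum(axis=1) == 1).mean()
        return n, p, h

    n1, p1, h1 = summarize(g1)
    n2, p2, h2 = summarize(g2)
    r = 2
    nbar = (n1 + n2) / 2
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def test_wc_fst_toy_counts_match_oracle():
    g1 = _genotypes_for_counts(10, 4)[None]   # pop1: 4/20 alt
    g2 = _genotypes_for_counts(10, 16)[None]  # pop2: 16/20 alt
    data = _two_pop_data(g1, g2)
    win = selection.fst_windows(data, "p1", "p2", window=10_000)
    a, b, c = _wc_oracle(g1[0], g2[0])
    assert win["fst"].iloc[0] == pytest.approx(a / (a + b + c), abs=1e-12)


def test_wc_fst_random_sites_match_oracle():
    rng = np.random.default_rng(2)
    g1 = rng.integers(0, 2, size=(50, 8, 2))
    g2 = rng.integers(0, 2, size=(50, 12, 2))
    data = _two_pop_data(g1, g2)
    win = selection.fst_windows(data, "p1", "p2", window=10_000)
    num = den = 0.0
    for s in range(50):
        p1, p2 = g1[s].mean(), g2[s].mean()
        if (p1 == 0 and p2 == 0) or (p1 == 1 and p2 == 1):
            continue
        a, b, c = _wc_oracle(g1[s], g2[s])
        num += a
        den += a + b + c
    assert win["fst"].iloc[0] == pytest.approx(num / den, abs=1e-10)


def test_fst_limits():
    rng = np.random.default_rng(0)
    shared = rng.integers(0, 2, size=(40, 20, 2))
    same = _two_pop_data(shared[:, :10], shared[:, 10:])
    v = selection.fst_windows(same, "p1", "p2", window=10_000)["fst"].iloc[0]
    assert abs(v) < 0.08  # identical sampling distribution -> near zero
    fixed = _two_pop_data(np.zeros((40, 20, 2)), np.ones((40, 20, 2)))
    v1 = selection.fst_windows(fixed, "p1", "p2", window=10_000)["fst"].iloc[0]
    assert v1 == pytest.approx(1.0, abs=1e-6)


def test_wc_and_hudson_correlate(cohort_std):
    _, _, data, _ = cohort_std
    wc = selection.fst_windows(data, "ancA", "ancB", window=500_000)
    hu = selection.fst_windows(data, "ancA", "ancB", window=500_000, estimator="hudson")
    ok = wc["fst"].notna() & hu["fst"].notna()
    assert np.corrcoef(wc["fst"][ok], hu["fst"][ok])[0, 1] > 0.99


def test_pi_monomorphic_and_single_site():
    mono = _two_pop_data(np.zeros((10, 10, 2)), np.zeros((10, 10, 2)))
    assert (selection.pi_windows(mono, "p1", window=10_000)["pi_site"] == 0).all()
    # single site at p = 0.5 with many samples: per-site pi ~ 0.5
    half = np.zeros((1, 200, 2), dtype=np.int8)
    half[0, :, 0] = 1
    data = _two_pop_data(half[:, :100], half[:, 100:])
    pi = selection.pi_windows(data, "p1", window=10_000)
    assert pi["pi_site"].iloc[0] == pytest.approx(0.5, abs=0.01)


def test_pi_matches_pairwise_difference_oracle():
    rng = np.random.default_rng(7)
    g = rng.integers(0, 2, size=(30, 9, 2))
    data = _two_pop_data(g, g[:, :1])
    pi = selection.pi_windows(data, "p1", window=10_000)
    # oracle: mean pairwise allele differences over all C(2n, 2) allele pairs
    total = 0.0
    for s in range(30):
        alleles = g[s].reshape(-1)
        diffs = sum(x != y for x, y in itertools.combinations(alleles, 2))
        total += diffs / (len(alleles) * (len(alleles) - 1) / 2)
    assert pi["pi_site"].iloc[0] * pi["n_variants"].iloc[0] == pytest.approx(total, abs=1e-9)


# ---------------------------------------------------------------------------
# EHH / XP-EHH


def _manual_ihh(hap, pos, core, cutoff):
    """Hand trapezoid of the EHH step function, both sides."""
    def side(indices):
        classes = [tuple()] * hap.shape[0]
        ehh_prev, x_prev, ihh = 1.0, pos[core], 0.0
        n = hap.shape[0]
        for j in indices:
            classes = [c + (hap[k, j],) for k, c in enumerate(classes)]
            counts = pd.Series(classes).value_counts().to_numpy()
            ehh = (counts * (counts - 1) / 2).sum() / (n * (n - 1) / 2)
            ihh += 0.5 * (ehh_prev + ehh) * abs(pos[j] - x_prev)
            if ehh < cutoff:
                return ihh
            ehh_prev, x_prev = ehh, pos[j]
        return None  # ran off the end
    right = side(range(core + 1, hap.shape[1]))
    left = side(range(core - 1, -1, -1))
    if right is None or left is None:
        return None
    return right + left


def test_ihh_matches_hand_computed_trapezoid():
    # 4 haplotypes over 9 sites; EHH collapses to 0 within the window
    hap = np.array(
        [
            [0, 1, 0, 1, 1, 0, 1, 0, 0],
            [1, 1, 0, 1, 1, 0, 1, 1, 0],
            [0, 0, 1, 0, 1, 1, 0, 0, 1],
            [1, 0, 1, 1, 1, 1, 1, 0, 1],
        ],
        dtype=np.int8,
    )
    pos = np.array([100, 300, 450, 700, 1000, 1150, 1400, 1800, 2100], dtype=np.int64)
    core = 4
    cutoff = 0.05
    expected = _manual_ihh(hap, pos, core, cutoff)
    right = selection._ihh_side(hap, pos, core, 1, cutoff, 10_000)
    left = selection._ihh_side(hap, pos, core, -1, cutoff, 10_000)
    assert right >= 0 and left >= 0
    assert right + left == pytest.approx(expected, abs=1e-12)


def test_ehh_is_one_at_core_and_monotone():
    rng = np.random.default_rng(4)
    hap = rng.integers(0, 2, size=(20, 60)).astype(np.int8)
    pos = np.sort(rng.choice(100_000, 60, replace=False)).astype(np.int64)
    xs, es = selection.ehh_decay(hap, pos, core=5)
    assert es[0] == 1.0
    assert (np.diff(es) <= 1e-12).all()


def test_xpehh_zero_for_identical_populations():
    rng = np.random.default_rng(8)
    hap = rng.integers(0, 2, size=(16, 400)).astype(np.int8)
    pos = np.sort(rng.choice(2_000_000, 400, replace=False)).astype(np.int64)
    xp = selection.xpehh_scan(hap, hap.copy(), pos)
    ok = np.isfinite(xp["raw"])
    assert ok.any()
    assert np.allclose(xp["raw"][ok], 0.0)


def test_xpehh_standardization_and_sweep_direction():
    cfg = simdata.SimConfig(seed=13, n_chrom=1, chrom_length=4_000_000, n_sites_per_chrom=1500)
    panels = simdata.simulate_panels(cfg)
    data, _ = simdata.simulate_admixed_cohort(cfg, panels)
    pos = data.pos
    iA, iB = data.sample_indices("ancA"), data.sample_indices("ancB")
    hapA = np.vstack([data.gt[:, i, h] for i in iA for h in (0, 1)])
    hapB = np.vstack([data.gt[:, i, h] for i in iB for h in (0, 1)])
    rng = np.random.default_rng(0)
    swept = simdata.paint_sweep(hapA, pos, center=2_000_000, width=600_000, carrier_frac=0.9, rng=rng)
    xp = selection.xpehh_scan(swept, hapB, pos)
    ok = np.isfinite(xp["std"])
    assert abs(xp["std"][ok].mean()) < 1e-6
    assert xp["std"][ok].std(ddof=0) == pytest.approx(1.0, abs=1e-6)
    in_sweep = ok & (pos > 1_800_000) & (pos < 2_200_000)
    out_sweep = ok & ((pos < 1_200_000) | (pos > 2_800_000))
    assert xp.loc[in_sweep, "raw"].mean() > xp.loc[out_sweep, "raw"].mean()


def test_sweep_localized_by_merged_regions():
    """A painted 500-kb hard sweep in popA (90% carriers) is localized by
    the merged top-1% XP-EHH regions: the top-scoring region falls inside
    the swept interval in >= 18 of 20 seeds."""
    hits = 0
    center, width = 1_000_000, 500_000
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n_sites = 1000
        pos = np.sort(rng.choice(2_000_000, n_sites, replace=False)).astype(np.int64)
        p = rng.uniform(0.1, 0.9, n_sites)
        hapA = (rng.random((24, n_sites)) < p).astype(np.int8)
        hapB = (rng.random((24, n_sites)) < p).astype(np.int8)
        hapA = simdata.paint_sweep(hapA, pos, center=center, width=width, carrier_frac=0.9, rng=rng)
        xp = selection.xpehh_scan(hapA, hapB, pos)
        xp["chrom"] = "c"
        xp["sig"] = xp["std"] >= np.nanquantile(xp["std"], 0.99)
        regions = selection.merge_regions(xp)
        if regions.empty:
            continue
        top = regions.loc[regions["peak"].idxmax()]
        mid = (top["start"] + top["end"]) / 2
        if abs(mid - center) <= width / 2:
            hits += 1
    assert hits >= 18


# ---------------------------------------------------------------------------
# region merging


def _scores(pos, sig):
    return pd.DataFrame({"chrom": "c", "pos": pos, "sig": sig})


def test_merge_allows_one_embedded_nonsignificant():
    reg = selection.merge_regions(_scores([10, 20, 30, 40, 50], [1, 1, 0, 1, 1]))
    assert len(reg) == 1
    assert reg["n_snps"].iloc[0] == 4


def test_merge_drops_isolated_significant_snps():
    reg = selection.merge_regions(_scores([10, 20, 30, 40], [1, 0, 0, 1]))
    assert reg.empty


def test_merge_half_distance_extension():
    reg = selection.merge_regions(_scores([50, 100, 200, 260], [0, 1, 1, 0]))
    assert len(reg) == 1
    assert reg["start"].iloc[0] == 75
    assert reg["end"].iloc[0] == 230


def test_overlap_selection_oracle():
    rng = np.random.default_rng(9)
    def regions(n):
        s = rng.integers(0, 5000, n)
        return pd.DataFrame({"chrom": "c", "start": s, "end": s + rng.integers(10, 200, n)})
    a, b = regions(25), regions(25)
    got = selection.overlap_selection(a, b)
    assert (got["method"] == "both").all()
    expected = set()
    for s1, e1 in a[["start", "end"]].to_numpy():
        for s2, e2 in b[["start", "end"]].to_numpy():
            if s1 < e2 and s2 < e1:
                expected.add(("c", max(s1, s2), min(e1, e2)))
    assert set(map(tuple, got[["chrom", "start", "end"]].to_numpy())) == expected
    nested_a = pd.DataFrame({"chrom": ["c"], "start": [100], "end": [500]})
    nested_b = pd.DataFrame({"chrom": ["c"], "start": [200], "end": [300]})
    inner = selection.overlap_selection(nested_a, nested_b)
    assert (inner.loc[0, "start"], inner.loc[0, "end"]) == (200, 300)
    disjoint = selection.overlap_selection(nested_b, pd.DataFrame({"chrom": ["c"], "start": [900], "end": [950]}))
    assert disjoint.empty
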