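"""Domestication-scan statistics.

Windowed F_ST (Weir–Cockerham 1984 variance components; Hudson estimator
as a cross-check), windowed nucleotide diversity, a cross-population
extended-haplotype-homozygosity (XP-EHH) scan with genome-wide
standardization, the region-merge rule for contiguous significant SNPs
(one embedded non-significant SNP tolerated, half-distance extension,
isolated significant SNPs discarded), and cross-method interval overlap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit

from .genomio import GenotypeData, make_windows
from .introgression import overlap_windows

__all__ = [
    "wc_fst_components",
    "hudson_fst_components",
    "fst_windows",
    "pi_windows",
    "ehh_decay",
    "xpehh_scan",
    "merge_regions",
    "overlap_selection",
]


# ---------------------------------------------------------------------------
# F_ST


def _pop_site_stats(data: GenotypeData, pop: str):
    """Per-site (n diploids called, alt freq, observed het fraction)."""
    idx = data.sample_indices(pop)
    g = data.gt[:, idx, :]
    called = (g >= 0).all(axis=2)
    n = called.sum(axis=1).astype(float)
    dose = np.where(called, g.sum(axis=2), 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dose.sum(axis=1) / (2 * n)
        het = (np.where(called, g.sum(axis=2) == 1, False)).sum(axis=1) / n
    return n, p, het


def wc_fst_components(n1, p1, h1, n2, p2, h2):
    """Weir–Cockerham (1984) per-site variance components (a, b, c) for
    two populations of diploids. Inputs are per-site arrays of called
    diploid counts, alt frequencies and observed heterozygote fractions."""
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    nbar = (n1 + n2) / 2.0
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1.0) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    return a, b, c


def hudson_fst_components(n1, p1, n2, p2):
    """Hudson/Bhatia per-site numerator and denominator from allele counts
    (n here = called diploids; allele counts are 2n)."""
    a1, a2 = 2 * np.asarray(n1, float), 2 * np.asarray(n2, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (a1 - 1) - p2 * (1 - p2) / (a2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def fst_windows(
    data: GenotypeData,
    pop1: str,
    pop2: str,
    window: int = 100_000,
    estimator: str = "WC84",
) -> pd.DataFrame:
    """Windowed F_ST between two populations.

    Window value is the ratio of summed per-site components (sum a /
    sum(a+b+c) for WC84; sum num / sum den for Hudson); negative values
    are retained. Windows with no polymorphic site are missing. The
    genome mean +/- SD over non-missing windows is stored in ``attrs``.
    """
    n1, p1, h1 = _pop_site_stats(data, pop1)
    n2, p2, h2 = _pop_site_stats(data, pop2)
    usable = (n1 >= 2) & (n2 >= 2)
    poly = usable & ~(((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1)))
    if estimator == "WC84":
        a, b, c = wc_fst_components(n1, p1, h1, n2, p2, h2)
        num, den = a, a + b + c
    elif estimator == "hudson":
        num, den = hudson_fst_components(n1, p1, n2, p2)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    num = np.where(poly, num, 0.0)
    den = np.where(poly, den, 0.0)

    pos0 = data.pos - 1
    rows = []
    for w in make_windows(data.chrom_lengths, window):
        sel = (data.chrom == w.chrom) & (pos0 >= w.start) & (pos0 < w.end)
        n_poly = int(poly[sel].sum())
        d = den[sel].sum()
        val = num[sel].sum() / d if (n_poly > 0 and d != 0) else np.nan
        rows.append((w.chrom, w.start, w.end, val, n_poly))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "fst", "n_sites"])
    ok = out["fst"].notna()
    out["quantile"] = np.nan
    out.loc[ok, "quantile"] = out.loc[ok, "fst"].rank(pct=True)
    out.attrs["genome_mean"] = float(out.loc[ok, "fst"].mean())
    out.attrs["genome_sd"] = float(out.loc[ok, "fst"].std(ddof=1))
    return out


def pi_windows(data: GenotypeData, pop: str, window: int = 100_000) -> pd.DataFrame:
    """Windowed nucleotide diversity for one population.

    Per-site unbiased heterozygosity 2p(1-p) * n_alleles/(n_alleles - 1)
    summed over sites; reported as mean per variant site (``pi_site``)
    and per bp (``pi_bp``).
    """
    n, p, _ = _pop_site_stats(data, pop)
    alleles = 2 * n
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2 * p * (1 - p) * alleles / (alleles - 1)
    pi = np.where(alleles >= 2, pi, 0.0)
    pos0 = data.pos - 1
    rows = []
    for w in make_windows(data.chrom_lengths, window):
        sel = (data.chrom == w.chrom) & (pos0 >= w.start) & (pos0 < w.end)
        tot = pi[sel].sum()
        n_var = int((pi[sel] > 0).sum())
        rows.append(
            (w.chrom, w.start, w.end, tot / n_var if n_var else 0.0, tot / (w.end - w.start), n_var)
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "pi_site", "pi_bp", "n_variants"])


# ---------------------------------------------------------------------------
# XP-EHH


@njit(cache=False)
def _ihh_side(hap, pos, core, step, cutoff, max_gap):
    """Integrated EHH from a core outward in one direction.

    Haplotype classes are refined site by site (core site excluded;
    EHH = 1 at the core); the EHH curve is trapezoid-integrated over bp
    until it drops below ``cutoff``. Returns -1 if the chromosome end or
    a gap larger than ``max_gap`` is reached first (score undefined).
    """
    n, S = hap.shape
    ids = np.zeros(n, dtype=np.int64)
    ehh_prev = 1.0
    x_prev = pos[core]
    ihh = 0.0
    denom = n * (n - 1) / 2.0
    j = core + step
    while 0 <= j < S:
        if abs(pos[j] - x_prev) > max_gap:
            return -1.0
        for k in range(n):
            ids[k] = ids[k] * 2 + hap[k, j]
        order = np.argsort(ids)
        # dense renumber + class counts
        ehh_num = 0.0
        rank = 0
        count = 1
        prev = ids[order[0]]
        new_ids = np.empty(n, dtype=np.int64)
        new_ids[order[0]] = 0
        for k in range(1, n):
            v = ids[order[k]]
            if v == prev:
                count += 1
            else:
                ehh_num += count * (count - 1) / 2.0
                rank += 1
                count = 1
                prev = v
            new_ids[order[k]] = rank
        ehh_num += count * (count - 1) / 2.0
        ids = new_ids
        ehh = ehh_num / denom
        ihh += 0.5 * (ehh_prev + ehh) * abs(pos[j] - x_prev)
        if ehh < cutoff:
            return ihh
        ehh_prev = ehh
        x_prev = pos[j]
        j += step
    return -1.0


def ehh_decay(hap: np.ndarray, pos: np.ndarray, core: int) -> tuple:
    """EHH curve outward to the right of a core (positions, EHH values);
    diagnostic helper mirroring the kernel's class refinement."""
    n, S = hap.shape
    classes = [tuple()] * n
    xs, es = [int(pos[core])], [1.0]
    denom = n * (n - 1) / 2.0
    for j in range(core + 1, S):
        classes = [c + (int(hap[k, j]),) for k, c in enumerate(classes)]
        counts = pd.Series(classes).value_counts().to_numpy()
        es.append(float((counts * (counts - 1) / 2.0).sum() / denom))
        xs.append(int(pos[j]))
    return np.array(xs), np.array(es)


def xpehh_scan(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    pos: np.ndarray,
    maf_min: float = 0.05,
    ehh_cutoff: float = 0.05,
    max_gap: int = 200_000,
) -> pd.DataFrame:
    """Per-SNP raw and standardized XP-EHH for one chromosome.

    ``hap_a``/``hap_b`` are phased 0/1 haplotype matrices (n_hap, n_sites)
    on a shared sorted position vector. Cores are SNPs with pooled minor
    allele frequency >= ``maf_min``. raw = ln(iHH_A / iHH_B); scores are
    standardized to mean 0, SD 1 over finite raw values. Cores whose EHH
    fails to decay below ``ehh_cutoff`` before a chromosome end or a
    ``max_gap`` gap, or with iHH_B = 0, are missing.
    """
    hap_a = np.ascontiguousarray(hap_a, dtype=np.int8)
    hap_b = np.ascontiguousarray(hap_b, dtype=np.int8)
    pos = np.asarray(pos, dtype=np.int64)
    pooled = np.concatenate([hap_a, hap_b], axis=0)
    freq = pooled.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    cores = np.flatnonzero(maf >= maf_min)

    raw = np.full(len(pos), np.nan)
    for c in cores:
        ia = _ihh_side(hap_a, pos, c, 1, ehh_cutoff, max_gap)
        if ia < 0:
            continue
        il = _ihh_side(hap_a, pos, c, -1, ehh_cutoff, max_gap)
        if il < 0:
            continue
        ib = _ihh_side(hap_b, pos, c, 1, ehh_cutoff, max_gap)
        if ib < 0:
            continue
        ibl = _ihh_side(hap_b, pos, c, -1, ehh_cutoff, max_gap)
        if ibl < 0:
            continue
        ihh_a = ia + il
        ihh_b = ib + ibl
        if ihh_b <= 0 or ihh_a <= 0:
            continue
        raw[c] = np.log(ihh_a / ihh_b)

    out = pd.DataFrame({"pos": pos, "raw": raw})
    ok = np.isfinite(raw)
    if ok.sum() >= 2:
        mu, sd = raw[ok].mean(), raw[ok].std(ddof=0)
        out["std"] = (raw - mu) / sd if sd > 0 else 0.0
    else:
        out["std"] = np.nan
    return out


# ---------------------------------------------------------------------------
# region merging / overlap


def merge_regions(scores: pd.DataFrame, sig_col: str = "sig") -> pd.DataFrame:
    """Integrate contiguous significant SNPs into selection regions.

    ``scores`` has sorted (chrom, pos) for every scored SNP and a boolean
    ``sig`` column. Runs tolerate at most one embedded non-significant
    SNP; bounds extend by half the distance to the nearest flanking
    non-significant marker (or stop at the outer significant SNP at
    chromosome ends); runs containing a single significant SNP are
    discarded.
    """
    rows = []
    for chrom, grp in scores.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        sig = grp[sig_col].to_numpy(dtype=bool)
        sig_idx = np.flatnonzero(sig)
        if len(sig_idx) == 0:
            continue
        runs = [[sig_idx[0]]]
        for i in sig_idx[1:]:
            if i - runs[-1][-1] - 1 <= 1:  # at most one non-sig SNP between
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            if len(run) < 2:
                continue
            first, last = run[0], run[-1]
            left = pos[first] - (pos[first] - pos[first - 1]) / 2 if first > 0 else pos[first]
            right = pos[last] + (pos[last + 1] - pos[last]) / 2 if last < len(pos) - 1 else pos[last]
            peak = np.nan
            if "std" in grp.columns:
                peak = float(np.nanmax(grp["std"].to_numpy()[run]))
            rows.append((chrom, int(left), int(np.ceil(right)), len(run), peak))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "peak"])


def overlap_selection(fst_regions: pd.DataFrame, xpehh_regions: pd.DataFrame) -> pd.DataFrame:
    """Intervals detected by both methods, tagged method='both'."""
    out = overlap_windows(fst_regions, xpehh_regions)
    out["method"] = "both"
    return out
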