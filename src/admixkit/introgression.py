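"""Frequency-based ABBA-BABA statistics.

Patterson's D from per-population derived-allele frequencies with
block-resampled standard errors, the windowed f_d introgression-fraction
estimator, empirical-quantile outlier windows, interval overlap between
window sets, and the X-vs-autosome contrast.

Per site with derived frequencies (p1, p2, p3, pO):

    ABBA = (1 - p1) * p2 * p3 * (1 - pO)
    BABA = p1 * (1 - p2) * p3 * (1 - pO)
    D    = sum(ABBA - BABA) / sum(ABBA + BABA)

f_d normalizes the window D numerator by its value under complete
introgression, substituting the donor frequency max(p2, p3) for both P2
and P3 in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomio import GenomicWindow, make_windows

__all__ = [
    "DStatResult",
    "site_patterns",
    "patterson_d",
    "fd_windows",
    "outlier_windows",
    "overlap_windows",
    "x_autosome_contrast",
]


@dataclass
class DStatResult:
    D: float
    se: float
    z: float
    p: float
    n_blocks: int
    block_size: int
    abba_sum: float
    baba_sum: float
    method: str = "bootstrap"


def site_patterns(table: pd.DataFrame, trio: tuple) -> tuple:
    """Per-site ABBA/BABA weights for trio (P1, P2, P3) against the outgroup."""
    p1 = table[f"p_{trio[0]}"].to_numpy(dtype=float)
    p2 = table[f"p_{trio[1]}"].to_numpy(dtype=float)
    p3 = table[f"p_{trio[2]}"].to_numpy(dtype=float)
    pO = table["pO"].to_numpy(dtype=float)
    abba = (1 - p1) * p2 * p3 * (1 - pO)
    baba = p1 * (1 - p2) * p3 * (1 - pO)
    return abba, baba


def patterson_d(
    table: pd.DataFrame,
    trio: tuple,
    block_size: int = 30_000_000,
    n_boot: int = 1000,
    method: str = "bootstrap",
    seed: int = 0,
) -> DStatResult:
    """Genome-wide Patterson's D with block-resampled standard error.

    Contiguous genomic blocks of ``block_size`` bp are the resampling unit
    (bootstrap by default, delete-one jackknife as a cross-check). D is
    NaN when no site carries ABBA or BABA weight.
    """
    abba, baba = site_patterns(table, trio)
    tot_a, tot_b = abba.sum(), baba.sum()
    if tot_a + tot_b == 0:
        return DStatResult(np.nan, np.nan, np.nan, np.nan, 0, block_size, 0.0, 0.0, method)
    D = (tot_a - tot_b) / (tot_a + tot_b)

    block_key = pd.factorize(
        table["chrom"].astype(str) + ":" + ((table["pos"] - 1) // block_size).astype(str)
    )[0]
    n_blocks = block_key.max() + 1
    if n_blocks < 2:
        raise ValueError("need at least 2 non-empty blocks for resampling")
    a_blk = np.bincount(block_key, weights=abba, minlength=n_blocks)
    b_blk = np.bincount(block_key, weights=baba, minlength=n_blocks)

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        picks = rng.integers(0, n_blocks, size=(n_boot, n_blocks))
        a_rep = a_blk[picks].sum(axis=1)
        b_rep = b_blk[picks].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d_rep = (a_rep - b_rep) / (a_rep + b_rep)
        se = float(np.nanstd(d_rep, ddof=1))
    elif method == "jackknife":
        a_del = tot_a - a_blk
        b_del = tot_b - b_blk
        d_del = (a_del - b_del) / (a_del + b_del)
        se = float(np.sqrt((n_blocks - 1) / n_blocks * ((d_del - d_del.mean()) ** 2).sum()))
    else:
        raise ValueError(f"unknown method {method!r}")

    z = D / se if se > 0 else np.inf
    p = 2 * stats.norm.sf(abs(z))
    return DStatResult(float(D), se, float(z), float(p), int(n_blocks), block_size, float(tot_a), float(tot_b), method)


def fd_windows(
    table: pd.DataFrame,
    trio: tuple,
    chrom_lengths: dict,
    window: int = 100_000,
    min_sites: int = 10,
) -> pd.DataFrame:
    """Windowed f_d scan.

    Windows with fewer than ``min_sites`` informative sites (nonzero
    ABBA+BABA weight), negative window-level D, or zero denominator are
    reported missing (NaN), not zero, so they cannot dilute outlier
    quantiles. Returns a window table with f_d, window D and site counts.
    """
    abba, baba = site_patterns(table, trio)
    p1 = table[f"p_{trio[0]}"].to_numpy(dtype=float)
    p2 = table[f"p_{trio[1]}"].to_numpy(dtype=float)
    p3 = table[f"p_{trio[2]}"].to_numpy(dtype=float)
    pO = table["pO"].to_numpy(dtype=float)
    pD = np.maximum(p2, p3)
    abba_d = (1 - p1) * pD * pD * (1 - pO)
    baba_d = p1 * (1 - pD) * pD * (1 - pO)

    chrom = table["chrom"].to_numpy()
    pos0 = table["pos"].to_numpy() - 1
    informative = (abba + baba) > 0

    rows = []
    for w in make_windows(chrom_lengths, window):
        sel = (chrom == w.chrom) & (pos0 >= w.start) & (pos0 < w.end)
        n_inf = int((sel & informative).sum())
        num = abba[sel].sum() - baba[sel].sum()
        den_d = abba[sel].sum() + baba[sel].sum()
        den = abba_d[sel].sum() - baba_d[sel].sum()
        d_win = num / den_d if den_d > 0 else np.nan
        if n_inf < min_sites or den <= 0 or not np.isfinite(d_win) or d_win < 0:
            fd = np.nan
        else:
            fd = num / den
        rows.append((w.chrom, w.start, w.end, fd, d_win, n_inf))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "fd", "D", "n_sites"])
    ok = out["fd"].notna()
    out["quantile"] = np.nan
    out.loc[ok, "quantile"] = out.loc[ok, "fd"].rank(pct=True)
    return out


def outlier_windows(stats_df: pd.DataFrame, value_col: str = "fd", quantile: float = 0.99) -> pd.DataFrame:
    """Windows at or above the empirical upper quantile; threshold ties included."""
    vals = stats_df[value_col]
    ok = vals.notna()
    if not ok.any():
        return stats_df.iloc[0:0]
    thr = np.quantile(vals[ok], quantile)
    if vals[ok].nunique() == 1:
        import warnings

        warnings.warn("all window values identical; every window is a tied outlier")
    return stats_df[ok & (vals >= thr)]


def overlap_windows(set_a: pd.DataFrame, set_b: pd.DataFrame) -> pd.DataFrame:
    """Interval intersection of two window sets (>= 1 bp overlap).

    Returns the intersected intervals; symmetric in its arguments.
    """
    rows = []
    for chrom in sorted(set(set_a["chrom"]) & set(set_b["chrom"])):
        a = set_a[set_a["chrom"] == chrom]
        bi = set_b[set_b["chrom"] == chrom][["start", "end"]].to_numpy()
        for st, en in a[["start", "end"]].to_numpy():
            hit = (bi[:, 0] < en) & (bi[:, 1] > st)
            for s2, e2 in bi[hit]:
                rows.append((chrom, max(st, s2), min(en, e2)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).drop_duplicates().reset_index(drop=True)


def x_autosome_contrast(
    stats_df: pd.DataFrame,
    chrom_classes: list,
    value_col: str = "fd",
) -> dict:
    """Welch two-sample t contrast of window values on X vs autosomes.

    X windows overlapping PAR intervals and Y-like scaffolds are excluded.
    Returns group means, SDs, counts, Welch t and two-tailed p.
    """
    cls = {c.scaffold: c for c in chrom_classes}
    x_vals, auto_vals = [], []
    for row in stats_df.itertuples(index=False):
        c = cls.get(row.chrom)
        if c is None or not np.isfinite(getattr(row, value_col)):
            continue
        if c.chrom_class == "autosome":
            auto_vals.append(getattr(row, value_col))
        elif c.chrom_class == "X":
            if any(row.start < pe and row.end > ps for ps, pe in c.par_intervals):
                continue
            x_vals.append(getattr(row, value_col))
    if len(x_vals) < 2 or len(auto_vals) < 2:
        raise ValueError("need >= 2 windows in each of X and autosome groups")
    t, p = stats.ttest_ind(x_vals, auto_vals, equal_var=False)
    return {
        "x_mean": float(np.mean(x_vals)),
        "x_sd": float(np.std(x_vals, ddof=1)),
        "n_x": len(x_vals),
        "autosome_mean": float(np.mean(auto_vals)),
        "autosome_sd": float(np.std(auto_vals, ddof=1)),
        "n_autosome": len(auto_vals),
        "t": float(t),
        "p": float(p),
    }
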