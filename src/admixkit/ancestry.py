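"""Local ancestry inference and single-pulse admixture dating.

A two-ancestry hidden Markov model over ancestry-informative markers
(AIMs). Each haploid chain switches ancestry between AIMs d bp apart with
probability 1 - exp(-r*d*t), redrawing Bernoulli(m) toward the donor;
the diploid donor-dosage chain (states 0/1/2 donor copies) is the product
of two independent haploid chains, so the stationary distribution is
Binomial(2, m) and transitions are convolutions of the haploid kernel.

Emissions are either filtered read counts (alt reads ~ Binomial(depth,
expected alt fraction given dosage, with per-read error eps)) or called
genotypes. (m, t) are estimated by profile likelihood: m is maximized
numerically at each t on a log grid over [1, 2000] generations followed
by golden-section refinement. Confidence intervals come from 1000 block
bootstraps of contiguous AIM blocks, resampled over precomputed per-block
likelihood surfaces.

Tract-based dating inverts the exponential tract-length model:
t = 1 / ((1 - m) * r * mean donor tract length), censoring
chromosome-end-truncated tracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize_scalar
from scipy.stats import binom

from .genomio import GenotypeData

__all__ = [
    "AIMPanel",
    "PulseModel",
    "select_aims",
    "pulse_hmm_fit",
    "call_tracts",
    "tract_time",
    "ancestry_proportions",
    "merge_mask_flags",
    "mask_introgressed",
]


@dataclass
class AIMPanel:
    """Ancestry-informative marker panel: sites with |pA - pB| >= min_diff
    and >= min_spacing bp between successive sites on a chromosome."""

    sites: pd.DataFrame  # chrom, pos, pA, pB
    min_diff: float
    min_spacing: int
    n_removed: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class PulseModel:
    m: float
    t: float
    ci_m: tuple
    ci_t: tuple
    n_bootstrap: int
    block_size_aims: int
    loglik: float
    t_at_boundary: bool = False


# ---------------------------------------------------------------------------
# AIM selection


def select_aims(
    table: pd.DataFrame,
    panel_a: str,
    panel_b: str,
    min_diff: float = 0.5,
    min_spacing: int = 10_000,
    smooth: bool = True,
) -> AIMPanel:
    """Select AIMs from a polarized site table (already depth-filtered).

    Applies the frequency-difference filter then greedy left-to-right
    spacing enforcement per chromosome; counts removed per filter are
    recorded on the panel. With ``smooth`` (default), panel frequencies
    carried into the HMM are Jeffreys-shrunk toward 0.5 by half a
    pseudo-allele, (p*n + 0.5) / (n + 1), guarding emissions against
    finite-panel estimates of exactly 0 or 1; the frequency-difference
    filter itself uses the raw estimates.
    """
    pA = table[f"p_{panel_a}"].to_numpy(dtype=float)
    pB = table[f"p_{panel_b}"].to_numpy(dtype=float)
    pA_use, pB_use = pA, pB
    if smooth and f"n_{panel_a}" in table.columns:
        nA = table[f"n_{panel_a}"].to_numpy(dtype=float)
        nB = table[f"n_{panel_b}"].to_numpy(dtype=float)
        pA_use = (pA * nA + 0.5) / (nA + 1)
        pB_use = (pB * nB + 0.5) / (nB + 1)
    diff_ok = np.abs(pA - pB) >= min_diff
    n_diff = int((~diff_ok).sum())

    keep_rows = []
    sub = table[diff_ok]
    subA, subB = pA[diff_ok], pB[diff_ok]
    n_spacing = 0
    for chrom, grp in sub.groupby("chrom", sort=False):
        last = -np.inf
        for i, p in zip(grp.index, grp["pos"]):
            if p - last >= min_spacing:
                keep_rows.append(i)
                last = p
            else:
                n_spacing += 1
    if not keep_rows:
        raise ValueError(
            f"no AIMs survive |p_{panel_a} - p_{panel_b}| >= {min_diff}: panel divergence too low"
        )
    loc = table.index.get_indexer(keep_rows)
    sites = table.loc[keep_rows, ["chrom", "pos"]].copy()
    sites["pA"] = pA_use[loc]
    sites["pB"] = pB_use[loc]
    sites = sites.reset_index(drop=True)
    return AIMPanel(
        sites=sites,
        min_diff=min_diff,
        min_spacing=min_spacing,
        n_removed={"freq_diff": n_diff, "spacing": n_spacing},
    )


# ---------------------------------------------------------------------------
# HMM kernels (numba)


@njit(cache=False)
def _forward_block(emit, gaps, rt, m):
    """Total forward log-likelihood over samples for one chain block.

    emit: (S, N, 3) linear emission probabilities; gaps: (S,) bp to the
    previous AIM (gaps[0] unused; chain starts at the Binomial(2, m)
    stationary distribution). Scaled arithmetic.
    """
    S, N, _ = emit.shape
    pi0 = (1.0 - m) * (1.0 - m)
    pi1 = 2.0 * m * (1.0 - m)
    pi2 = m * m
    total = 0.0
    for n in range(N):
        a0 = pi0 * emit[0, n, 0]
        a1 = pi1 * emit[0, n, 1]
        a2 = pi2 * emit[0, n, 2]
        c = a0 + a1 + a2
        ll = np.log(c)
        a0 /= c
        a1 /= c
        a2 /= c
        for i in range(1, S):
            s = np.exp(-rt * gaps[i])
            h00 = s + (1.0 - s) * (1.0 - m)
            h01 = (1.0 - s) * m
            h10 = (1.0 - s) * (1.0 - m)
            h11 = s + (1.0 - s) * m
            b0 = (a0 * h00 * h00 + a1 * h00 * h10 + a2 * h10 * h10) * emit[i, n, 0]
            b1 = (a0 * 2.0 * h00 * h01 + a1 * (h00 * h11 + h01 * h10) + a2 * 2.0 * h10 * h11) * emit[i, n, 1]
            b2 = (a0 * h01 * h01 + a1 * h01 * h11 + a2 * h11 * h11) * emit[i, n, 2]
            c = b0 + b1 + b2
            ll += np.log(c)
            a0 = b0 / c
            a1 = b1 / c
            a2 = b2 / c
        total += ll
    return total


@njit(cache=False)
def _posterior_block(emit, gaps, rt, m):
    """Forward-backward posteriors (S, N, 3) for one chain block."""
    S, N, _ = emit.shape
    post = np.empty((S, N, 3))
    pi = np.empty(3)
    pi[0] = (1.0 - m) * (1.0 - m)
    pi[1] = 2.0 * m * (1.0 - m)
    pi[2] = m * m
    T = np.empty((S, 3, 3))
    for i in range(1, S):
        s = np.exp(-rt * gaps[i])
        h00 = s + (1.0 - s) * (1.0 - m)
        h01 = (1.0 - s) * m
        h10 = (1.0 - s) * (1.0 - m)
        h11 = s + (1.0 - s) * m
        T[i, 0, 0] = h00 * h00
        T[i, 0, 1] = 2.0 * h00 * h01
        T[i, 0, 2] = h01 * h01
        T[i, 1, 0] = h00 * h10
        T[i, 1, 1] = h00 * h11 + h01 * h10
        T[i, 1, 2] = h01 * h11
        T[i, 2, 0] = h10 * h10
        T[i, 2, 1] = 2.0 * h10 * h11
        T[i, 2, 2] = h11 * h11
    alpha = np.empty((S, 3))
    beta = np.empty((S, 3))
    for n in range(N):
        for k in range(3):
            alpha[0, k] = pi[k] * emit[0, n, k]
        c = alpha[0].sum()
        alpha[0] /= c
        for i in range(1, S):
            for k in range(3):
                acc = 0.0
                for j in range(3):
                    acc += alpha[i - 1, j] * T[i, j, k]
                alpha[i, k] = acc * emit[i, n, k]
            c = alpha[i].sum()
            alpha[i] /= c
        for k in range(3):
            beta[S - 1, k] = 1.0
        for i in range(S - 2, -1, -1):
            for k in range(3):
                acc = 0.0
                for j in range(3):
                    acc += T[i + 1, k, j] * emit[i + 1, n, j] * beta[i + 1, j]
                beta[i, k] = acc
            c = beta[i].sum()
            beta[i] /= c
        for i in range(S):
            tot = 0.0
            for k in range(3):
                post[i, n, k] = alpha[i, k] * beta[i, k]
                tot += post[i, n, k]
            for k in range(3):
                post[i, n, k] /= tot
    return post


# ---------------------------------------------------------------------------
# emissions


def _genotype_given_dosage(pA: np.ndarray, pB: np.ndarray) -> np.ndarray:
    """P(genotype alt count j | donor dosage d) per site; shape (S, 3, 3)
    indexed [site, d, j]. Haplotype alt prob is pB on donor background,
    pA on native."""
    S = len(pA)
    out = np.empty((S, 3, 3))
    qA, qB = 1 - pA, 1 - pB
    out[:, 0, 0] = qA * qA
    out[:, 0, 1] = 2 * pA * qA
    out[:, 0, 2] = pA * pA
    out[:, 1, 0] = qA * qB
    out[:, 1, 1] = pA * qB + qA * pB
    out[:, 1, 2] = pA * pB
    out[:, 2, 0] = qB * qB
    out[:, 2, 1] = 2 * pB * qB
    out[:, 2, 2] = pB * pB
    return out


def build_emissions(
    data: GenotypeData,
    aim_rows: np.ndarray,
    sample_idx: np.ndarray,
    pA: np.ndarray,
    pB: np.ndarray,
    mode: str = "reads",
    error_rate: float = 0.01,
) -> np.ndarray:
    """Emission probabilities (S, N, 3) at AIM sites for the target samples."""
    g_given_d = _genotype_given_dosage(pA, pB)  # (S, 3 dosage, 3 genotype)
    if mode == "reads":
        if data.ad is None or data.dp is None:
            raise ValueError("read-count emissions need AD and DP in the dataset")
        alt = data.ad[np.ix_(aim_rows, sample_idx)][:, :, 1].astype(float)
        dp = data.dp[np.ix_(aim_rows, sample_idx)].astype(float)
        e = error_rate
        f = np.array([e, 0.5, 1.0 - e])  # alt-read fraction per genotype
        # P(k | n, genotype j), shape (S, N, 3)
        p_reads = np.stack([binom.pmf(alt, dp, fj) for fj in f], axis=2)
        emit = np.einsum("snj,sdj->snd", p_reads, g_given_d)
    elif mode == "genotypes":
        gt = data.gt[np.ix_(aim_rows, sample_idx)]
        dos = np.where((gt < 0).any(axis=2), -1, gt.sum(axis=2))  # (S, N)
        S, N = dos.shape
        emit = np.take_along_axis(
            np.broadcast_to(g_given_d.transpose(0, 2, 1)[:, None, :, :], (S, N, 3, 3)),
            np.clip(dos, 0, 2)[:, :, None, None].astype(int),
            axis=2,
        )[:, :, 0, :]
        emit[dos < 0] = 1.0  # missing genotype: uninformative
    else:
        raise ValueError(f"unknown emission mode {mode!r}")
    bad = ~np.isfinite(emit).all(axis=(1, 2)) | (emit.sum(axis=(1, 2)) == 0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-finite or zero emission at AIM row {i}")
    return emit


# ---------------------------------------------------------------------------
# fitting


def _chains(aims: AIMPanel) -> list:
    """Per-chromosome (row slice, gaps) over the AIM table."""
    out = []
    sites = aims.sites
    start = 0
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=float)
        gaps = np.empty(len(pos))
        gaps[0] = 0.0
        gaps[1:] = np.diff(pos)
        out.append((np.arange(start, start + len(pos)), gaps))
        start += len(pos)
    return out


def pulse_hmm_fit(
    data: GenotypeData,
    aims: AIMPanel,
    r: float,
    target_pop: str = "admixed",
    mode: str = "reads",
    error_rate: float = 0.01,
    t_bounds: tuple = (1.0, 2000.0),
    n_t_grid: int = 25,
    n_bootstrap: int = 1000,
    block_size_aims: int = 5000,
    seed: int = 0,
) -> tuple:
    """Joint (m, t) profile-likelihood fit with block-bootstrap CIs.

    Returns ``(PulseModel, posteriors)`` where posteriors is a long table
    (chrom, pos, sample, p0, p1, p2) of donor-dosage posteriors at the
    MLE. CIs resample contiguous blocks of ``block_size_aims`` AIMs
    (percentile method, ``n_bootstrap`` replicates) over per-block
    likelihood surfaces evaluated on a fine local (t, m) grid.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    sample_idx = data.sample_indices(target_pop)
    sites = aims.sites
    key = pd.MultiIndex.from_arrays([data.chrom, data.pos])
    aim_rows = key.get_indexer(pd.MultiIndex.from_arrays([sites["chrom"], sites["pos"]]))
    if (aim_rows < 0).any():
        raise ValueError("AIM panel contains sites absent from the dataset")
    pA = sites["pA"].to_numpy(dtype=float)
    pB = sites["pB"].to_numpy(dtype=float)
    emit = build_emissions(data, aim_rows, sample_idx, pA, pB, mode=mode, error_rate=error_rate)
    chains = _chains(aims)

    def loglik(t: float, m: float) -> float:
        tot = 0.0
        for rows, gaps in chains:
            tot += _forward_block(emit[rows], gaps, r * t, m)
        return tot

    def profile_m(t: float) -> tuple:
        res = minimize_scalar(
            lambda m: -loglik(t, m), bounds=(1e-4, 1 - 1e-4), method="bounded",
            options={"xatol": 1e-4},
        )
        return float(res.x), float(-res.fun)

    t_grid = np.geomspace(t_bounds[0], t_bounds[1], n_t_grid)
    prof = [profile_m(t) for t in t_grid]
    lls = np.array([ll for _, ll in prof])
    k = int(np.argmax(lls))
    t_at_boundary = k in (0, n_t_grid - 1)
    if t_at_boundary:
        warnings.warn("profile-likelihood optimum of t lies at the search boundary")
    lo = t_grid[max(k - 1, 0)]
    hi = t_grid[min(k + 1, n_t_grid - 1)]
    res = minimize_scalar(
        lambda logt: -profile_m(np.exp(logt))[1],
        bounds=(np.log(lo), np.log(hi)), method="bounded", options={"xatol": 1e-3},
    )
    t_hat = float(np.exp(res.x))
    m_hat, ll_hat = profile_m(t_hat)

    ci_m, ci_t = _bootstrap_ci(
        emit, chains, r, t_hat, m_hat, block_size_aims, n_bootstrap, seed
    )

    post_parts = []
    names = [data.samples[i] for i in sample_idx]
    for rows, gaps in chains:
        post = _posterior_block(emit[rows], gaps, r * t_hat, m_hat)
        for n, name in enumerate(names):
            post_parts.append(
                pd.DataFrame(
                    {
                        "chrom": sites["chrom"].to_numpy()[rows],
                        "pos": sites["pos"].to_numpy()[rows],
                        "sample": name,
                        "p0": post[:, n, 0],
                        "p1": post[:, n, 1],
                        "p2": post[:, n, 2],
                    }
                )
            )
    posteriors = pd.concat(post_parts, ignore_index=True)
    model = PulseModel(
        m=m_hat, t=t_hat, ci_m=ci_m, ci_t=ci_t,
        n_bootstrap=n_bootstrap, block_size_aims=block_size_aims,
        loglik=ll_hat, t_at_boundary=t_at_boundary,
    )
    return model, posteriors


def _bootstrap_ci(emit, chains, r, t_hat, m_hat, block_size, n_boot, seed, n_t=31, n_m=31):
    """Percentile CIs from block-resampled per-block likelihood surfaces."""
    blocks = []
    for rows, gaps in chains:
        for s in range(0, len(rows), block_size):
            sl = slice(s, min(s + block_size, len(rows)))
            g = gaps[sl].copy()
            g[0] = 0.0
            blocks.append((rows[sl], g))
    t_vals = t_hat * np.exp(np.linspace(-0.4, 0.4, n_t))
    m_vals = np.clip(np.linspace(m_hat - 0.08, m_hat + 0.08, n_m), 1e-4, 1 - 1e-4)
    surf = np.empty((len(blocks), n_t, n_m))
    for b, (rows, gaps) in enumerate(blocks):
        eb = emit[rows]
        for i, t in enumerate(t_vals):
            for j, m in enumerate(m_vals):
                surf[b, i, j] = _forward_block(eb, gaps, r * t, m)
    rng = np.random.default_rng(seed)
    B = len(blocks)
    t_reps = np.empty(n_boot)
    m_reps = np.empty(n_boot)
    for rep in range(n_boot):
        pick = rng.integers(0, B, size=B)
        tot = surf[pick].sum(axis=0)
        i, j = np.unravel_index(np.argmax(tot), tot.shape)
        t_reps[rep] = t_vals[i]
        m_reps[rep] = m_vals[j]
    ci_t = (float(np.percentile(t_reps, 2.5)), float(np.percentile(t_reps, 97.5)))
    ci_m = (float(np.percentile(m_reps, 2.5)), float(np.percentile(m_reps, 97.5)))
    return ci_m, ci_t


# ---------------------------------------------------------------------------
# tracts, dating, proportions


def call_tracts(
    posteriors: pd.DataFrame,
    threshold: float = 0.8,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Maximal runs of AIMs whose donor posterior P(dosage >= 1) meets the
    threshold, one tract row per (sample, run).

    Tract boundaries sit at midpoints between flanking AIMs; runs touching
    the first or last AIM of a chromosome extend to the chromosome end
    (when lengths are given) and are flagged censored.
    """
    rows = []
    for (sample, chrom), grp in posteriors.groupby(["sample", "chrom"], sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        p_donor = (grp["p1"] + grp["p2"]).to_numpy()
        dclass = np.argmax(grp[["p0", "p1", "p2"]].to_numpy(), axis=1)
        hot = p_donor >= threshold
        if not hot.any():
            continue
        edges = np.diff(np.concatenate([[0], hot.view(np.int8), [0]]))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1) - 1
        L = (chrom_lengths or {}).get(chrom)
        for a, b in zip(starts, ends):
            if a > 0:
                start = int((pos[a - 1] + pos[a]) // 2)
                left_censored = False
            else:
                start = 0
                left_censored = True
            if b < len(pos) - 1:
                end = int((pos[b] + pos[b + 1]) // 2)
                right_censored = False
            else:
                end = int(L) if L else int(pos[b])
                right_censored = True
            end = max(end, start + 1)
            counts = np.bincount(dclass[a : b + 1], minlength=3)
            rows.append(
                (
                    chrom, start, end, sample,
                    int(np.argmax(counts[1:]) + 1),
                    float(p_donor[a : b + 1].mean()),
                    left_censored or right_censored,
                )
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "sample", "dosage_class", "mean_posterior", "censored"]
    )


def tract_time(tracts: pd.DataFrame, r: float, m: float, ploidy: str = "union") -> float:
    """Method-of-moments pulse age from donor tract lengths over
    uncensored tracts.

    ``ploidy='haploid'`` inverts the exponential tract-length mean
    directly, t = 1 / ((1 - m) * r * mean length). The default
    ``'union'`` is for tracts called from unphased diploid dosage
    posteriors, where each tract is the union of donor segments on two
    independent haplotypes: by renewal-reward on the stationary
    two-haplotype chain the mean donor-present run is
    (2 - m) / (2 * (1 - m)^2 * r * t), which is inverted instead.
    """
    keep = tracts[~tracts["censored"]] if "censored" in tracts.columns else tracts
    if keep.empty:
        raise ValueError("all tracts are chromosome-end censored; dating impossible")
    if len(keep) < 30:
        warnings.warn(f"only {len(keep)} uncensored tracts; tract-based date is noisy")
    mean_len = float((keep["end"] - keep["start"]).mean())
    if ploidy == "haploid":
        return 1.0 / ((1.0 - m) * r * mean_len)
    if ploidy == "union":
        return (2.0 - m) / (2.0 * (1.0 - m) ** 2 * r * mean_len)
    raise ValueError(f"unknown ploidy {ploidy!r}")


def ancestry_proportions(posteriors: pd.DataFrame) -> pd.Series:
    """Per-sample genome-wide donor fraction: mean posterior dosage / 2."""
    dose = posteriors["p1"] + 2.0 * posteriors["p2"]
    return dose.groupby(posteriors["sample"]).mean() / 2.0


# ---------------------------------------------------------------------------
# de-introgression masking


def merge_mask_flags(flags: np.ndarray, reconnect_min: int = 3) -> np.ndarray:
    """Merge masked site runs separated by short clean gaps.

    ``flags`` marks sites inside qualifying introgression tracts. Flanking
    regions are only reconnected across a gap of >= ``reconnect_min``
    contiguous non-introgressed sites; shorter gaps are absorbed into a
    single mask.
    """
    flags = np.asarray(flags, dtype=bool).copy()
    n = len(flags)
    i = 0
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j < n and flags[j]:
            j += 1
        # gap after run [i, j)
        k = j
        while k < n and not flags[k]:
            k += 1
        if k < n and (k - j) < reconnect_min:
            flags[j:k] = True
            continue  # re-scan the extended run
        i = k
    return flags


def mask_introgressed(
    data: GenotypeData,
    tracts: pd.DataFrame,
    target_pop: str = "admixed",
    reconnect_min: int = 3,
) -> tuple:
    """Mask introgressed sites per target sample; returns (masked data,
    mask intervals DataFrame).

    Sites falling in a sample's qualifying tracts (as produced by
    :func:`call_tracts` at its threshold) have GT/AD/DP set missing for
    that sample; mask runs separated by fewer than ``reconnect_min``
    clean sites are merged. Mask intervals are 0-based half-open.
    """
    out = data.subset_sites(np.arange(data.n_sites))
    out.gt = out.gt.copy()
    if out.ad is not None:
        out.ad = out.ad.copy()
    if out.dp is not None:
        out.dp = out.dp.copy()
    mask_rows = []
    sample_to_col = {s: i for i, s in enumerate(data.samples)}
    for sample in sorted(set(tracts["sample"])):
        col = sample_to_col[sample]
        sub = tracts[tracts["sample"] == sample]
        for chrom in pd.unique(sub["chrom"]):
            site_sel = np.flatnonzero(data.chrom == chrom)
            pos0 = data.pos[site_sel] - 1
            flags = np.zeros(len(site_sel), dtype=bool)
            for st, en in sub[sub["chrom"] == chrom][["start", "end"]].to_numpy():
                flags |= (pos0 >= st) & (pos0 < en)
            flags = merge_mask_flags(flags, reconnect_min)
            if not flags.any():
                continue
            rows = site_sel[flags]
            out.gt[rows, col, :] = -1
            if out.ad is not None:
                out.ad[rows, col, :] = 0
            if out.dp is not None:
                out.dp[rows, col] = 0
            edges = np.diff(np.concatenate([[0], flags.view(np.int8), [0]]))
            for a, b in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1) - 1):
                mask_rows.append((chrom, int(pos0[a]), int(pos0[b]) + 1, sample))
    mask_df = pd.DataFrame(mask_rows, columns=["chrom", "start", "end", "sample"])
    return out, mask_df
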