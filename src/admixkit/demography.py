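"""Recent effective-population-size trajectories from linkage
disequilibrium, slope-change detection, and admixture-date arithmetic.

The LD method bins SNP pairs by physical distance, converts distance to a
recombination fraction c (Sved mapping c = d*r / (1 + d*r) by default,
Haldane optional), assigns each bin the generation t = 1/(2c), and
inverts

    E[r2_adj] = 1 / (alpha + 4 * Ne * c)
    Ne(t)     = (1 / (4c)) * (1 / E[r2_adj] - alpha)

with r2_adj the sample-size-adjusted squared genotypic correlation
(r2 - 1/n unphased, r2 - 1/(2n) phased) and alpha = 2.2 when mutation is
modeled (2 otherwise).

Slope-change detection compares each interval's local finite-difference
slope of Ne against time with the overall least-squares slope; deviations
below zero mark intervals where Ne falls faster toward the present than
the global trend (a steeper decline).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "NeTrajectory",
    "pairwise_r2_binned",
    "ldne_trajectory",
    "ldne_from_r2",
    "nes_slopes",
    "generations_to_years",
    "infer_generation_length",
]


from dataclasses import dataclass


@dataclass
class NeTrajectory:
    """Per-bin distance class, recombination fraction c, generations
    t = 1/(2c), mean adjusted r2, pair count and Ne estimate."""

    table: pd.DataFrame  # columns: dist, c, t, r2_adj, n_pairs, ne

    def __post_init__(self):
        t = self.table["t"].to_numpy()
        if not (np.diff(t) < 0).all():
            raise ValueError("t must be strictly decreasing with increasing c")


def _map_c(dist: np.ndarray, r: float, mapping: str) -> np.ndarray:
    d = np.asarray(dist, dtype=float) * r
    if mapping == "sved":
        return d / (1.0 + d)
    if mapping == "haldane":
        return 0.5 * (1.0 - np.exp(-2.0 * d))
    raise ValueError(f"unknown mapping {mapping!r}")


def pairwise_r2_binned(
    dosage: np.ndarray,
    pos: np.ndarray,
    chrom: np.ndarray,
    bin_edges: np.ndarray,
) -> pd.DataFrame:
    """Mean squared genotypic correlation per physical-distance bin.

    ``dosage`` is (n_sites, n_diploids); pairs are formed within
    chromosomes up to the largest bin edge. Monomorphic sites are
    skipped. Returns per-bin mean r2 and pair counts.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    max_d = bin_edges[-1]
    sums = np.zeros(len(bin_edges) - 1)
    counts = np.zeros(len(bin_edges) - 1, dtype=np.int64)
    for c in pd.unique(np.asarray(chrom)):
        sel = np.flatnonzero(np.asarray(chrom) == c)
        X = dosage[sel].astype(float)
        sd = X.std(axis=1)
        ok = sd > 0
        X = X[ok]
        cpos = np.asarray(pos)[sel][ok].astype(float)
        n = X.shape[1]
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        hi = np.searchsorted(cpos, cpos + max_d, side="right")
        for i in range(len(cpos) - 1):
            j = hi[i]
            if j <= i + 1:
                continue
            r = Z[i] @ Z[i + 1 : j].T / n
            d = cpos[i + 1 : j] - cpos[i]
            which = np.digitize(d, bin_edges) - 1
            good = (which >= 0) & (which < len(sums))
            np.add.at(sums, which[good], r[good] ** 2)
            np.add.at(counts, which[good], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mid = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    return pd.DataFrame({"dist": mid, "r2": mean_r2, "n_pairs": counts})


def ldne_from_r2(
    binned: pd.DataFrame,
    n_diploids: int,
    r: float,
    alpha: float = 2.2,
    mapping: str = "sved",
    phased: bool = False,
    min_pairs: int = 100,
) -> NeTrajectory:
    """Invert binned mean r2 into an Ne-per-generation trajectory."""
    adj = 1.0 / (2 * n_diploids) if phased else 1.0 / n_diploids
    c = _map_c(binned["dist"].to_numpy(), r, mapping)
    t = 1.0 / (2.0 * c)
    r2_adj = binned["r2"].to_numpy() - adj
    with np.errstate(invalid="ignore", divide="ignore"):
        inv = 1.0 / r2_adj - alpha
        ne = inv / (4.0 * c)
    bad = (
        (binned["n_pairs"].to_numpy() < min_pairs)
        | ~np.isfinite(ne)
        | (r2_adj <= 0)
        | (inv <= 0)
    )
    ne = np.where(bad, np.nan, ne)
    table = pd.DataFrame(
        {
            "dist": binned["dist"].to_numpy(),
            "c": c,
            "t": t,
            "r2_adj": r2_adj,
            "n_pairs": binned["n_pairs"].to_numpy(),
            "ne": ne,
        }
    )
    return NeTrajectory(table=table)


def ldne_trajectory(
    dosage: np.ndarray,
    pos: np.ndarray,
    chrom: np.ndarray,
    r: float,
    bin_edges: np.ndarray | None = None,
    alpha: float = 2.2,
    mapping: str = "sved",
    phased: bool = False,
    min_pairs: int = 100,
    maf_min: float = 0.05,
) -> NeTrajectory:
    """LD-based recent-Ne trajectory from unphased genotype dosages.

    Sites below ``maf_min`` minor-allele frequency are excluded before
    pairing: rare variants bound r2 well below 1 and dilute the bin means,
    which would inflate Ne.
    """
    if bin_edges is None:
        bin_edges = np.geomspace(2e4, 2e6, 31)
    dosage = np.asarray(dosage)
    f = dosage.mean(axis=1) / 2.0
    sel = np.minimum(f, 1 - f) >= maf_min
    dosage, pos, chrom = dosage[sel], np.asarray(pos)[sel], np.asarray(chrom)[sel]
    binned = pairwise_r2_binned(dosage, pos, chrom, np.asarray(bin_edges))
    n = dosage.shape[1]
    return ldne_from_r2(binned, n, r, alpha=alpha, mapping=mapping, phased=phased, min_pairs=min_pairs)


def nes_slopes(traj: NeTrajectory | pd.DataFrame) -> pd.DataFrame:
    """Per-interval deviation of the local Ne-vs-t slope from the global
    least-squares trend.

    Slopes are taken toward the present (decreasing t); deviations below
    zero mark a steeper-than-trend decline, above zero a shallower one.
    Rows are interval midpoints in generations.
    """
    table = traj.table if isinstance(traj, NeTrajectory) else traj
    sub = table.dropna(subset=["ne"]).sort_values("t", ascending=False)
    if len(sub) < 3:
        raise ValueError("need at least 3 trajectory points")
    t = sub["t"].to_numpy(dtype=float)
    ne = sub["ne"].to_numpy(dtype=float)
    b = np.polyfit(t, ne, 1)[0]  # overall dNe/dt
    local = np.diff(ne) / np.diff(t)  # dNe/dt on each interval
    # toward-present slope = -dNe/dt; deviation = local_toward - overall_toward = b - local
    dev = b - local
    mid = 0.5 * (t[:-1] + t[1:])
    return pd.DataFrame({"t_mid": mid, "slope_dev": dev, "local_slope": local, "overall_slope": b})


# ---------------------------------------------------------------------------
# calendar arithmetic


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def generations_to_years(t_generations: float, gen_lengths=(3, 4, 5, 6, 7)) -> pd.DataFrame:
    """Years before present per generation-length scenario (round half up)."""
    if t_generations <= 0:
        raise ValueError("t must be positive")
    rows = [(g, t_generations * g, _round_half_up(t_generations * g)) for g in gen_lengths]
    return pd.DataFrame(rows, columns=["gen_length_years", "years_exact", "years"])


def infer_generation_length(
    t_generations: float, event_year: int = 1529, reference_year: int = 2020
) -> tuple:
    """Generation length implied by anchoring the pulse to a calendar
    event: g = (reference - event) / t. Returns (exact, nearest int)."""
    if t_generations <= 0:
        raise ValueError("t must be positive")
    if reference_year <= event_year:
        raise ValueError("reference_year must postdate event_year")
    g = (reference_year - event_year) / t_generations
    return g, _round_half_up(g)
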