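"""Shared genomic data layer.

Readers/writers, outgroup polarization, site filters, windowing, SNP
thinning, X-scaffold identification from sexed depth, and the genome-wide
recombination-rate helper.

Coordinate conventions: VCF positions are 1-based on disk and kept 1-based
in :class:`GenotypeData.pos`; all interval types (windows, BED, tracts) are
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeData",
    "GenomicWindow",
    "ChromClass",
    "load_genotypes",
    "polarize_and_filter",
    "make_windows",
    "thin_snps",
    "identify_x_scaffolds",
    "genome_recombination_rate",
    "write_site_table",
    "write_bed",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeData:
    """In-memory biallelic-SNP genotype matrix with optional read counts.

    ``gt`` has shape (n_sites, n_samples, 2) with allele codes 0 (REF),
    1 (ALT) and -1 (missing). ``ad`` holds per-sample (ref, alt) read
    counts; ``dp`` the per-sample total depth. Positions are 1-based.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    samples: list
    pops: dict
    gt: np.ndarray
    phased: np.ndarray | None = None
    ad: np.ndarray | None = None
    dp: np.ndarray | None = None
    chrom_lengths: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, pop: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.pops.get(s) == pop]
        if not idx:
            raise ValueError(f"no samples in population {pop!r}")
        return np.asarray(idx)

    def dosage(self) -> np.ndarray:
        """ALT-allele dosage (n_sites, n_samples); NaN where either allele is missing."""
        g = self.gt.astype(float)
        g[self.gt < 0] = np.nan
        return g.sum(axis=2)

    def allele_freq(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        """ALT-allele frequency and called-allele count per site for one population."""
        idx = self.sample_indices(pop)
        g = self.gt[:, idx, :]
        called = g >= 0
        n = called.sum(axis=(1, 2))
        alt = np.where(called, g, 0).sum(axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        return p, n

    def subset_sites(self, keep: np.ndarray) -> "GenotypeData":
        return GenotypeData(
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            ref=self.ref[keep],
            alt=self.alt[keep],
            samples=list(self.samples),
            pops=dict(self.pops),
            gt=self.gt[keep],
            phased=None if self.phased is None else self.phased[keep],
            ad=None if self.ad is None else self.ad[keep],
            dp=None if self.dp is None else self.dp[keep],
            chrom_lengths=dict(self.chrom_lengths),
        )


@dataclass(frozen=True)
class GenomicWindow:
    """0-based half-open interval; ``partial`` flags a trailing short window."""

    chrom: str
    start: int
    end: int
    n_sites: int = 0
    partial: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("window end must exceed start")


@dataclass
class ChromClass:
    """Scaffold sex classification from the male/female depth ratio."""

    scaffold: str
    chrom_class: str  # autosome | X | Y-like | unknown
    mf_ratio: float
    par_intervals: list = field(default_factory=list)  # 0-based half-open


# ---------------------------------------------------------------------------
# VCF input


def load_genotypes(vcf_path: str, sample_pops: dict) -> GenotypeData:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeData`.

    Multiallelic records and indels are dropped (counts logged). Every
    sample named in ``sample_pops`` must be present in the VCF header.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path, gts012=False)
    vcf_samples = list(vcf.samples)
    missing = [s for s in sample_pops if s not in vcf_samples]
    if missing:
        raise ValueError(f"samples not present in VCF: {', '.join(sorted(missing))}")

    chrom_lengths = {}
    for name, length in zip(vcf.seqnames, vcf.seqlens or []):
        chrom_lengths[name] = int(length)

    chroms, poss, refs, alts = [], [], [], []
    gts, phased, ads, dps = [], [], [], []
    n_multi = n_indel = 0
    has_ad = has_dp = True
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_indel += 1
            continue
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        g = np.array(v.genotypes, dtype=np.int8)  # (N, 3): a0, a1, phased
        gts.append(g[:, :2])
        phased.append(g[:, 2].astype(bool))
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            has_ad = False
        else:
            ads.append(np.asarray(ad, dtype=np.int32)[:, :2])
        dp = v.format("DP")
        if dp is None:
            has_dp = False
        else:
            dps.append(np.asarray(dp, dtype=np.int32).reshape(-1))
    if n_multi or n_indel:
        logger.info("dropped %d multiallelic and %d indel records", n_multi, n_indel)

    n_sites = len(poss)
    shape_gt = (n_sites, len(vcf_samples), 2)
    data = GenotypeData(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        samples=vcf_samples,
        pops=dict(sample_pops),
        gt=np.array(gts, dtype=np.int8).reshape(shape_gt) if n_sites else np.empty(shape_gt, np.int8),
        phased=np.array(phased, dtype=bool) if n_sites else np.empty((0, len(vcf_samples)), bool),
        ad=np.array(ads, dtype=np.int32) if (has_ad and n_sites) else None,
        dp=np.array(dps, dtype=np.int32) if (has_dp and n_sites) else None,
        chrom_lengths=chrom_lengths,
    )
    return data


# ---------------------------------------------------------------------------
# polarization


def polarize_and_filter(
    data: GenotypeData,
    outgroup: str,
    min_depth: int = 10,
    min_called_frac: float = 0.9,
    outgroup_fixed_tol: float = 0.05,
) -> pd.DataFrame:
    """Polarize sites against the outgroup and apply the depth filter.

    The derived allele at each site is the allele absent (or nearly so,
    within ``outgroup_fixed_tol``) from the outgroup. Sites where the
    outgroup is genuinely polymorphic or fully missing are dropped, as are
    sites where fewer than ``min_called_frac`` of samples reach
    ``min_depth`` reads. Returns a tidy per-site table with one derived
    frequency column ``p_<pop>`` and count column ``n_<pop>`` per
    population, plus ``pO`` for the outgroup; ``attrs['drop_reasons']``
    tallies removals.
    """
    pops = sorted(set(data.pops.values()))
    if outgroup not in pops:
        raise ValueError(f"outgroup population {outgroup!r} not in sample map")
    non_out = [p for p in pops if p != outgroup]

    pO_raw, nO = data.allele_freq(outgroup)
    drop = {"outgroup_missing": 0, "outgroup_polymorphic": 0, "low_depth": 0}

    keep = np.ones(data.n_sites, dtype=bool)
    miss = nO == 0
    drop["outgroup_missing"] = int(miss.sum())
    keep &= ~miss

    poly = (~miss) & (pO_raw > outgroup_fixed_tol) & (pO_raw < 1 - outgroup_fixed_tol)
    drop["outgroup_polymorphic"] = int(poly.sum())
    keep &= ~poly

    if data.dp is not None:
        frac_deep = (data.dp >= min_depth).mean(axis=1)
        shallow = frac_deep < min_called_frac
        drop["low_depth"] = int((shallow & keep).sum())
        keep &= ~shallow

    if not keep.any():
        logger.warning("all %d sites removed during polarization", data.n_sites)

    flip = pO_raw >= 1 - outgroup_fixed_tol  # ALT is ancestral -> derived is REF
    cols = {"chrom": data.chrom[keep], "pos": data.pos[keep]}
    for pop in non_out:
        p, n = data.allele_freq(pop)
        p = np.where(flip, 1.0 - p, p)
        cols[f"p_{pop}"] = p[keep]
        cols[f"n_{pop}"] = n[keep]
    cols["pO"] = np.where(flip, 1.0 - pO_raw, pO_raw)[keep]
    cols["nO"] = nO[keep]

    table = pd.DataFrame(cols)
    table = table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    table.attrs["drop_reasons"] = drop
    table.attrs["outgroup"] = outgroup
    table.attrs["populations"] = non_out
    return table


# ---------------------------------------------------------------------------
# windows / thinning


def make_windows(chrom_lengths: dict, size: int, step: int | None = None) -> list:
    """Tile each chromosome with half-open windows; trailing partial kept."""
    if size <= 0:
        raise ValueError("size must be positive")
    step = size if step is None else step
    if step <= 0:
        raise ValueError("step must be positive")
    windows = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            end = min(start + size, length)
            windows.append(GenomicWindow(chrom, start, end, partial=(end - start < size)))
            if end == length and start + size >= length:
                break
            start += step
    return windows


def thin_snps(chrom: np.ndarray, pos: np.ndarray, window: int = 250) -> np.ndarray:
    """Keep the first SNP per ``window``-bp bin; returns kept site indices.

    Bins are [0, w), [w, 2w), ... per chromosome on the 0-based position
    (pos - 1), matching a tiling sliding window of equal length and step.
    """
    pos0 = np.asarray(pos) - 1
    keep = []
    for c in pd.unique(np.asarray(chrom)):
        idx = np.flatnonzero(np.asarray(chrom) == c)
        bins = pos0[idx] // window
        # first occurrence per bin (sites are sorted within chromosome)
        first = np.ones(len(idx), dtype=bool)
        first[1:] = bins[1:] != bins[:-1]
        keep.append(idx[first])
    return np.sort(np.concatenate(keep)) if keep else np.empty(0, dtype=int)


# ---------------------------------------------------------------------------
# sexed depth -> chromosome class


def identify_x_scaffolds(
    depth_table: pd.DataFrame,
    sex_labels: dict,
    x_band: tuple = (0.35, 0.65),
    auto_band: tuple = (0.85, 1.15),
) -> list:
    """Classify scaffolds as autosome/X/Y-like from male:female depth.

    ``depth_table`` columns: scaffold, start, end, sample, depth (window
    rows). The ratio is normalized by each sex's modal autosome-scale depth
    (the median over all windows) so that samples sequenced to different
    depths are comparable. Terminal windows of an X scaffold with an
    autosomal ratio are flagged as PAR.
    """
    sexes = set(sex_labels.values())
    if "M" not in sexes or "F" not in sexes:
        raise ValueError("need at least one male and one female sample")
    for s in depth_table["sample"].unique():
        if s not in sex_labels:
            raise ValueError(f"missing sex label for sample {s!r}")

    df = depth_table.copy()
    df["sex"] = df["sample"].map(sex_labels)
    norm = df.groupby("sex")["depth"].median()
    df["rel"] = df["depth"] / df["sex"].map(norm)

    out = []
    for scaf, sub in df.groupby("scaffold", sort=False):
        by_sex = sub.groupby("sex")["rel"].mean()
        f_rel = by_sex.get("F", np.nan)
        m_rel = by_sex.get("M", np.nan)
        ratio = m_rel / f_rel if f_rel > 0 else np.inf
        if f_rel < 0.05:
            cls = "Y-like"
        elif auto_band[0] <= ratio <= auto_band[1]:
            cls = "autosome"
        elif x_band[0] <= ratio <= x_band[1]:
            cls = "X"
        else:
            cls = "unknown"
        par = []
        if cls == "X":
            win = (
                sub.pivot_table(index=["start", "end"], columns="sex", values="rel")
                .reset_index()
                .sort_values("start")
            )
            wr = win["M"] / win["F"]
            auto_like = (wr >= auto_band[0]) & (wr <= auto_band[1])
            # terminal runs only: PARs sit at scaffold ends
            vals = auto_like.to_numpy()
            i = 0
            while i < len(vals) and vals[i]:
                i += 1
            if i > 0:
                par.append((int(win["start"].iloc[0]), int(win["end"].iloc[i - 1])))
            j = len(vals)
            while j > 0 and vals[j - 1] and j - 1 >= i:
                j -= 1
            if j < len(vals):
                par.append((int(win["start"].iloc[j]), int(win["end"].iloc[len(vals) - 1])))
        out.append(ChromClass(scaffold=scaf, chrom_class=cls, mf_ratio=float(ratio), par_intervals=par))
    return out


def genome_recombination_rate(n_chromosomes: int, mapped_length: float) -> float:
    """Genome-wide r per bp per generation assuming one crossover per chromosome."""
    if n_chromosomes <= 0 or mapped_length <= 0:
        raise ValueError("n_chromosomes and mapped_length must be positive")
    return n_chromosomes / mapped_length


# ---------------------------------------------------------------------------
# writers


def write_site_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_bed(intervals, path: str, names=None) -> None:
    """Write (chrom, start, end[, name]) 0-based half-open intervals as BED."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            row = list(iv[:3])
            if names is not None:
                row.append(names[i])
            elif len(iv) > 3:
                row.extend(iv[3:])
            fh.write("\t".join(str(x) for x in row) + "\n")
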