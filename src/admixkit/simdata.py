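"""Synthetic admixed-cohort generator with ground truth.

Emulates the data structure the downstream analyses assume: two diverged
ancestral panels (Balding–Nichols drift around a shared ancestral
frequency), an outgroup fixed for the ancestral allele at most sites, a
dated single admixture pulse laying down exponentially distributed
ancestry tracts at per-bp recombination rate ``r``, binomial read counts
over Poisson depth, and X scaffolds sequenced at half depth in males.

The generator is the study-conditions oracle for the test suite: every
cohort carries a :class:`SimTruth` with the exact tract mosaic it was
built from. All generative choices here are stand-ins for real data (the
source study had resequencing data, not a simulator); what they do and do
not emulate is documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genomio import GenotypeData

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_panels",
    "simulate_admixed_cohort",
    "simulate_depth_profiles",
    "simulate_wf_genotypes",
    "paint_sweep",
    "write_vcf",
    "write_truth_bed",
    "write_config",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    ``m`` and ``t`` define the single admixture pulse (donor proportion
    and age in generations); ``divergence`` is the Balding–Nichols drift
    parameter F of each ancestral panel; ``r`` the uniform per-bp
    recombination rate.
    """

    n_chrom: int = 5
    chrom_length: int = 20_000_000
    n_anc_a: int = 8
    n_anc_b: int = 8
    n_admixed: int = 8
    n_outgroup: int = 4
    divergence: tuple = (0.5, 0.5)
    m: float = 0.36
    t: float = 120.0
    r: float = 1.82e-8
    mean_depth: float = 16.0
    error_rate: float = 0.01
    n_sites_per_chrom: int = 10_000
    outgroup_poly_frac: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("m must lie in [0, 1]")
        if self.t < 1:
            raise ValueError("t must be >= 1 generation")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if not all(0.0 <= F < 1.0 for F in self.divergence):
            raise ValueError("divergence F must lie in [0, 1)")
        if self.chrom_length * self.r * self.t >= 1e3:
            raise ValueError("chrom_length * r * t >= 1e3: tracts unresolvable")

    @property
    def chrom_names(self) -> list:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort.

    ``tracts`` is a DataFrame (chrom, start, end, sample, hap, ancestry)
    of 0-based half-open segments that tile every admixed haplotype;
    ``panels`` the per-site true panel frequencies.
    """

    tracts: pd.DataFrame
    params: SimConfig
    panels: pd.DataFrame

    def donor_fraction(self) -> float:
        """Realized genome-wide donor-ancestry fraction over all haplotypes."""
        lengths = self.tracts["end"] - self.tracts["start"]
        donor = lengths[self.tracts["ancestry"] == "donor"].sum()
        return float(donor / lengths.sum())

    def donor_tract_lengths(self, interior_only: bool = False) -> np.ndarray:
        """Donor tract lengths in bp; optionally drop chromosome-end-truncated tracts."""
        tr = self.tracts[self.tracts["ancestry"] == "donor"]
        if interior_only:
            L = self.params.chrom_length
            tr = tr[(tr["start"] > 0) & (tr["end"] < L)]
        return (tr["end"] - tr["start"]).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# panels


def simulate_panels(cfg: SimConfig) -> pd.DataFrame:
    """Draw per-site true allele frequencies for the two ancestral panels
    and the outgroup.

    Shared ancestral frequency p ~ U(0.05, 0.95); each panel drifts as
    Beta(p(1-F)/F, (1-p)(1-F)/F) (F = 0 means no drift: the panel keeps p
    exactly). The outgroup carries the derived allele only at
    ``outgroup_poly_frac`` of sites, at low frequency. The realized
    ancestry-informative fraction |pA - pB| >= 0.5 is stored in
    ``attrs['aim_fraction']``.
    """
    rng = np.random.default_rng(cfg.seed)
    frames = []
    for chrom in cfg.chrom_names:
        pos = np.unique(rng.integers(1, cfg.chrom_length + 1, size=cfg.n_sites_per_chrom))
        n = len(pos)
        p = rng.uniform(0.05, 0.95, size=n)
        pA = _drift(p, cfg.divergence[0], rng)
        pB = _drift(p, cfg.divergence[1], rng)
        pO = np.zeros(n)
        poly = rng.random(n) < cfg.outgroup_poly_frac
        pO[poly] = rng.uniform(0.0, 0.3, size=poly.sum())
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "p_anc": p, "pA": pA, "pB": pB, "pO": pO}))
    panels = pd.concat(frames, ignore_index=True)
    panels.attrs["aim_fraction"] = float((np.abs(panels["pA"] - panels["pB"]) >= 0.5).mean())
    if cfg.divergence == (0.0, 0.0):
        panels.attrs["zero_aims"] = True
    return panels


def _drift(p: np.ndarray, F: float, rng) -> np.ndarray:
    if F == 0.0:
        return p.copy()
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return rng.beta(a, b)


# ---------------------------------------------------------------------------
# admixed cohort


def _simulate_haplotype_tracts(cfg: SimConfig, m: float, rng) -> list:
    """One haplotype's ancestry mosaic on one chromosome.

    Ancestry-switch opportunities fall as a Poisson process of rate r*t
    per bp; at each, ancestry is redrawn Bernoulli(m) toward the donor, so
    donor tracts end at rate (1-m)*r*t and are exponential. Returns merged
    (start, end, ancestry) segments, 0-based half-open.
    """
    L = cfg.chrom_length
    k = rng.poisson(cfg.r * cfg.t * L)
    cuts = np.sort(rng.integers(0, L, size=k))
    bounds = np.concatenate([[0], cuts, [L]])
    states = rng.random(k + 1) < m  # True = donor
    segs = []
    for i in range(k + 1):
        s, e, a = int(bounds[i]), int(bounds[i + 1]), bool(states[i])
        if e <= s:
            continue
        if segs and segs[-1][2] == a:
            segs[-1] = (segs[-1][0], e, a)
        else:
            segs.append((s, e, a))
    return [(s, e, "donor" if a else "native") for s, e, a in segs]


def simulate_admixed_cohort(
    cfg: SimConfig,
    panels: pd.DataFrame,
    m_per_chrom: dict | None = None,
) -> tuple:
    """Simulate the four-population cohort and its ground truth.

    Populations: ``ancA`` (native panel), ``ancB`` (donor panel),
    ``admixed`` (pulse mosaic of the two), ``outgroup``. Haplotypes within
    a diploid are independent ancestry chains. Returns
    ``(GenotypeData, SimTruth)`` with phased GT, AD and DP per sample.
    ``m_per_chrom`` overrides the pulse proportion on named chromosomes
    (used to emulate suppressed X introgression).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    samples, pops = [], {}
    for pop, n in [("ancA", cfg.n_anc_a), ("ancB", cfg.n_anc_b), ("admixed", cfg.n_admixed), ("outgroup", cfg.n_outgroup)]:
        for i in range(n):
            name = f"{pop}_{i}"
            samples.append(name)
            pops[name] = pop
    n_samp = len(samples)
    adm_idx = [i for i, s in enumerate(samples) if pops[s] == "admixed"]

    gt_parts, tract_rows = [], []
    for chrom in cfg.chrom_names:
        sub = panels[panels["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        n_sites = len(pos)
        pA = sub["pA"].to_numpy()
        pB = sub["pB"].to_numpy()
        pO = sub["pO"].to_numpy()
        m_here = (m_per_chrom or {}).get(chrom, cfg.m)

        gt = np.zeros((n_sites, n_samp, 2), dtype=np.int8)
        for j, s in enumerate(samples):
            pop = pops[s]
            if pop == "admixed":
                for hap in range(2):
                    segs = _simulate_haplotype_tracts(cfg, m_here, rng)
                    for st, en, anc in segs:
                        tract_rows.append((chrom, st, en, s, hap, anc))
                    ends = np.array([e for _, e, _ in segs])
                    donor = np.array([a == "donor" for _, _, a in segs])
                    site_donor = donor[np.searchsorted(ends, pos - 1, side="right")]
                    freq = np.where(site_donor, pB, pA)
                    gt[:, j, hap] = rng.random(n_sites) < freq
            else:
                freq = {"ancA": pA, "ancB": pB, "outgroup": pO}[pop]
                gt[:, j, 0] = rng.random(n_sites) < freq
                gt[:, j, 1] = rng.random(n_sites) < freq
        gt_parts.append((chrom, pos, gt))

    chroms = np.concatenate([np.full(len(p), c, dtype=object) for c, p, _ in gt_parts])
    pos_all = np.concatenate([p for _, p, _ in gt_parts])
    gt_all = np.concatenate([g for _, _, g in gt_parts], axis=0)

    # read counts: Poisson depth, binomial alt reads with per-read error
    dosage = gt_all.sum(axis=2)
    dp = rng.poisson(cfg.mean_depth, size=dosage.shape).astype(np.int32)
    e = cfg.error_rate
    f_alt = (dosage / 2.0) * (1 - e) + (1 - dosage / 2.0) * e
    alt = rng.binomial(dp, f_alt).astype(np.int32)
    ad = np.stack([dp - alt, alt], axis=2)

    data = GenotypeData(
        chrom=chroms,
        pos=pos_all.astype(np.int64),
        ref=np.full(len(pos_all), "A", dtype=object),
        alt=np.full(len(pos_all), "T", dtype=object),
        samples=samples,
        pops=pops,
        gt=gt_all,
        phased=np.ones((len(pos_all), n_samp), dtype=bool),
        ad=ad,
        dp=dp,
        chrom_lengths={c: cfg.chrom_length for c in cfg.chrom_names},
    )
    tracts = pd.DataFrame(tract_rows, columns=["chrom", "start", "end", "sample", "hap", "ancestry"])
    return data, SimTruth(tracts=tracts, params=cfg, panels=panels)


# ---------------------------------------------------------------------------
# sexed depth profiles


def simulate_depth_profiles(
    cfg: SimConfig,
    sex_labels: dict,
    scaffolds: list,
    window: int = 1_000_000,
    n_obs_per_window: int = 200,
) -> pd.DataFrame:
    """Per-scaffold windowed mean depth per sample under the sexed model.

    ``scaffolds`` rows are (name, length, is_x, par_bp): X scaffolds get
    half depth in males except within the terminal PAR of ``par_bp`` bp at
    each end. Depth per window is a Poisson average over
    ``n_obs_per_window`` sites.
    """
    sexes = set(sex_labels.values())
    if "M" not in sexes or "F" not in sexes:
        raise ValueError("need at least one male and one female")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    rows = []
    for name, length, is_x, par_bp in scaffolds:
        starts = np.arange(0, length, window)
        for st in starts:
            en = min(st + window, length)
            in_par = is_x and par_bp > 0 and (en <= par_bp or st >= length - par_bp)
            for sample, sex in sex_labels.items():
                lam = cfg.mean_depth
                if is_x and sex == "M" and not in_par:
                    lam *= 0.5
                depth = rng.poisson(lam * n_obs_per_window) / n_obs_per_window
                rows.append((name, int(st), int(en), sample, depth))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "sample", "depth"])


# ---------------------------------------------------------------------------
# auxiliary generators for property tests


def simulate_wf_genotypes(
    n_diploids: int,
    ne: float,
    seq_length: float,
    r: float,
    mu: float,
    seed: int,
) -> tuple:
    """Neutral Wright–Fisher diploid genotypes via the coalescent (msprime).

    Independent of the pulse-mosaic generator; used as the LD ground truth
    for the recent-Ne estimator. Returns (positions bp, dosage matrix
    (n_sites, n_diploids)).
    """
    import msprime

    ts = msprime.sim_ancestry(
        samples=n_diploids,
        population_size=ne,
        sequence_length=seq_length,
        recombination_rate=r,
        random_seed=seed + 1,
    )
    ts = msprime.sim_mutations(ts, rate=mu, random_seed=seed + 1, model="binary")
    G = ts.genotype_matrix()  # (sites, 2n)
    pos = np.array([s.position for s in ts.sites()])
    biall = G.max(axis=1) <= 1
    G = G[biall]
    pos = pos[biall]
    dosage = G[:, 0::2] + G[:, 1::2]
    return pos.astype(np.int64), dosage.astype(np.int8)


def paint_sweep(
    haplotypes: np.ndarray,
    pos: np.ndarray,
    center: int,
    width: int,
    carrier_frac: float,
    rng,
) -> np.ndarray:
    """Paint a hard-sweep haplotype structure centred on ``center``.

    A fraction ``carrier_frac`` of haplotypes receives the first
    haplotype's alleles over a per-carrier interval around the centre
    whose one-sided extents are Exponential with mean ``width/2`` —
    emulating recombination eroding the swept haplotype with distance
    from the selected site, so haplotype homozygosity (and iHH) peaks at
    the centre. ``haplotypes`` is (n_hap, n_sites); returns a painted
    copy.
    """
    out = haplotypes.copy()
    donor = out[0].copy()
    n_carriers = int(round(carrier_frac * out.shape[0]))
    carriers = rng.choice(out.shape[0], size=n_carriers, replace=False)
    for h in carriers:
        lo = center - rng.exponential(width / 2)
        hi = center + rng.exponential(width / 2)
        in_region = (pos >= lo) & (pos < hi)
        out[h, in_region] = donor[in_region]
    return out


# ---------------------------------------------------------------------------
# writers


def write_vcf(data: GenotypeData, path: str) -> None:
    """Write the cohort as VCF v4.2 with GT (phased), AD and DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=admixkit.simdata\n")
        for chrom, length in data.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth per allele">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(data.samples) + "\n")
        sep = "|" if data.phased is not None else "/"
        for i in range(data.n_sites):
            fields = [
                str(data.chrom[i]), str(data.pos[i]), ".", str(data.ref[i]), str(data.alt[i]),
                ".", "PASS", ".", "GT:AD:DP",
            ]
            for j in range(data.n_samples):
                a0, a1 = data.gt[i, j]
                gt = "./." if a0 < 0 or a1 < 0 else f"{a0}{sep}{a1}"
                ad = f"{data.ad[i, j, 0]},{data.ad[i, j, 1]}" if data.ad is not None else "."
                dp = str(data.dp[i, j]) if data.dp is not None else "."
                fields.append(f"{gt}:{ad}:{dp}")
            fh.write("\t".join(fields) + "\n")


def write_truth_bed(truth: SimTruth, path: str) -> None:
    with open(path, "w") as fh:
        for row in truth.tracts.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.ancestry}\t{row.sample}\t{row.hap}\n")


def write_config(cfg: SimConfig, path: str) -> None:
    with open(path, "w") as fh:
        for k, v in vars(cfg).items():
            fh.write(f"{k} = {v}\n")
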