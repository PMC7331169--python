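"""SNP phylogeny and quartet-topology discordance.

A neighbor-joining tree from uncorrected P-distances over thinned SNP
genotypes, with site-resampling bootstrap support on bipartitions, and a
windowed quartet-topology tally: each window is assigned one of the three
unrooted quartet topologies by the four-point condition on group-mean
P-distances, giving genome-wide topology proportions whose asymmetry
between the two minor topologies indicates admixture rather than pure
incomplete lineage sorting.

Genotype P-distance between diploids i and j is
sum_sites |dosage_i - dosage_j| / (2 * n shared called sites).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genomio import GenotypeData, make_windows

__all__ = [
    "p_distance_matrix",
    "nj_tree",
    "tree_bipartitions",
    "quartet_ils",
]


def _pair_arrays(data: GenotypeData, sample_names: list) -> tuple:
    """Per-site |dosage difference| and both-called flags for every pair."""
    idx = [data.samples.index(s) for s in sample_names]
    g = data.gt[:, idx, :]
    called = (g >= 0).all(axis=2)
    dose = g.sum(axis=2).astype(np.int16)
    n = len(idx)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    diff = np.empty((data.n_sites, len(pairs)), dtype=np.int8)
    both = np.empty((data.n_sites, len(pairs)), dtype=bool)
    for k, (i, j) in enumerate(pairs):
        both[:, k] = called[:, i] & called[:, j]
        diff[:, k] = np.where(both[:, k], np.abs(dose[:, i] - dose[:, j]), 0)
    return pairs, diff, both


def p_distance_matrix(data: GenotypeData, sample_names: list | None = None, site_weights=None) -> pd.DataFrame:
    """Pairwise uncorrected P-distances between diploid samples."""
    names = list(sample_names) if sample_names is not None else list(data.samples)
    pairs, diff, both = _pair_arrays(data, names)
    w = np.ones(data.n_sites) if site_weights is None else np.asarray(site_weights, float)
    num = w @ diff
    den = 2.0 * (w @ both)
    if (den == 0).any():
        k = int(np.flatnonzero(den == 0)[0])
        raise ValueError(f"no overlapping called sites for pair {names[pairs[k][0]]}/{names[pairs[k][1]]}")
    dm = np.zeros((len(names), len(names)))
    for k, (i, j) in enumerate(pairs):
        dm[i, j] = dm[j, i] = num[k] / den[k]
    return pd.DataFrame(dm, index=names, columns=names)


def _nj(dm: pd.DataFrame):
    from skbio import DistanceMatrix
    from skbio.tree import nj

    return nj(DistanceMatrix(dm.to_numpy(), ids=list(dm.index)))


def tree_bipartitions(tree) -> set:
    """Non-trivial bipartitions of a (possibly unrooted) skbio TreeNode,
    each canonicalized as a frozenset of the two tip-name sets."""
    all_tips = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            splits.add(frozenset({side, all_tips - side}))
    return splits


def nj_tree(
    data: GenotypeData,
    sample_names: list | None = None,
    n_bootstrap: int = 100,
    seed: int = 0,
):
    """Neighbor-joining tree with site-bootstrap bipartition support.

    Support (percent of replicates containing each bipartition) is
    written onto internal node names. Returns (TreeNode, support dict
    keyed by bipartition).
    """
    names = list(sample_names) if sample_names is not None else list(data.samples)
    if len(names) < 4:
        raise ValueError("need at least 4 samples")
    dm = p_distance_matrix(data, names)
    tree = _nj(dm)

    rng = np.random.default_rng(seed)
    counts: dict = {}
    for _ in range(n_bootstrap):
        w = rng.multinomial(data.n_sites, np.full(data.n_sites, 1.0 / data.n_sites))
        bdm = p_distance_matrix(data, names, site_weights=w)
        for split in tree_bipartitions(_nj(bdm)):
            counts[split] = counts.get(split, 0) + 1
    support = {s: 100.0 * c / n_bootstrap for s, c in counts.items()}

    all_tips = frozenset(names)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = frozenset({side, all_tips - side})
        if key in support:
            node.name = str(int(round(support[key])))
    return tree, support


# ---------------------------------------------------------------------------
# quartet topologies


def _group_distance(dose: np.ndarray, called: np.ndarray, ga: np.ndarray, gb: np.ndarray) -> float:
    """Mean per-site P-distance between two sample groups over a window."""
    num = den = 0.0
    for i in ga:
        for j in gb:
            both = called[:, i] & called[:, j]
            num += np.abs(dose[both, i] - dose[both, j]).sum()
            den += 2.0 * both.sum()
    return num / den if den else np.nan


def quartet_ils(
    data: GenotypeData,
    groups: dict,
    window: int = 1_000_000,
    min_sites: int = 50,
    margin: float = 0.0,
) -> tuple:
    """Windowed quartet-topology proportions for taxa (A, B, C, D).

    ``groups`` maps the four labels 'A'..'D' to population names. Each
    window's topology is the pairing with the smallest four-point sum
    (d(XY) + d(ZW)); windows where the two smallest sums differ by less
    than ``margin`` are ambiguous. Returns (proportions Series,
    per-window table). Topology keys: 'AB|CD', 'AC|BD', 'AD|BC'.
    """
    for lbl in "ABCD":
        if lbl not in groups:
            raise ValueError("groups must map labels A, B, C, D")
    cols = {lbl: data.sample_indices(groups[lbl]) for lbl in "ABCD"}
    g = data.gt
    called = (g >= 0).all(axis=2)
    dose = g.sum(axis=2).astype(float)

    pos0 = data.pos - 1
    rows = []
    for w in make_windows(data.chrom_lengths, window):
        sel = np.flatnonzero((data.chrom == w.chrom) & (pos0 >= w.start) & (pos0 < w.end))
        if len(sel) < min_sites:
            continue
        d = {}
        for x, y in ("AB", "CD", "AC", "BD", "AD", "BC"):
            d[x + y] = _group_distance(dose[sel], called[sel], cols[x], cols[y])
        sums = {
            "AB|CD": d["AB"] + d["CD"],
            "AC|BD": d["AC"] + d["BD"],
            "AD|BC": d["AD"] + d["BC"],
        }
        ranked = sorted(sums.items(), key=lambda kv: kv[1])
        topo = ranked[0][0] if (ranked[1][1] - ranked[0][1]) > margin else "ambiguous"
        rows.append((w.chrom, w.start, w.end, len(sel), topo, *sums.values()))
    per_window = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "topology", "s_AB|CD", "s_AC|BD", "s_AD|BC"]
    )
    if per_window.empty:
        props = pd.Series(0.0, index=["AB|CD", "AC|BD", "AD|BC", "ambiguous"])
    else:
        props = (
            per_window["topology"].value_counts(normalize=True)
            .reindex(["AB|CD", "AC|BD", "AD|BC", "ambiguous"], fill_value=0.0)
        )
    return props, per_window
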