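import numpy as np
import pytest

from admixkit import genomio, simdata


@pytest.fixture(scope="session")
def cohort_small():
    """Compact admixed cohort: 2 x 5 Mb chromosomes, 8+8+8+4 diploids."""
    cfg = simdata.SimConfig(seed=3, n_chrom=2, chrom_length=5_000_000, n_sites_per_chrom=3000)
    panels = simdata.simulate_panels(cfg)
    data, truth = simdata.simulate_admixed_cohort(cfg, panels)
    return cfg, panels, data, truth


@pytest.fixture(scope="session")
def cohort_std():
    """Study-scale cohort: 5 x 20 Mb chromosomes, m=0.36, t=120."""
    cfg = simdata.SimConfig(seed=1)
    panels = simdata.simulate_panels(cfg)
    data, truth = simdata.simulate_admixed_cohort(cfg, panels)
    return cfg, panels, data, truth


@pytest.fixture(scope="session")
def table_std(cohort_std):
    _, _, data, _ = cohort_std
    return genomio.polarize_and_filter(data, "outgroup")


@pytest.fixture(scope="session")
def table_small(cohort_small):
    _, _, data, _ = cohort_small
    return genomio.polarize_and_filter(data, "outgroup")


def make_site_table(p1, p2, p3, pO, chrom=None, pos=None, spacing=1000):
    """Hand-built polarized site table for statistic fixtures."""
    import pandas as pd

    n = len(p1)
    return pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["chr1"] * n,
            "pos": pos if pos is not None else np.arange(1, n + 1) * spacing,
            "p_P1": p1,
            "n_P1": 16,
            "p_P2": p2,
            "n_P2": 16,
            "p_P3": p3,
            "n_P3": 16,
            "pO": pO,
            "nO": 8,
        }
    )
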