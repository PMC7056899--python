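import numpy as np
import pandas as pd
import pytest

from panelgp.genotype_io import GenotypeDataset
from panelgp.synthetic_data import SimConfig, simulate_dataset


def small_config(seed=0, **overrides):
    """A fast family-structured simulation used across module tests."""
    defaults = dict(
        n_families=120,
        offspring_per_family=8,
        n_snps=1500,
        n_chromosomes=10,
        chrom_lengths=tuple([1e8] * 10),
        h2_true=0.35,
        n_qtl=200,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def family_sim():
    """120 full-sib families x 8 offspring, 1500 SNPs, h2 = 0.35."""
    cfg = small_config(seed=7)
    dataset, phenos, truth = simulate_dataset(cfg)
    return cfg, dataset, phenos, truth


def random_dataset(rng, n=12, m=30, missing_rate=0.0):
    """Unstructured random genotypes for format / QC round trips."""
    dosages = rng.integers(0, 3, size=(n, m)).astype(float)
    if missing_rate:
        dosages[rng.random((n, m)) < missing_rate] = np.nan
    markers = pd.DataFrame(
        {
            "snp_id": [f"m{j}" for j in range(m)],
            "chrom": ["1"] * (m // 2) + ["2"] * (m - m // 2),
            "pos": np.concatenate(
                [np.sort(rng.choice(10**6, m // 2, replace=False)),
                 np.sort(rng.choice(10**6, m - m // 2, replace=False))]
            ),
            "a1": ["A"] * m,
            "a2": ["G"] * m,
        }
    )
    samples = pd.DataFrame(
        {
            "fid": [f"f{i}" for i in range(n)],
            "iid": [f"i{i}" for i in range(n)],
            "sire": ["0"] * n,
            "dam": ["0"] * n,
            "sex": ["0"] * n,
        }
    )
    return GenotypeDataset(dosages, markers, samples)
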