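"""Shared fixtures: small hand-built paired datasets and seeded synthetic
generators used across the suite."""

import numpy as np
import pytest

from extremocodon.codon_model import CODON_INDEX
from extremocodon.dataset_io import PairedDataset
from extremocodon.synthetic import (
    ClassCodonProfile,
    SyntheticConfig,
    generate_paired_dataset,
    make_profiles,
    thermophile_like_biases,
)


def paired_from_columns(col_e: dict[str, list[float]],
                        col_ne: dict[str, list[float]],
                        label: str = "toy") -> PairedDataset:
    """Build a PairedDataset with chosen per-codon columns, zeros elsewhere."""
    n = len(next(iter(col_e.values())))
    me = np.zeros((n, 64))
    mn = np.zeros((n, 64))
    for codon, vals in col_e.items():
        me[:, CODON_INDEX[codon]] = vals
    for codon, vals in col_ne.items():
        mn[:, CODON_INDEX[codon]] = vals
    return PairedDataset(dataset_label=label,
                         pair_ids=[f"p{i}" for i in range(n)],
                         matrix_e=me, matrix_ne=mn)


@pytest.fixture(scope="session")
def thermophile_profile() -> ClassCodonProfile:
    """AGG enriched / CAA depleted by 0.3 within-family mass."""
    return make_profiles(ClassCodonProfile.uniform(), thermophile_like_biases(0.3))


@pytest.fixture(scope="session")
def biased_paired(thermophile_profile):
    """One seeded strong-bias dataset: 100 pairs, 300-codon genes."""
    cfg = SyntheticConfig(n_pairs=100, gene_length=300, seed=42,
                          profile_e=thermophile_profile, dataset_label="T-M")
    paired, truth = generate_paired_dataset(cfg)
    return paired, truth


@pytest.fixture(scope="session")
def null_paired():
    """One seeded zero-bias dataset (both classes uniform profiles)."""
    cfg = SyntheticConfig(n_pairs=100, gene_length=300, seed=43,
                          dataset_label="NULL")
    paired, truth = generate_paired_dataset(cfg)
    return paired, truth
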