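from __future__ import annotations

import numpy as np
import pytest

from refstab.dataset import CqDataset


@pytest.fixture
def hand_matrix() -> CqDataset:
    """4 samples x 3 genes with two groups; values chosen by hand."""
    cq = np.array(
        [
            [20.0, 24.5, 28.1],
            [20.4, 24.9, 28.0],
            [19.8, 24.2, 28.6],
            [20.1, 24.7, 28.2],
        ]
    )
    return CqDataset(
        samples=["s1", "s2", "s3", "s4"],
        genes=["gA", "gB", "gC"],
        cq=cq,
        groups={"s1": "ctrl", "s2": "ctrl", "s3": "case", "s4": "case"},
        tissue="DRG",
    )


def random_dataset(
    rng: np.random.Generator,
    n_samples: int,
    n_genes: int,
    n_groups: int = 2,
) -> CqDataset:
    """Random Cq matrix in a plausible 18-32 cycle range."""
    samples = [f"s{i}" for i in range(n_samples)]
    genes = [f"g{j}" for j in range(n_genes)]
    base = rng.uniform(18, 32, size=n_genes)
    cq = base[None, :] + rng.normal(0, 0.5, size=(n_samples, n_genes))
    labels = [f"grp{t}" for t in range(n_groups)]
    # at least 2 samples per group
    assign = [labels[i % n_groups] for i in range(n_samples)]
    return CqDataset(
        samples=samples,
        genes=genes,
        cq=cq,
        groups=dict(zip(samples, assign)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
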