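"""Shared fixtures and independent oracles.

The oracles here must stay independent of the package internals: the PSD
oracle is a direct O(n^2) DFT, and the clustering oracle enumerates every
partition.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from spectraclust import FamilySpec, generate_dataset, kmeans_fit, spectrum_set

# Frozen experiment: three planted families with distinct spectral
# signatures (period-2 motif, period-3 motif, uniform random), 15 members
# each, length 300, per-site substitution rate 0.02.
PLANTED_SEED = 42
PLANTED_KMEANS_SEED = 1
PLANTED_SPECS = (
    FamilySpec(family_id="per2", n_sequences=15, length=300, motif="AT", mu=0.02),
    FamilySpec(family_id="per3", n_sequences=15, length=300, motif="ACG", mu=0.02),
    FamilySpec(family_id="unif", n_sequences=15, length=300, mu=0.02),
)


def direct_psd(residues: str, n: int, drop_dc: bool = False) -> np.ndarray:
    """O(n^2) DFT power spectrum oracle (no FFT)."""
    L = len(residues)
    assert n >= L
    W = np.exp(-2j * np.pi * np.outer(np.arange(n), np.arange(n)) / n)
    vals = np.zeros(n)
    for base in "AGCT":
        x = np.zeros(n)
        for i, c in enumerate(residues):
            if c == base:
                x[i] = 1.0
        vals += np.abs(W @ x) ** 2
    if drop_dc:
        vals[0] = 0.0
    return vals


def best_partition_objective(X: np.ndarray, k: int) -> float:
    """Minimal within-cluster sum of squares over ALL partitions into <= k
    parts, by exhaustive enumeration (label symmetry broken by pinning
    point 0 to part 0)."""
    m, _ = X.shape
    if m == 1:
        return 0.0
    rest = np.array(list(itertools.product(range(k), repeat=m - 1)), dtype=np.int8)
    labels = np.concatenate([np.zeros((rest.shape[0], 1), dtype=np.int8), rest], axis=1)
    onehot = labels[:, :, None] == np.arange(k, dtype=np.int8)  # (P, m, k)
    counts = onehot.sum(axis=1).astype(float)  # (P, k)
    sums = np.einsum("pmk,mn->pkn", onehot, X)
    ss = (sums**2).sum(axis=2)
    contrib = np.divide(ss, counts, out=np.zeros_like(ss), where=counts > 0)
    objectives = (X**2).sum() - contrib.sum(axis=1)
    return float(objectives.min())


@pytest.fixture(scope="session")
def planted_dataset():
    seqs, table = generate_dataset(list(PLANTED_SPECS), seed=PLANTED_SEED)
    return seqs, table


@pytest.fixture(scope="session")
def planted_spectra(planted_dataset):
    seqs, _ = planted_dataset
    return spectrum_set(seqs, n="auto")


@pytest.fixture(scope="session")
def planted_model(planted_spectra):
    return kmeans_fit(planted_spectra, k=3, restarts=50, seed=PLANTED_KMEANS_SEED)
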