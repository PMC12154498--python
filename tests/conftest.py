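"""Shared fixtures and helpers: small genotype matrices built from call strings."""

from __future__ import annotations

import numpy as np
import pytest

from kaspanel.io import GenotypeMatrix, MarkerMeta
from kaspanel.simulate import PopulationModel, simulate_panel


def make_matrix(calls: list[list[str]],
                markers: list[tuple[str, str, int, str, str]] | None = None,
                samples: list[str] | None = None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from rows of two-letter call strings.

    ``markers`` entries are (id, chrom, pos, ref, alt); defaults to A/G
    markers m1..mL on one chromosome at positions 100, 200, ...
    """
    n = len(calls)
    L = len(calls[0])
    if markers is None:
        markers = [(f"m{j+1}", "chr01", 100 * (j + 1), "A", "G") for j in range(L)]
    metas = [MarkerMeta(*m) for m in markers]
    if samples is None:
        samples = [f"S{i+1}" for i in range(n)]
    dosage = np.array([[metas[j].dosage_of(calls[i][j]) for j in range(L)]
                       for i in range(n)], dtype=np.int8)
    return GenotypeMatrix(samples, metas, dosage)


@pytest.fixture(scope="session")
def structured_panel():
    """280 samples × 32 loci from 8 strongly diverged, near-pure populations."""
    model = PopulationModel(n_pops=8, n_loci=32, n_samples=280,
                            freq_prior=(0.2, 0.2), admix_alpha=0.05,
                            missing_rate=0.02, seed=7)
    return simulate_panel(model)


@pytest.fixture(scope="session")
def small_panel():
    """60 samples × 20 loci from 2 diverged populations (fast tests)."""
    model = PopulationModel(n_pops=2, n_loci=20, n_samples=60,
                            freq_prior=(0.2, 0.2), admix_alpha=0.05,
                            missing_rate=0.0, seed=11)
    return simulate_panel(model)
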