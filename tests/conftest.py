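"""Shared fixtures: small synthetic genomes, matrices and architectures.

Everything is generated programmatically at test time with fixed seeds.
"""

import numpy as np
import pytest

from mitohic.genome import GenomeSpec, SampleKey, full_design
from mitohic.matrix import ContactMatrix, kr_balance
from mitohic import simulate as sim


@pytest.fixture(scope="session")
def small_genome():
    return GenomeSpec({"chr1": 8_000_000}, 10_000)


@pytest.fixture(scope="session")
def small_arch(small_genome):
    return sim.PlantedArchitecture.random(
        small_genome, seed=1, n_structural=6, n_dual=2, n_cre_stable=3,
        n_cre_transient=4, n_cre_gained=2, n_genes=20,
    )


@pytest.fixture(scope="session")
def small_decay():
    return sim.DecayModel(budget_per_replicate=4.0e6)


@pytest.fixture(scope="session")
def small_timecourse(small_genome, small_arch, small_decay):
    design = full_design()
    matrices, truth = sim.generate_timecourse(
        small_genome, small_arch, small_decay, design, seed=1
    )
    merged = sim.merge_replicates(matrices)
    return {"matrices": matrices, "merged": merged, "truth": truth, "design": design}


@pytest.fixture(scope="session")
def balanced_midg1(small_timecourse):
    m = small_timecourse["merged"][SampleKey("mid_G1", "control", 0)]["chr1"]
    if m.weights is None:
        kr_balance(m)
    return m


def poisson_matrix(mean_dense: np.ndarray, seed: int, chrom="chr1", bin_size=10_000):
    """Poisson sample of a symmetric mean surface (helper for tests)."""
    rng = np.random.default_rng(seed)
    upper = np.triu(mean_dense)
    counts = rng.poisson(upper)
    return ContactMatrix.from_dense(chrom, bin_size, counts.astype(float))


def decayed_surface(n: int, total: float, alpha: float = 1.0) -> np.ndarray:
    """Symmetric power-law decay surface scaled to a contact budget."""
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    surf = (d + 1.0) ** (-alpha)
    surf *= total / np.triu(surf).sum()
    return surf
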