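"""Shared fixtures for the test suite.

All randomness comes from fixed seeds; every fixture is deterministic.
"""

import numpy as np
import pytest

from matealloc.genotypes import GenotypeMatrix, PedigreeTable
from matealloc.markerfx import MarkerEffects
from matealloc.simdata import SimConfig, simulate_founder_genotypes


@pytest.fixture(scope="session")
def founders_small() -> GenotypeMatrix:
    """30 boars + 45 sows x 120 SNPs, frequencies frozen."""
    cfg = SimConfig(n_boars=30, n_sows=45, m_snps=120, seed=42)
    g = simulate_founder_genotypes(cfg)
    g.freeze_freqs()
    return g


@pytest.fixture()
def toy_geno() -> GenotypeMatrix:
    """4 animals x 3 SNPs with one missing call, unfrozen frequencies."""
    counts = np.array(
        [
            [2.0, 1.0, 0.0],
            [0.0, 1.0, 2.0],
            [1.0, np.nan, 1.0],
            [2.0, 2.0, 0.0],
        ]
    )
    return GenotypeMatrix(counts, ["a1", "a2", "a3", "a4"], ["s1", "s2", "s3"])


@pytest.fixture()
def trio_pedigree() -> PedigreeTable:
    import pandas as pd

    return PedigreeTable(
        pd.DataFrame(
            {
                "animal": ["sire", "dam", "kid1", "kid2"],
                "sire": ["0", "0", "sire", "sire"],
                "dam": ["0", "0", "dam", "dam"],
            }
        )
    )


def make_effects(geno: GenotypeMatrix, seed: int = 0, b: float = 0.0) -> MarkerEffects:
    rng = np.random.default_rng(seed)
    m = geno.n_snps
    return MarkerEffects(
        snp_ids=list(geno.snp_ids),
        a=rng.normal(0.0, 0.3, m),
        d_star=rng.normal(0.1, 0.05, m),
        b_hat=b,
        p=geno.p,
        sigma2_a=0.09,
        sigma2_d=0.0025,
    )
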