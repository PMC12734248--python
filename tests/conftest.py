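import numpy as np
import pytest

import dorsatrace as dt


@pytest.fixture(scope="session")
def two_pop_table():
    """A modest two-population genotype table with 2 planted diagnostic
    sites among neutral loci; shared across read-only tests."""
    cfg = dt.SimConfig(
        n_pop_a=60,
        n_pop_b=60,
        n_sites=202,
        planted_sites=2,
        planted_freqs=(0.02, 0.98),
        divergence=0.05,
        missing_rate=0.005,
        seed=11,
    )
    gt, planted = dt.simulate_genotypes(cfg)
    return gt, planted


@pytest.fixture(scope="session")
def barcode_reference():
    """A two-region barcode reference with disjoint haplotype pools."""
    cfg = dt.disjoint_pool_config(
        {"Africa": 50, "Southeast Asia": 50}, mutation_rate=0.002, seed=7
    )
    aln, truth = dt.simulate_barcodes(cfg)
    return cfg, aln, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
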