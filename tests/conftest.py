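import numpy as np
import pytest

import crmkit as ck


@pytest.fixture(scope="session")
def toy():
    """The printed 5-animal, 30-SNP worked example plus its toy pedigree."""
    return ck.toy_fixture()


@pytest.fixture(scope="session")
def toy_genotypes(toy):
    return toy[0]


@pytest.fixture(scope="session")
def halfsib_population():
    """40 sires x 5 half-sib offspring, 5000 unlinked loci (heavy; shared)."""
    cfg = ck.SimConfig(seed=20260901, n_loci=5000, n_halfsib_families=40, halfsib_size=5)
    return ck.simulate_pedigree_population(cfg)


@pytest.fixture(scope="session")
def fullsib_population():
    """40 full-sib families of size 2, 5000 unlinked loci (heavy; shared)."""
    cfg = ck.SimConfig(seed=20260902, n_loci=5000, n_fullsib_families=40, fullsib_size=2)
    return ck.simulate_pedigree_population(cfg)


@pytest.fixture(scope="session")
def hwe_population():
    """200 unrelated Hardy-Weinberg individuals at 5000 loci (heavy; shared)."""
    cfg = ck.SimConfig(seed=20260903, n_loci=5000, n_unrelated=200)
    g, _ = ck.simulate_pedigree_population(cfg)
    return g


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
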