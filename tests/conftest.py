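import pytest

from abcfam import simulate

SEED = 7


@pytest.fixture(scope="session")
def spec():
    return simulate.SyntheticSpec()


@pytest.fixture(scope="session")
def registry(spec):
    return simulate.gen_cohort_registry(spec, seed=SEED)


@pytest.fixture(scope="session")
def proteins(spec, registry):
    return simulate.gen_proteins(spec, registry, seed=SEED)


@pytest.fixture(scope="session")
def promoters(spec, registry):
    return simulate.gen_promoters(spec, registry, seed=SEED)


@pytest.fixture(scope="session")
def sim_counts(spec, registry):
    return simulate.gen_counts(spec, registry, seed=SEED)


@pytest.fixture(scope="session")
def sim_ct(spec):
    return simulate.gen_ct(spec, seed=SEED)
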