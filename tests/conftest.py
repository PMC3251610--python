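import warnings

import pytest
from hypothesis import settings

from snpforge import simgen

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_cfg():
    """The default study conditions of the synthetic experiment."""
    return simgen.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def sim_dataset(sim_cfg):
    """One fully simulated dataset shared across tests: reference with
    injected ambiguities, planted variants, reads, manifest, truth."""
    emitted, clean = simgen.simulate_reference(sim_cfg)
    haplotypes, truth = simgen.plant_variants(clean, sim_cfg)
    store, manifest = simgen.simulate_alignments(haplotypes, sim_cfg, truth)
    return {
        "cfg": sim_cfg,
        "emitted": emitted,
        "clean": clean,
        "haplotypes": haplotypes,
        "truth": truth,
        "store": store,
        "manifest": manifest,
    }


@pytest.fixture(scope="session")
def sim_matrix(sim_cfg):
    matrix, truth_freqs = simgen.simulate_genotype_matrix(sim_cfg)
    return matrix, truth_freqs


@pytest.fixture()
def no_warnings():
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        yield caught
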