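from types import SimpleNamespace

import pytest

from radicl.pipeline import process_reads
from radicl.simulate import (SimConfig, build_fixture, sample_contacts,
                             synthesize_reads)


@pytest.fixture(scope="session")
def sim():
    """A clean simulated library shared across tests: fixture genome,
    ground-truth contacts, error-free reads."""
    config = SimConfig(seed=11, n_contacts=4000)
    fixture = build_fixture(config)
    contacts = sample_contacts(fixture)
    reads, truth = synthesize_reads(contacts, fixture)
    return SimpleNamespace(config=config, fixture=fixture,
                           contacts=contacts, reads=reads, truth=truth)


@pytest.fixture(scope="session")
def processed(sim):
    """Annotated pair table from the clean library."""
    pairs, stats = process_reads(sim.reads, sim.fixture,
                                 screen_rrna=False, deduplicate=False)
    return pairs, stats
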