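import pytest

import mlstpop as M

# short-locus scheme for fast tests (sixth-scale fragments, 30 bp implants)
SHORT_LENGTHS = (60, 66, 48, 57, 35, 49)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition dataset: 3 lineages x 20 isolates, full-length loci."""
    cfg = M.SimulationConfig(seed=7)
    records, truth = M.simulate_dataset(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def typed_sim(default_sim):
    cfg, records, truth = default_sim
    scheme = truth.reference_scheme()
    profiles, st_table, catalog = M.type_dataset(records, scheme)
    return records, truth, scheme, profiles, st_table


@pytest.fixture(scope="session")
def small_sim():
    """Small short-locus dataset for I/O and CLI tests."""
    cfg = M.SimulationConfig(
        seed=11,
        isolates_per_lineage=(6, 5, 4),
        locus_lengths=SHORT_LENGTHS,
        fragment_length=30,
    )
    records, truth = M.simulate_dataset(cfg)
    return cfg, records, truth
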