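import pytest

from sterolpath.annotate import assign_orthologs, load_default_motif, load_default_rule
from sterolpath.catalog import load_default_catalog
from sterolpath.synth import ProteomeScenario, generate_proteome, load_reference_library


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def references():
    return load_reference_library()


@pytest.fixture(scope="session")
def osc_rule():
    return load_default_rule()


@pytest.fixture(scope="session")
def altsqe_motif():
    return load_default_motif()


@pytest.fixture(scope="session")
def default_proteome(catalog, references):
    """Seed-1 synthetic proteome with its truth table (expensive, shared)."""
    scenario = ProteomeScenario(seed=1)
    records, truth = generate_proteome(scenario, catalog, references)
    return records, truth


@pytest.fixture(scope="session")
def default_calls(default_proteome, catalog, references):
    records, _ = default_proteome
    return assign_orthologs(records, catalog, references)
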