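import pytest

import srnaome as so


@pytest.fixture(scope="session")
def dataset():
    """The default synthetic study (seed 1), shared across tests."""
    return so.make_dataset(so.SynthConfig(seed=1))


@pytest.fixture(scope="session")
def report(dataset):
    """A full pipeline run over the shared dataset."""
    return so.run_pipeline(dataset)


@pytest.fixture(scope="session")
def species_class(dataset):
    """Map from planted sRNA sequence to its true class of origin."""
    return {p["sequence"]: p["class"] for p in dataset.truth["species_plan"]}
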