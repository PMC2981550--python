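import numpy as np
import pytest

from hetphos import (
    Dataset,
    FeatureMatrix,
    PhosphoSite,
    Protein,
    StructureTable,
    SynthConfig,
    generate_dataset,
    null_dataset,
)


@pytest.fixture
def toy_proteome():
    return {
        "P1": Protein("P1", "MASTQPLVKSPTRRA"),
        "P2": Protein("P2", "AAAASAAAATTTTTT"),
    }


@pytest.fixture
def toy_dataset(toy_proteome):
    sites = [
        PhosphoSite("P1", 4, "T", "CDK"),
        PhosphoSite("P1", 10, "S", "CDK"),
        PhosphoSite("P2", 5, "S", "PKA"),
    ]
    mat = FeatureMatrix.from_pairs(
        "go_cc",
        [("P1", "go_cc:cytoplasm"), ("P2", "go_cc:nucleus"), ("P1", "go_cc:nucleus")],
        protein_ids=["P1", "P2"],
    )
    structure = StructureTable()
    for prot in toy_proteome.values():
        structure.add_protein(prot.id, "C" * len(prot), [3] * len(prot))
    ds = Dataset(
        proteome=toy_proteome,
        sites=sites,
        matrices={"go_cc": mat},
        structure=structure,
    )
    ds.validate()
    return ds


@pytest.fixture(scope="session")
def planted_config():
    # Generator defaults: 500 background + 50 substrates x 2 sites, S/T-P
    # motif at strength 0.8, seven namespaces with planted terms at OR 8.
    return SynthConfig(seed=11)


@pytest.fixture(scope="session")
def planted_ds(planted_config):
    return generate_dataset(planted_config)


@pytest.fixture(scope="session")
def null_ds(planted_config):
    return null_dataset(planted_config)
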