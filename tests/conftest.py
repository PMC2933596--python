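import numpy as np
import pandas as pd
import pytest

from chemlinker import (
    EngineConfig,
    FixtureSpec,
    generate_fixture_store,
    load_store,
)


@pytest.fixture(scope="session")
def fixture_store_dir(tmp_path_factory):
    """A generated store with two planted chains, shared across tests."""
    out = tmp_path_factory.mktemp("store")
    manifest = generate_fixture_store(FixtureSpec(seed=7), out)
    return out, manifest


@pytest.fixture(scope="session")
def fixture_store(fixture_store_dir):
    out, manifest = fixture_store_dir
    return load_store(out, EngineConfig()), manifest


class FakeStore:
    """Minimal duck-typed store for annotation-chain tests."""

    def __init__(self, lexicon, go_genes, matrix):
        self.go_lexicon = lexicon
        self.go_genes = go_genes
        self.gene_disease = matrix


@pytest.fixture
def tiny_annotation_store():
    from chemlinker import GOLexicon
    from chemlinker.datastore import GeneDiseaseMatrix

    lexicon = GOLexicon({"apoptosis": "GO:0006915", "cell cycle": "GO:0007049"})
    go_genes = {"GO:0006915": ("TP53",), "GO:0007049": ("CDK1", "TP53")}
    matrix = GeneDiseaseMatrix(pd.DataFrame(
        {"Leukemia": [0.9, 0.3], "Glioma": [0.4, 0.8]},
        index=["TP53", "CDK1"],
    ))
    return FakeStore(lexicon, go_genes, matrix)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
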