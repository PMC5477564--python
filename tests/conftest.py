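import numpy as np
import pytest

from sc3kit.annotation import AnnotationSet, GeneModel, GenomeLayout


@pytest.fixture
def layout():
    return GenomeLayout({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def toy_genes():
    return [
        GeneModel("geneA", "ALPHA", "chr1", "+", 10_001, 15_000,
                  exons=((10_001, 11_000), (12_001, 15_000))),
        GeneModel("geneB", "BETA", "chr1", "-", 40_001, 44_000),
        GeneModel("geneC", "GAMMA", "chr2", "+", 1_001, 3_000,
                  biotype="pseudogene"),
    ]


@pytest.fixture
def toy_annotation(layout, toy_genes):
    return AnnotationSet(layout, toy_genes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
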