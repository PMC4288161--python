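import numpy as np
import pytest

from modmotif.config import PipelineConfig
from modmotif.io import GenomicRegion, SequenceDataset
from modmotif.similarity import SimilarityEngine


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def engine(cfg) -> SimilarityEngine:
    return SimilarityEngine(cfg, seed=5)


def dataset_from_sequences(sequences, dataset_id="test", type_label=""):
    """Wrap raw sequences into a SequenceDataset on a synthetic chromosome."""
    regions = []
    cursor = 0
    for i, seq in enumerate(sequences):
        regions.append(GenomicRegion("chrT", cursor, cursor + len(seq),
                                     f"{dataset_id}:r{i}"))
        cursor += len(seq) + 10
    return SequenceDataset(dataset_id, type_label, regions, list(sequences))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
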