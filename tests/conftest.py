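import numpy as np
import pytest

from ssm6ma import (GeneratorConfig, LabeledDataset, LabeledSequence,
                    ModelConfig, MotifSpec, generate_dataset)


@pytest.fixture
def tiny_model_config():
    """Small architecture for fast functional tests."""
    return ModelConfig(L=41, N=8, M=12, S=4, window_sizes=(3,),
                       layers_per_block=1, fc_dims=(32, 8, 1),
                       dropout=0.0, dtype="float64")


@pytest.fixture
def grad_check_config():
    """Tiny configuration for finite-difference gradient checks."""
    return ModelConfig(L=7, N=4, M=6, S=3, window_sizes=(3, 5, 7),
                       layers_per_block=1, fc_dims=(8, 5, 1),
                       dropout=0.0, dtype="float64")


@pytest.fixture
def small_planted_dataset():
    """120 sequences with a strongly planted GAG motif."""
    return generate_dataset(GeneratorConfig(
        n_per_class=60, seed=7,
        motif=MotifSpec(plant_probability=1.0, decoy_probability=0.0)))


def make_dataset(seqs_with_labels):
    return LabeledDataset([LabeledSequence(f"s{i}", b, y)
                           for i, (b, y) in enumerate(seqs_with_labels)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
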