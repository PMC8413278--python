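import numpy as np
import pytest

from cytophase.classifier import build_model
from cytophase.pipeline import (
    PipelineConfig,
    generate_condition_captures,
    run_holdout_evaluation,
    run_training_pipeline,
)
from cytophase.sad_filter import train_sad
from cytophase.synthetic_data import generate_labeled_dataset


@pytest.fixture(scope="session")
def vgg_model():
    """The full VGG-19-style model (seeded random weights); built once, ~10 s."""
    return build_model("vgg19_full", seed=0)


@pytest.fixture(scope="session")
def sad_training_sets():
    """Curated SAD training set at the protocol's counts: 200 alive + 100 + 100."""
    groups = generate_labeled_dataset(200, seed=901, id_prefix="sadsup").by_class()
    return groups["alive"], groups["apoptosis"][:100], groups["necroptosis"][:100]


@pytest.fixture(scope="session")
def sad_model(sad_training_sets):
    alive, apo, necro = sad_training_sets
    return train_sad(alive, apo, necro, seed=0)


@pytest.fixture(scope="session")
def pipeline_run():
    """One default end-to-end training run plus a fresh holdout evaluation."""
    config = PipelineConfig(seed=1)
    result = run_training_pipeline(config)
    holdout = generate_condition_captures(config, seed_offset=500_000)
    report = run_holdout_evaluation(
        config, result.classifier, holdout, result.train_capture_ids, result.sad_model
    )
    return config, result, holdout, report
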