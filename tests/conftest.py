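import numpy as np
import pytest

from beatid import protocol, synth
from beatid.model import ArchitectureSpec
from beatid.protocol import TrainConfig, SplitSpec

# Fixed study conditions for the end-to-end tests: 10 synthetic subjects,
# mixed normal/arrhythmic beats, default noise (0.02 mV), seeded throughout.
COHORT_PERSON_SEEDS = list(range(100, 110))
COHORT_RECORD_SEED = 7
COHORT_TRAIN_SEED = 3
COHORT_BEATS = 150
COHORT_MIX = {"N": 0.6, "A": 0.2, "V": 0.2}


@pytest.fixture(scope="session")
def cohort_persons():
    return [synth.sample_person(s) for s in COHORT_PERSON_SEEDS]


@pytest.fixture(scope="session")
def cohort_images(cohort_persons):
    """Scalogram images for a 10-subject cohort with N/A/V beats."""
    records = synth.synth_record(
        cohort_persons, COHORT_BEATS, COHORT_MIX, seed=COHORT_RECORD_SEED
    )
    segments = protocol.dataset_from_records(records)
    return protocol.images_from_segments(segments)


@pytest.fixture(scope="session")
def cohort_model(cohort_images):
    """Identifier trained on the cohort's normal beats (the N_vs_A protocol)."""
    split = protocol.make_split(
        cohort_images, SplitSpec(scenario="N_vs_A", arrhythmia_filter="all")
    )
    train_ds = cohort_images.select(split.train_idx)
    spec = ArchitectureSpec(n_classes=len(split.subjects))
    model = protocol.train_identifier(
        spec, train_ds, TrainConfig(epochs=10, seed=COHORT_TRAIN_SEED)
    )
    return model, split
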