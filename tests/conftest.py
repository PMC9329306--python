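"""Shared fixtures: tiny architectures for fast unit tests and one
session-scoped synthetic study (cohort -> trained model) reused by the
end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

import sleepcam as sc
from sleepcam.model import BlockConfig, ModelConfig
from sleepcam.preprocess import EpochSet, prepare_record

#: cohort seed for the end-to-end study; fixed so results are reproducible
STUDY_SEED = 11

#: records held out of training, evaluated as unseen test nights
N_TEST_RECORDS = 10


def tiny_model_config(seed: int = 0) -> ModelConfig:
    """Smallest legal architecture (pooled length 6); for contract tests."""
    return ModelConfig(
        eeg=BlockConfig(3, 5, 3, 3, 1000),
        eog=BlockConfig(2, 5, 2, 3, 500),
        emg=BlockConfig(2, 5, 2, 3, 1000),
        cam_kernel_width=3,
        seed=seed,
    )


def random_epochset(n: int, seed: int = 0, labels=None) -> EpochSet:
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = rng.choice(sc.STAGES, size=n)
    return EpochSet(
        eeg=rng.normal(size=(n, 6, 6000)).astype(np.float32),
        eog=rng.normal(size=(n, 2, 3000)).astype(np.float32),
        emg=rng.normal(size=(n, 1, 6000)).astype(np.float32),
        labels=np.asarray(labels, dtype=object).astype(str),
        record_ids=np.array(["rec"] * n, dtype=object),
    )


@pytest.fixture(scope="session")
def study_cohort():
    """40 one-hour synthetic records with default generation settings."""
    cfg = sc.SyntheticConfig(n_records=40, record_hours=1.0, seed=STUDY_SEED)
    return sc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def study_sets(study_cohort):
    return [prepare_record(r.record, r.hypnogram) for r in study_cohort]


@pytest.fixture(scope="session")
def study_model(study_sets):
    """Reduced-architecture model trained on the first 30 study records."""
    train = EpochSet.concatenate(study_sets[:-N_TEST_RECORDS])
    tconfig = sc.TrainingConfig(
        learning_rate=1.5e-3, max_iterations=8, patience=3,
        batch_size=128, seed=0,
    )
    return sc.train_model(sc.reduced_config(0), tconfig, train)


@pytest.fixture(scope="session")
def study_test_data(study_cohort, study_sets):
    """Held-out records with their epoch sets, for evaluation and audits."""
    return list(zip(study_cohort[-N_TEST_RECORDS:], study_sets[-N_TEST_RECORDS:]))
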