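"""Shared fixtures.

The expensive trained-model fixtures are session-scoped so the whole suite
trains each configuration exactly once:

* ``recovery_run`` — one model on the noiseless receptive-field-recovery
  dataset (200 neurons, 2000 training images at the reduced 36x64 stimulus
  resolution), up to 20 epochs.
* ``ensemble_run`` — a 5-member split ensemble on a smaller noiseless
  dataset, a few epochs per member.
"""

from __future__ import annotations

import numpy as np
import pytest

import v1enc as v


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small noisy dataset for I/O, split and metric plumbing tests."""
    cfg = v.SimulatorConfig(
        n_neurons=30,
        n_train_images=60,
        n_validation_images=20,
        n_test_images=10,
        n_repeats=3,
        image_shape=(36, 64),
        noise_model="gaussian",
        seed=3,
    )
    return (*v.generate_synthetic_dataset(cfg), cfg)


@pytest.fixture(scope="session")
def recovery_dataset():
    """Noiseless synthetic subject for parameter recovery: 200 neurons,
    2000 training images, reduced resolution."""
    cfg = v.SimulatorConfig(
        n_neurons=200,
        n_train_images=2000,
        n_validation_images=200,
        n_test_images=50,
        n_repeats=2,
        image_shape=(36, 64),
        noise_model="none",
        seed=5,
    )
    return (*v.generate_synthetic_dataset(cfg), cfg)


@pytest.fixture(scope="session")
def recovery_run(recovery_dataset):
    """One model trained on the recovery dataset (<= 20 epochs)."""
    dataset, truth, _ = recovery_dataset
    config = v.TrainConfig(max_epochs=20, seed=0)
    split = v.make_splits(dataset, 1, config.seed)[0]
    model, history = v.train_model(dataset, split, config)
    return dataset, truth, model, history


@pytest.fixture(scope="session")
def ensemble_run():
    """Five-member ensemble on a small noiseless dataset."""
    cfg = v.SimulatorConfig(
        n_neurons=64,
        n_train_images=512,
        n_validation_images=64,
        n_test_images=20,
        n_repeats=4,
        image_shape=(36, 64),
        noise_model="none",
        seed=11,
    )
    dataset, truth = v.generate_synthetic_dataset(cfg)
    config = v.TrainConfig(max_epochs=5, seed=1)
    models, histories = v.train_ensemble(dataset, n_models=5, config=config)
    return dataset, truth, models, histories


def standardized_test_table(dataset: v.Dataset, predictions: np.ndarray, split: str = "final_test"):
    """RepeatTable of standardized responses vs per-trial predictions."""
    idx = dataset.indices(split)
    resp = v.standardize_responses(dataset.responses[idx], dataset.response_std)
    return v.table_from_trials(resp, dataset.repeat_ids[idx], predictions)


@pytest.fixture(scope="session")
def random_tables():
    """Random small repeat tables for oracle-equivalence checks."""

    def make(n: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        tables = []
        for _ in range(n):
            n_img = int(rng.integers(2, 6))
            m = int(rng.integers(1, 4))
            responses = [rng.normal(size=(int(rng.integers(2, 5)), m)) for _ in range(n_img)]
            preds = rng.normal(size=(n_img, m))
            tables.append(v.RepeatTable(responses=responses, predictions=preds))
        return tables

    return make
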