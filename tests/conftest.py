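"""Shared fixtures.

The expensive session fixtures (simulated training cohort, trained models)
are built lazily, so lightweight test files never pay for them. All
trained models for the head-comparison and recovery tests share one
simulated cohort.
"""

from __future__ import annotations

import os

os.environ.setdefault("MPLBACKEND", "Agg")

import numpy as np
import pytest

from ecgsurv.model import EcgRiskModel, TrainConfig, train_model
from ecgsurv.pipeline import (assemble_model_data, make_classification_sets,
                              make_survival_sets)
from ecgsurv.simulate import SimulationConfig


#: Simulation seed of the shared training cohort (chosen once).
COHORT_SEED = 11
TRAIN_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def model_data():
    """Preprocessed synthetic cohort: ~1000 patients, ~2300 training pairs."""
    return assemble_model_data(SimulationConfig(n_patients=1000, seed=COHORT_SEED))


def _train(data, head: str, seed: int, shuffle_labels: bool = False):
    from ecgsurv.model import BackboneConfig

    if head == "survival":
        train_set, tune_set = make_survival_sets(data, "mr")
    else:
        train_set, tune_set = make_classification_sets(data, "mr")
    if shuffle_labels:
        # independent permutation per training seed: three distinct draws
        # from the null, not one shared chance assignment
        rng = np.random.default_rng(10_000 + seed)
        for ds in (train_set, tune_set):
            perm = rng.permutation(len(ds))
            ds.y = ds.y[perm]
            ds.mask = ds.mask[perm]
    model = EcgRiskModel(BackboneConfig.tiny(), head=head, seed=seed)
    log = train_model(model, train_set, tune_set,
                      TrainConfig(max_epochs=25), seed=seed)
    return model, log


@pytest.fixture(scope="session")
def trained_models(model_data):
    """Survival and classification models at three matched training seeds."""
    return {(head, seed): _train(model_data, head, seed)
            for head in ("survival", "classification")
            for seed in TRAIN_SEEDS}


@pytest.fixture(scope="session")
def shuffled_models(model_data):
    """Survival models trained on label-shuffled data (null-signal controls),
    one per matched training seed."""
    return [_train(model_data, "survival", seed, shuffle_labels=True)
            for seed in TRAIN_SEEDS]
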