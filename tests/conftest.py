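"""Shared fixtures.

The expensive fixture is ``recovery_study``: one tiny-preset training run
under the phantom parameter-recovery conditions (200 training series, 50
held-out, 15 epochs).  It is session-scoped and shared by the acceptance,
inference and saliency tests so the suite trains exactly once.
"""

from dataclasses import dataclass

import numpy as np
import pytest

from tiscout.estimator import TIScoutNullModel
from tiscout.phantom import PhantomConfig, simulate_dataset, simulate_series
from tiscout.preprocess import label_series


@pytest.fixture(scope="session")
def phantom_series():
    """A single noise-free phantom series with its true null index."""
    config = PhantomConfig(noise_sigma=0.0, myocardium_t1=400.0,
                           ti_start=100.0, ti_step=25.0, n_frames=20, seed=3)
    return simulate_series(config)


@dataclass
class RecoveryStudy:
    estimator: TIScoutNullModel
    test_series: list
    test_nulls: list
    truth: np.ndarray
    pred: np.ndarray

    @property
    def errors(self) -> np.ndarray:
        return np.abs(self.pred - self.truth)


@pytest.fixture(scope="session")
def recovery_study() -> RecoveryStudy:
    """Train the tiny preset under the parameter-recovery study conditions."""
    train_series, train_nulls = simulate_dataset(200, seed=11)
    test_series, test_nulls = simulate_dataset(50, seed=12)
    dataset = [label_series(s, k) for s, k in zip(train_series, train_nulls)]
    est = TIScoutNullModel(preset="tiny", epochs=15, batch_size=32,
                           lr_backbone=3e-3, lr_recurrent=1e-3, seed=0)
    est.fit(dataset)
    truth = np.array([s.ti_values[k] for s, k in zip(test_series, test_nulls)])
    pred = est.predict(test_series)
    return RecoveryStudy(estimator=est, test_series=test_series,
                         test_nulls=test_nulls, truth=truth, pred=pred)
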