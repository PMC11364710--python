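"""Loss weighting, weighted BCE, training behaviour, cross-validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tiscout.estimator import TIScoutNullModel, loss_weight, weighted_bce
from tiscout.model import ModelSpec
from tiscout.phantom import simulate_dataset
from tiscout.preprocess import label_series
from tiscout.series import TIScoutSeries
from tiscout.train import TrainConfig, crossvalidate, train


class TestLossWeight:
    def test_cap_at_optimal_ti(self):
        assert loss_weight(300.0, 300.0) == 3.0

    @pytest.mark.parametrize("factor,expected", [
        (math.e, 1.0),          # ln e = 1
        (math.sqrt(math.e), 2.0),  # 1 / 0.5
        (math.e ** 3, 1.0 / 3.0),
    ])
    def test_closed_form_values(self, factor, expected):
        assert loss_weight(factor * 250.0, 250.0) == pytest.approx(expected, rel=1e-12)

    def test_custom_cap(self):
        assert loss_weight(300.0, 300.0, cap=5.0) == 5.0

    def test_nonpositive_ti_rejected(self):
        with pytest.raises(ValueError):
            loss_weight(-1.0, 300.0)
        with pytest.raises(ValueError):
            loss_weight(300.0, 0.0)

    @given(ratio=st.floats(1.01, 50.0), t_opt=st.floats(100.0, 600.0))
    @settings(max_examples=60, deadline=None)
    def test_symmetric_in_ratio_inversion_and_decreasing(self, ratio, t_opt):
        """weight(r * T, T) == weight(T / r, T), both = min(1/|ln r|, 3),
        decreasing as the ratio moves away from 1."""
        up = loss_weight(ratio * t_opt, t_opt)
        down = loss_weight(t_opt / ratio, t_opt)
        assert up == pytest.approx(down, rel=1e-9)
        further = loss_weight(ratio * 1.5 * t_opt, t_opt)
        assert further <= up + 1e-12


class TestWeightedBCE:
    def test_perfect_hard_predictions_have_zero_loss(self):
        assert weighted_bce([0.0, 1.0], [0.0, 1.0], [2.0, 3.0]) == pytest.approx(0.0, abs=1e-9)

    def test_soft_target_half_gives_ln2(self):
        assert weighted_bce([0.5], [0.5], [1.0]) == pytest.approx(math.log(2), rel=1e-9)

    def test_linear_in_weights(self):
        p, t = [0.3, 0.8], [0.0, 1.0]
        base = weighted_bce(p, t, [1.0, 1.0])
        assert weighted_bce(p, t, [2.0, 2.0]) == pytest.approx(2 * base, rel=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_bce([0.5], [0.5, 0.5], [1.0])


@pytest.fixture(scope="module")
def small_dataset():
    series, nulls = simulate_dataset(8, seed=21)
    return [label_series(s, k) for s, k in zip(series, nulls)]


class TestTraining:
    def test_overfits_five_series(self, small_dataset):
        """Capacity sanity check: training loss on 5 series collapses to
        well below its starting value within 30 epochs."""
        est = TIScoutNullModel(preset="tiny", epochs=30, batch_size=5,
                               lr_backbone=3e-3, lr_recurrent=1e-3,
                               augment=False, seed=1)
        est.fit(small_dataset[:5])
        assert est.history_[-1] < 0.5 * est.history_[0]
        # weighted soft-label floor: the 0.5-target window alone contributes
        # about cap * ln2 / 5 to the mean, so compare against that floor
        floor = 3.0 * math.log(2) / 5.0
        assert est.history_[-1] < floor * 1.25

    def test_same_seed_reproduces_parameters(self, small_dataset):
        kw = dict(preset="tiny", epochs=2, batch_size=4, seed=3)
        a = TIScoutNullModel(**kw).fit(small_dataset)
        b = TIScoutNullModel(**kw).fit(small_dataset)
        for (_, pa), (_, pb) in zip(a.network_.named_parameters(),
                                    b.network_.named_parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)
        assert a.history_ == b.history_

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            TIScoutNullModel(preset="tiny").fit([])

    def test_short_series_rejected_by_name(self, small_dataset):
        rng = np.random.default_rng(0)
        short = TIScoutSeries(frames=rng.normal(size=(8, 16, 16)),
                              ti_values=100.0 + 25 * np.arange(8),
                              series_id="too-short")
        bad = small_dataset + [label_series(short, 4)]
        with pytest.raises(ValueError, match="too-short"):
            TIScoutNullModel(preset="tiny").fit(bad)


class TestTrainFunction:
    def test_returns_bundle_and_history(self, small_dataset):
        config = TrainConfig.desk_scale(seed=2, epochs=2, batch_size=4)
        bundle, history = train(small_dataset, ModelSpec.tiny("resnet18"), config)
        assert len(history) == 2
        assert bundle.spec.backbone == "resnet18"
        assert bundle.norm_stats.std > 0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(folds=1)
        with pytest.raises(ValueError):
            TrainConfig(val_fraction=1.5)
        with pytest.raises(ValueError):
            TrainConfig(lr_backbone=0.0)


@pytest.fixture(scope="module")
def cv_run():
    series, nulls = simulate_dataset(10, seed=31)
    dataset = [label_series(s, k) for s, k in zip(series, nulls)]
    config = TrainConfig.desk_scale(seed=5, epochs=1, batch_size=4)
    results, best = crossvalidate(dataset, ModelSpec.tiny("resnet18"), config)
    return dataset, config, results, best


class TestCrossValidation:
    def test_folds_partition_the_dataset(self, cv_run):
        dataset, _, results, _ = cv_run
        all_val = np.concatenate([r.val_indices for r in results])
        assert sorted(all_val.tolist()) == list(range(len(dataset)))
        assert all(len(r.val_indices) == 2 for r in results)

    def test_selection_minimises_mae(self, cv_run):
        _, _, results, best = cv_run
        best_mae = min(r.report.mae for r in results)
        winner = [r for r in results if r.bundle is best][0] if any(
            r.bundle is best for r in results) else None
        assert winner is not None
        assert winner.report.mae == best_mae

    def test_same_seed_same_fold_assignment(self, cv_run):
        dataset, config, results, _ = cv_run
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
        expected = [val for _, val in splitter.split(np.arange(len(dataset)))]
        for r, val in zip(results, expected):
            np.testing.assert_array_equal(r.val_indices, val)

    def test_too_few_series_rejected(self):
        series, nulls = simulate_dataset(3, seed=41)
        dataset = [label_series(s, k) for s, k in zip(series, nulls)]
        with pytest.raises(ValueError):
            crossvalidate(dataset, ModelSpec.tiny("resnet18"),
                          TrainConfig.desk_scale(seed=0))
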