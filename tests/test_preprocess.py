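"""Labelling, sampling, windowing and augmentation contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tiscout.phantom import PhantomConfig, simulate_series
from tiscout.preprocess import (
    AugmentPolicy,
    NormalizationStats,
    admissible_splice_starts,
    augment,
    drop_frames,
    extract_windows,
    inference_windows,
    label_series,
    normalize,
    resize,
    sample_splice,
    training_sample,
)
from tiscout.series import TIScoutSeries


def _series(n, start=100.0, step=25.0, size=16, seed=0):
    rng = np.random.default_rng(seed)
    return TIScoutSeries(frames=rng.normal(size=(n, size, size)),
                         ti_values=start + step * np.arange(n),
                         series_id=f"s{n}")


class TestLabelSeries:
    @pytest.mark.parametrize("n,null,expected", [
        (5, 2, [0, 0, 0.5, 1, 1]),
        (4, 0, [0.5, 1, 1, 1]),
        (4, 3, [0, 0, 0, 0.5]),
    ])
    def test_soft_label_scheme(self, n, null, expected):
        labelled = label_series(_series(n), null)
        np.testing.assert_array_equal(labelled.labels, expected)

    def test_out_of_range_null_rejected(self):
        with pytest.raises(ValueError):
            label_series(_series(5), 5)
        with pytest.raises(ValueError):
            label_series(_series(5), -1)

    @given(n=st.integers(1, 60), data=st.data())
    @settings(max_examples=40, deadline=None)
    def test_monotone_with_exactly_one_half(self, n, data):
        null = data.draw(st.integers(0, n - 1))
        labels = label_series(_series(n), null).labels
        assert np.all(np.diff(labels) >= 0)
        assert np.sum(labels == 0.5) == 1
        assert labels[null] == 0.5


class TestNormalize:
    def test_centres_constant_image(self):
        stats = NormalizationStats(mean=7.0, std=2.0)
        out = normalize(np.full((3, 4, 4), 7.0), stats)
        np.testing.assert_array_equal(out, 0.0)

    def test_identity_stats(self):
        x = np.random.default_rng(0).normal(size=(2, 5, 5))
        out = normalize(x, NormalizationStats(mean=0.0, std=1.0))
        np.testing.assert_allclose(out, x, rtol=1e-6)

    def test_self_stats_standardise(self):
        series = [_series(6, seed=1), _series(4, seed=2)]
        stats = NormalizationStats.from_series(series)
        pooled = np.concatenate([normalize(s.frames, stats).ravel() for s in series])
        assert pooled.mean() == pytest.approx(0.0, abs=1e-5)
        assert pooled.std() == pytest.approx(1.0, abs=1e-5)

    def test_zero_std_rejected(self):
        with pytest.raises(ValueError):
            NormalizationStats(mean=0.0, std=0.0)


class TestResize:
    def test_shape_contract(self):
        out = resize(np.random.default_rng(0).normal(size=(300, 200)), 256)
        assert out.shape == (256, 256)

    def test_noop_at_target_size(self):
        x = np.random.default_rng(0).normal(size=(256, 256)).astype(np.float32)
        np.testing.assert_array_equal(resize(x, 256), x)

    def test_constancy_preserved(self):
        out = resize(np.full((128, 128), 3.5), 256)
        np.testing.assert_allclose(out, 3.5, rtol=1e-6)


class TestSampleSplice:
    def test_nine_frame_series_returned_whole(self):
        labelled = label_series(_series(9), 4)
        out = sample_splice(labelled, np.random.default_rng(0))
        assert len(out.series) == 9
        np.testing.assert_array_equal(out.series.ti_values, labelled.series.ti_values)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="< 9"):
            sample_splice(label_series(_series(8), 3), np.random.default_rng(0))

    @pytest.mark.parametrize("n,null", [(34, 15), (34, 2), (34, 33), (12, 0), (20, 19)])
    def test_splice_always_contains_null(self, n, null):
        labelled = label_series(_series(n), null)
        rng = np.random.default_rng(1)
        for _ in range(25):
            out = sample_splice(labelled, rng)
            assert len(out.series) == 9
            assert out.labels[out.null_index] == 0.5
            # same frame content as the annotated null
            np.testing.assert_array_equal(
                out.series.frames[out.null_index], labelled.series.frames[null])

    def test_admissible_starts_enumeration(self):
        # null at index 2 of 34 -> only starts 0..2 keep the null inside
        np.testing.assert_array_equal(admissible_splice_starts(34, 2), [0, 1, 2])
        # null at 15 -> starts 7..15
        np.testing.assert_array_equal(admissible_splice_starts(34, 15), np.arange(7, 16))

    def test_rng_state_determinism(self):
        labelled = label_series(_series(30), 14)
        a = sample_splice(labelled, np.random.default_rng(5))
        b = sample_splice(labelled, np.random.default_rng(5))
        np.testing.assert_array_equal(a.series.ti_values, b.series.ti_values)


class TestDropFrames:
    def test_keeps_seven_ordered_frames_and_null(self):
        labelled = label_series(_series(9), 0)  # null at the boundary
        rng = np.random.default_rng(0)
        for _ in range(50):
            out = drop_frames(labelled, rng)
            assert len(out.series) == 7
            assert np.all(np.diff(out.series.ti_values) > 0)
            assert out.labels[out.null_index] == 0.5
            np.testing.assert_array_equal(
                out.series.frames[out.null_index], labelled.series.frames[0])

    def test_all_admissible_removals_reachable(self):
        """Monte-Carlo over the C(8,2) = 28 admissible removal pairs: every
        outcome preserves order and the null, and all pairs occur."""
        labelled = label_series(_series(9), 4)
        rng = np.random.default_rng(0)
        seen = set()
        for _ in range(600):
            out = drop_frames(labelled, rng)
            removed = tuple(sorted(set(labelled.series.ti_values) -
                                   set(out.series.ti_values)))
            assert labelled.series.ti_values[4] not in removed
            seen.add(removed)
        assert len(seen) == 28

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            drop_frames(label_series(_series(7), 3), np.random.default_rng(0))


class TestExtractWindows:
    @pytest.mark.parametrize("n,expected", [(7, 5), (3, 1), (34, 32)])
    def test_window_count(self, n, expected):
        windows = extract_windows(label_series(_series(n), n // 2))
        assert len(windows) == expected
        centre_tis = [w.centre_ti for w in windows]
        assert np.all(np.diff(centre_tis) > 0)

    def test_targets_follow_centre_labels(self):
        labelled = label_series(_series(7), 3)
        windows = extract_windows(labelled)
        assert [w.target for w in windows] == [0.0, 0.0, 0.5, 1.0, 1.0]
        assert windows[2].centre_index == 3

    def test_channel_order_is_temporal(self):
        labelled = label_series(_series(5), 2)
        w = extract_windows(labelled)[0]
        np.testing.assert_allclose(w.channels[0], labelled.series.frames[0], rtol=1e-6)
        np.testing.assert_allclose(w.channels[2], labelled.series.frames[2], rtol=1e-6)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            extract_windows(label_series(_series(2), 0))


class TestAugment:
    def _window(self):
        return extract_windows(label_series(_series(5, size=12), 2))[1]

    def test_identity_policy_is_identity(self):
        w = self._window()
        out = augment(w, AugmentPolicy.identity(), np.random.default_rng(0))
        np.testing.assert_array_equal(out.channels, w.channels)
        assert out.centre_ti == w.centre_ti and out.target == w.target

    def test_horizontal_flip_is_involution(self):
        w = self._window()
        policy = AugmentPolicy(flip_horizontal=1.0)
        rng = np.random.default_rng(0)
        once = augment(w, policy, np.random.default_rng(0))
        twice = augment(once, policy, np.random.default_rng(0))
        np.testing.assert_array_equal(twice.channels, w.channels)

    def test_shape_preserved_under_full_policy(self):
        w = self._window()
        out = augment(w, AugmentPolicy.training_default(), np.random.default_rng(3))
        assert out.channels.shape == w.channels.shape


class TestCompositeSampler:
    @pytest.mark.parametrize("n,null", [(9, 4), (14, 2), (26, 20), (34, 17)])
    def test_five_windows_exactly_one_soft_target(self, n, null):
        labelled = label_series(_series(n), null)
        rng = np.random.default_rng(2)
        for _ in range(20):
            windows = training_sample(labelled, rng)
            assert len(windows) == 5
            targets = [w.target for w in windows]
            assert targets.count(0.5) == 1
            assert set(targets) <= {0.0, 0.5, 1.0}

    def test_inference_path_has_no_sampling(self):
        config = PhantomConfig(seed=1, n_frames=18)
        series, _ = simulate_series(config)
        windows = inference_windows(series)
        assert len(windows) == 16  # n - 2, the whole series as is
        np.testing.assert_allclose([w.centre_ti for w in windows],
                                   series.ti_values[1:-1])
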