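import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gaitfuse.features_fusion as ff
from gaitfuse.errors import AlignmentError, DataError, SplitError
from gaitfuse.signal_model import MultiChannelSignal

finite_floats = st.floats(min_value=-1e6, max_value=1e6,
                          allow_nan=False, allow_infinity=False)
windows = st.lists(finite_floats, min_size=1, max_size=64)


def brute_mav(xs):
    return sum(abs(x) for x in xs) / len(xs)


def brute_rms(xs):
    m = sum(xs) / len(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / len(xs))


@pytest.mark.parametrize("window,expected", [
    (np.zeros(30), 0.0),
    ([2, 2, 2, 2], 2.0),
    ([1, -1, 2, -2, 3, -3], 2.0),
])
def test_mav_examples(window, expected):
    assert ff.mav(window) == pytest.approx(expected, abs=1e-15)


@pytest.mark.parametrize("window,expected", [
    ([5, 5, 5, 5], 0.0),       # mean-centering annihilates constants
    ([1, -1, 1, -1], 1.0),
    (np.zeros(30), 0.0),
])
def test_rms_examples(window, expected):
    assert ff.rms_eq2(window) == pytest.approx(expected, abs=1e-15)


def test_classic_rms_option_is_uncentered():
    assert ff.rms_eq2([5, 5, 5, 5], centered=False) == pytest.approx(5.0)


def test_empty_window_errors():
    with pytest.raises(DataError):
        ff.mav([])
    with pytest.raises(DataError):
        ff.rms_eq2([])


@given(windows)
def test_features_match_brute_force(xs):
    assert ff.mav(xs) == pytest.approx(brute_mav(xs), rel=1e-12, abs=1e-12)
    assert ff.rms_eq2(xs) == pytest.approx(brute_rms(xs), rel=1e-9, abs=1e-9)


@given(windows, st.floats(min_value=-100, max_value=100, allow_nan=False))
def test_scale_and_translation_properties(xs, a):
    xs = np.asarray(xs)
    assert ff.mav(a * xs) == pytest.approx(abs(a) * ff.mav(xs), rel=1e-9, abs=1e-9)
    assert ff.rms_eq2(a * xs) == pytest.approx(abs(a) * ff.rms_eq2(xs),
                                               rel=1e-9, abs=1e-9)
    # translation invariance is a direct consequence of mean-centering
    assert ff.rms_eq2(xs + a) == pytest.approx(ff.rms_eq2(xs), rel=1e-7, abs=1e-7)


def _semg(n_samples, n_channels=6, rate=1500.0, seed=0):
    rng = np.random.default_rng(seed)
    return MultiChannelSignal([f"c{i}" for i in range(n_channels)], rate, 0.0,
                              rng.standard_normal((n_samples, n_channels)))


def test_extract_features_counts_and_channel_doubling():
    frames = ff.extract_features(_semg(3000))
    assert len(frames) == 100            # floor(3000 / 30)
    assert frames[0].values.shape == (12,)
    assert np.all(frames[0].values >= 0)


def test_extract_features_matches_scalar_oracles():
    sig = _semg(90)
    frames = ff.extract_features(sig)
    k, ch = 2, 4
    window = sig.values[60:90, ch]
    assert frames[k].values[ch] == pytest.approx(ff.mav(window), rel=1e-12)
    assert frames[k].values[6 + ch] == pytest.approx(ff.rms_eq2(window), rel=1e-12)


def test_extract_features_below_one_window_warns_empty():
    with pytest.warns(UserWarning):
        frames = ff.extract_features(_semg(29))
    assert frames == []


def test_frame_timestamps_align_with_low_rate_ticks():
    frames = ff.extract_features(_semg(3000))
    times = np.array([f.time_s for f in frames])
    np.testing.assert_allclose(times, np.arange(100) / 50.0, atol=1e-12)


def _angle(n, rate=50.0):
    return MultiChannelSignal(["knee_angle_deg"], rate, 0.0,
                              np.arange(n, dtype=float)[:, None])


def test_fuse_concatenates_to_13_columns():
    frames = ff.extract_features(_semg(3000))
    times, fused = ff.fuse(frames, _angle(100))
    assert fused.shape == (100, 13)
    np.testing.assert_array_equal(fused[:, 12], np.arange(100.0))


def test_fuse_tolerates_off_by_one_but_not_more():
    frames = ff.extract_features(_semg(3000))
    _, fused = ff.fuse(frames, _angle(99))
    assert fused.shape == (99, 13)
    with pytest.raises(AlignmentError):
        ff.fuse(frames, _angle(98))


def test_window_images_count_and_end_labels():
    fused = np.arange(100 * 13, dtype=float).reshape(100, 13)
    labels = np.arange(100) % 4
    ds = ff.window_images(fused, labels)
    assert len(ds) == 81                 # 100 - 20 + 1
    assert ds.images.shape == (81, 20, 13)
    np.testing.assert_array_equal(ds.labels, labels[19:])
    np.testing.assert_array_equal(ds.images[0], fused[:20])


def test_window_images_single_window():
    fused = np.zeros((20, 13))
    labels = np.r_[np.zeros(19, dtype=int), 3]
    ds = ff.window_images(fused, labels)
    assert len(ds) == 1
    assert ds.labels[0] == 3             # labels[19]


def test_window_images_too_short_warns_empty():
    with pytest.warns(UserWarning):
        ds = ff.window_images(np.zeros((5, 13)), np.zeros(5, dtype=int))
    assert len(ds) == 0


def _dataset(n=100, channels=13, seed=0):
    rng = np.random.default_rng(seed)
    return ff.FeatureDataset(rng.standard_normal((n, 20, channels)),
                             rng.integers(0, 4, n), np.arange(n, dtype=float))


def test_temporal_split_80_20_partition():
    ds = _dataset(100)
    train, test = ff.temporal_split(ds, 0.8, normalize=False)
    assert len(train) == 80 and len(test) == 20
    np.testing.assert_array_equal(np.r_[train.times, test.times], ds.times)
    assert train.times.max() < test.times.min()


def test_temporal_split_norm_stats_come_from_train_only():
    ds = _dataset(100)
    raw_train_imgs = ds.images[:80].copy()
    train, test = ff.temporal_split(ds, 0.8, normalize=True)
    center, scale = train.norm_center, train.norm_scale
    np.testing.assert_allclose(center, raw_train_imgs.mean(axis=(0, 1)))
    # train is z-scored by its own stats; test uses the same (train) stats
    np.testing.assert_allclose(train.images.mean(axis=(0, 1)), 0.0, atol=1e-12)
    np.testing.assert_allclose(test.norm_center, center)
    assert abs(test.images.mean()) > 1e-6  # not re-centered on itself


def test_temporal_split_rejects_degenerate():
    with pytest.raises(SplitError):
        ff.temporal_split(_dataset(1))
    with pytest.raises(SplitError):
        ff.temporal_split(_dataset(10), 1.5)


def test_kfold_blocks_partition_dataset():
    ds = _dataset(100)
    folds = ff.kfold_split(ds, 5, normalize=False)
    assert len(folds) == 5
    test_times = np.concatenate([te.times for _, te in folds])
    np.testing.assert_array_equal(np.sort(test_times), ds.times)
    for tr, te in folds:
        assert len(te) == 20 and len(tr) == 80
        assert not np.intersect1d(tr.times, te.times).size


def test_kfold_near_equal_blocks_when_uneven():
    folds = ff.kfold_split(_dataset(103), 5, normalize=False)
    sizes = [len(te) for _, te in folds]
    assert max(sizes) - min(sizes) <= 1
    assert sum(sizes) == 103


def test_kfold_too_few_items_errors():
    with pytest.raises(SplitError):
        ff.kfold_split(_dataset(3), 5)


def test_drop_angle_gives_single_information_dataset():
    ds = _dataset(50, channels=13)
    ds.channel_names = list(ff.DEFAULT_CHANNEL_NAMES)
    single = ds.drop_angle()
    assert single.images.shape == (50, 20, 12)
    assert "knee_angle_deg" not in single.channel_names
    assert single.meta["single_information"]


def test_dataset_hdf5_round_trip(tmp_path, small_dataset):
    path = str(tmp_path / "ds.h5")
    ff.save_dataset(small_dataset, path)
    back = ff.load_dataset(path)
    np.testing.assert_array_equal(back.images, small_dataset.images)
    np.testing.assert_array_equal(back.labels, small_dataset.labels)
    assert back.channel_names == small_dataset.channel_names
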