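"""Windowed sEMG features, 13-channel fusion and dataset construction.

From the denoised 1500 Hz sEMG, non-overlapping 30-sample windows (step 30)
yield one feature frame per 50 Hz tick: per channel the mean absolute value

    MAV = (1/N) * sum_i |x_i|

and the mean-centered root-mean-square

    RMS = sqrt( (1/N) * sum_i (x_i - mean(x))^2 )

doubling 6 raw channels into 12 feature channels.  Note the RMS here is the
mean-centered form (a window standard deviation), which is translation-
invariant — ``rms(x + c) == rms(x)``; the classic uncentered RMS is
available via ``centered=False``.

The 12 feature channels are fused with the knee-angle stream into a T x 13
matrix (column order MAV ch1..6, RMS ch1..6, angle), sliced by a length-20,
step-1 sliding window into 20 x 13 feature images.  Each image is labeled
with the gait phase at its *last* row's timestamp.  Splits are temporal
(first 80% train / last 20% test) or contiguous k-fold blocks; per-channel
z-score normalization is fit on the training portion only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, DataError, SplitError
from .phase_labeler import N_PHASES
from .signal_model import MultiChannelSignal

log = logging.getLogger(__name__)

WINDOW_SAMPLES = 30
WINDOW_STEP = 30
IMAGE_LENGTH = 20
IMAGE_STEP = 1
TRAIN_FRAC = 0.8
N_FUSED_CHANNELS = 13


def mav(window: np.ndarray) -> float:
    """Mean absolute value of one feature window."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise DataError("mav: empty window")
    return float(np.mean(np.abs(window)))


def rms_eq2(window: np.ndarray, centered: bool = True) -> float:
    """Root-mean-square feature; mean-centered by default (see module doc)."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise DataError("rms: empty window")
    if centered:
        window = window - window.mean()
    return float(np.sqrt(np.mean(window ** 2)))


@dataclass
class FeatureFrame:
    """One 50 Hz tick's 12 sEMG feature values (MAV ch1..6, RMS ch1..6)."""

    time_s: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (12,):
            raise DataError(f"FeatureFrame needs 12 values, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < -1e-12):
            raise DataError("feature values must be finite and nonnegative")


def extract_features(semg: MultiChannelSignal, win: int = WINDOW_SAMPLES,
                     step: int = WINDOW_STEP, centered_rms: bool = True
                     ) -> list[FeatureFrame]:
    """Sliding-window MAV/RMS features over all sEMG channels.

    Frame ``k`` covers raw samples ``[k*step, k*step + win)`` and carries the
    timestamp of the low-rate tick that owns that block.  With the default
    30/30 windowing at 1500 Hz this is exactly one frame per 50 Hz sample.
    """
    if win < 1 or step < 1:
        raise DataError("win and step must be >= 1")
    n = semg.n_samples
    if n < win:
        warnings.warn(f"only {n} samples (< window {win}); no feature frames",
                      stacklevel=2)
        return []
    n_frames = (n - win) // step + 1
    frames: list[FeatureFrame] = []
    vals = semg.values
    for k in range(n_frames):
        block = vals[k * step: k * step + win]
        mavs = np.mean(np.abs(block), axis=0)
        centered = block - block.mean(axis=0) if centered_rms else block
        rmss = np.sqrt(np.mean(centered ** 2, axis=0))
        t = semg.start_time_s + (k * step) / semg.rate_hz
        frames.append(FeatureFrame(t, np.concatenate([mavs, rmss])))
    return frames


def fuse(frames: list[FeatureFrame], angle: MultiChannelSignal
         ) -> tuple[np.ndarray, np.ndarray]:
    """Stack 12 feature columns with the knee-angle column into T x 13.

    Lengths may differ by at most one (trailing partial block); anything
    larger is an alignment error.  Returns ``(times, matrix)``.
    """
    n_f, n_a = len(frames), angle.n_samples
    if abs(n_f - n_a) > 1:
        raise AlignmentError(
            f"feature stream ({n_f}) and angle stream ({n_a}) lengths differ "
            "by more than 1"
        )
    t = min(n_f, n_a)
    if n_f != n_a:
        log.warning("truncating fused streams to %d rows (features %d, angle %d)",
                    t, n_f, n_a)
    feat = np.stack([f.values for f in frames[:t]])
    fused = np.hstack([feat, angle.values[:t, :1]])
    times = np.array([f.time_s for f in frames[:t]])
    return times, fused


@dataclass
class FeatureDataset:
    """Ordered collection of feature images with labels and provenance.

    ``norm_center``/``norm_scale`` are per-channel z-score statistics; they
    are only set by the split functions, fit on the training portion, and
    the recorded images are already normalized when ``normalized`` is True.
    """

    images: np.ndarray          # (n, length, n_channels)
    labels: np.ndarray          # (n,) phase codes
    times: np.ndarray           # (n,) end-of-image timestamps
    channel_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)
    norm_center: np.ndarray | None = None
    norm_scale: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if self.images.ndim != 3:
            raise DataError("images must be (n, length, channels)")
        if len(self.labels) != len(self.images) or len(self.times) != len(self.images):
            raise DataError("images, labels and times must have equal length")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= N_PHASES):
            raise DataError("labels must be phase codes 0..3")

    def __len__(self) -> int:
        return len(self.images)

    def take(self, idx: np.ndarray) -> "FeatureDataset":
        return FeatureDataset(self.images[idx], self.labels[idx], self.times[idx],
                              list(self.channel_names), dict(self.meta),
                              self.norm_center, self.norm_scale, self.normalized)

    def drop_angle(self) -> "FeatureDataset":
        """Single-information variant: sEMG feature channels only (drops the
        final knee-angle column, 13 -> 12 channels)."""
        names = self.channel_names[:-1] if self.channel_names else []
        return FeatureDataset(
            self.images[:, :, :-1], self.labels, self.times, names,
            {**self.meta, "single_information": True},
            None if self.norm_center is None else self.norm_center[:-1],
            None if self.norm_scale is None else self.norm_scale[:-1],
            self.normalized,
        )


DEFAULT_CHANNEL_NAMES = (
    [f"MAV_{c}" for c in ("VM", "VL", "BF", "ST", "GA", "TA")]
    + [f"RMS_{c}" for c in ("VM", "VL", "BF", "ST", "GA", "TA")]
    + ["knee_angle_deg"]
)


def window_images(fused: np.ndarray, labels: np.ndarray,
                  times: np.ndarray | None = None,
                  length: int = IMAGE_LENGTH, step: int = IMAGE_STEP,
                  channel_names: list[str] | None = None) -> FeatureDataset:
    """Slice the fused T x C matrix into (length x C) feature images.

    Image ``k`` covers rows ``[k*step, k*step + length)`` and is labeled by
    the phase at its last row — the label the classifier must anticipate at
    that instant.
    """
    fused = np.asarray(fused, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    t_total = fused.shape[0]
    if labels.shape[0] != t_total:
        raise DataError(f"labels length {labels.shape[0]} != rows {t_total}")
    if times is None:
        times = np.arange(t_total, dtype=float)
    if t_total < length:
        warnings.warn(f"{t_total} rows < image length {length}; empty dataset",
                      stacklevel=2)
        return FeatureDataset(np.empty((0, length, fused.shape[1])),
                              np.empty(0, dtype=np.int64), np.empty(0))
    n_img = (t_total - length) // step + 1
    idx = np.arange(n_img) * step
    ends = idx + length - 1
    images = np.stack([fused[i: i + length] for i in idx])
    names = channel_names if channel_names is not None else (
        list(DEFAULT_CHANNEL_NAMES) if fused.shape[1] == N_FUSED_CHANNELS else
        [f"ch{j}" for j in range(fused.shape[1])]
    )
    return FeatureDataset(images, labels[ends], np.asarray(times)[ends],
                          list(names),
                          meta={"image_length": length, "image_step": step})


def _fit_norm(images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = images.mean(axis=(0, 1))
    scale = images.std(axis=(0, 1))
    scale = np.where(scale > 1e-12, scale, 1.0)
    return center, scale


def _normalize_pair(train: FeatureDataset, test: FeatureDataset,
                    normalize: bool) -> tuple[FeatureDataset, FeatureDataset]:
    if not normalize:
        return train, test
    center, scale = _fit_norm(train.images)
    for ds in (train, test):
        ds.images = (ds.images - center) / scale
        ds.norm_center, ds.norm_scale = center, scale
        ds.normalized = True
    return train, test


def temporal_split(ds: FeatureDataset, train_frac: float = TRAIN_FRAC,
                   normalize: bool = True) -> tuple[FeatureDataset, FeatureDataset]:
    """Chronological split: first ``train_frac`` of images train, rest test.

    Normalization statistics are fit on the training images only and applied
    to both sides, so no information flows backward from the test period.
    """
    if not 0.0 < train_frac < 1.0:
        raise SplitError("train_frac must be in (0, 1)")
    n = len(ds)
    n_train = int(np.floor(n * train_frac))
    if n < 2 or n_train < 1 or n_train >= n:
        raise SplitError(f"cannot split {n} images at fraction {train_frac}")
    train = ds.take(np.arange(n_train))
    test = ds.take(np.arange(n_train, n))
    return _normalize_pair(train, test, normalize)


def kfold_split(ds: FeatureDataset, k: int = 5, normalize: bool = True
                ) -> list[tuple[FeatureDataset, FeatureDataset]]:
    """Contiguous k-fold split: block i tests, the rest train.

    Blocks are contiguous in time (sizes differing by at most one) rather
    than shuffled — step-1 images overlap heavily, and random folds would
    leak near-duplicates between train and test.
    """
    n = len(ds)
    if k < 2 or n < k:
        raise SplitError(f"cannot make {k} folds from {n} images")
    bounds = np.linspace(0, n, k + 1).astype(int)
    folds = []
    for i in range(k):
        test_idx = np.arange(bounds[i], bounds[i + 1])
        train_idx = np.concatenate([np.arange(0, bounds[i]),
                                    np.arange(bounds[i + 1], n)])
        folds.append(_normalize_pair(ds.take(train_idx), ds.take(test_idx),
                                     normalize))
    return folds


def build_dataset(semg_filtered: MultiChannelSignal, angle: MultiChannelSignal,
                  labels: np.ndarray, win: int = WINDOW_SAMPLES,
                  step: int = WINDOW_STEP, length: int = IMAGE_LENGTH,
                  image_step: int = IMAGE_STEP,
                  single_information: bool = False) -> FeatureDataset:
    """Convenience chain: extract -> fuse -> window, with angle optional."""
    frames = extract_features(semg_filtered, win, step)
    times, fused = fuse(frames, angle)
    labels = np.asarray(labels)[: fused.shape[0]]
    ds = window_images(fused, labels, times, length, image_step)
    return ds.drop_angle() if single_information else ds


def save_dataset(ds: FeatureDataset, path: str) -> None:
    """Persist a dataset to HDF5 (/images, /labels, /times + attributes)."""
    import h5py
    import json

    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=ds.images)
        f.create_dataset("labels", data=ds.labels)
        f.create_dataset("times", data=ds.times)
        f.attrs["channel_names"] = [str(c) for c in ds.channel_names]
        f.attrs["meta_json"] = json.dumps(ds.meta)
        f.attrs["normalized"] = ds.normalized
        if ds.norm_center is not None:
            f.create_dataset("norm_center", data=ds.norm_center)
            f.create_dataset("norm_scale", data=ds.norm_scale)


def load_dataset(path: str) -> FeatureDataset:
    import h5py
    import json

    with h5py.File(path, "r") as f:
        return FeatureDataset(
            f["images"][...], f["labels"][...], f["times"][...],
            [c if isinstance(c, str) else c.decode()
             for c in f.attrs.get("channel_names", [])],
            json.loads(f.attrs.get("meta_json", "{}")),
            f["norm_center"][...] if "norm_center" in f else None,
            f["norm_scale"][...] if "norm_scale" in f else None,
            bool(f.attrs.get("normalized", False)),
        )
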