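"""Core data types for multi-rate, synchronized gait recordings.

A recording bundles three uniformly sampled streams sharing a time origin:
six surface-EMG channels at a high rate (nominally 1500 Hz), one knee-joint
angle channel and six plantar-pressure channels at a low rate (nominally
50 Hz, one A/D clock).  The high rate must be an integer multiple R of the
low rate; low-rate tick ``k`` owns the half-open sEMG sample block
``[R*k, R*(k+1))``, which is what makes the 30-sample / 30-step feature
windowing land exactly on the 50 Hz clock.

On-disk formats: one CSV per rate group (``time_s`` column then channels,
UTF-8, '.' decimal) plus a ``meta.json`` sidecar, or a single HDF5 container
with ``/semg``, ``/angle``, ``/pressure`` datasets carrying ``rate_hz``,
``channel_names`` and ``start_time_s`` attributes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ChannelError, SamplingError

SEMG_CHANNELS = ("VM", "VL", "BF", "ST", "GA", "TA")
PRESSURE_CHANNELS = ("R_heel", "R_sole", "R_toe", "L_heel", "L_sole", "L_toe")
ANGLE_CHANNELS = ("knee_angle_deg",)

#: relative tolerance for timestamp uniformity / declared-rate validation
RATE_TOL = 0.01


@dataclass
class MultiChannelSignal:
    """Uniformly sampled block of named channels.

    Sample ``i`` of every channel is implicitly at
    ``start_time_s + i / rate_hz``.
    """

    channel_names: list[str]
    rate_hz: float
    start_time_s: float
    values: np.ndarray  # (n_samples, n_channels)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SamplingError("values must be a 2-D (n_samples, n_channels) array")
        self.channel_names = list(self.channel_names)
        if self.values.shape[1] != len(self.channel_names):
            raise ChannelError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ChannelError("channel names must be unique")
        if not self.rate_hz > 0:
            raise SamplingError("rate_hz must be positive")
        if not np.all(np.isfinite(self.values)):
            raise SamplingError("values contain non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.rate_hz

    def channel(self, name: str) -> np.ndarray:
        try:
            j = self.channel_names.index(name)
        except ValueError:
            raise ChannelError(f"no channel named {name!r}") from None
        return self.values[:, j]

    def select(self, names: list[str]) -> "MultiChannelSignal":
        """Sub-signal restricted to ``names`` (in the given order)."""
        cols = [self.channel(n) for n in names]
        return MultiChannelSignal(
            list(names), self.rate_hz, self.start_time_s, np.column_stack(cols)
        )

    def with_values(self, values: np.ndarray) -> "MultiChannelSignal":
        return MultiChannelSignal(
            list(self.channel_names), self.rate_hz, self.start_time_s, values
        )


@dataclass
class GaitRecording:
    """One synchronized recording: sEMG + knee angle + plantar pressure."""

    semg: MultiChannelSignal
    angle: MultiChannelSignal
    pressure: MultiChannelSignal
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if abs(self.angle.rate_hz - self.pressure.rate_hz) > RATE_TOL * self.angle.rate_hz:
            raise AlignmentError("angle and pressure must share one A/D rate")
        if abs(self.angle.start_time_s - self.pressure.start_time_s) > 0.5 / self.angle.rate_hz:
            raise AlignmentError("angle and pressure must share a start time")
        ratio = self.semg.rate_hz / self.angle.rate_hz
        r = int(round(ratio))
        if r < 1 or abs(ratio - r) > RATE_TOL:
            raise AlignmentError(
                f"sEMG rate must be an integer multiple of the low rate "
                f"(got ratio {ratio:.4f})"
            )
        unknown = set(self.semg.channel_names) - set(SEMG_CHANNELS)
        if unknown:
            raise ChannelError(f"unknown sEMG channels: {sorted(unknown)}")
        unknown = set(self.pressure.channel_names) - set(PRESSURE_CHANNELS)
        if unknown:
            raise ChannelError(f"unknown pressure channels: {sorted(unknown)}")

    @property
    def ratio(self) -> int:
        """Integer rate ratio R = semg rate / low rate."""
        return int(round(self.semg.rate_hz / self.angle.rate_hz))

    @property
    def n_low_rate(self) -> int:
        return min(self.angle.n_samples, self.pressure.n_samples)


def align_index(rec: GaitRecording, low_rate_index: int) -> tuple[int, int]:
    """sEMG sample block [R*k, R*(k+1)) owned by low-rate tick ``k``.

    The returned half-open ranges tile the sEMG stream: tick k's feature
    frame shares its timestamp.
    """
    if not 0 <= low_rate_index < rec.n_low_rate:
        raise IndexError(
            f"low-rate index {low_rate_index} out of range [0, {rec.n_low_rate})"
        )
    r = rec.ratio
    return r * low_rate_index, r * (low_rate_index + 1)


@dataclass
class CsvLayout:
    """Column/file naming for the CSV-pair on-disk format."""

    semg_file: str = "semg.csv"
    lowrate_file: str = "lowrate.csv"
    meta_file: str = "meta.json"
    time_column: str = "time_s"
    semg_channels: tuple = SEMG_CHANNELS
    angle_channels: tuple = ANGLE_CHANNELS
    pressure_channels: tuple = PRESSURE_CHANNELS
    semg_rate_hz: float | None = None  # optional declared rates, validated at 1%
    lowrate_rate_hz: float | None = None


def _infer_rate(times: np.ndarray, declared: float | None, what: str) -> float:
    if times.size < 2:
        raise SamplingError(f"{what}: need at least 2 samples to infer a rate")
    dt = np.diff(times)
    med = float(np.median(dt))
    if med <= 0:
        raise SamplingError(f"{what}: timestamps not strictly increasing")
    if np.max(np.abs(dt - med)) > RATE_TOL * med:
        raise SamplingError(f"{what}: timestamps not uniform within {RATE_TOL:.0%}")
    rate = 1.0 / med
    if declared is not None and abs(rate - declared) > RATE_TOL * declared:
        raise SamplingError(
            f"{what}: inferred rate {rate:.3f} Hz disagrees with declared "
            f"{declared:.3f} Hz beyond {RATE_TOL:.0%}"
        )
    # snap to the declared (or nearest integer) rate to absorb float jitter
    return declared if declared is not None else float(round(rate, 6))


def _frame_to_signal(
    df: pd.DataFrame, time_col: str, channels: list[str],
    declared_rate: float | None, what: str,
) -> MultiChannelSignal:
    if df.empty:
        raise SamplingError(f"{what}: file is empty")
    missing = [c for c in [time_col, *channels] if c not in df.columns]
    if missing:
        raise ChannelError(f"{what}: missing columns {missing}")
    times = df[time_col].to_numpy(dtype=float)
    rate = _infer_rate(times, declared_rate, what)
    return MultiChannelSignal(
        list(channels), rate, float(times[0]), df[list(channels)].to_numpy(dtype=float)
    )


def read_recording(path: str, layout: CsvLayout | None = None) -> GaitRecording:
    """Load a recording from a CSV-pair directory or an HDF5 container.

    Rates are inferred from timestamps and validated against any declared
    rates within 1%.  Trailing sEMG samples not filling a complete block of
    R are discarded so the block contract always holds.
    """
    layout = layout or CsvLayout()
    if path.endswith((".h5", ".hdf5")):
        return _read_h5(path)
    semg_path = os.path.join(path, layout.semg_file)
    low_path = os.path.join(path, layout.lowrate_file)
    for p in (semg_path, low_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    try:
        semg_df = pd.read_csv(semg_path)
        low_df = pd.read_csv(low_path)
    except pd.errors.EmptyDataError as e:
        raise SamplingError(f"empty CSV under {path}: {e}") from e
    semg = _frame_to_signal(
        semg_df, layout.time_column, list(layout.semg_channels),
        layout.semg_rate_hz, "semg",
    )
    angle = _frame_to_signal(
        low_df, layout.time_column, list(layout.angle_channels),
        layout.lowrate_rate_hz, "angle",
    )
    pressure = _frame_to_signal(
        low_df, layout.time_column, list(layout.pressure_channels),
        layout.lowrate_rate_hz, "pressure",
    )
    meta = {}
    meta_path = os.path.join(path, layout.meta_file)
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = json.load(fh)
    return _assemble(semg, angle, pressure, meta)


def _assemble(semg, angle, pressure, meta) -> GaitRecording:
    rec = GaitRecording(semg, angle, pressure, meta)
    r = rec.ratio
    n_low = rec.n_low_rate
    n_blocks = min(n_low, semg.n_samples // r)
    if semg.n_samples != r * n_blocks:
        rec.semg = semg.with_values(semg.values[: r * n_blocks])
    if angle.n_samples != n_blocks:
        rec.angle = angle.with_values(angle.values[:n_blocks])
    if pressure.n_samples != n_blocks:
        rec.pressure = pressure.with_values(pressure.values[:n_blocks])
    return rec


def write_recording(rec: GaitRecording, path: str, layout: CsvLayout | None = None) -> None:
    """Write a recording as a CSV pair (directory path) or HDF5 (.h5 path).

    Round-trips through :func:`read_recording` reproduce values to at least
    6 significant digits (CSV uses 12 significant digits).
    """
    layout = layout or CsvLayout(
        semg_channels=tuple(rec.semg.channel_names),
        angle_channels=tuple(rec.angle.channel_names),
        pressure_channels=tuple(rec.pressure.channel_names),
    )
    if path.endswith((".h5", ".hdf5")):
        _write_h5(rec, path)
        return
    os.makedirs(path, exist_ok=True)
    semg_df = pd.DataFrame(rec.semg.values, columns=rec.semg.channel_names)
    semg_df.insert(0, layout.time_column, rec.semg.times)
    semg_df.to_csv(os.path.join(path, layout.semg_file), index=False,
                   float_format="%.12g")
    low_df = pd.DataFrame(
        np.hstack([rec.angle.values, rec.pressure.values]),
        columns=rec.angle.channel_names + rec.pressure.channel_names,
    )
    low_df.insert(0, layout.time_column, rec.angle.times)
    low_df.to_csv(os.path.join(path, layout.lowrate_file), index=False,
                  float_format="%.12g")
    with open(os.path.join(path, layout.meta_file), "w") as fh:
        json.dump(rec.meta, fh, indent=1)


def _write_h5(rec: GaitRecording, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for name, sig in (("semg", rec.semg), ("angle", rec.angle),
                          ("pressure", rec.pressure)):
            ds = f.create_dataset(name, data=sig.values)
            ds.attrs["rate_hz"] = sig.rate_hz
            ds.attrs["start_time_s"] = sig.start_time_s
            ds.attrs["channel_names"] = [str(c) for c in sig.channel_names]
        f.attrs["meta_json"] = json.dumps(rec.meta)


def _read_h5(path: str) -> GaitRecording:
    import h5py

    sigs = {}
    with h5py.File(path, "r") as f:
        for name in ("semg", "angle", "pressure"):
            if name not in f:
                raise ChannelError(f"HDF5 container missing /{name}")
            ds = f[name]
            sigs[name] = MultiChannelSignal(
                [c if isinstance(c, str) else c.decode() for c in ds.attrs["channel_names"]],
                float(ds.attrs["rate_hz"]),
                float(ds.attrs["start_time_s"]),
                ds[...],
            )
        meta = json.loads(f.attrs.get("meta_json", "{}"))
    return _assemble(sigs["semg"], sigs["angle"], sigs["pressure"], meta)
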