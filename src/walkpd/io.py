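"""Reading, validation, down-sampling, and windowing of 6-channel inertial recordings.

A recording is one contiguous span of triaxial accelerometer (unit g) and
triaxial gyroscope (unit deg/s) samples with integer epoch-millisecond
timestamps. Files with wear gaps are split into multiple recordings so that
every recording has consistent sample spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

MS_PER_DAY = 86_400_000

#: canonical CSV column order
COLUMNS = ("timestamp", "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class FormatError(ValueError):
    """Input data violates a structural invariant (e.g. non-monotonic time)."""


class UnsupportedRateError(ValueError):
    """Down-sampling factor is not a positive integer."""


@dataclass
class InertialRecording:
    """One contiguous subject recording of 6-channel IMU samples.

    acc and gyro are (3, n) arrays, axis order x, y, z.
    """

    subject_id: str
    sample_rate: float
    timestamps: np.ndarray  # int64 epoch milliseconds, monotone non-decreasing
    acc: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        n = self.timestamps.shape[0]
        if self.sample_rate <= 0:
            raise FormatError("sample_rate must be positive")
        if self.acc.shape != (3, n) or self.gyro.shape != (3, n):
            raise FormatError(
                f"channel shapes {self.acc.shape}/{self.gyro.shape} do not match "
                f"{n} timestamps"
            )
        if n > 1:
            dt = np.diff(self.timestamps)
            if np.any(dt < 0):
                raise FormatError("timestamps must be monotone non-decreasing")
            nominal = 1000.0 / self.sample_rate
            if abs(float(np.median(dt)) - nominal) > 0.01 * nominal:
                raise FormatError(
                    f"median sample spacing {np.median(dt)} ms inconsistent with "
                    f"sample_rate {self.sample_rate} Hz"
                )

    def __len__(self) -> int:
        return self.timestamps.shape[0]

    @property
    def samples(self) -> np.ndarray:
        """(6, n) channel matrix, rows acc x,y,z then gyro x,y,z."""
        return np.vstack([self.acc, self.gyro])


@dataclass
class EventWindow:
    """One non-overlapping fixed-length window cut from a recording."""

    subject_id: str
    day_index: int
    start_time: int  # epoch ms of the first sample
    samples: np.ndarray  # (6, L) — acc x,y,z then gyro x,y,z
    sample_rate: float

    @property
    def acc(self) -> np.ndarray:
        return self.samples[:3]

    @property
    def gyro(self) -> np.ndarray:
        return self.samples[3:]


def read_recording(
    path,
    schema: dict[str, str] | None = None,
    sample_rate: float = 100.0,
    gap_limit_s: float = 1.0,
    subject_id: str | None = None,
) -> list[InertialRecording]:
    """Read a flat CSV of IMU samples, splitting at gaps longer than *gap_limit_s*.

    *schema* maps canonical column names (``timestamp``, ``acc_x``, ...) to the
    file's column names; identity by default. Rows containing NaN are dropped;
    if the dropped run leaves a timestamp gap longer than the limit the
    recording is split there, so NaN runs longer than the gap limit also split.

    Returns a list of recording segments (empty file -> one empty recording).
    """
    schema = schema or {}
    colmap = {c: schema.get(c, c) for c in COLUMNS}
    df = pd.read_csv(path)
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = df[[colmap[c] for c in COLUMNS]]
    df.columns = list(COLUMNS)
    df = df.dropna()
    sid = subject_id if subject_id is not None else _stem(path)

    ts = df["timestamp"].to_numpy(dtype=np.int64)
    data = df[list(COLUMNS[1:])].to_numpy(dtype=float).T  # (6, n)
    if ts.size and np.any(np.diff(ts) < 0):
        raise FormatError(f"{path}: non-monotonic timestamps")

    segments = []
    gap_ms = gap_limit_s * 1000.0
    if ts.size == 0:
        bounds = [(0, 0)]
    else:
        cuts = np.flatnonzero(np.diff(ts) > gap_ms) + 1
        edges = np.concatenate([[0], cuts, [ts.size]])
        bounds = list(zip(edges[:-1], edges[1:]))
    for lo, hi in bounds:
        segments.append(
            InertialRecording(
                subject_id=sid,
                sample_rate=sample_rate,
                timestamps=ts[lo:hi],
                acc=data[:3, lo:hi],
                gyro=data[3:, lo:hi],
            )
        )
    return segments


def write_recording(rec: InertialRecording, path) -> None:
    """Write a recording in the canonical CSV schema."""
    df = pd.DataFrame({"timestamp": rec.timestamps})
    for i, name in enumerate(COLUMNS[1:4]):
        df[name] = rec.acc[i]
    for i, name in enumerate(COLUMNS[4:]):
        df[name] = rec.gyro[i]
    df.to_csv(path, index=False, float_format="%.6g")


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def downsample(rec: InertialRecording, target_rate: float) -> InertialRecording:
    """Anti-alias low-pass then take every k-th sample.

    The filter is a zero-phase FIR (Hamming-window design, cutoff at 0.45 x
    target rate) applied forward-backward, so content above the target Nyquist
    is attenuated far beyond 40 dB. Output length is floor(n / k).
    """
    factor = rec.sample_rate / target_rate
    k = int(round(factor))
    if abs(factor - k) > 1e-9 or k < 1:
        raise UnsupportedRateError(
            f"{rec.sample_rate} Hz -> {target_rate} Hz is not an integer factor"
        )
    if k == 1:
        return replace(rec)
    n = len(rec)
    m = n // k
    if n == 0 or m == 0:
        return InertialRecording(
            rec.subject_id, target_rate, rec.timestamps[:0], rec.acc[:, :0], rec.gyro[:, :0]
        )
    numtaps = min(301, max(31, 2 * (n // 3) - 1))  # shrink for short inputs
    if numtaps % 2 == 0:
        numtaps -= 1
    taps = signal.firwin(numtaps, 0.45 * target_rate, fs=rec.sample_rate)
    data = rec.samples
    if n > 3 * numtaps:
        filtered = signal.filtfilt(taps, [1.0], data, axis=1)
    else:
        filtered = signal.filtfilt(taps, [1.0], data, axis=1, method="gust")
    dec = filtered[:, ::k][:, :m]
    return InertialRecording(
        subject_id=rec.subject_id,
        sample_rate=target_rate,
        timestamps=rec.timestamps[::k][:m],
        acc=dec[:3],
        gyro=dec[3:],
    )


def epoch_day(timestamp_ms: np.ndarray | int, utc_offset_hours: float = 0.0):
    """Calendar-day number of an epoch-ms timestamp at a fixed UTC offset."""
    return (np.asarray(timestamp_ms, dtype=np.int64) + int(utc_offset_hours * 3_600_000)) // MS_PER_DAY


def segment_windows(
    rec: InertialRecording,
    window_seconds: float = 5.0,
    utc_offset_hours: float = 0.0,
    day0: int | None = None,
) -> list[EventWindow]:
    """Cut a recording into consecutive, non-overlapping windows.

    Windows never span a calendar-day boundary; the trailing partial window of
    each day is dropped. *day0* is the epoch-day of the subject's first sample
    (defaults to this recording's first sample) so that day_index is an offset
    from the start of the subject's data.
    """
    L = int(round(rec.sample_rate * window_seconds))
    n = len(rec)
    if n < L:
        return []
    days = epoch_day(rec.timestamps, utc_offset_hours)
    if day0 is None:
        day0 = int(days[0])
    windows: list[EventWindow] = []
    data = rec.samples
    # recordings are gap-free, so each day occupies one contiguous index run
    change = np.flatnonzero(np.diff(days)) + 1
    edges = np.concatenate([[0], change, [n]])
    for lo, hi in zip(edges[:-1], edges[1:]):
        day_index = int(days[lo]) - day0
        for start in range(lo, hi - L + 1, L):
            windows.append(
                EventWindow(
                    subject_id=rec.subject_id,
                    day_index=day_index,
                    start_time=int(rec.timestamps[start]),
                    samples=data[:, start : start + L],
                    sample_rate=rec.sample_rate,
                )
            )
    return windows


def windows_to_array(windows: Sequence[EventWindow]) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack windows into an (N, 6, L) float32 array plus a metadata frame."""
    if not windows:
        return np.zeros((0, 6, 0), dtype=np.float32), pd.DataFrame(
            columns=["subject_id", "day_index", "start_time"]
        )
    X = np.stack([w.samples for w in windows]).astype(np.float32)
    meta = pd.DataFrame(
        {
            "subject_id": [w.subject_id for w in windows],
            "day_index": [w.day_index for w in windows],
            "start_time": [w.start_time for w in windows],
        }
    )
    return X, meta
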