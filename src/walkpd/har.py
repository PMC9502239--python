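"""Rules-based human-activity recognition for 5-s inertial windows.

Each window is annotated as ``static``, ``dynamic_nonwalk`` or ``walk_like``:

1.  A per-subject adaptive amplitude threshold is computed from the first
    recorded day only: half the maximum, over that day's windows, of the
    dominant-axis detrended mean absolute value (MAV).
2.  A window is *dynamic* when its dominant-axis accelerometer MAV strictly
    exceeds the subject's accelerometer threshold.
3.  A dynamic window is *walk-like* when the Welch PSD of its dominant
    gyroscope axis has higher mean power inside the 0.6-2 Hz walking band
    than outside it (DC excluded) and the band mean clears an absolute
    power floor (default 100 (deg/s)^2/Hz).

Detrending (per-window mean subtraction) removes gravity from the
accelerometer and bias from the gyroscope, so amplitudes compare movement,
not orientation. Dominant-axis selection makes the rules insensitive to how
the watch is worn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .io import EventWindow

AXES = ("x", "y", "z")
WALKING_BAND = (0.6, 2.0)
POWER_FLOOR = 100.0  # mean one-sided PSD, (deg/s)^2/Hz
WELCH_SEGMENT_SECONDS = 2.0

Sensor = Literal["acc", "gyro"]


class UsageError(RuntimeError):
    """An operation was called outside its contract (e.g. wrong subject)."""


@dataclass(frozen=True)
class SubjectThresholds:
    """Per-subject adaptive amplitude thresholds from day-1 data only."""

    subject_id: str
    acc_threshold: float  # g
    gyro_threshold: float  # deg/s
    source_day: int = 0


@dataclass(frozen=True)
class SpectralEstimate:
    frequencies: np.ndarray  # Hz, ascending in [0, rate/2]
    psd: np.ndarray  # one-sided density, units^2/Hz


@dataclass(frozen=True)
class ActivityAnnotation:
    label: Literal["static", "dynamic_nonwalk", "walk_like"]
    dominant_acc_axis: str
    dominant_gyro_axis: str
    walking_band_power: float
    rest_band_power: float


def mean_absolute_value(x: Sequence[float] | np.ndarray, detrend: bool = True) -> float:
    """Mean absolute value of a segment, optionally after mean subtraction."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("mean_absolute_value of an empty sequence")
    if detrend:
        x = x - x.mean()
    return float(np.abs(x).mean())


def _sensor_block(window: EventWindow, sensor: Sensor) -> np.ndarray:
    return window.acc if sensor == "acc" else window.gyro


def _axis_mavs(block: np.ndarray) -> np.ndarray:
    """Detrended MAV of each row of a (3, L) block."""
    centred = block - block.mean(axis=1, keepdims=True)
    return np.abs(centred).mean(axis=1)


def dominant_axis(window: EventWindow, sensor: Sensor) -> str:
    """Axis with the highest detrended MAV; ties break toward x < y < z."""
    mavs = _axis_mavs(_sensor_block(window, sensor))
    return AXES[int(np.argmax(mavs))]


def compute_adaptive_threshold(
    day1_windows: Sequence[EventWindow], sensor: Sensor
) -> float:
    """Half the max over day-1 windows of the dominant-axis detrended MAV."""
    if len(day1_windows) == 0:
        raise ValueError("adaptive threshold needs at least one day-1 window")
    peak = max(
        float(_axis_mavs(_sensor_block(w, sensor)).max()) for w in day1_windows
    )
    return 0.5 * peak


def compute_subject_thresholds(
    day1_windows: Sequence[EventWindow],
) -> SubjectThresholds:
    """Both sensor thresholds for one subject (accelerometer gates dynamism;
    the gyroscope threshold is retained for audit)."""
    sid = day1_windows[0].subject_id
    days = {w.day_index for w in day1_windows}
    if len(days) != 1:
        raise UsageError(f"day-1 windows span multiple days: {sorted(days)}")
    return SubjectThresholds(
        subject_id=sid,
        acc_threshold=compute_adaptive_threshold(day1_windows, "acc"),
        gyro_threshold=compute_adaptive_threshold(day1_windows, "gyro"),
        source_day=days.pop(),
    )


def is_dynamic(window: EventWindow, thresholds: SubjectThresholds) -> bool:
    """Dominant-axis accelerometer MAV strictly above the subject threshold."""
    if window.subject_id != thresholds.subject_id:
        raise UsageError(
            f"thresholds for {thresholds.subject_id} applied to {window.subject_id}"
        )
    mav = float(_axis_mavs(window.acc).max())
    return mav > thresholds.acc_threshold


def welch_psd(
    x: np.ndarray,
    rate: float,
    segment_seconds: float = WELCH_SEGMENT_SECONDS,
) -> SpectralEstimate:
    """One-sided Welch PSD: Hann taper, 50% overlap, mean-detrended segments."""
    x = np.asarray(x, dtype=float)
    nperseg = int(round(rate * segment_seconds))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"signal of {x.shape[-1]} samples shorter than one Welch segment ({nperseg})"
        )
    f, p = signal.welch(
        x,
        fs=rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        scaling="density",
    )
    return SpectralEstimate(frequencies=f, psd=p)


def band_vs_rest(
    est: SpectralEstimate, band: tuple[float, float] = WALKING_BAND
) -> tuple[float, float]:
    """Mean PSD inside the band vs mean PSD outside it, excluding the DC bin."""
    f = est.frequencies
    in_band = (f >= band[0]) & (f <= band[1])
    rest = ~in_band & (f > 0)
    return float(est.psd[..., in_band].mean()), float(est.psd[..., rest].mean())


def is_walk_like(
    window: EventWindow,
    band: tuple[float, float] = WALKING_BAND,
    power_floor: float = POWER_FLOOR,
    dynamic: bool = True,
) -> ActivityAnnotation:
    """Classify a dynamic window as walk-like via its dominant-gyro spectrum."""
    if not dynamic:
        raise UsageError("walk-like test called on a static window")
    gyro_mavs = _axis_mavs(window.gyro)
    g_axis = int(np.argmax(gyro_mavs))
    est = welch_psd(window.gyro[g_axis], window.sample_rate)
    band_power, rest_power = band_vs_rest(est, band)
    walk = band_power > rest_power and band_power >= power_floor
    return ActivityAnnotation(
        label="walk_like" if walk else "dynamic_nonwalk",
        dominant_acc_axis=dominant_axis(window, "acc"),
        dominant_gyro_axis=AXES[g_axis],
        walking_band_power=band_power,
        rest_band_power=rest_power,
    )


def annotate_windows(
    windows: Sequence[EventWindow],
    thresholds: SubjectThresholds,
    band: tuple[float, float] = WALKING_BAND,
    power_floor: float = POWER_FLOOR,
) -> pd.DataFrame:
    """Annotate many windows at once (vectorised over the window axis).

    Returns a frame with columns ``subject_id, day_index, start_time, label,
    dom_acc_axis, dom_gyro_axis, band_power, rest_power``.
    """
    n = len(windows)
    if n == 0:
        return pd.DataFrame(
            columns=[
                "subject_id", "day_index", "start_time", "label",
                "dom_acc_axis", "dom_gyro_axis", "band_power", "rest_power",
            ]
        )
    if any(w.subject_id != thresholds.subject_id for w in windows):
        raise UsageError("annotate_windows: subject mismatch with thresholds")
    X = np.stack([w.samples for w in windows])  # (n, 6, L)
    rate = windows[0].sample_rate
    centred = X - X.mean(axis=2, keepdims=True)
    mavs = np.abs(centred).mean(axis=2)  # (n, 6)
    acc_dom = np.argmax(mavs[:, :3], axis=1)
    gyro_dom = np.argmax(mavs[:, 3:], axis=1)
    dynamic = mavs[np.arange(n), acc_dom] > thresholds.acc_threshold

    labels = np.full(n, "static", dtype=object)
    band_power = np.zeros(n)
    rest_power = np.zeros(n)
    dyn_idx = np.flatnonzero(dynamic)
    if dyn_idx.size:
        gyro_sig = X[dyn_idx, 3 + gyro_dom[dyn_idx], :]
        nperseg = int(round(rate * WELCH_SEGMENT_SECONDS))
        f, p = signal.welch(
            gyro_sig,
            fs=rate,
            window="hann",
            nperseg=nperseg,
            noverlap=nperseg // 2,
            detrend="constant",
            axis=-1,
        )
        in_band = (f >= band[0]) & (f <= band[1])
        rest = ~in_band & (f > 0)
        bp = p[:, in_band].mean(axis=1)
        rp = p[:, rest].mean(axis=1)
        band_power[dyn_idx] = bp
        rest_power[dyn_idx] = rp
        walk = (bp > rp) & (bp >= power_floor)
        labels[dyn_idx[walk]] = "walk_like"
        labels[dyn_idx[~walk]] = "dynamic_nonwalk"

    return pd.DataFrame(
        {
            "subject_id": [w.subject_id for w in windows],
            "day_index": [w.day_index for w in windows],
            "start_time": [w.start_time for w in windows],
            "label": labels,
            "dom_acc_axis": [AXES[i] for i in acc_dom],
            "dom_gyro_axis": [AXES[i] for i in gyro_dom],
            "band_power": band_power,
            "rest_power": rest_power,
        }
    )
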