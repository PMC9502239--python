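"""Synthetic free-living IMU cohorts with ground-truth activity labels.

Real multi-day wrist-sensor recordings from PD cohorts are access-restricted,
so this module generates labelled stand-ins that exercise every pipeline
stage: long mostly-static days interleaved with quasi-periodic walk bouts
and broadband non-walk movement bursts.

Signal model per subject-day (at the raw rate, default 100 Hz):

* rest: a constant 1 g gravity vector on a per-subject random orientation
  (slowly wandering) plus white sensor noise;
* non-walk dynamics: 2.5-8 Hz band-limited bursts on accelerometer and
  gyroscope with a smooth on/off envelope;
* walk bouts: a quasi-periodic oscillation (fundamental drawn per subject
  from 0.8-1.8 Hz, plus one 0.4-amplitude harmonic) on a random dominant
  gyroscope orientation, with matched accelerometer modulation; the phase
  advances cycle by cycle, so cycle-time jitter is expressible.

PD effects: walking amplitudes scaled by (1 - amplitude_attenuation), an
added 4-6 Hz tremor tone on both sensors, increased cycle-time jitter, and
a lower walk-bout rate (less daily walking). All effects are tunable and can
be nulled to make the two groups exchangeable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from math import log

import numpy as np
import pandas as pd

from .io import MS_PER_DAY, InertialRecording


@dataclass(frozen=True)
class PDEffects:
    """Effect sizes applied to PD subjects' walking signal."""

    amplitude_attenuation: float = 0.35  # fractional reduction of walk amplitudes
    tremor_band: tuple[float, float] = (4.0, 6.0)  # Hz, inside the 4-9 Hz tremor range
    tremor_amplitude_gyro: float = 60.0  # deg/s (moderate rest tremor)
    tremor_amplitude_acc: float = 0.12  # g
    cycle_time_jitter_sd: float = 0.12  # relative sd of cycle duration

    @classmethod
    def null(cls) -> "PDEffects":
        """No PD effect at all: groups become exchangeable."""
        return cls(0.0, (4.0, 6.0), 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort, bout, and PD-effect parameters (all randomness from *seed*).

    Defaults emulate the study conditions: 100 Hz sampling, ~18 h daily wear,
    and bout rates giving mean daily walking near 5.65 h (HC) and 4.3 h (PD)
    at full wear time. Evaluation runs pass a smaller ``wear_hours_per_day``.
    """

    n_hc: int = 4
    n_pd: int = 7
    day_indices: tuple[int, ...] = tuple(range(10))
    sample_rate: float = 100.0
    wear_hours_per_day: float = 18.0
    walk_bout_rate_hc: float = 16.6  # bouts/h
    walk_bout_rate_pd: float = 12.6  # bouts/h -> ~4.3/5.65 of HC walking time
    bout_duration_log_mu: float = log(60.0)  # lognormal median 60 s
    bout_duration_log_sigma: float = 0.5
    step_frequency_range: tuple[float, float] = (0.8, 1.8)  # Hz, inside 0.6-2
    walk_amplitude_gyro: float = 150.0  # deg/s
    walk_amplitude_acc: float = 0.35  # g
    base_cycle_jitter_sd: float = 0.03
    # within-subject bout-to-bout variability: no two walks are alike, which
    # keeps subject identity from being a trivially learnable fingerprint
    bout_frequency_jitter_sd: float = 0.12  # lognormal sd on the bout's cadence
    bout_amplitude_sigma: float = 0.2  # lognormal sd on the bout's amplitudes
    gait_noise_fraction: float = 0.15  # broadband 0.6-6 Hz component of walking
    nonwalk_rate_per_hour: float = 8.0
    nonwalk_duration_s: float = 20.0
    # bursts stay below walking intensity so the day-1 half-max rule keeps
    # gating on walking (the adaptive threshold's working assumption)
    nonwalk_amplitude_acc: float = 0.25  # g
    nonwalk_amplitude_gyro: float = 60.0  # deg/s
    noise_sd_acc: float = 0.02  # g
    noise_sd_gyro: float = 2.0  # deg/s
    pd_effects: PDEffects = field(default_factory=PDEffects)
    seed: int = 0


REST, NONWALK, WALK = 0, 1, 2
ACTIVITY_NAMES = {REST: "rest", NONWALK: "nonwalk_dynamic", WALK: "walk"}


@dataclass
class SubjectDay:
    """One simulated subject-day: the recording plus per-sample truth labels."""

    recording: InertialRecording
    activity: np.ndarray  # int8 per sample: 0 rest, 1 nonwalk_dynamic, 2 walk
    diagnosis: str  # "HC" | "PD"


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _dominant_direction(rng: np.random.Generator) -> np.ndarray:
    """Random unit vector with one clearly dominant component.

    Wrist arm-swing has a preferred rotation/acceleration axis set by how the
    watch is worn; the dominant weight (0.85-0.98) keeps dominant-axis
    selection meaningful while the residual exercises the other channels.
    """
    axis = int(rng.integers(3))
    w = float(rng.uniform(0.85, 0.98))
    perp = rng.normal(size=3)
    perp[axis] = 0.0
    perp /= np.linalg.norm(perp)
    u = np.sqrt(1.0 - w**2) * perp
    u[axis] = w * (1.0 if rng.integers(2) else -1.0)
    return u


def _subject_rng(cfg: SimulationConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, subject_index)))


def _day_rng(cfg: SimulationConfig, subject_index: int, day: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, subject_index, day)))


@dataclass(frozen=True)
class _SubjectTraits:
    step_frequency: float
    gravity_dir: np.ndarray
    gyro_walk_dir: np.ndarray
    acc_walk_dir: np.ndarray
    tremor_freq: float


def subject_ids(cfg: SimulationConfig) -> list[tuple[str, str]]:
    """(subject_id, diagnosis) pairs, HC first."""
    out = [(f"hc{i:02d}", "HC") for i in range(cfg.n_hc)]
    out += [(f"pd{i:02d}", "PD") for i in range(cfg.n_pd)]
    return out


def _traits(cfg: SimulationConfig, subject_index: int) -> _SubjectTraits:
    rng = _subject_rng(cfg, subject_index)
    lo, hi = cfg.step_frequency_range
    tb_lo, tb_hi = cfg.pd_effects.tremor_band
    return _SubjectTraits(
        step_frequency=float(rng.uniform(lo, hi)),
        gravity_dir=_unit_vector(rng),
        gyro_walk_dir=_dominant_direction(rng),
        acc_walk_dir=_dominant_direction(rng),
        tremor_freq=float(rng.uniform(tb_lo, tb_hi)),
    )


def _renewal_spans(rng, n_samples, rate, rate_per_hour, mean_duration_s, dur_sampler):
    """Alternating gap/bout renewal process -> non-overlapping (start, stop) spans.

    Exponential gaps with mean 3600/rate_per_hour - mean_duration keep the
    realised bout rate and occupied fraction at their configured values.
    """
    if rate_per_hour <= 0:
        return []
    mean_gap = max(3600.0 / rate_per_hour - mean_duration_s, 1.0)
    spans: list[tuple[int, int]] = []
    t = rng.exponential(mean_gap)
    while True:
        d = float(dur_sampler(rng))
        start, stop = int(round(t * rate)), int(round((t + d) * rate))
        if stop >= n_samples:
            break
        if stop > start:
            spans.append((start, stop))
        t += d + rng.exponential(mean_gap)
    return spans


def _walk_phase(rng, n_samples, rate, f0, jitter_sd):
    """Phase with per-cycle duration jitter: 2*pi per completed gait cycle."""
    mean_cycle = 1.0 / f0
    total_s = n_samples / rate
    n_cycles = int(np.ceil(total_s / mean_cycle * 1.5)) + 4
    cyc = mean_cycle * (1.0 + jitter_sd * rng.standard_normal(n_cycles))
    cyc = np.clip(cyc, 0.3 * mean_cycle, 3.0 * mean_cycle)
    edges = np.concatenate([[0.0], np.cumsum(cyc)])
    t = np.arange(n_samples) / rate
    return 2.0 * np.pi * np.interp(t, edges, np.arange(edges.size, dtype=float))


def _wobble(direction: np.ndarray, rng: np.random.Generator, sd: float = 0.08) -> np.ndarray:
    """Small random tilt of a unit direction (bout-to-bout posture change)."""
    v = direction + sd * rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _bandlimited_noise(rng, n, rate, lo=2.5, hi=8.0):
    """Unit-RMS noise confined to [lo, hi] Hz via FFT masking."""
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    spec[(f < lo) | (f > hi)] = 0.0
    y = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def simulate_subject_day(
    cfg: SimulationConfig, subject_index: int, day: int
) -> SubjectDay:
    """Simulate one subject-day deterministically from (seed, subject, day)."""
    sid, diagnosis = subject_ids(cfg)[subject_index]
    traits = _traits(cfg, subject_index)
    rng = _day_rng(cfg, subject_index, day)
    rate = cfg.sample_rate
    n = int(round(cfg.wear_hours_per_day * 3600.0 * rate))
    is_pd = diagnosis == "PD"
    eff = cfg.pd_effects

    acc = cfg.noise_sd_acc * rng.standard_normal((3, n))
    gyro = cfg.noise_sd_gyro * rng.standard_normal((3, n))
    activity = np.zeros(n, dtype=np.int8)

    # gravity: constant orientation with a slow (<0.05 Hz) wander
    wander = 0.05 * np.stack(
        [_bandlimited_noise(rng, n, rate, 0.005, 0.05) for _ in range(3)]
    )
    gdir = traits.gravity_dir[:, None] + wander
    gdir /= np.linalg.norm(gdir, axis=0, keepdims=True)
    acc += gdir

    # walk bouts
    bout_rate = cfg.walk_bout_rate_pd if is_pd else cfg.walk_bout_rate_hc
    mean_bout = float(
        np.exp(cfg.bout_duration_log_mu + 0.5 * cfg.bout_duration_log_sigma**2)
    )
    walk_spans = _renewal_spans(
        rng, n, rate, bout_rate, mean_bout,
        lambda r: np.exp(
            cfg.bout_duration_log_mu + cfg.bout_duration_log_sigma * r.standard_normal()
        ),
    )

    atten = (1.0 - eff.amplitude_attenuation) if is_pd else 1.0
    jitter = cfg.base_cycle_jitter_sd + (eff.cycle_time_jitter_sd if is_pd else 0.0)
    a_gyro = cfg.walk_amplitude_gyro * atten
    a_acc = cfg.walk_amplitude_acc * atten
    lo_f, hi_f = cfg.step_frequency_range
    for start, stop in walk_spans:
        m = stop - start
        # bout-level draws: cadence, amplitude, and lean of the walk direction
        # vary from one walk to the next around the subject's habitual values
        f0 = float(
            np.clip(
                traits.step_frequency
                * np.exp(cfg.bout_frequency_jitter_sd * rng.standard_normal()),
                max(0.6, lo_f - 0.1),
                min(2.0, hi_f + 0.1),
            )
        )
        amp = float(np.exp(cfg.bout_amplitude_sigma * rng.standard_normal()))
        g_dir = _wobble(traits.gyro_walk_dir, rng)
        a_dir = _wobble(traits.acc_walk_dir, rng)
        phase = _walk_phase(rng, m, rate, f0, jitter)
        phi = rng.uniform(0, 2 * np.pi)
        env = np.minimum(1.0, np.minimum(np.arange(m), np.arange(m)[::-1]) / (0.5 * rate))
        osc = np.sin(phase) + 0.4 * np.sin(2.0 * phase + phi)
        if cfg.gait_noise_fraction > 0 and m > 4:
            osc = osc + cfg.gait_noise_fraction * _bandlimited_noise(rng, m, rate, 0.6, 6.0)
        gyro[:, start:stop] += g_dir[:, None] * (a_gyro * amp * env * osc)
        acc_osc = np.sin(phase + phi) + 0.3 * np.sin(2.0 * phase)
        if cfg.gait_noise_fraction > 0 and m > 4:
            acc_osc = acc_osc + cfg.gait_noise_fraction * _bandlimited_noise(rng, m, rate, 0.6, 6.0)
        acc[:, start:stop] += a_dir[:, None] * (a_acc * amp * env * acc_osc)
        if is_pd and (eff.tremor_amplitude_gyro > 0 or eff.tremor_amplitude_acc > 0):
            t = np.arange(m) / rate
            tone = np.sin(2 * np.pi * traits.tremor_freq * t + rng.uniform(0, 2 * np.pi))
            gyro[:, start:stop] += g_dir[:, None] * (eff.tremor_amplitude_gyro * env * tone)
            acc[:, start:stop] += a_dir[:, None] * (eff.tremor_amplitude_acc * env * tone)
        activity[start:stop] = WALK

    # non-walk dynamic bursts; draws landing on a walk bout are dropped
    burst_spans = _renewal_spans(
        rng, n, rate, cfg.nonwalk_rate_per_hour, cfg.nonwalk_duration_s,
        lambda r: cfg.nonwalk_duration_s * np.exp(0.4 * r.standard_normal()),
    )
    for start, stop in burst_spans:
        length = stop - start
        if length < int(rate):
            continue
        if any(s < stop and start < e for s, e in walk_spans):
            continue
        env = np.minimum(1.0, np.minimum(np.arange(length), np.arange(length)[::-1]) / (0.5 * rate))
        for ch in range(3):
            acc[ch, start:stop] += cfg.nonwalk_amplitude_acc * env * _bandlimited_noise(
                rng, length, rate
            ) * rng.uniform(0.5, 1.0)
            gyro[ch, start:stop] += cfg.nonwalk_amplitude_gyro * env * _bandlimited_noise(
                rng, length, rate
            ) * rng.uniform(0.5, 1.0)
        activity[start:stop] = NONWALK

    start_ms = day * MS_PER_DAY + 6 * 3_600_000  # wear starts 06:00
    timestamps = start_ms + np.round(np.arange(n) * (1000.0 / rate)).astype(np.int64)
    rec = InertialRecording(
        subject_id=sid, sample_rate=rate, timestamps=timestamps, acc=acc, gyro=gyro
    )
    return SubjectDay(recording=rec, activity=activity, diagnosis=diagnosis)


def iter_subject_days(cfg: SimulationConfig):
    """Yield (subject_index, subject_id, diagnosis, day, SubjectDay) lazily.

    Day-level generation is independent of iteration order, so partial
    consumption is safe and memory stays bounded by one subject-day.
    """
    for si, (sid, diag) in enumerate(subject_ids(cfg)):
        for day in cfg.day_indices:
            yield si, sid, diag, day, simulate_subject_day(cfg, si, day)


def simulate_cohort(cfg: SimulationConfig) -> tuple[list[SubjectDay], pd.DataFrame]:
    """Materialise the whole cohort (small configs only) plus a subjects table."""
    days = [sd for *_, sd in iter_subject_days(cfg)]
    subjects = pd.DataFrame(subject_ids(cfg), columns=["subject_id", "diagnosis"])
    return days, subjects


def ground_truth_frame(day: SubjectDay) -> pd.DataFrame:
    """Run-length encoded activity labels: subject_id, start_ms, end_ms, activity."""
    act = day.activity
    ts = day.recording.timestamps
    change = np.flatnonzero(np.diff(act)) + 1
    edges = np.concatenate([[0], change, [act.size]])
    rows = [
        (day.recording.subject_id, int(ts[lo]), int(ts[hi - 1]), ACTIVITY_NAMES[int(act[lo])])
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    return pd.DataFrame(rows, columns=["subject_id", "start_ms", "end_ms", "activity"])


def make_fixture(small: bool = True, seed: int = 7) -> SimulationConfig:
    """Configuration for a tiny packaged cohort (2 HC, 2 PD, 2 minutes-long days).

    The fixture runs the full pipeline end-to-end in well under a minute and
    is regenerated deterministically rather than shipped as data.
    """
    return SimulationConfig(
        n_hc=2,
        n_pd=2,
        day_indices=(0, 1),
        wear_hours_per_day=0.1 if small else 0.5,
        seed=seed,
    )


def cohort_checksum(cfg: SimulationConfig) -> str:
    """SHA-256 over all recordings and labels; pins generator determinism."""
    h = hashlib.sha256()
    for _, sid, diag, day, sd in iter_subject_days(cfg):
        h.update(f"{sid}|{diag}|{day}".encode())
        h.update(np.ascontiguousarray(sd.recording.timestamps).tobytes())
        h.update(np.ascontiguousarray(np.round(sd.recording.samples, 12)).tobytes())
        h.update(np.ascontiguousarray(sd.activity).tobytes())
    return h.hexdigest()
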