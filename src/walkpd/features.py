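"""Hand-crafted feature extraction from 5-s walk-like windows.

The 35-element vector used by the comparison classifiers:

* per sensor (acc, gyro): mean, variance, skew, Fisher excess kurtosis of
  each axis (24 features) and the maximum absolute amplitude across the
  three axes (2 features);
* accelerometer band powers per axis for the low (0-4 Hz, DC excluded),
  tremor (4-9 Hz) and high (9 Hz-Nyquist) bands (9 features).

Band powers are computed by mean-detrending, applying a Hann taper, taking
the FFT and summing the squared modulus over the band's bins. Bands are
half-open [lo, hi); the high band includes the Nyquist bin, so the three
bands partition the full non-DC power.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import EventWindow

BANDS = ((0.0, 4.0), (4.0, 9.0), (9.0, None))  # None -> Nyquist, inclusive
_BAND_TAGS = ("low", "tremor", "high")

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{sensor}_{stat}_{ax}"
    for sensor in ("acc", "gyro")
    for stat in ("mean", "var", "skew", "kurt")
    for ax in ("x", "y", "z")
) + ("acc_max", "gyro_max") + tuple(
    f"acc_bp_{tag}_{ax}" for tag in _BAND_TAGS for ax in ("x", "y", "z")
)

N_FEATURES = len(FEATURE_NAMES)  # 35


def _tapered_power_spectrum(x: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann-tapered power spectrum (freqs, |X|^2 per bin).

    x may be (..., n); DC retains the (detrended, hence ~0) mean term.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    w = np.hanning(n)
    xt = (x - x.mean(axis=-1, keepdims=True)) * w
    spec = np.fft.rfft(xt, axis=-1)
    power = np.abs(spec) ** 2
    # fold negative frequencies so the bins sum to total tapered power
    scale = np.full(power.shape[-1], 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    power = power * scale / (n * np.sum(w**2))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    return freqs, power


def band_power_tapered(
    x: np.ndarray, rate: float, lo: float, hi: float | None
) -> float | np.ndarray:
    """Sum of Hann-tapered spectral power over lo <= f < hi.

    ``hi=None`` (or ``hi == rate/2``) closes the band at Nyquist inclusive.
    """
    nyq = rate / 2.0
    hi_val = nyq if hi is None else hi
    if not (0.0 <= lo < hi_val <= nyq + 1e-12):
        raise ValueError(f"invalid band [{lo}, {hi_val}) for rate {rate}")
    freqs, power = _tapered_power_spectrum(x, rate)
    if hi is None or hi_val >= nyq:
        mask = (freqs >= lo) & (freqs <= nyq)
    else:
        mask = (freqs >= lo) & (freqs < hi_val)
    mask &= freqs > 0  # DC never contributes (the mean is its own feature)
    out = power[..., mask].sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def _moments(block: np.ndarray) -> np.ndarray:
    """mean, variance, skew, excess kurtosis per row; degenerate rows -> 0."""
    mean = block.mean(axis=-1)
    c = block - mean[..., None]
    m2 = (c**2).mean(axis=-1)
    m3 = (c**3).mean(axis=-1)
    m4 = (c**4).mean(axis=-1)
    safe = np.where(m2 > 0, m2, 1.0)
    skew = np.where(m2 > 0, m3 / safe**1.5, 0.0)
    kurt = np.where(m2 > 0, m4 / safe**2 - 3.0, 0.0)
    return np.stack([mean, m2, skew, kurt], axis=-2)  # (..., 4, 3)


def extract_feature_matrix(X: np.ndarray, rate: float) -> np.ndarray:
    """Feature matrix (N, 35) for a stack of windows X of shape (N, 6, L)."""
    X = np.asarray(X, dtype=float)
    acc, gyro = X[:, :3, :], X[:, 3:, :]
    cols = []
    for block in (acc, gyro):
        cols.append(_moments(block).reshape(X.shape[0], 12))
    cols.append(np.abs(acc).max(axis=(1, 2))[:, None])
    cols.append(np.abs(gyro).max(axis=(1, 2))[:, None])
    for lo, hi in BANDS:
        cols.append(band_power_tapered(acc, rate, lo, hi))
    out = np.concatenate(cols, axis=1)
    assert out.shape[1] == N_FEATURES
    return out


def extract_features(window: EventWindow) -> pd.Series:
    """Named 35-feature vector for a single window."""
    vec = extract_feature_matrix(window.samples[None, :, :], window.sample_rate)[0]
    return pd.Series(vec, index=list(FEATURE_NAMES))


def feature_frame(X: np.ndarray, meta: pd.DataFrame, rate: float) -> pd.DataFrame:
    """Feature matrix with metadata columns, one row per window."""
    feats = pd.DataFrame(extract_feature_matrix(X, rate), columns=list(FEATURE_NAMES))
    return pd.concat([meta.reset_index(drop=True), feats], axis=1)
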