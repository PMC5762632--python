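"""Time-domain, power-spectral-density, and Morlet-wavelet features.

The 100-sample, 1000 Hz window puts DFT bins exactly on a 10 Hz grid, so
"PSD at 10–200 Hz in 10 Hz intervals" is read directly off a rectangular-
window one-sided periodogram with no interpolation or detrending.  The
angular grid stops at 180 Hz because the gyroscope bandwidth is 184 Hz;
the linear grid stops at 200 Hz to stay clear of undersampled content.

Wavelet features use the analytic Morlet (centre frequency omega0 = 6);
amplitude is the modulus of the complex transform.  No cone-of-influence
masking is applied over the 100 ms window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import periodogram as _scipy_periodogram

from .io import DT_S, FS_HZ, N_SAMPLES
from .preprocess import AnatomicalSignals
from .registry import (ANG_CHANNELS, ANG_FREQS_HZ, BLOCK_SIZES, BLOCKS,
                       FEATURE_NAMES, LIN_CHANNELS, LIN_FREQS_HZ, RegistryError)

MORLET_OMEGA0 = 6.0
#: PyWavelets complex Morlet matching exp(i*omega0*t) * exp(-t^2/2)
_MORLET_WAVELET = f"cmor2.0-{MORLET_OMEGA0 / (2 * math.pi):.12f}"


@dataclass
class Scalogram:
    """Morlet transform amplitude |W(f, t)| on a frequency/time grid."""

    freqs_hz: np.ndarray     # ascending
    times_ms: np.ndarray
    amplitude: np.ndarray    # (n_freq, n_time), >= 0


# ---------------------------------------------------------------------------
# time domain

def fwhm_duration(series: np.ndarray, dt: float = DT_S) -> float:
    """Width of the impulse at half its maximum, in seconds.

    Measured around the global peak with linear sub-sample interpolation of
    the half-max crossings; clamped to the window edge on a side where the
    series never falls below half-max.  An all-zero (or non-positive)
    series has a degenerate duration of 0.
    """
    s = np.asarray(series, dtype=float)
    peak = s.max()
    if peak <= 0:
        return 0.0
    half = peak / 2.0
    ipk = int(np.argmax(s))
    left = 0.0
    for i in range(ipk, -1, -1):
        if s[i] < half:
            left = i + (half - s[i]) / (s[i + 1] - s[i])
            break
    right = float(len(s) - 1)
    for i in range(ipk, len(s)):
        if s[i] < half:
            right = i - (half - s[i]) / (s[i - 1] - s[i])
            break
    return (right - left) * dt


def time_domain_features(sig: AnatomicalSignals) -> dict[str, float]:
    """Peak kinematics and FWHM impulse durations (24 features).

    Directional components score the peak magnitude along the axis
    (max |.|); "change in" velocity per component is max - min over the
    window, while for the vector magnitude it is the max of the magnitude
    series.  FWHM of directional components is measured on |component|.
    """
    out: dict[str, float] = {}
    for quantity, channels, triad, mag in (
        ("peak_lin_acc", LIN_CHANNELS, sig.lin_acc, sig.lin_acc_mag),
        ("delta_lin_vel", LIN_CHANNELS, sig.lin_vel, sig.lin_vel_mag),
        ("peak_ang_acc", ANG_CHANNELS, sig.ang_acc, sig.ang_acc_mag),
        ("delta_ang_vel", ANG_CHANNELS, sig.ang_vel, sig.ang_vel_mag),
    ):
        delta = quantity.startswith("delta")
        for k, ch in enumerate(channels[:3]):
            series = triad[k]
            out[f"td_{quantity}_{ch}"] = float(
                series.max() - series.min() if delta else np.abs(series).max())
        out[f"td_{quantity}_{channels[3]}"] = float(mag.max())
    for name, channels, triad, mag in (
        ("lin_acc", LIN_CHANNELS, sig.lin_acc, sig.lin_acc_mag),
        ("ang_acc", ANG_CHANNELS, sig.ang_acc, sig.ang_acc_mag),
    ):
        for k, ch in enumerate(channels[:3]):
            out[f"td_fwhm_{name}_{ch}"] = fwhm_duration(np.abs(triad[k]), sig.dt)
        out[f"td_fwhm_{name}_{channels[3]}"] = fwhm_duration(mag, sig.dt)
    return out


# ---------------------------------------------------------------------------
# power spectral density

def periodogram_psd(series: np.ndarray, fs: float = FS_HZ):
    """One-sided rectangular-window periodogram of a length-100 series.

    Returns (freqs, psd) with bins exactly at 0, 10, ..., 500 Hz.  The
    window length is part of the method: other lengths are refused rather
    than padded or truncated.  Parseval holds: sum(psd) * 10 Hz equals the
    mean square of the series.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] != N_SAMPLES:
        raise ValueError(
            f"periodogram is defined for length-{N_SAMPLES} windows, "
            f"got {series.shape[-1]}")
    freqs, psd = _scipy_periodogram(series, fs=fs, window="boxcar", detrend=False)
    return freqs, psd


def psd_features(sig: AnatomicalSignals) -> dict[str, float]:
    """PSD amplitudes: linear acceleration at 10–200 Hz, angular at 10–180 Hz."""
    out: dict[str, float] = {}
    for prefix, channels, freq_grid, triad, mag in (
        ("psd_lin_acc", LIN_CHANNELS, LIN_FREQS_HZ, sig.lin_acc, sig.lin_acc_mag),
        ("psd_ang_acc", ANG_CHANNELS, ANG_FREQS_HZ, sig.ang_acc, sig.ang_acc_mag),
    ):
        series_by_ch = [triad[0], triad[1], triad[2], mag]
        for ch, series in zip(channels, series_by_ch):
            freqs, psd = periodogram_psd(series)
            for f in freq_grid:
                out[f"{prefix}_{ch}_{f}hz"] = float(psd[int(f // 10)])
    return out


# ---------------------------------------------------------------------------
# Morlet wavelet

def morlet_scalogram(series: np.ndarray, fs: float = FS_HZ,
                     freqs_hz=None) -> Scalogram:
    """Continuous Morlet transform amplitude on a 10 Hz frequency grid."""
    if freqs_hz is None:
        freqs_hz = np.asarray(LIN_FREQS_HZ, dtype=float)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if np.any(freqs_hz > fs / 2):
        raise ValueError("requested wavelet frequency above Nyquist")
    series = np.asarray(series, dtype=float)
    centre = pywt.central_frequency(_MORLET_WAVELET)
    scales = centre * fs / freqs_hz
    coefs, _ = pywt.cwt(series, scales, _MORLET_WAVELET, sampling_period=1.0 / fs)
    times_ms = np.arange(series.shape[-1]) / fs * 1e3
    return Scalogram(freqs_hz=freqs_hz, times_ms=times_ms,
                     amplitude=np.abs(coefs))


def _channel_series(sig: AnatomicalSignals):
    """(name, channel, series, freq grid) for the 8 wavelet/PSD channels."""
    for prefix, channels, grid, triad, mag in (
        ("lin_acc", LIN_CHANNELS, LIN_FREQS_HZ, sig.lin_acc, sig.lin_acc_mag),
        ("ang_acc", ANG_CHANNELS, ANG_FREQS_HZ, sig.ang_acc, sig.ang_acc_mag),
    ):
        for ch, series in zip(channels, [triad[0], triad[1], triad[2], mag]):
            yield prefix, ch, series, np.asarray(grid, dtype=float)


def wavelet_features(sig: AnatomicalSignals) -> dict[str, float]:
    """Per-frequency time-max amplitudes (152) + per-channel descriptors (32).

    Descriptors: peak scalogram amplitude; its frequency; its timing
    relative to the channel's time-domain peak (seconds); and the 10%
    bandwidth — the distance from the peak frequency up to the first grid
    frequency whose time-max amplitude falls below 10% of the scalogram
    maximum (the full remaining span if it never does).  A zero channel
    yields the degenerate descriptors (0, lowest grid frequency, 0, 0).
    """
    out: dict[str, float] = {}
    for prefix, ch, series, grid in _channel_series(sig):
        scal = morlet_scalogram(series, FS_HZ, grid)
        tmax = scal.amplitude.max(axis=1)          # per-frequency time max
        for f, a in zip(grid, tmax):
            out[f"wt_{prefix}_{ch}_{int(f)}hz"] = float(a)

        base = f"wtd_{prefix}_{ch}"
        peak_amp = float(scal.amplitude.max())
        if peak_amp <= 0:
            out[f"{base}_peak_amp"] = 0.0
            out[f"{base}_peak_freq"] = float(grid[0])
            out[f"{base}_peak_time_offset"] = 0.0
            out[f"{base}_bandwidth10"] = 0.0
            continue
        i_f, i_t = np.unravel_index(int(np.argmax(scal.amplitude)),
                                    scal.amplitude.shape)
        td_peak_t = float(np.argmax(np.abs(series))) / FS_HZ
        out[f"{base}_peak_amp"] = peak_amp
        out[f"{base}_peak_freq"] = float(grid[i_f])
        out[f"{base}_peak_time_offset"] = float(scal.times_ms[i_t]) / 1e3 - td_peak_t
        bw = float(grid[-1] - grid[i_f])
        for j in range(i_f, len(grid)):
            if tmax[j] < 0.1 * peak_amp:
                bw = float(grid[j] - grid[i_f])
                break
        out[f"{base}_bandwidth10"] = bw
    return out


# ---------------------------------------------------------------------------
# assembly

def assemble_feature_vector(time24: dict[str, float], psd152: dict[str, float],
                            wt184: dict[str, float],
                            model51: dict[str, float]) -> "np.ndarray":
    """Assemble the canonical 411-slot vector (as a pandas Series)."""
    import pandas as pd

    wt_grid = {k: v for k, v in wt184.items() if k.startswith("wt_")}
    wt_desc = {k: v for k, v in wt184.items() if k.startswith("wtd_")}
    blocks = {"time_domain": time24, "psd": psd152, "wavelet_grid": wt_grid,
              "wavelet_descriptors": wt_desc, "model": model51}
    merged: dict[str, float] = {}
    for name, block in blocks.items():
        expected = BLOCKS[name]
        if set(block) != set(expected):
            raise RegistryError(
                f"block {name!r} has {len(block)} features, expected "
                f"{BLOCK_SIZES[name]} matching the registry")
        merged.update(block)
    return pd.Series([merged[n] for n in FEATURE_NAMES], index=list(FEATURE_NAMES),
                     dtype=float)
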