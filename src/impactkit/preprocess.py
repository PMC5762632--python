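"""Raw recording -> anatomical-frame kinematic channel set.

Pipeline: rotate device triads to the head anatomical frame (AP = +anterior,
LR = +left, IS = +superior, right-handed), low-pass filter each channel at
its sensor bandwidth with a zero-phase 4th-order Butterworth, integrate
linear acceleration (after g -> m/s^2 conversion) to linear velocity with a
zero initial condition, differentiate angular velocity to angular
acceleration with a five-point stencil, and compute vector magnitudes.

Linear acceleration is deliberately NOT transformed to the head centre of
gravity here: keeping the sensor-point acceleration avoids cross-coupling
linear and angular content in the spectral features.  The head-neck model
(:mod:`impactkit.neck`) performs that transform for its own features.

Gravity is not subtracted: a 10 g-triggered 100 ms window gives no stable
orientation reference to resolve it, and it is small against the trigger
threshold.

The accelerometer bandwidth (500 Hz) coincides with Nyquist at the 1000 Hz
sampling rate, where a Butterworth design is ill-posed; cutoffs at or above
0.99x Nyquist pass the signal through unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .io import DT_S, FS_HZ, GRAVITY, N_SAMPLES, CalibrationError, Recording, SensorCalibration

logger = logging.getLogger(__name__)

_passthrough_logged = False


@dataclass
class AnatomicalSignals:
    """Anatomical-frame channel set every feature block is computed from."""

    lin_acc: np.ndarray   # (3, 100) AP/LR/IS, g
    lin_vel: np.ndarray   # (3, 100) m/s
    ang_vel: np.ndarray   # (3, 100) coronal/sagittal/horizontal, rad/s
    ang_acc: np.ndarray   # (3, 100) rad/s^2
    lin_acc_mag: np.ndarray
    lin_vel_mag: np.ndarray
    ang_vel_mag: np.ndarray
    ang_acc_mag: np.ndarray
    dt: float = DT_S

    @classmethod
    def from_triads(cls, lin_acc: np.ndarray, lin_vel: np.ndarray,
                    ang_vel: np.ndarray, ang_acc: np.ndarray) -> "AnatomicalSignals":
        return cls(
            lin_acc=lin_acc, lin_vel=lin_vel, ang_vel=ang_vel, ang_acc=ang_acc,
            lin_acc_mag=np.linalg.norm(lin_acc, axis=0),
            lin_vel_mag=np.linalg.norm(lin_vel, axis=0),
            ang_vel_mag=np.linalg.norm(ang_vel, axis=0),
            ang_acc_mag=np.linalg.norm(ang_acc, axis=0),
        )


def rotate_to_anatomical(triad: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Apply rotation R to every sample of a (3, N) triad."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or np.linalg.norm(R.T @ R - np.eye(3)) > 1e-8 \
            or np.linalg.det(R) < 0:
        raise CalibrationError("rotation matrix is not orthonormal with det +1")
    return R @ np.asarray(triad, dtype=float)


def lowpass_butterworth(series: np.ndarray, fs: float = FS_HZ,
                        cutoff: float = 184.0, order: int = 4) -> np.ndarray:
    """Zero-phase low-pass Butterworth; passthrough at >= 0.99 Nyquist."""
    global _passthrough_logged
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    series = np.asarray(series, dtype=float)
    if cutoff >= 0.99 * fs / 2.0:
        if not _passthrough_logged:
            logger.info("cutoff %.1f Hz >= 0.99 Nyquist at fs %.0f Hz: passthrough",
                        cutoff, fs)
            _passthrough_logged = True
        return series.copy()
    b, a = butter(order, cutoff, fs=fs)
    return filtfilt(b, a, series)


def cumulative_trapezoid_integral(series: np.ndarray, dt: float = DT_S) -> np.ndarray:
    """Running trapezoid-rule integral with value 0 at the first sample."""
    from scipy.integrate import cumulative_trapezoid
    series = np.asarray(series, dtype=float)
    return cumulative_trapezoid(series, dx=dt, initial=0.0, axis=-1)


def five_point_derivative(series: np.ndarray, dt: float = DT_S) -> np.ndarray:
    """Five-point central-stencil derivative, one-sided near the edges.

    Interior: (-f[i+2] + 8 f[i+1] - 8 f[i-1] + f[i-2]) / (12 h), exact for
    polynomials of degree <= 4.  Indices 1 and N-2 use 4-point one-sided
    differences; the end samples use 2-point forward/backward differences,
    keeping the output the same length as the input with no padding.
    """
    f = np.asarray(series, dtype=float)
    n = f.shape[-1]
    if n < 5:
        raise ValueError(f"five-point stencil needs >= 5 samples, got {n}")
    h = dt
    d = np.empty_like(f)
    d[..., 2:-2] = (-f[..., 4:] + 8 * f[..., 3:-1] - 8 * f[..., 1:-3]
                    + f[..., :-4]) / (12 * h)
    # 4-point one-sided (third-order) at the second and second-to-last samples
    d[..., 1] = (-2 * f[..., 0] - 3 * f[..., 1] + 6 * f[..., 2] - f[..., 3]) / (6 * h)
    d[..., -2] = (f[..., -4] - 6 * f[..., -3] + 3 * f[..., -2] + 2 * f[..., -1]) / (6 * h)
    d[..., 0] = (f[..., 1] - f[..., 0]) / h
    d[..., -1] = (f[..., -1] - f[..., -2]) / h
    return d


def preprocess_recording(rec: Recording,
                         calib: SensorCalibration) -> AnatomicalSignals:
    """rotate -> filter -> integrate/differentiate -> magnitudes."""
    lin_acc = rotate_to_anatomical(rec.lin_acc_device, calib.device_to_anatomical)
    ang_vel = rotate_to_anatomical(rec.ang_vel_device, calib.device_to_anatomical)
    lin_acc = np.stack([lowpass_butterworth(ch, FS_HZ, calib.accel_cutoff)
                        for ch in lin_acc])
    ang_vel = np.stack([lowpass_butterworth(ch, FS_HZ, calib.gyro_cutoff)
                        for ch in ang_vel])
    lin_vel = cumulative_trapezoid_integral(lin_acc * GRAVITY, DT_S)
    ang_acc = five_point_derivative(ang_vel, DT_S)
    assert lin_acc.shape == (3, N_SAMPLES)
    return AnatomicalSignals.from_triads(lin_acc, lin_vel, ang_vel, ang_acc)
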