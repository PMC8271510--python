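"""Two-sensor gyroscope data model and kinematic primitives.

A pass is recorded by two gyroscopes on the throwing arm (wrist and
humerus), each delivering a 3-axis angular-velocity stream at a fixed
sampling rate (128 Hz by default).  The pattern signal used downstream is
the magnitude of the vector sum of the two streams, ``|gyr1 + gyr2|``,
low-pass filtered with a zero-phase 4th-order Butterworth design.

Axis convention (sensor frame, upright standing): X vertical, Y
mediolateral, Z anteroposterior.  Angular velocities are in deg/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sps

from .errors import AlignmentError, ConfigurationError, InputError

DEFAULT_FS = 128.0
DEFAULT_CUTOFF_HZ = 25.0
DEFAULT_FILTER_ORDER = 4

#: relative tolerance for the uniform-spacing check on time stamps
_SPACING_RTOL = 1e-6


@dataclass(frozen=True)
class GyroSample:
    """One gyroscope sample: time (s) and angular velocity (deg/s) per axis."""

    t: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise InputError(f"sample time must be >= 0, got {self.t}")
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise InputError("angular-velocity components must be finite")


@dataclass(frozen=True)
class FilterSettings:
    """Low-pass filter configuration (Butterworth, applied zero-phase)."""

    cutoff_hz: float = DEFAULT_CUTOFF_HZ
    order: int = DEFAULT_FILTER_ORDER


@dataclass
class GyroTrace:
    """One sensor's 3-axis angular-velocity time series at a fixed rate.

    Parameters
    ----------
    sensor_id:
        Label of the sensor, conventionally ``"wrist"`` or ``"humerus"``.
    fs:
        Sampling rate in Hz.
    t:
        Sample times in seconds, uniformly spaced at 1/fs.
    w:
        Angular velocities, shape ``(n, 3)`` in deg/s (x, y, z columns).
    """

    sensor_id: str
    fs: float
    t: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.fs <= 0:
            raise InputError(f"sampling rate must be > 0, got {self.fs}")
        if self.t.ndim != 1 or self.t.size < 1:
            raise InputError("trace needs at least one sample")
        if self.w.shape != (self.t.size, 3):
            raise InputError(
                f"angular-velocity array must be (n, 3); got {self.w.shape}"
            )
        if not np.all(np.isfinite(self.w)) or not np.all(np.isfinite(self.t)):
            raise InputError("trace contains non-finite values")
        if self.t[0] < 0:
            raise InputError("sample times must be >= 0")
        if self.t.size > 1:
            dt = np.diff(self.t)
            expected = 1.0 / self.fs
            if np.any(np.abs(dt - expected) > _SPACING_RTOL * expected + 1e-12):
                raise InputError(
                    "sample times are not uniformly spaced at 1/fs "
                    f"(fs={self.fs} Hz)"
                )

    def __len__(self) -> int:
        return self.t.size

    @classmethod
    def from_arrays(
        cls,
        sensor_id: str,
        w: np.ndarray,
        fs: float = DEFAULT_FS,
        t0: float = 0.0,
    ) -> "GyroTrace":
        """Build a trace from an ``(n, 3)`` array with an implicit time base."""
        w = np.asarray(w, dtype=float)
        t = t0 + np.arange(w.shape[0]) / fs
        return cls(sensor_id=sensor_id, fs=fs, t=t, w=w)

    @property
    def samples(self) -> list[GyroSample]:
        """The trace as a list of :class:`GyroSample` (convenience view)."""
        return [
            GyroSample(float(ti), float(x), float(y), float(z))
            for ti, (x, y, z) in zip(self.t, self.w)
        ]


@dataclass
class SensorPair:
    """The wrist + humerus gyroscope pair for one recording."""

    gyr1: GyroTrace  # wrist
    gyr2: GyroTrace  # humerus

    def __post_init__(self) -> None:
        if len(self.gyr1) != len(self.gyr2):
            raise AlignmentError(
                f"sensor traces differ in length: {len(self.gyr1)} vs {len(self.gyr2)}"
            )
        if abs(self.gyr1.fs - self.gyr2.fs) > _SPACING_RTOL * self.gyr1.fs:
            raise AlignmentError(
                f"sensor traces differ in sampling rate: {self.gyr1.fs} vs {self.gyr2.fs}"
            )
        tol = 1.0 / (2.0 * self.gyr1.fs)
        if np.any(np.abs(self.gyr1.t - self.gyr2.t) > tol):
            raise AlignmentError("sensor sample times misaligned beyond 1/(2 fs)")

    def __len__(self) -> int:
        return len(self.gyr1)

    @property
    def fs(self) -> float:
        return self.gyr1.fs


def resultant_magnitude(s: GyroSample) -> float:
    """Angular speed of one sample: Euclidean norm sqrt(x^2 + y^2 + z^2)."""
    return float(np.sqrt(s.x * s.x + s.y * s.y + s.z * s.z))


def sum_magnitude(s1: GyroSample, s2: GyroSample, *, t_tol: float | None = None) -> float:
    """Magnitude of the componentwise vector sum of two aligned samples.

    Implements ``|gyr1 + gyr2|`` for a single time point: the components are
    added axis by axis and the Euclidean norm of the sum is returned.  The
    two samples must carry (near-)identical time stamps.
    """
    tol = 1e-9 if t_tol is None else t_tol
    if abs(s1.t - s2.t) > tol:
        raise AlignmentError(
            f"samples are not time-aligned: t1={s1.t}, t2={s2.t} (tol {tol})"
        )
    return float(
        np.sqrt((s1.x + s2.x) ** 2 + (s1.y + s2.y) ** 2 + (s1.z + s2.z) ** 2)
    )


def magnitude_series(pair: SensorPair) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample ``|gyr1 + gyr2|`` over a whole recording.

    Returns ``(t, m)`` where ``m[i]`` is the norm of the componentwise sum of
    the wrist and humerus angular-velocity vectors at sample ``i``.
    """
    summed = pair.gyr1.w + pair.gyr2.w
    m = np.linalg.norm(summed, axis=1)
    return pair.gyr1.t.copy(), m


def min_filter_length(order: int = DEFAULT_FILTER_ORDER) -> int:
    """Smallest series length accepted by :func:`lowpass_filter`."""
    return 3 * (order + 1) + 1


def lowpass_filter(
    series: np.ndarray,
    fs: float,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter of a scalar series.

    The filter is the standard biomechanics smoother: an ``order``-th order
    Butterworth design applied forward and backward (``filtfilt``) so that
    no phase lag is introduced and event timing is preserved.  Because of
    the double pass the effective magnitude response is the square of a
    single pass.  Edges are handled by reflective padding of length
    ``3 * (order + 1)``.

    Parameters
    ----------
    series:
        1-D array of values to filter (typically the ``|gyr1+gyr2|`` signal).
    fs:
        Sampling rate in Hz.
    cutoff:
        Cut-off frequency in Hz; must be below the Nyquist rate ``fs/2``.
    order:
        Order of the underlying Butterworth design.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise InputError("series must be one-dimensional")
    if cutoff >= fs / 2.0:
        raise ConfigurationError(
            f"cutoff ({cutoff} Hz) must be below the Nyquist rate ({fs / 2.0} Hz)"
        )
    padlen = 3 * (order + 1)
    if x.size <= padlen:
        raise InputError(
            f"series too short to filter: {x.size} samples <= padding {padlen}"
        )
    b, a = _sps.butter(order, cutoff, btype="low", fs=fs)
    return _sps.filtfilt(b, a, x, padtype="even", padlen=padlen)
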