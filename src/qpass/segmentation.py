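"""Pass-execution windowing and the rectangle-rule pattern integral.

Window boundaries come from annotations (video-derived in the original
protocol): a pass starts when the player receives the ball and ends at
release.  Windows are half-open ``[start_sample, end_sample)`` in 0-based
indices, so ``n = end - start`` exactly and contiguous windows partition.
Filtering is applied to the full recording before slicing, which avoids
per-window edge transients.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import AnnotationError, InputError
from .signal_core import FilterSettings, SensorPair, lowpass_filter, magnitude_series


class PassType(str, enum.Enum):
    """The five passing situations of the modified AAHPERD wall-target test."""

    CHEST = "chest"
    BOUNCE = "bounce"
    CROSSOVER = "crossover"
    BETWEEN_THE_LEG = "between_the_leg"
    BEHIND_THE_BACK = "behind_the_back"

    @classmethod
    def coerce(cls, value: "PassType | str") -> "PassType":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError as exc:
            names = ", ".join(p.value for p in cls)
            raise AnnotationError(
                f"unknown pass type {value!r}; expected one of: {names}"
            ) from exc


PASS_TYPES: tuple[PassType, ...] = tuple(PassType)


@dataclass(frozen=True)
class PassEvent:
    """Annotation of one executed pass.

    ``accuracy`` is either a discrete penalty category in {0, 25, 50, 75,
    100} or ``None`` when ball-impact geometry is supplied separately.
    """

    player_id: str
    group: str
    pass_type: PassType
    target_id: str
    trial_index: int
    start_sample: int
    end_sample: int
    accuracy: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pass_type", PassType.coerce(self.pass_type))
        if self.trial_index < 1:
            raise AnnotationError(f"trial_index must be >= 1, got {self.trial_index}")
        if not (0 <= self.start_sample < self.end_sample):
            raise AnnotationError(
                f"need 0 <= start < end; got [{self.start_sample}, {self.end_sample})"
            )
        if self.accuracy is not None and self.accuracy not in (0, 25, 50, 75, 100):
            raise AnnotationError(
                f"accuracy category must be in {{0,25,50,75,100}}, got {self.accuracy}"
            )

    @property
    def n(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class PassWindow:
    """The filtered ``|gyr1+gyr2|`` values over one pass window."""

    event: PassEvent
    magnitude: np.ndarray
    n: int
    dt: float

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.n != self.event.n or self.magnitude.size != self.n:
            raise InputError("window length inconsistent with its event")
        if self.dt <= 0:
            raise InputError(f"dt must be > 0, got {self.dt}")


def extract_window(
    pair: SensorPair,
    event: PassEvent,
    filt: FilterSettings = FilterSettings(),
) -> PassWindow:
    """Slice one pass window out of a filtered full-recording magnitude series."""
    if event.end_sample > len(pair):
        raise AnnotationError(
            f"event [{event.start_sample}, {event.end_sample}) exceeds trace "
            f"length {len(pair)}"
        )
    _, m = magnitude_series(pair)
    filtered = lowpass_filter(m, pair.fs, cutoff=filt.cutoff_hz, order=filt.order)
    return PassWindow(
        event=event,
        magnitude=filtered[event.start_sample : event.end_sample],
        n=event.n,
        dt=1.0 / pair.fs,
    )


def elapsed_time(n: int, fs: float) -> float:
    """Pass duration in seconds: ``n`` samples at rate ``fs`` give n/fs s."""
    if n < 0:
        raise InputError(f"sample count must be >= 0, got {n}")
    if fs <= 0:
        raise InputError(f"sampling rate must be > 0, got {fs}")
    return n / fs


def integral_approx(window: PassWindow) -> float:
    """Left-endpoint rectangle-rule integral of the window magnitude.

    Returns ``dt * sum(magnitude)`` in degrees — the accumulated angular
    displacement proxy that summarises one pass's movement pattern.  It is
    additive over contiguous sub-windows and homogeneous in the magnitude.
    """
    if window.n == 0 or window.magnitude.size == 0:
        raise InputError("cannot integrate an empty window")
    return float(window.dt * np.sum(window.magnitude))
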