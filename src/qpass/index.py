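"""Quality conversion, weighted Q-Pass index, and modified-mean aggregation.

Penalties measure what went wrong; qualities measure what went right:
``q = 100 - normalized_penalty``.  The Q-Pass index of one execution is
the weighted combination ``x1*q1 + x2*q2 + x3*q3`` with coach-configurable
weights summing to 1, so it lives on the same 0-100 scale and higher is
better.  Repeated executions are summarised per player x pass type with a
modified mean that discards one maximum, one minimum and one median value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AggregationError, ConfigurationError, InputError

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class Weights:
    """Factor weights (accuracy, time, variability); must sum to 1."""

    x1: float = 1.0 / 3.0
    x2: float = 1.0 / 3.0
    x3: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if min(self.x1, self.x2, self.x3) < 0:
            raise ConfigurationError("weights must be non-negative")
        total = self.x1 + self.x2 + self.x3
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise ConfigurationError(f"weights must sum to 1, got {total!r}")

    @classmethod
    def parse(cls, text: str) -> "Weights":
        """Parse ``"0.34,0.33,0.33"`` into a Weights triple."""
        parts = [p.strip() for p in text.split(",")]
        if len(parts) != 3:
            raise ConfigurationError(f"expected three weights, got {text!r}")
        return cls(*(float(p) for p in parts))


@dataclass(frozen=True)
class QPassResult:
    """Per-execution qualities and the combined Q-Pass score."""

    player_id: str
    group: str
    pass_type: str
    target_id: str
    trial_index: int
    q1: float
    q2: float
    q3: float
    index: float


def quality_from_penalty(p: float) -> float:
    """Convert a normalized penalty in [0, 100] to a quality: 100 - p."""
    if not 0.0 <= p <= 100.0:
        raise InputError(f"normalized penalty must be in [0, 100], got {p}")
    return 100.0 - p


def qpass_index(q1: float, q2: float, q3: float, w: Weights) -> float:
    """The Q-Pass score of one execution: x1*q1 + x2*q2 + x3*q3."""
    for q in (q1, q2, q3):
        if not 0.0 <= q <= 100.0:
            raise InputError(f"qualities must be in [0, 100], got {q}")
    return w.x1 * q1 + w.x2 * q2 + w.x3 * q3


def modified_mean(values: Sequence[float] | np.ndarray) -> float:
    """Mean after discarding one maximum, one minimum and one median value.

    Exactly one occurrence of each is removed, located by position in the
    sorted order; for an even-length input the lower of the two middle
    order statistics is taken as the median.  Requires at least 4 values so
    something remains.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 4:
        raise InputError(f"modified mean needs >= 4 values, got {arr.size}")
    s = np.sort(arr)
    keep = np.ones(s.size, dtype=bool)
    keep[[0, (s.size - 1) // 2, s.size - 1]] = False
    return float(s[keep].mean())


def aggregate_scores(
    results: pd.DataFrame | Iterable[QPassResult],
    by: Sequence[str] = ("player_id", "group", "pass_type"),
) -> pd.DataFrame:
    """Modified-mean summary per player x pass type.

    Parameters
    ----------
    results:
        Per-execution scores: a DataFrame with columns ``q1, q2, q3, index``
        plus the grouping keys, or an iterable of :class:`QPassResult`.
    by:
        Grouping keys; the default gives the standard player x pass-type
        table.

    Returns
    -------
    DataFrame with one row per group and columns ``q1, q2, q3, qpass_index,
    n_executions`` (modified means).
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame([r.__dict__ for r in results])
    required = set(by) | {"q1", "q2", "q3", "index"}
    missing = required - set(results.columns)
    if missing:
        raise InputError(f"results table missing columns: {sorted(missing)}")

    undersized = [
        key for key, grp in results.groupby(list(by), sort=True) if len(grp) < 4
    ]
    if undersized:
        raise AggregationError(
            f"groups with fewer than 4 executions cannot be aggregated: {undersized}"
        )

    rows = []
    for key, grp in results.groupby(list(by), sort=True):
        rows.append(
            dict(
                zip(by, key if isinstance(key, tuple) else (key,)),
                q1=modified_mean(grp["q1"].to_numpy()),
                q2=modified_mean(grp["q2"].to_numpy()),
                q3=modified_mean(grp["q3"].to_numpy()),
                qpass_index=modified_mean(grp["index"].to_numpy()),
                n_executions=len(grp),
            )
        )
    return pd.DataFrame(rows)
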