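"""The three penalty factors and their cohort references.

Each executed pass receives three natural-number penalties:

* **f1 — accuracy**: one of {0, 25, 50, 75, 100} according to how much of
  the ball's impact surface lies inside the 0.61 m target square (0 is a
  clean hit not touching any boundary line, 100 is completely outside).
* **f2 — execution time**: ``round(|n - Ex_Tr|)`` in samples, where Ex_Tr
  is the mean duration (in samples) of the quickest pass type in the
  reference (A-level) cohort.
* **f3 — pattern variability**: ``round(|I - ExPT_ir|)`` where I is the
  rectangle-rule integral of the filtered ``|gyr1+gyr2|`` over the pass and
  ExPT_ir the per-pass-type mean of that integral in the reference cohort.

Raw f2/f3 penalties are then normalised to [0, 100] by mapping the maximum
penalty in a pool to 100 (f2 pools across the whole cohort by default, f3
per pass type).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from shapely.geometry import Point, box

from .errors import AnnotationError, GeometryError, InputError, ReferenceGroupError
from .segmentation import PASS_TYPES, PassType, PassWindow
from .signal_core import FilterSettings

ACCURACY_PENALTIES = (0, 25, 50, 75, 100)

#: verbal impact categories -> penalty value
ACCURACY_CATEGORIES: dict[str, int] = {
    "perfect": 0,            # fully inside, no boundary-line contact
    "mostly_inside": 25,     # most of the impact surface inside
    "half": 50,              # about half in, half out
    "mostly_outside": 75,    # most of the impact surface outside
    "outside": 100,          # completely outside the boundary lines
}

# circle discretisation for the overlap scorer; relative area error ~1e-6
_QUAD_SEGS = 256


def round_natural(x: float) -> int:
    """Round a non-negative value to the nearest natural number.

    Half-way cases round away from zero (7.5 -> 8), the plain reading of
    "nearest natural number" without banker's bias.
    """
    if x < 0:
        raise InputError(f"penalty quantities must be >= 0, got {x}")
    return int(math.floor(x + 0.5))


def accuracy_penalty(category: int | str) -> int:
    """Map discrete accuracy evidence to its penalty in {0, 25, 50, 75, 100}.

    Accepts either the penalty value itself (as recorded by a video scorer)
    or one of the verbal categories in :data:`ACCURACY_CATEGORIES`.
    """
    if isinstance(category, str):
        key = category.strip().lower()
        if key in ACCURACY_CATEGORIES:
            return ACCURACY_CATEGORIES[key]
        try:
            category = int(key)
        except ValueError:
            raise AnnotationError(f"unknown accuracy category {category!r}") from None
    if category not in ACCURACY_PENALTIES:
        raise AnnotationError(
            f"accuracy penalty must be one of {ACCURACY_PENALTIES}, got {category}"
        )
    return int(category)


@dataclass(frozen=True)
class BallImpact:
    """Ball-impact geometry on the target plane (metres).

    ``center``/``radius`` describe the ball's impact disc; ``square`` is
    the target square as (lower-left x, lower-left y, side).
    """

    center: tuple[float, float]
    radius: float
    square: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryError(f"ball radius must be > 0, got {self.radius}")
        if self.square[2] <= 0:
            raise GeometryError(f"square side must be > 0, got {self.square[2]}")


def overlap_fraction(impact: BallImpact) -> float:
    """Fraction of the ball's impact disc inside the open square interior."""
    (cx, cy), r = impact.center, impact.radius
    sx, sy, side = impact.square
    circle = Point(cx, cy).buffer(r, quad_segs=_QUAD_SEGS)
    square = box(sx, sy, sx + side, sy + side)
    return float(circle.intersection(square).area / circle.area)


def touches_boundary(impact: BallImpact) -> bool:
    """Whether the impact disc contacts the square's boundary lines."""
    (cx, cy), r = impact.center, impact.radius
    sx, sy, side = impact.square
    strictly_inside = (
        sx + r < cx < sx + side - r and sy + r < cy < sy + side - r
    )
    if strictly_inside:
        return False
    # distance from the centre to the square's boundary ring
    ring = box(sx, sy, sx + side, sy + side).exterior
    return bool(ring.distance(Point(cx, cy)) <= r)


def fraction_to_penalty(frac: float, touches: bool) -> int:
    """Bin an inside-area fraction into the five accuracy penalties.

    A clean full hit (fraction 1, no boundary contact) scores 0; a hit that
    covers the square but touches a boundary line is demoted to 25.  The
    "most of the area" wording is operationalised with bin edges at 1/3 and
    2/3.
    """
    if not 0.0 <= frac <= 1.0:
        raise InputError(f"fraction must be in [0, 1], got {frac}")
    if frac == 0.0:
        return 100
    if frac == 1.0 and not touches:
        return 0
    if frac >= 2.0 / 3.0:
        return 25
    if frac > 1.0 / 3.0:
        return 50
    return 75


def impact_penalty(impact: BallImpact) -> int:
    """Accuracy penalty straight from ball-impact geometry."""
    return fraction_to_penalty(overlap_fraction(impact), touches_boundary(impact))


def _values(windows: Iterable[PassWindow | float], attr: str) -> np.ndarray:
    out = []
    for w in windows:
        if isinstance(w, PassWindow):
            if attr == "n":
                out.append(w.n)
            else:
                from .segmentation import integral_approx

                out.append(integral_approx(w))
        else:
            out.append(float(w))
    return np.asarray(out, dtype=float)


def time_reference(
    windows_by_type: Mapping[PassType | str, Iterable[PassWindow | float]],
) -> int:
    """Reference execution time Ex_Tr in samples.

    The mean duration of each pass type in the reference cohort is taken
    and the smallest of those means — the quickest pass type — becomes the
    reference, rounded to the nearest integer sample count.
    """
    if not windows_by_type:
        raise ReferenceGroupError("reference group has no pass windows")
    means = []
    for pt, windows in windows_by_type.items():
        ns = _values(windows, "n")
        if ns.size == 0:
            raise ReferenceGroupError(f"reference group has no windows for {pt}")
        means.append(float(np.mean(ns)))
    return round_natural(min(means))


def time_penalty_raw(n: int, ex_tr: int) -> int:
    """Raw f2 penalty: |n - Ex_Tr| in samples, rounded to a natural number."""
    if n < 0 or ex_tr < 0:
        raise InputError("sample counts must be >= 0")
    return round_natural(abs(float(n) - float(ex_tr)))


def variability_reference(
    windows_by_type: Mapping[PassType | str, Iterable[PassWindow | float]],
) -> dict[PassType, float]:
    """Per-pass-type references ExPT_ir: mean pattern integral in the cohort."""
    if not windows_by_type:
        raise ReferenceGroupError("reference group has no pass windows")
    out: dict[PassType, float] = {}
    for pt, windows in windows_by_type.items():
        vals = _values(windows, "integral")
        if vals.size == 0:
            raise ReferenceGroupError(f"reference group has no windows for {pt}")
        out[PassType.coerce(pt)] = float(np.mean(vals))
    return out


def variability_penalty_raw(integral: float, expt_ir_value: float) -> int:
    """Raw f3 penalty: |integral - ExPT_ir|, rounded to a natural number."""
    if integral < 0 or expt_ir_value < 0:
        raise InputError("integrals must be >= 0")
    return round_natural(abs(integral - expt_ir_value))


def normalize_penalties(raw: Iterable[float]) -> np.ndarray:
    """Scale raw penalties so the pool maximum maps to exactly 100.

    Order- and ratio-preserving; an all-zero pool (a cohort of perfect
    executions) normalises to all zeros rather than dividing by zero.
    """
    arr = np.asarray(list(raw), dtype=float)
    if arr.size == 0:
        raise InputError("cannot normalize an empty penalty pool")
    if np.any(arr < 0):
        raise InputError("raw penalties must be >= 0")
    top = arr.max()
    if top == 0:
        return np.zeros_like(arr)
    return arr * (100.0 / top)


@dataclass
class CohortReference:
    """Frozen cohort references: Ex_Tr (samples) and ExPT_ir per pass type.

    Serialisable so a reference built from one cohort (typically the
    A-level group) can be reused to score another.
    """

    ex_tr: int
    expt_ir: dict[PassType, float]
    source_group: str
    fs: float
    filter: FilterSettings = FilterSettings()

    def __post_init__(self) -> None:
        self.expt_ir = {PassType.coerce(k): float(v) for k, v in self.expt_ir.items()}
        if self.ex_tr < 0:
            raise InputError(f"ex_tr must be >= 0, got {self.ex_tr}")
        if set(self.expt_ir) != set(PASS_TYPES):
            missing = sorted(p.value for p in set(PASS_TYPES) - set(self.expt_ir))
            raise ReferenceGroupError(f"expt_ir missing pass types: {missing}")
        if any(v < 0 for v in self.expt_ir.values()):
            raise InputError("expt_ir values must be >= 0")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ex_tr_samples": self.ex_tr,
            "expt_ir": {pt.value: self.expt_ir[pt] for pt in PASS_TYPES},
            "source_group": self.source_group,
            "fs": self.fs,
            "filter": {"cutoff_hz": self.filter.cutoff_hz, "order": self.filter.order},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortReference":
        payload = json.loads(Path(path).read_text())
        return cls(
            ex_tr=int(payload["ex_tr_samples"]),
            expt_ir={PassType(k): v for k, v in payload["expt_ir"].items()},
            source_group=payload["source_group"],
            fs=float(payload["fs"]),
            filter=FilterSettings(
                cutoff_hz=float(payload["filter"]["cutoff_hz"]),
                order=int(payload["filter"]["order"]),
            ),
        )
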