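"""Reliability and group-comparison statistics for Q-Pass scores.

Reliability follows the standard-error-of-measurement (SEM) tradition:
SEM is the square root of the mean-square error term of a one-way
repeated-measures ANOVA (subjects x trials), and the coefficient of
variation is CV = SEM / mean x 100.  Group comparisons use the pooled
Student's t with a 95% CI of the mean difference and Hedge's g with the
usual small-sample correction J = 1 - 3/(4N - 9).

No multiplicity correction is applied; p-values are reported raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .errors import IncompleteDesignError, InputError, UndefinedStatisticError

EFFECT_THRESHOLDS = ((0.2, "negligible"), (0.5, "small"), (0.8, "medium"), (1.2, "large"))
#: magnitude >= 1.2
EXTRA_LARGE = "extra-large"

#: significance-marker style used in the report tables
EFFECT_MARKERS = {"negligible": "", "small": "", "medium": "*", "large": "**", EXTRA_LARGE: "***"}


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD and size of one group x pass-type cell."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InputError(f"sd must be >= 0, got {self.sd}")
        if self.n < 2:
            raise InputError(f"n must be >= 2, got {self.n}")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        return cls(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=arr.size)


@dataclass(frozen=True)
class ReliabilityResult:
    """SEM (score units) and CV (percent) for one cell."""

    sem: float
    cv: float


@dataclass(frozen=True)
class EffectResult:
    """Mean difference with 95% CI, p, Hedge's g and its verbal label."""

    mean_diff: float
    ci95: tuple[float, float]
    p: float
    g: float
    interpretation: str

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo <= self.mean_diff <= hi:
            raise InputError("CI does not bracket the mean difference")


def sem_repeated_measures(data: np.ndarray | pd.DataFrame) -> float:
    """SEM from the residual mean square of a subjects x trials ANOVA.

    ``data`` is a complete two-way table with one row per subject and one
    column per trial.  The residual sum of squares after removing subject
    and trial main effects is divided by ``(s-1)(t-1)`` and the square
    root returned.  Adding a constant to everything, or a per-subject
    constant, leaves the result unchanged.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InputError("need a 2-D table with >= 2 subjects and >= 2 trials")
    if not np.all(np.isfinite(x)):
        raise IncompleteDesignError("repeated-measures table has missing cells")
    s, t = x.shape
    grand = x.mean()
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand
    ms_error = np.sum(resid**2) / ((s - 1) * (t - 1))
    return float(np.sqrt(ms_error))


def cv_percent(sem: float, mean: float) -> float:
    """Coefficient of variation in percent: SEM / mean x 100."""
    if mean == 0:
        raise UndefinedStatisticError("CV is undefined for a zero mean")
    return sem / mean * 100.0


def _hedges_correction(n_total: int, exact: bool) -> float:
    if exact:
        from scipy.special import gammaln

        df = n_total - 2
        return float(
            np.exp(gammaln(df / 2) - np.log(np.sqrt(df / 2)) - gammaln((df - 1) / 2))
        )
    return 1.0 - 3.0 / (4.0 * n_total - 9.0)


def hedges_g(a: GroupSummary, b: GroupSummary, *, exact_correction: bool = False) -> float:
    """Hedge's g: small-sample-corrected standardised mean difference.

    ``J * (mean_a - mean_b) / s_pooled`` with the pooled SD over both
    groups and ``J = 1 - 3/(4N - 9)`` (set ``exact_correction`` for the
    gamma-function version of J).
    """
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    if sp2 == 0:
        if a.mean == b.mean:
            return 0.0
        raise UndefinedStatisticError("zero pooled SD with unequal means")
    j = _hedges_correction(a.n + b.n, exact_correction)
    return float(j * (a.mean - b.mean) / np.sqrt(sp2))


def effect_label(g: float) -> str:
    """Verbal interpretation of |g|: negligible/small/medium/large/extra-large."""
    if not np.isfinite(g):
        raise InputError("effect size must be finite")
    mag = abs(g)
    for threshold, label in EFFECT_THRESHOLDS:
        if mag < threshold:
            return label
    return EXTRA_LARGE


def ttest_mean_difference(a: Sequence[float], b: Sequence[float]) -> EffectResult:
    """Pooled-variance Student's t comparison of two samples.

    Returns the mean difference a - b, its 95% CI from the t distribution
    with ``n_a + n_b - 2`` degrees of freedom, the two-sided p-value, and
    Hedge's g (with label) computed from the sample summaries.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise InputError("each sample needs n >= 2")
    na, nb = xa.size, xb.size
    diff = float(xa.mean() - xb.mean())
    df = na + nb - 2
    sp2 = ((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / df
    if sp2 == 0:
        warnings.warn(
            "both samples have zero variance; reporting the exact difference",
            stacklevel=2,
        )
        g = 0.0 if diff == 0 else np.inf
        return EffectResult(
            mean_diff=diff,
            ci95=(diff, diff),
            p=1.0 if diff == 0 else 0.0,
            g=0.0 if diff == 0 else float(np.sign(diff)) * np.inf,
            interpretation=EXTRA_LARGE if diff != 0 else "negligible",
        )
    se = float(np.sqrt(sp2 * (1.0 / na + 1.0 / nb)))
    tcrit = float(_st.t.ppf(0.975, df))
    tstat = diff / se
    p = float(2.0 * _st.t.sf(abs(tstat), df))
    g = hedges_g(GroupSummary.from_values(xa), GroupSummary.from_values(xb))
    return EffectResult(
        mean_diff=diff,
        ci95=(diff - tcrit * se, diff + tcrit * se),
        p=p,
        g=g,
        interpretation=effect_label(g),
    )


def percent_change(a_mean: float, b_mean: float, base: str = "b") -> float:
    """Percent change between group means: (a - b) / base x 100.

    The base group is configurable ("a" or "b"); "X% greater" phrasing
    conventionally uses the lower-scoring group as base.
    """
    if base not in ("a", "b"):
        raise InputError(f"base must be 'a' or 'b', got {base!r}")
    denom = a_mean if base == "a" else b_mean
    if denom == 0:
        raise InputError("percent change undefined for a zero base mean")
    return (a_mean - b_mean) / denom * 100.0


def zscore_outliers(values: Sequence[float], threshold: float = 3.0) -> np.ndarray:
    """Flag values whose |z| against the sample mean/SD exceeds ``threshold``."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise InputError("outlier screen needs n >= 3")
    sd = arr.std(ddof=1)
    if sd == 0:
        warnings.warn("zero SD: no outliers can be flagged", stacklevel=2)
        return np.zeros(arr.size, dtype=bool)
    return np.abs((arr - arr.mean()) / sd) > threshold
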