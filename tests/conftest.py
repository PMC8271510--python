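"""Shared fixtures and independent oracles for the qpass test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qpass import pipeline
from qpass.factors import BallImpact
from qpass.synthetic import SyntheticCohortConfig, generate_cohort

settings.register_profile(
    "qpass",
    deadline=None,
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("qpass")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort (2 players/group, 10 trials/type)."""
    cfg = SyntheticCohortConfig(n_players_per_group=2, trials_per_type=10, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def scored_small(small_cohort):
    """The reduced cohort taken through windows -> reference -> scores."""
    data = small_cohort
    windows = pipeline.compute_windows(data.recordings, data.annotations)
    ref = pipeline.build_reference(windows, "A", data.config.fs)
    scored = pipeline.score_windows(windows, ref)
    return windows, ref, scored


def monte_carlo_overlap(impact: BallImpact, n: int, rng: np.random.Generator) -> float:
    """Monte-Carlo oracle for the circle/open-square overlap fraction.

    Samples ``n`` points uniformly over the impact disc and returns the
    fraction landing strictly inside the square.
    """
    (cx, cy), r = impact.center, impact.radius
    sx, sy, side = impact.square
    radii = r * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    px = cx + radii * np.cos(theta)
    py = cy + radii * np.sin(theta)
    inside = (px > sx) & (px < sx + side) & (py > sy) & (py < sy + side)
    return float(inside.mean())


def modified_mean_oracle(values) -> float:
    """Sort, drop first, last and middle, average the rest."""
    s = sorted(values)
    mid = (len(s) - 1) // 2
    kept = [v for i, v in enumerate(s) if i not in (0, mid, len(s) - 1)]
    return sum(kept) / len(kept)
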