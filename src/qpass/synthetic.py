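"""Seeded synthetic two-sensor gyroscope cohorts emulating the study design.

The generator emits, for each player and pass type, one continuous
recording containing a sequence of pass executions: smooth unimodal
angular-speed bursts (raised-cosine, i.e. Hann-shaped) separated by 1-2 s
of low-noise baseline, split between the wrist and humerus sensors with a
fixed amplitude ratio.  The raised-cosine profile is band-limited well
below the 25 Hz filter cutoff, so filtering is nearly transparent and the
pattern integral has the closed form ``peak * duration / 2``.

Two skill groups are modelled after an experienced (A) vs novice (B)
contrast: A-level players are faster, more accurate and less variable.
Every drawn parameter is recorded in a truth table, and all randomness
flows from one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .segmentation import PASS_TYPES, PassEvent, PassType
from .signal_core import DEFAULT_FS, GyroTrace, SensorPair

TARGETS = ("A", "B", "C", "D", "E")

#: share of the combined angular speed carried by the wrist sensor
WRIST_SHARE = 0.65

#: common unit direction of both sensors' angular-velocity vectors
_DIRECTION = np.array([0.6, 0.7, 0.4]) / np.linalg.norm([0.6, 0.7, 0.4])


@dataclass(frozen=True)
class PassTypeParams:
    """Generative parameters of one pass type for one skill profile.

    duration_mean/_sd in seconds; peak_mean/_sd in deg/s (combined
    two-sensor peak); shape_jitter is the relative amplitude of a
    low-frequency modulation of the burst; accuracy_probs is the
    categorical distribution over penalties (0, 25, 50, 75, 100).
    """

    duration_mean: float
    duration_sd: float
    peak_mean: float
    peak_sd: float
    shape_jitter: float
    accuracy_probs: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if min(self.duration_sd, self.peak_sd, self.shape_jitter) < 0:
            raise ConfigurationError("spread parameters must be >= 0")
        if self.duration_mean <= 0 or self.peak_mean <= 0:
            raise ConfigurationError("duration and peak means must be > 0")
        if abs(sum(self.accuracy_probs) - 1.0) > 1e-9 or min(self.accuracy_probs) < 0:
            raise ConfigurationError("accuracy_probs must be a distribution")


@dataclass(frozen=True)
class PlayerProfile:
    """One synthetic player's per-pass-type generative parameters."""

    player_id: str
    group: str
    pass_types: Mapping[PassType, PassTypeParams]


def _a_level_params() -> dict[PassType, PassTypeParams]:
    # Experienced players: quick, accurate, repeatable.  The chest pass is
    # the quickest type and therefore sets the cohort time reference.
    return {
        PassType.CHEST: PassTypeParams(0.55, 0.04, 750.0, 40.0, 0.05,
                                       (0.70, 0.20, 0.07, 0.03, 0.00)),
        PassType.BOUNCE: PassTypeParams(0.85, 0.05, 850.0, 40.0, 0.05,
                                        (0.55, 0.25, 0.12, 0.06, 0.02)),
        PassType.CROSSOVER: PassTypeParams(0.95, 0.05, 900.0, 45.0, 0.06,
                                           (0.50, 0.27, 0.13, 0.07, 0.03)),
        PassType.BETWEEN_THE_LEG: PassTypeParams(1.05, 0.06, 950.0, 45.0, 0.06,
                                                 (0.50, 0.25, 0.15, 0.07, 0.03)),
        PassType.BEHIND_THE_BACK: PassTypeParams(1.00, 0.06, 980.0, 50.0, 0.06,
                                                 (0.45, 0.28, 0.15, 0.08, 0.04)),
    }


def _b_level_params() -> dict[PassType, PassTypeParams]:
    # Novices: slower (most markedly in the chest pass), weaker peaks,
    # roughly doubled trial-to-trial spread, flatter accuracy distributions.
    return {
        PassType.CHEST: PassTypeParams(0.68, 0.09, 660.0, 70.0, 0.12,
                                       (0.45, 0.28, 0.15, 0.08, 0.04)),
        PassType.BOUNCE: PassTypeParams(0.92, 0.10, 750.0, 70.0, 0.12,
                                        (0.28, 0.27, 0.22, 0.13, 0.10)),
        PassType.CROSSOVER: PassTypeParams(1.03, 0.10, 790.0, 75.0, 0.13,
                                           (0.30, 0.27, 0.20, 0.13, 0.10)),
        PassType.BETWEEN_THE_LEG: PassTypeParams(1.12, 0.11, 840.0, 75.0, 0.13,
                                                 (0.27, 0.28, 0.20, 0.14, 0.11)),
        PassType.BEHIND_THE_BACK: PassTypeParams(1.10, 0.11, 860.0, 80.0, 0.13,
                                                 (0.22, 0.26, 0.22, 0.16, 0.14)),
    }


def default_group_params() -> dict[str, dict[PassType, PassTypeParams]]:
    """The study-design defaults: an A-level and a B-level skill template."""
    return {"A": _a_level_params(), "B": _b_level_params()}


@dataclass
class SyntheticCohortConfig:
    """Design of a synthetic cohort (defaults mirror the study protocol).

    Two groups of 8 players each perform 25 executions (5 targets x 5
    passes) of each of the 5 pass types, recorded at 128 Hz.  Player-level
    heterogeneity multiplies each player's duration and peak means by
    lognormal-like factors with the given relative SDs.
    """

    n_players_per_group: int = 8
    trials_per_type: int = 25
    fs: float = DEFAULT_FS
    seed: int = 0
    noise_sd: float = 2.0
    gap_range: tuple[float, float] = (1.0, 2.0)
    player_duration_var: float = 0.06
    player_peak_var: float = 0.08
    groups: dict[str, dict[PassType, PassTypeParams]] = field(
        default_factory=default_group_params
    )

    def __post_init__(self) -> None:
        if self.trials_per_type < 4:
            raise ConfigurationError("trials_per_type must be >= 4")
        if self.n_players_per_group < 1:
            raise ConfigurationError("n_players_per_group must be >= 1")
        if self.fs <= 0:
            raise ConfigurationError("fs must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not self.groups:
            raise ConfigurationError("at least one group template is required")


@dataclass
class CohortData:
    """An in-memory synthetic cohort: recordings, annotations, ground truth."""

    recordings: dict[tuple[str, PassType], SensorPair]
    annotations: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticCohortConfig


def burst_profile(n: int, peak: float) -> np.ndarray:
    """Raised-cosine angular-speed burst over ``n`` samples.

    Sampled at the left endpoints of the period, so the rectangle-rule
    integral is exactly ``peak * n * dt / 2``.
    """
    i = np.arange(n)
    return peak / 2.0 * (1.0 - np.cos(2.0 * np.pi * i / n))


def generate_pass_trace(
    profile: PlayerProfile,
    pass_type: PassType,
    rng: np.random.Generator,
    fs: float = DEFAULT_FS,
) -> tuple[np.ndarray, dict]:
    """Draw one pass execution: the combined-magnitude burst and its truth.

    Returns the noise-free combined ``|gyr1+gyr2|`` burst (the per-sensor
    split and additive noise are applied when recordings are assembled)
    together with the drawn parameters.
    """
    p = profile.pass_types[pass_type]
    duration = max(0.25, rng.normal(p.duration_mean, p.duration_sd))
    peak = max(100.0, rng.normal(p.peak_mean, p.peak_sd))
    accuracy = int(rng.choice((0, 25, 50, 75, 100), p=p.accuracy_probs))
    n = max(8, int(round(duration * fs)))
    m = burst_profile(n, peak)
    if p.shape_jitter > 0:
        freq = rng.uniform(1.0, 3.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        t = np.arange(n) / fs
        m = m * (1.0 + p.shape_jitter * np.sin(2.0 * np.pi * freq * t + phase))
        m = np.clip(m, 0.0, None)
    else:
        # keep the draw count identical so seeds stay comparable
        rng.uniform(1.0, 3.0)
        rng.uniform(0.0, 2.0 * np.pi)
    truth = {
        "duration_s": duration,
        "n_samples": n,
        "peak_deg_s": peak,
        "accuracy": accuracy,
        "integral_closed_form": peak * n / fs / 2.0,
    }
    return m, truth


def _assemble_recording(
    bursts: list[np.ndarray],
    rng: np.random.Generator,
    fs: float,
    noise_sd: float,
    gap_range: tuple[float, float],
) -> tuple[SensorPair, list[tuple[int, int]]]:
    """Concatenate bursts with baseline gaps into a two-sensor recording."""
    lo, hi = gap_range
    pieces: list[np.ndarray] = []
    spans: list[tuple[int, int]] = []
    cursor = 0
    for m in bursts:
        gap_n = int(round(rng.uniform(lo, hi) * fs))
        pieces.append(np.zeros(gap_n))
        cursor += gap_n
        spans.append((cursor, cursor + m.size))
        pieces.append(m)
        cursor += m.size
    tail = int(round(rng.uniform(lo, hi) * fs))
    pieces.append(np.zeros(tail))
    combined = np.concatenate(pieces)
    total = combined.size

    w1 = np.outer(WRIST_SHARE * combined, _DIRECTION)
    w2 = np.outer((1.0 - WRIST_SHARE) * combined, _DIRECTION)
    if noise_sd > 0:
        w1 = w1 + rng.normal(0.0, noise_sd, size=(total, 3))
        w2 = w2 + rng.normal(0.0, noise_sd, size=(total, 3))
    else:
        rng.normal(0.0, 1.0, size=(total, 3))
        rng.normal(0.0, 1.0, size=(total, 3))
    pair = SensorPair(
        gyr1=GyroTrace.from_arrays("wrist", w1, fs=fs),
        gyr2=GyroTrace.from_arrays("humerus", w2, fs=fs),
    )
    return pair, spans


def _player_profile(
    base: Mapping[PassType, PassTypeParams],
    player_id: str,
    group: str,
    cfg: SyntheticCohortConfig,
    rng: np.random.Generator,
) -> PlayerProfile:
    dur_f = max(0.5, rng.normal(1.0, cfg.player_duration_var))
    peak_f = max(0.5, rng.normal(1.0, cfg.player_peak_var))
    per_type = {
        pt: replace(
            p,
            duration_mean=p.duration_mean * dur_f,
            peak_mean=p.peak_mean * peak_f,
        )
        for pt, p in base.items()
    }
    return PlayerProfile(player_id=player_id, group=group, pass_types=per_type)


def generate_cohort(config: SyntheticCohortConfig) -> CohortData:
    """Generate a full synthetic cohort, deterministic in ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    recordings: dict[tuple[str, PassType], SensorPair] = {}
    ann_rows: list[dict] = []
    truth_rows: list[dict] = []

    for group in sorted(config.groups):
        base = config.groups[group]
        missing = set(PASS_TYPES) - set(base)
        if missing:
            raise ConfigurationError(
                f"group {group!r} template missing pass types: "
                f"{sorted(p.value for p in missing)}"
            )
        for k in range(config.n_players_per_group):
            player_id = f"{group}{k + 1:02d}"
            profile = _player_profile(base, player_id, group, config, rng)
            for pt in PASS_TYPES:
                bursts, truths = [], []
                for trial in range(config.trials_per_type):
                    m, truth = generate_pass_trace(profile, pt, rng, fs=config.fs)
                    bursts.append(m)
                    truths.append(truth)
                pair, spans = _assemble_recording(
                    bursts, rng, config.fs, config.noise_sd, config.gap_range
                )
                recordings[(player_id, pt)] = pair
                # consecutive blocks per target, as in the wall-target protocol
                per_target = -(-config.trials_per_type // len(TARGETS))
                for trial, (truth, (start, end)) in enumerate(zip(truths, spans)):
                    target = TARGETS[trial // per_target]
                    trial_index = trial % per_target + 1
                    ann_rows.append(
                        dict(
                            player_id=player_id,
                            group=group,
                            pass_type=pt.value,
                            target_id=target,
                            trial_index=trial_index,
                            start_sample=start,
                            end_sample=end,
                            accuracy=truth["accuracy"],
                        )
                    )
                    truth_rows.append(
                        dict(
                            player_id=player_id,
                            group=group,
                            pass_type=pt.value,
                            target_id=target,
                            trial_index=trial_index,
                            **truth,
                        )
                    )

    annotations = pd.DataFrame(ann_rows)
    truth = pd.DataFrame(truth_rows)
    # every generated event must satisfy the annotation invariants
    for row in ann_rows:
        PassEvent(**row)
    return CohortData(
        recordings=recordings, annotations=annotations, truth=truth, config=config
    )


def write_cohort(data: CohortData, outdir: str | Path) -> None:
    """Write a cohort to disk in the package's CSV dialects.

    Layout: ``recordings/<player>__<pass_type>.csv`` (combined two-sensor
    gyroscope files), ``annotations.csv``, ``truth.csv`` and
    ``config_used.yaml`` recording the seed and generation parameters.
    """
    from . import io as _io

    outdir = Path(outdir)
    rec_dir = outdir / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    for (player_id, pt), pair in sorted(data.recordings.items(),
                                        key=lambda kv: (kv[0][0], kv[0][1].value)):
        _io.write_sensor_pair_csv(pair, rec_dir / f"{player_id}__{pt.value}.csv")
    data.annotations.to_csv(outdir / "annotations.csv", index=False)
    data.truth.to_csv(outdir / "truth.csv", index=False)
    _io.write_synthetic_config(data.config, outdir / "config_used.yaml")
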