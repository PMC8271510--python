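"""CSV/JSON/YAML readers and writers for recordings, annotations, configs.

Gyroscope CSV dialect: header ``sample,t,gx,gy,gz`` (t in s, g* in deg/s),
either one file per sensor or a combined file with a leading ``sensor_id``
column.  Annotation CSV: ``player_id,group,pass_type,target_id,
trial_index,start_sample,end_sample,accuracy`` with ``accuracy`` an
integer in {0,25,50,75,100} or empty when ball-impact geometry is supplied
in a companion file.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import yaml

from .errors import AnnotationError, InputError
from .segmentation import PassEvent, PassType
from .signal_core import GyroTrace, SensorPair

if TYPE_CHECKING:  # pragma: no cover
    from .factors import BallImpact
    from .synthetic import SyntheticCohortConfig

_GYRO_COLUMNS = ["sample", "t", "gx", "gy", "gz"]
ANNOTATION_COLUMNS = [
    "player_id", "group", "pass_type", "target_id", "trial_index",
    "start_sample", "end_sample", "accuracy",
]
IMPACT_COLUMNS = [
    "player_id", "pass_type", "target_id", "trial_index",
    "ball_x", "ball_y", "ball_r", "sq_x", "sq_y", "sq_side",
]


def _trace_from_frame(df: pd.DataFrame, sensor_id: str, fs: float) -> GyroTrace:
    has_t = "t" in df.columns and df["t"].notna().all()
    if "sample" in df.columns:
        # the sample index is the authoritative time base; a stored t column
        # (possibly rounded on write) must agree with it within half a sample
        t = df["sample"].to_numpy(dtype=float) / fs
        if has_t:
            stored = df["t"].to_numpy(dtype=float)
            if np.any(np.abs(stored - t) > 0.5 / fs):
                raise InputError(
                    f"{sensor_id}: timestamp column inconsistent with sample "
                    "indices beyond 1/(2 fs); refusing to resample"
                )
    elif has_t:
        t = df["t"].to_numpy(dtype=float)
    else:
        raise InputError("gyroscope CSV needs a 't' or 'sample' column")
    w = df[["gx", "gy", "gz"]].to_numpy(dtype=float)
    return GyroTrace(sensor_id=sensor_id, fs=fs, t=t, w=w)


def read_gyro_csv(path: str | Path, fs: float) -> dict[str, GyroTrace]:
    """Read one gyroscope CSV; returns ``{sensor_id: GyroTrace}``.

    A file without a ``sensor_id`` column yields a single entry keyed by
    the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"gx", "gy", "gz"} - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing gyroscope columns {sorted(missing)}")
    if "sensor_id" in df.columns:
        return {
            str(sid): _trace_from_frame(grp.reset_index(drop=True), str(sid), fs)
            for sid, grp in df.groupby("sensor_id", sort=True)
        }
    return {path.stem: _trace_from_frame(df, path.stem, fs)}


def read_sensor_pair_csv(path: str | Path, fs: float) -> SensorPair:
    """Read a combined two-sensor file into a wrist/humerus pair."""
    traces = read_gyro_csv(path, fs)
    try:
        return SensorPair(gyr1=traces["wrist"], gyr2=traces["humerus"])
    except KeyError as exc:
        raise InputError(
            f"{path}: expected sensor_id values 'wrist' and 'humerus', "
            f"found {sorted(traces)}"
        ) from exc


def write_sensor_pair_csv(pair: SensorPair, path: str | Path) -> None:
    """Write a wrist/humerus pair as one combined CSV."""
    frames = []
    for trace in (pair.gyr1, pair.gyr2):
        frames.append(
            pd.DataFrame(
                {
                    "sensor_id": trace.sensor_id,
                    "sample": np.arange(len(trace)),
                    "t": trace.t,
                    "gx": trace.w[:, 0],
                    "gy": trace.w[:, 1],
                    "gz": trace.w[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_recordings_dir(
    directory: str | Path, fs: float
) -> dict[tuple[str, PassType], SensorPair]:
    """Load every ``<player>__<pass_type>.csv`` recording in a directory."""
    directory = Path(directory)
    out: dict[tuple[str, PassType], SensorPair] = {}
    for path in sorted(directory.glob("*.csv")):
        stem = path.stem
        if "__" not in stem:
            raise InputError(
                f"{path}: recording files must be named <player>__<pass_type>.csv"
            )
        player_id, pt_name = stem.split("__", 1)
        out[(player_id, PassType.coerce(pt_name))] = read_sensor_pair_csv(path, fs)
    if not out:
        raise InputError(f"no recording CSVs found in {directory}")
    return out


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read and validate the pass-event annotation table."""
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing annotation columns {sorted(missing)}")
    df = df[ANNOTATION_COLUMNS].copy()
    for _, row in df.iterrows():
        acc = row["accuracy"]
        PassEvent(
            player_id=str(row["player_id"]),
            group=str(row["group"]),
            pass_type=row["pass_type"],
            target_id=str(row["target_id"]),
            trial_index=int(row["trial_index"]),
            start_sample=int(row["start_sample"]),
            end_sample=int(row["end_sample"]),
            accuracy=None if pd.isna(acc) else int(acc),
        )
    dup = df.duplicated(
        subset=["player_id", "pass_type", "target_id", "trial_index"]
    )
    if dup.any():
        raise AnnotationError(
            f"{path}: duplicate (player, pass_type, target, trial) keys at rows "
            f"{list(df.index[dup])}"
        )
    return df


def read_ball_impacts(path: str | Path) -> pd.DataFrame:
    """Read the companion ball-impact geometry table (target-plane metres)."""
    df = pd.read_csv(path)
    missing = set(IMPACT_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing impact columns {sorted(missing)}")
    return df[IMPACT_COLUMNS].copy()


def impact_from_row(row: pd.Series) -> "BallImpact":
    from .factors import BallImpact

    return BallImpact(
        center=(float(row["ball_x"]), float(row["ball_y"])),
        radius=float(row["ball_r"]),
        square=(float(row["sq_x"]), float(row["sq_y"]), float(row["sq_side"])),
    )


def write_synthetic_config(config: "SyntheticCohortConfig", path: str | Path) -> None:
    """Serialise the generator configuration (including the seed) to YAML."""
    def _params_dict(p) -> dict:
        d = dataclasses.asdict(p)
        d["accuracy_probs"] = list(d["accuracy_probs"])
        return d

    payload = {
        f.name: getattr(config, f.name)
        for f in dataclasses.fields(config)
        if f.name != "groups"
    }
    payload["gap_range"] = list(config.gap_range)
    payload["groups"] = {
        group: {pt.value: _params_dict(params) for pt, params in template.items()}
        for group, template in config.groups.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
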