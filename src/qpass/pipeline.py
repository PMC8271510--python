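"""End-to-end orchestration: windows -> references -> penalties -> scores -> report.

This module wires the primitives together in the order the scoring
protocol prescribes:

1. filter each recording's combined ``|gyr1+gyr2|`` magnitude and slice
   the annotated pass windows (duration ``n`` and pattern integral per
   execution);
2. build the cohort references Ex_Tr and ExPT_ir from the reference group
   (A-level by default), or load a frozen reference;
3. assign raw penalties, normalise them (f2 pooled across the cohort by
   default, f3 per pass type), convert to qualities and combine into the
   weighted Q-Pass index;
4. aggregate per player x pass type with the modified mean and produce
   the reliability / group-comparison report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import factors, index as index_mod, stats as stats_mod
from .errors import ReconciliationError, ReferenceGroupError
from .factors import CohortReference
from .index import Weights
from .segmentation import PASS_TYPES, PassEvent, PassType, elapsed_time
from .signal_core import FilterSettings, SensorPair, lowpass_filter, magnitude_series

F2_POOLS = ("cohort", "per_pass_type")


def run_synthetic(
    config,
    weights: Weights = Weights(),
    reference_group: str = "A",
    f2_pool: str = "cohort",
):
    """Generate a synthetic cohort and take it through the full pipeline.

    Returns ``(cohort, reference, scored, aggregated)``.
    """
    from .synthetic import generate_cohort

    data = generate_cohort(config)
    windows = compute_windows(data.recordings, data.annotations)
    ref = build_reference(windows, reference_group, config.fs)
    scored = score_windows(windows, ref, weights, f2_pool)
    return data, ref, scored, aggregate(scored)


def compute_windows(
    recordings: dict[tuple[str, PassType], SensorPair],
    annotations: pd.DataFrame,
    filt: FilterSettings = FilterSettings(),
) -> pd.DataFrame:
    """Per-execution durations and pattern integrals.

    Filters each recording's combined magnitude once, then slices every
    annotated half-open window, returning the annotation table augmented
    with ``n``, ``duration_s`` and ``integral``.
    """
    ann = annotations.copy()
    ann["pass_type"] = ann["pass_type"].map(lambda v: PassType.coerce(v).value)
    keys = set(zip(ann["player_id"].astype(str), ann["pass_type"]))
    rec_keys = {(pid, pt.value) for pid, pt in recordings}
    orphans = sorted(keys - rec_keys)
    if orphans:
        raise ReconciliationError(f"annotations without recordings: {orphans}")

    ns, durations, integrals = [], [], []
    filtered_cache: dict[tuple[str, str], tuple[np.ndarray, float]] = {}
    for (pid, pt_name), grp in ann.groupby(["player_id", "pass_type"], sort=False):
        pair = recordings[(str(pid), PassType(pt_name))]
        _, m = magnitude_series(pair)
        filtered = lowpass_filter(m, pair.fs, cutoff=filt.cutoff_hz, order=filt.order)
        filtered_cache[(str(pid), pt_name)] = (filtered, pair.fs)

    for _, row in ann.iterrows():
        filtered, fs = filtered_cache[(str(row["player_id"]), row["pass_type"])]
        event = PassEvent(
            player_id=str(row["player_id"]),
            group=str(row["group"]),
            pass_type=row["pass_type"],
            target_id=str(row["target_id"]),
            trial_index=int(row["trial_index"]),
            start_sample=int(row["start_sample"]),
            end_sample=int(row["end_sample"]),
            accuracy=None if pd.isna(row["accuracy"]) else int(row["accuracy"]),
        )
        if event.end_sample > filtered.size:
            raise ReconciliationError(
                f"event {event.player_id}/{event.pass_type.value} trial "
                f"{event.trial_index} exceeds its recording"
            )
        window = filtered[event.start_sample : event.end_sample]
        ns.append(event.n)
        durations.append(elapsed_time(event.n, fs))
        integrals.append(float(np.sum(window) / fs))

    ann["n"] = ns
    ann["duration_s"] = durations
    ann["integral"] = integrals
    return ann


def build_reference(
    windows: pd.DataFrame,
    group: str,
    fs: float,
    filt: FilterSettings = FilterSettings(),
) -> CohortReference:
    """Cohort references from one group's windows (Ex_Tr and ExPT_ir)."""
    ref_rows = windows[windows["group"].astype(str) == str(group)]
    if ref_rows.empty:
        raise ReferenceGroupError(f"no windows found for reference group {group!r}")
    present = set(ref_rows["pass_type"])
    missing = sorted(p.value for p in PASS_TYPES if p.value not in present)
    if missing:
        raise ReferenceGroupError(
            f"reference group {group!r} missing pass types: {missing}"
        )
    by_type_n = {
        pt: grp["n"].tolist() for pt, grp in ref_rows.groupby("pass_type")
    }
    by_type_int = {
        pt: grp["integral"].tolist() for pt, grp in ref_rows.groupby("pass_type")
    }
    return CohortReference(
        ex_tr=factors.time_reference(by_type_n),
        expt_ir=factors.variability_reference(by_type_int),
        source_group=str(group),
        fs=fs,
        filter=filt,
    )


def score_windows(
    windows: pd.DataFrame,
    reference: CohortReference,
    weights: Weights = Weights(),
    f2_pool: str = "cohort",
    impacts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Penalties, qualities and the Q-Pass index for every execution.

    ``impacts`` (optional) supplies ball-impact geometry for events whose
    ``accuracy`` cell is empty; the geometric overlap scorer then assigns
    the f1 category.
    """
    if f2_pool not in F2_POOLS:
        raise ReferenceGroupError(f"f2_pool must be one of {F2_POOLS}, got {f2_pool!r}")
    df = windows.copy()

    f1_raw = []
    impact_index = None
    if impacts is not None:
        impact_index = impacts.set_index(
            ["player_id", "pass_type", "target_id", "trial_index"]
        )
    for _, row in df.iterrows():
        if not pd.isna(row["accuracy"]):
            f1_raw.append(factors.accuracy_penalty(int(row["accuracy"])))
            continue
        if impact_index is None:
            raise ReconciliationError(
                f"event {row['player_id']}/{row['pass_type']} trial "
                f"{row['trial_index']} has no accuracy category and no impact table"
            )
        try:
            imp_row = impact_index.loc[
                (row["player_id"], row["pass_type"], row["target_id"],
                 int(row["trial_index"]))
            ]
        except KeyError:
            raise ReconciliationError(
                f"no ball-impact geometry for {row['player_id']}/"
                f"{row['pass_type']} trial {row['trial_index']}"
            ) from None
        from .io import impact_from_row

        f1_raw.append(factors.impact_penalty(impact_from_row(imp_row)))
    df["f1_raw"] = f1_raw

    df["f2_raw"] = [
        factors.time_penalty_raw(int(n), reference.ex_tr) for n in df["n"]
    ]
    df["f3_raw"] = [
        factors.variability_penalty_raw(
            float(i), reference.expt_ir[PassType(pt)]
        )
        for i, pt in zip(df["integral"], df["pass_type"])
    ]

    # f1 is already on the 0-100 scale; f2/f3 are normalised over their pools
    df["f1"] = df["f1_raw"].astype(float)
    if f2_pool == "cohort":
        df["f2"] = factors.normalize_penalties(df["f2_raw"].to_numpy())
    else:
        df["f2"] = (
            df.groupby("pass_type")["f2_raw"]
            .transform(lambda s: factors.normalize_penalties(s.to_numpy()))
        )
    df["f3"] = (
        df.groupby("pass_type")["f3_raw"]
        .transform(lambda s: factors.normalize_penalties(s.to_numpy()))
    )

    df["q1"] = 100.0 - df["f1"]
    df["q2"] = 100.0 - df["f2"]
    df["q3"] = 100.0 - df["f3"]
    df["index"] = weights.x1 * df["q1"] + weights.x2 * df["q2"] + weights.x3 * df["q3"]
    return df


def aggregate(scored: pd.DataFrame) -> pd.DataFrame:
    """Modified-mean player x pass-type score table."""
    return index_mod.aggregate_scores(scored)


def _execution_table(scored: pd.DataFrame, group: str, pass_type: str) -> np.ndarray:
    """Players x trials table of per-execution Q-Pass scores for one cell."""
    cell = scored[
        (scored["group"].astype(str) == group) & (scored["pass_type"] == pass_type)
    ].copy()
    cell["trial"] = cell.groupby("player_id").cumcount()
    table = cell.pivot(index="player_id", columns="trial", values="index")
    return table.to_numpy()


def compare_groups(
    scored: pd.DataFrame,
    aggregated: pd.DataFrame,
    group_a: str | None = None,
    group_b: str | None = None,
) -> pd.DataFrame:
    """Per-pass-type reliability and group-comparison report.

    One row per group x pass type with the group's mean/SD/n of
    player-level Q-Pass scores, SEM and CV from the per-execution
    repeated-measures table, and (on the first group's row) the between-
    group mean difference with 95% CI, p, Hedge's g and its label.
    With a single group only the reliability columns are filled.
    """
    groups = sorted(aggregated["group"].astype(str).unique())
    if group_a is None:
        group_a = groups[0]
    if group_b is None and len(groups) > 1:
        group_b = groups[1]

    rows = []
    for pt in PASS_TYPES:
        per_group: dict[str, np.ndarray] = {}
        for g in groups:
            sel = aggregated[
                (aggregated["group"].astype(str) == g)
                & (aggregated["pass_type"] == pt.value)
            ]
            per_group[g] = sel["qpass_index"].to_numpy()

        effect = None
        if group_b is not None and per_group.get(group_a) is not None:
            a_vals, b_vals = per_group[group_a], per_group[group_b]
            if a_vals.size >= 2 and b_vals.size >= 2:
                effect = stats_mod.ttest_mean_difference(a_vals, b_vals)

        for g in groups:
            vals = per_group[g]
            if vals.size == 0:
                continue
            table = _execution_table(scored, g, pt.value)
            sem = stats_mod.sem_repeated_measures(table)
            mean = float(vals.mean())
            row = {
                "pass_type": pt.value,
                "group": g,
                "mean": mean,
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
                "sem": sem,
                "cv_pct": stats_mod.cv_percent(sem, mean),
                "mean_diff": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": np.nan,
                "hedges_g": np.nan,
                "label": "",
            }
            if effect is not None and g == group_a:
                row.update(
                    mean_diff=effect.mean_diff,
                    ci_low=effect.ci95[0],
                    ci_high=effect.ci95[1],
                    p=effect.p,
                    hedges_g=effect.g,
                    label=effect.interpretation,
                )
            rows.append(row)
    return pd.DataFrame(rows)
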