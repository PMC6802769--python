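"""Latency-to-first-saccade and fixation-duration analyses.

Latency is the time from stimulus onset to the onset of the first saccade
leaving the pre-stimulus start position.  Fixation-report tables cannot
express this exactly, so the ``saccade_onset_ms`` column is used when
present; otherwise it is approximated as the ordinal-1 fixation start minus
a configured mean saccade transit time.

Duration analyses use only *uninterrupted* fixations: a fixation is kept iff
it ends no later than both the stimulus presentation window and the
response (test trials terminate on response).  Excluded fractions are
reported per (phase x presentation time) cell.

Participant-level outliers (|value - group median| > 2.5 group SD within a
condition) are flagged in a single pass; the SD is the conventional
mean-centred standard deviation over participants.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import Dataset

__all__ = [
    "experience_category",
    "trial_latencies",
    "latency_table",
    "exclude_outlier_participants",
    "filter_uninterrupted",
    "latency_by_trial_series",
    "duration_by_condition",
]

DEFAULT_TRANSIT_MS = 30.0


def experience_category(trials: pd.DataFrame) -> pd.Series:
    """'study', 'test-old' or 'test-new' per trial row."""
    cat = np.where(
        trials["phase"] == "study",
        "study",
        np.where(trials["exposure"] == "old", "test-old", "test-new"),
    )
    return pd.Series(cat, index=trials.index)


def trial_latencies(
    fixations: pd.DataFrame, transit_ms: float = DEFAULT_TRANSIT_MS
) -> pd.Series:
    """First-saccade latency per trial_id (NaN for trials without an
    ordinal-1 fixation)."""
    first = fixations[fixations["ordinal"] == 1]
    if "saccade_onset_ms" in first.columns:
        lat = first["saccade_onset_ms"].where(
            first["saccade_onset_ms"].notna(), first["start_ms"] - transit_ms
        )
    else:
        lat = first["start_ms"] - transit_ms
    return pd.Series(lat.to_numpy(dtype=float), index=pd.Index(first["trial_id"], name="trial_id"))


def latency_table(ds: Dataset, transit_ms: float = DEFAULT_TRANSIT_MS) -> pd.DataFrame:
    """Median first-saccade latency per participant x stimulus-experience
    category x presentation time."""
    lat = trial_latencies(ds.fixations, transit_ms)
    trials = ds.trials.copy()
    trials["latency_ms"] = trials["trial_id"].map(lat)
    trials["experience"] = experience_category(trials)
    out = (
        trials.dropna(subset=["latency_ms"])
        .groupby(["participant_id", "experience", "presentation_s"])["latency_ms"]
        .median()
        .rename("median_latency_ms")
        .reset_index()
    )
    return out


def exclude_outlier_participants(values: pd.DataFrame) -> tuple[set, pd.DataFrame]:
    """Single-pass outlier screen on a participants x conditions table.

    A participant is flagged for each condition where the value lies more
    than 2.5 group standard deviations from the group *median* of that
    condition.  Returns (participants clean in every condition, flags with
    columns participant_id/condition/value).  With fewer than 3 participants
    the rule is skipped with a warning.
    """
    if len(values) < 3:
        warnings.warn("outlier screening skipped: fewer than 3 participants", stacklevel=2)
        return set(values.index), pd.DataFrame(columns=["participant_id", "condition", "value"])
    flags = []
    for col in values.columns:
        v = values[col].dropna()
        med = v.median()
        sd = v.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            continue
        out = v[(v - med).abs() > 2.5 * sd]
        for pid, val in out.items():
            flags.append({"participant_id": pid, "condition": col, "value": val})
    flags_df = pd.DataFrame(flags, columns=["participant_id", "condition", "value"])
    kept = set(values.index) - set(flags_df["participant_id"])
    return kept, flags_df


def filter_uninterrupted(
    fixations: pd.DataFrame, trials: pd.DataFrame, ordinal: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep fixations ending within min(presentation window, response time).

    Returns (kept fixations, exclusion table per phase x presentation time
    with the excluded fraction).  ``ordinal`` restricts the bookkeeping to
    one ordinal position (the duration analyses use ordinal 2).
    """
    fx = fixations if ordinal is None else fixations[fixations["ordinal"] == ordinal]
    meta = trials.set_index("trial_id")[["phase", "presentation_s", "rt_ms"]]
    joined = fx.join(meta, on="trial_id")
    window = joined["presentation_s"].astype(float) * 1000.0
    rt = joined["rt_ms"].astype(float)
    limit = np.fmin(window, rt.fillna(np.inf))
    keep = joined["end_ms"] <= limit
    kept = fx[keep.to_numpy()]
    stats = (
        pd.DataFrame(
            {
                "phase": joined["phase"],
                "presentation_s": joined["presentation_s"],
                "excluded": ~keep,
            }
        )
        .groupby(["phase", "presentation_s"])
        .agg(n_total=("excluded", "size"), n_excluded=("excluded", "sum"))
        .reset_index()
    )
    stats["fraction_excluded"] = stats["n_excluded"] / stats["n_total"]
    return kept, stats


def latency_by_trial_series(
    ds: Dataset, transit_ms: float = DEFAULT_TRANSIT_MS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-mean first-saccade latency per trial position, plus block
    means/SEs with each block's first trial excluded (first trials carry a
    task-(re)engagement cost and would bias the block level).

    Returns (per-trial series, per-block summary).
    """
    lat = trial_latencies(ds.fixations, transit_ms)
    trials = ds.trials.copy()
    trials["latency_ms"] = trials["trial_id"].map(lat)
    per_trial = (
        trials.groupby("trial_index")
        .agg(
            mean_latency_ms=("latency_ms", "mean"),
            se_ms=("latency_ms", lambda v: v.std(ddof=1) / np.sqrt(v.notna().sum())),
            block_index=("block_index", "first"),
            phase=("phase", "first"),
        )
        .reset_index()
    )
    first_of_block = per_trial.groupby("block_index")["trial_index"].transform("min")
    per_trial["is_block_first"] = per_trial["trial_index"] == first_of_block
    retained = per_trial[~per_trial["is_block_first"]]
    blocks = (
        retained.groupby("block_index")
        .agg(
            phase=("phase", "first"),
            mean_latency_ms=("mean_latency_ms", "mean"),
            se_ms=("mean_latency_ms", lambda v: v.std(ddof=1) / np.sqrt(len(v))),
            n_trials=("trial_index", "size"),
        )
        .reset_index()
    )
    return per_trial, blocks


def duration_by_condition(ds: Dataset, ordinal: int) -> pd.DataFrame:
    """Per-participant median duration of uninterrupted fixations of the
    given ordinal, by stimulus-experience category x presentation time.

    Correct and incorrect trials are pooled (their durations do not differ);
    downstream tests come from the behavioural stats helpers.
    """
    if ordinal < 1:
        raise ValueError("ordinal must be >= 1")
    kept, _ = filter_uninterrupted(ds.fixations, ds.trials, ordinal=ordinal)
    kept = kept.copy()
    kept["duration_ms"] = kept["end_ms"] - kept["start_ms"]
    trials = ds.trials.copy()
    trials["experience"] = experience_category(trials)
    meta = trials.set_index("trial_id")[["experience", "presentation_s"]]
    joined = kept.join(meta, on="trial_id")
    return (
        joined.groupby(["participant_id", "experience", "presentation_s"])["duration_ms"]
        .median()
        .rename("median_duration_ms")
        .reset_index()
    )
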