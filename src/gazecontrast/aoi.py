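"""Area-of-interest dwell-time proportions and the time-window artefact.

Each fixation is assigned to the rectangle containing it (half-open:
min-inclusive, max-exclusive); the left-eye, bridge and right-eye
rectangles are combined into a single "eyes" AOI, and anything outside all
rectangles is "other".  Dwell within an analysis window is the clipped
fixation time ``min(end, window) - start`` for fixations starting inside
the window; proportions are normalized per trial and then averaged across
trials per participant (a pooled-milliseconds alternative is available).

Comparing the same five-second trials against their own first second
demonstrates the analysis-window artefact: late fixations are more
dispersed, so the full window shows *lower* eyes/nose proportions and a
*higher* "other" proportion even though nothing about the underlying
behaviour differs — proportions are not monotone in window length even
though absolute dwell times are.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .data import DataError, Dataset, FaceLayout
from . import behavior

__all__ = ["AOI_LABELS", "assign_aoi", "dwell_proportions", "truncation_contrast"]

AOI_LABELS = ("eyes", "nose", "mouth", "other")

_EYES_PARTS = ("left_eye", "bridge", "right_eye")


def assign_aoi(x, y, layout: FaceLayout) -> np.ndarray:
    """AOI label per point: 'eyes' (union of left eye, bridge, right eye),
    'nose', 'mouth' or 'other'."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    labels = np.full(len(x), "other", dtype=object)
    for part in _EYES_PARTS:
        labels[layout.rects[part].contains(x, y)] = "eyes"
    labels[layout.rects["nose"].contains(x, y)] = "nose"
    labels[layout.rects["mouth"].contains(x, y)] = "mouth"
    return labels


def _labelled_fixations(ds: Dataset, trial_ids: pd.Series) -> pd.DataFrame:
    fx = ds.fixations[ds.fixations["trial_id"].isin(set(trial_ids))].copy()
    stim = ds.trial_stimulus()
    labels = np.empty(len(fx), dtype=object)
    for sid, idx in fx.groupby(fx["trial_id"].map(stim)).groups.items():
        layout = ds.layouts.get(sid)
        if layout is None:
            raise DataError(f"no layout for stimulus {sid!r}")
        sub = fx.loc[idx]
        pos = fx.index.get_indexer(idx)
        labels[pos] = assign_aoi(sub["x"].to_numpy(), sub["y"].to_numpy(), layout)
    fx["aoi"] = labels
    return fx


def dwell_proportions(
    ds: Dataset,
    window_ms: float,
    selector: Mapping[str, object] | None = None,
    mode: str = "per_trial",
) -> pd.DataFrame:
    """Mean proportion of in-window dwell time per participant x AOI.

    A fixation contributes ``min(end, window) - start`` when it starts
    inside the window.  ``mode='per_trial'`` normalizes per trial and then
    averages proportions over trials; ``mode='pooled'`` pools dwell
    milliseconds over trials before normalizing.  Trials with zero in-window
    dwell are skipped (and counted in the ``n_skipped_trials`` attribute).
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    if mode not in ("per_trial", "pooled"):
        raise ValueError("mode must be 'per_trial' or 'pooled'")
    trials = ds.trials
    if selector:
        from .data import select_trials

        trials = select_trials(trials, selector)
    fx = _labelled_fixations(ds, trials["trial_id"])
    # dwell never extends past the stimulus offset or the response, whatever
    # the analysis window
    meta = trials.set_index("trial_id")
    trial_end = np.fmin(
        meta["presentation_s"].astype(float) * 1000.0,
        pd.to_numeric(meta["rt_ms"], errors="coerce").fillna(np.inf),
    )
    limit = np.fmin(fx["trial_id"].map(trial_end), window_ms)
    fx = fx[fx["start_ms"] < limit].copy()
    fx["dwell_ms"] = np.minimum(fx["end_ms"], limit[fx.index]) - fx["start_ms"]

    pid_of = trials.set_index("trial_id")["participant_id"]
    dwell = (
        fx.groupby(["trial_id", "aoi"])["dwell_ms"].sum().unstack(fill_value=0.0)
    )
    for label in AOI_LABELS:
        if label not in dwell.columns:
            dwell[label] = 0.0
    dwell = dwell[list(AOI_LABELS)]
    totals = dwell.sum(axis=1)
    n_skipped = int((totals <= 0).sum()) + int(len(trials) - len(dwell))
    dwell = dwell[totals > 0]

    if mode == "per_trial":
        props = dwell.div(dwell.sum(axis=1), axis=0)
        out = props.groupby(dwell.index.map(pid_of)).mean()
    else:
        pooled = dwell.groupby(dwell.index.map(pid_of)).sum()
        out = pooled.div(pooled.sum(axis=1), axis=0)
    out.index.name = "participant_id"
    out = out.reset_index()
    out.attrs["n_skipped_trials"] = n_skipped
    out.attrs["window_ms"] = window_ms
    return out


def truncation_contrast(
    ds: Dataset,
    full_window_ms: float = 5000.0,
    short_window_ms: float = 1000.0,
    selector: Mapping[str, object] | None = None,
    mode: str = "per_trial",
) -> pd.DataFrame:
    """Paired t-tests (full window minus truncated window) per AOI on the
    same trials — by default the five-second study-phase trials.

    Negative t means the AOI's proportion is lower in the full window (the
    eyes/nose pattern); positive t means higher (the "other" pattern).
    """
    selector = selector or {"phase": "study", "presentation_s": 5}
    full = dwell_proportions(ds, full_window_ms, selector, mode)
    short = dwell_proportions(ds, short_window_ms, selector, mode)
    merged = full.merge(short, on="participant_id", suffixes=("_full", "_short"))
    if len(merged) < 2:
        raise DataError("truncation_contrast needs at least 2 participants")
    rows = []
    for label in AOI_LABELS:
        res = behavior.paired_t(merged[f"{label}_full"], merged[f"{label}_short"])
        rows.append(
            {
                "aoi": label,
                "mean_full": merged[f"{label}_full"].mean(),
                "mean_short": merged[f"{label}_short"].mean(),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "hedges_g": res.effect_size,
            }
        )
    return pd.DataFrame(rows)
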