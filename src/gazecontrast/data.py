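"""Data model and I/O for fixation-report experiments.

The package analyses pre-parsed eye-movement *events* (fixations), not raw
gaze samples.  Three plain-text artefacts describe an experiment:

``fixations.tsv``
    One fixation per row (UTF-8, tab-separated, ``.`` decimal).  Required
    columns: ``participant_id, trial_id, ordinal, x, y, start_ms, end_ms``.
    Optional: ``saccade_onset_ms`` (onset of the saccade that preceded the
    ordinal-1 fixation), ``interrupted``.  Unknown columns are preserved.

``trials.tsv``
    One trial per row with design metadata (phase, presentation time,
    old/new exposure, start side, response, reaction time).

``layouts.json``
    Per-stimulus facial-feature rectangles, the reference point, and the
    registration transform into the canonical face frame.

Canonical face frame: origin at the per-face *reference point* (the point
equidistant from the centres of the nearest eye, nearest half-nose and
nearest half-mouth), x rightward, y increasing *downward*, units = degrees
of visual angle.  Timing is trial-relative (stimulus onset = 0 ms).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "DataError",
    "ConfigError",
    "Rect",
    "Registration",
    "FaceLayout",
    "Dataset",
    "Violation",
    "FEATURE_NAMES",
    "FIXATION_COLUMNS",
    "TRIAL_COLUMNS",
    "read_fixation_table",
    "write_fixation_table",
    "read_trials_table",
    "write_trials_table",
    "read_layouts",
    "write_layouts",
    "register_to_canonical",
    "register_dataset",
    "select_trials",
    "validate_dataset",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class DataError(ValueError):
    """Structurally valid input with scientifically inconsistent content."""


class ConfigError(ValueError):
    """Invalid run or generator configuration."""


FEATURE_NAMES = ("left_eye", "right_eye", "bridge", "nose", "mouth")

FIXATION_COLUMNS = ("participant_id", "trial_id", "ordinal", "x", "y", "start_ms", "end_ms")

TRIAL_COLUMNS = (
    "participant_id",
    "block_index",
    "trial_index",
    "phase",
    "presentation_s",
    "stimulus_id",
    "exposure",
    "start_side",
    "response",
    "rt_ms",
    "correct",
)


class Rect(NamedTuple):
    """Axis-aligned rectangle in canonical degrees, half-open:
    min-inclusive, max-exclusive."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x_min) & (x < self.x_max) & (y >= self.y_min) & (y < self.y_max)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    @property
    def degenerate(self) -> bool:
        return not (self.x_max > self.x_min and self.y_max > self.y_min)


@dataclass(frozen=True)
class Registration:
    """Similarity transform from recorded screen coordinates to the canonical
    face frame: translation to the reference point, isotropic scale
    (degrees per screen unit) and an optional horizontal mirror.

    ``canonical_x = mirror_sign * scale * (screen_x - ref_x)``
    ``canonical_y =               scale * (screen_y - ref_y)``
    """

    ref_x: float = 0.0
    ref_y: float = 0.0
    scale: float = 1.0
    mirrored: bool = False

    def to_canonical(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        sign = -1.0 if self.mirrored else 1.0
        return sign * self.scale * (x - self.ref_x), self.scale * (y - self.ref_y)

    def from_canonical(self, cx, cy):
        cx = np.asarray(cx, dtype=float)
        cy = np.asarray(cy, dtype=float)
        sign = -1.0 if self.mirrored else 1.0
        return self.ref_x + sign * cx / self.scale, self.ref_y + cy / self.scale


@dataclass
class FaceLayout:
    """Per-stimulus feature rectangles and registration.

    ``rects`` are expressed in the canonical frame.  ``reference_point`` is
    the screen-coordinate location of the equidistant point; by construction
    it maps to the canonical origin under ``registration``.
    """

    stimulus_id: str
    rects: dict[str, Rect]
    reference_point: tuple[float, float] = (0.0, 0.0)
    registration: Registration = field(default_factory=Registration)
    mirrored: bool = False

    def feature_center(self, name: str) -> tuple[float, float]:
        return self.rects[name].center

    def eyes_rects(self) -> tuple[Rect, Rect, Rect]:
        """The combined 'eyes' region is the union of these three."""
        return (self.rects["left_eye"], self.rects["bridge"], self.rects["right_eye"])


@dataclass
class Dataset:
    """A complete experiment: design table, fixation events, layouts."""

    trials: pd.DataFrame
    fixations: pd.DataFrame
    layouts: dict[str, FaceLayout]

    def trial_stimulus(self) -> pd.Series:
        """Map trial_id -> stimulus_id."""
        return self.trials.set_index("trial_id")["stimulus_id"]


@dataclass(frozen=True)
class Violation:
    entity: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.entity}: {self.rule}: {self.message}"


# ---------------------------------------------------------------------------
# Fixation table I/O
# ---------------------------------------------------------------------------

_NUMERIC_FIX_COLS = ("ordinal", "x", "y", "start_ms", "end_ms")


def read_fixation_table(source) -> pd.DataFrame:
    """Read a fixation-report TSV.

    Raises :class:`FormatError` naming the first missing required column, or
    a row-level error (with the 1-based file line number) for non-numeric
    coordinates/timestamps or non-positive durations.  Unknown columns are
    preserved untouched; row order is irrelevant to all downstream analyses.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    for col in FIXATION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"fixation table is missing required column {col!r}")
    for col in _NUMERIC_FIX_COLS + (("saccade_onset_ms",) if "saccade_onset_ms" in df.columns else ()):
        raw = df[col]
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(f"line {line}: non-numeric value {raw[bad.idxmax()]!r} in column {col!r}")
        df[col] = converted
    df["ordinal"] = df["ordinal"].astype(int)
    nonpos = df["end_ms"] <= df["start_ms"]
    if nonpos.any():
        line = int(nonpos.idxmax()) + 2
        raise FormatError(f"line {line}: end_ms <= start_ms (fixation duration must be positive)")
    if "interrupted" in df.columns:
        df["interrupted"] = df["interrupted"].map(
            {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}
        ).astype(bool)
    else:
        df["interrupted"] = False
    return df


def write_fixation_table(df: pd.DataFrame, dest) -> None:
    df.to_csv(dest, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trials table I/O
# ---------------------------------------------------------------------------


def read_trials_table(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", dtype=str)
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"trials table is missing required column {col!r}")
    for col in ("block_index", "trial_index", "presentation_s"):
        df[col] = pd.to_numeric(df[col]).astype(int)
    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    df["correct"] = df["correct"].map(
        {"True": True, "False": False, "true": True, "false": False, "": np.nan}
    )
    df["response"] = df["response"].fillna("none")
    if "trial_id" not in df.columns:
        df["trial_id"] = df["participant_id"] + ":" + df["trial_index"].astype(str)
    return df


def write_trials_table(df: pd.DataFrame, dest) -> None:
    df.to_csv(dest, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Layout JSON I/O
# ---------------------------------------------------------------------------


def layout_to_dict(layout: FaceLayout) -> dict:
    return {
        "stimulus_id": layout.stimulus_id,
        "rects": {name: list(r) for name, r in layout.rects.items()},
        "reference_point": list(layout.reference_point),
        "registration": dataclasses.asdict(layout.registration),
        "mirrored": layout.mirrored,
    }


def layout_from_dict(d: Mapping) -> FaceLayout:
    return FaceLayout(
        stimulus_id=d["stimulus_id"],
        rects={name: Rect(*vals) for name, vals in d["rects"].items()},
        reference_point=tuple(d.get("reference_point", (0.0, 0.0))),
        registration=Registration(**d.get("registration", {})),
        mirrored=bool(d.get("mirrored", False)),
    )


def write_layouts(layouts: Mapping[str, FaceLayout], dest) -> None:
    payload = {sid: layout_to_dict(lay) for sid, lay in layouts.items()}
    if hasattr(dest, "write"):
        json.dump(payload, dest, indent=1)
    else:
        with open(dest, "w") as fh:
            json.dump(payload, fh, indent=1)


def read_layouts(source) -> dict[str, FaceLayout]:
    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        with open(source) as fh:
            payload = json.load(fh)
    return {sid: layout_from_dict(d) for sid, d in payload.items()}


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------


def register_to_canonical(x, y, layout: FaceLayout):
    """Map screen coordinates into the canonical face frame of ``layout``.

    Mirrored stimuli are flipped so that the face's own left/right are
    consistent across trials and stimuli.
    """
    if layout is None:
        raise DataError("no layout available for registration")
    return layout.registration.to_canonical(x, y)


def register_dataset(ds: Dataset) -> Dataset:
    """Return a dataset whose fixation coordinates are canonical.

    Requires every fixation's trial to resolve to a stimulus with a layout.
    """
    stim = ds.trial_stimulus()
    fx = ds.fixations.copy()
    sids = fx["trial_id"].map(stim)
    if sids.isna().any():
        missing = fx.loc[sids.isna(), "trial_id"].iloc[0]
        raise DataError(f"fixation references unknown trial {missing!r}")
    cx = np.empty(len(fx))
    cy = np.empty(len(fx))
    for sid, idx in fx.groupby(sids).groups.items():
        layout = ds.layouts.get(sid)
        if layout is None:
            raise DataError(f"no layout for stimulus {sid!r}")
        sub = fx.loc[idx]
        cxx, cyy = layout.registration.to_canonical(sub["x"].to_numpy(), sub["y"].to_numpy())
        pos = fx.index.get_indexer(idx)
        cx[pos], cy[pos] = cxx, cyy
    fx["x"], fx["y"] = cx, cy
    return Dataset(trials=ds.trials, fixations=fx, layouts=ds.layouts)


# ---------------------------------------------------------------------------
# Trial selection
# ---------------------------------------------------------------------------


def select_trials(trials: pd.DataFrame, selector: Mapping[str, object]) -> pd.DataFrame:
    """Filter a trials table by exact-match (or membership) conditions.

    ``selector`` maps column name -> value or sequence of values, e.g.
    ``{"phase": "test", "presentation_s": 1}`` or
    ``{"exposure": ["old", "new"]}``.
    """
    mask = pd.Series(True, index=trials.index)
    for col, val in selector.items():
        if col not in trials.columns:
            raise ConfigError(f"unknown trial field {col!r} in condition selector")
        if isinstance(val, (list, tuple, set, frozenset)):
            mask &= trials[col].isin(list(val))
        else:
            mask &= trials[col] == val
    return trials[mask]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_dataset(ds: Dataset) -> list[Violation]:
    """Check all data-model invariants; violations are data, not exceptions."""
    out: list[Violation] = []
    trials, fx = ds.trials, ds.fixations

    known_trials = set(trials["trial_id"])
    for tid in fx.loc[~fx["trial_id"].isin(known_trials), "trial_id"].unique():
        out.append(Violation(f"fixation trial {tid}", "trial-resolves", "fixation references absent trial"))

    for sid in trials.loc[~trials["stimulus_id"].isin(ds.layouts.keys()), "stimulus_id"].unique():
        out.append(Violation(f"stimulus {sid}", "layout-present", "trial references absent layout"))

    bad = fx["end_ms"] <= fx["start_ms"]
    for _, row in fx[bad].iterrows():
        out.append(
            Violation(
                f"fixation {row['trial_id']}#{row['ordinal']}",
                "positive-duration",
                "end_ms must exceed start_ms",
            )
        )

    for tid, grp in fx.groupby("trial_id"):
        ords = np.sort(grp["ordinal"].to_numpy())
        if len(np.unique(ords)) != len(ords):
            out.append(Violation(f"trial {tid}", "unique-ordinals", "duplicate fixation ordinal"))
        elif not np.array_equal(ords, np.arange(1, len(ords) + 1)):
            out.append(Violation(f"trial {tid}", "consecutive-ordinals", "ordinals must run 1..k"))

    study_mismatch = (trials["phase"] == "study") != (trials["exposure"] == "study")
    for tid in trials.loc[study_mismatch, "trial_id"]:
        out.append(Violation(f"trial {tid}", "exposure-phase", "exposure=study iff phase=study"))

    resp_on_study = (trials["phase"] == "study") & (trials["response"].fillna("none") != "none")
    for tid in trials.loc[resp_on_study, "trial_id"]:
        out.append(Violation(f"trial {tid}", "response-test-only", "study trials carry no response"))

    rt_bad = trials["rt_ms"].notna() & (trials["rt_ms"] > 5000)
    for tid in trials.loc[rt_bad, "trial_id"]:
        out.append(Violation(f"trial {tid}", "rt-bound", "rt_ms exceeds the 5000 ms response window"))

    for name, layout in ds.layouts.items():
        for feat, rect in layout.rects.items():
            if rect.degenerate:
                out.append(Violation(f"layout {name}", "nondegenerate-rect", f"rectangle {feat} is degenerate"))
        ox, oy = layout.registration.to_canonical(*layout.reference_point)
        if abs(float(ox)) > 1e-9 or abs(float(oy)) > 1e-9:
            out.append(
                Violation(f"layout {name}", "reference-origin", "reference point does not map to canonical origin")
            )
    return out
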