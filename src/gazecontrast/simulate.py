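"""Synthetic face encoding/recognition sessions with known ground truth.

The generator emulates a two-phase old/new face recognition experiment:

* a **study** phase (two blocks) in which each face is shown for a fixed
  one- or five-second presentation time, followed by
* a **test** phase (four blocks) in which studied ("old") and unstudied
  ("new") faces are judged old/new within up to five seconds, with the
  stimulus visible for at most the block's one- or five-second limit.

Block presentation-time orders are counterbalanced across participants over
the four canonical orders; within every phase, presentation time, start
side and face gender are fully crossed; an old face appears on the same
side of fixation at study and at test.

Behaviour follows an equal-variance Gaussian signal-detection model: on an
old trial the latent evidence is N(d', 1), on a new trial N(0, 1), and the
observer responds "old" when evidence exceeds ``c + d'/2`` so the standard
estimators recover (d', c) without bias.

Scan paths are built from a first-saccade latency (log-normal), a saccade
transit time, and a sequence of log-normally distributed fixation
durations; as many fixations as fit the trial are generated, so the last
one may span the stimulus offset (or the response) and is flagged
``interrupted``.  Fixation locations are drawn from per-condition Gaussian
mixtures anchored to facial features; later (>2nd) fixations use a more
dispersed mixture, which reproduces the growth of off-feature gaze with
longer analysis windows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    ConfigError,
    Dataset,
    FaceLayout,
    Rect,
    Registration,
    FIXATION_COLUMNS,
    TRIAL_COLUMNS,
)

__all__ = [
    "MixtureComponent",
    "GeneratorConfig",
    "GroundTruth",
    "default_config",
    "null_config",
    "canonical_template",
    "reference_point",
    "generate_layouts",
    "generate_experiment",
    "generate_null_experiment",
    "BLOCK_ORDERS",
]

# The four counterbalanced block orders: (study block times, test block
# times).  Test blocks 1-2 hold the old faces of study block 1, test blocks
# 3-4 those of study block 2.
BLOCK_ORDERS: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...] = (
    ((1, 5), (1, 5, 1, 5)),
    ((1, 5), (5, 1, 5, 1)),
    ((5, 1), (1, 5, 1, 5)),
    ((5, 1), (5, 1, 5, 1)),
)

# Template facial-feature rectangles in a face-centred frame: x = 0 at the
# facial midline, y = 0 on the eye line, y increases downward, degrees of
# visual angle.  Scaled to a forehead width of ~10 deg.
_TEMPLATE_FACE_FRAME: dict[str, Rect] = {
    "left_eye": Rect(-2.9, -0.7, -0.55, 0.55),
    "right_eye": Rect(0.7, 2.9, -0.55, 0.55),
    "bridge": Rect(-0.7, 0.7, -0.55, 0.55),
    "nose": Rect(-1.0, 1.0, 0.55, 2.8),
    "mouth": Rect(-1.7, 1.7, 3.4, 4.6),
}


def _circumcenter(a, b, c) -> tuple[float, float]:
    """Point equidistant from three non-collinear points."""
    (ax, ay), (bx, by), (cx, cy) = a, b, c
    m = np.array([[2 * (bx - ax), 2 * (by - ay)], [2 * (cx - bx), 2 * (cy - by)]])
    v = np.array(
        [bx * bx - ax * ax + by * by - ay * ay, cx * cx - bx * bx + cy * cy - by * by]
    )
    try:
        sol = np.linalg.solve(m, v)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate jitter
        raise ConfigError("feature centres are collinear; no equidistant point") from exc
    return float(sol[0]), float(sol[1])


def reference_point(rects: Mapping[str, Rect], side: str = "left") -> tuple[float, float]:
    """The point equidistant from the centres of the nearest eye, nearest
    half-nose and nearest half-mouth (the start-dot alignment point)."""
    if side not in ("left", "right"):
        raise ConfigError(f"side must be 'left' or 'right', got {side!r}")
    eye = rects["left_eye"] if side == "left" else rects["right_eye"]
    nose, mouth = rects["nose"], rects["mouth"]

    def half_center(r: Rect) -> tuple[float, float]:
        xm = 0.5 * (r.x_min + r.x_max)
        if side == "left":
            return (0.5 * (r.x_min + xm), 0.5 * (r.y_min + r.y_max))
        return (0.5 * (xm + r.x_max), 0.5 * (r.y_min + r.y_max))

    return _circumcenter(eye.center, half_center(nose), half_center(mouth))


def canonical_template() -> dict[str, Rect]:
    """Template rectangles re-expressed in the canonical frame (origin at
    the left-side reference point)."""
    rx, ry = reference_point(_TEMPLATE_FACE_FRAME, "left")
    return {
        name: Rect(r.x_min - rx, r.x_max - rx, r.y_min - ry, r.y_max - ry)
        for name, r in _TEMPLATE_FACE_FRAME.items()
    }


def generate_layouts(
    n_stimuli: int,
    seed: int,
    jitter: float = 0.25,
    screen_scale: float = 1.0 / 32.0,
    mirror_half: bool = True,
) -> dict[str, FaceLayout]:
    """Per-stimulus layouts: the canonical template with a small independent
    jitter (<= 0.5 deg) of each rectangle, the reference point recomputed per
    face, and a screen registration (``screen_scale`` degrees per unit).
    """
    if n_stimuli < 1:
        raise ConfigError("n_stimuli must be >= 1")
    if not 0.0 <= jitter <= 0.5:
        raise ConfigError("layout jitter must lie in [0, 0.5] degrees")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFACE]))
    layouts: dict[str, FaceLayout] = {}
    for i in range(n_stimuli):
        sid = f"s{i:03d}"
        rects = {}
        for name, r in _TEMPLATE_FACE_FRAME.items():
            dx, dy = rng.uniform(-jitter, jitter, size=2)
            rects[name] = Rect(r.x_min + dx, r.x_max + dx, r.y_min + dy, r.y_max + dy)
        rx, ry = reference_point(rects, "left")
        canon = {
            name: Rect(r.x_min - rx, r.x_max - rx, r.y_min - ry, r.y_max - ry)
            for name, r in rects.items()
        }
        mirrored = bool(mirror_half and rng.random() < 0.5)
        ref_screen = (512.0, 384.0)
        layouts[sid] = FaceLayout(
            stimulus_id=sid,
            rects=canon,
            reference_point=ref_screen,
            registration=Registration(
                ref_x=ref_screen[0], ref_y=ref_screen[1], scale=screen_scale, mirrored=mirrored
            ),
            mirrored=mirrored,
        )
    return layouts


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixtureComponent:
    """One Gaussian component anchored to a facial feature.

    ``feature`` is one of the rectangle names or ``"face"`` (centroid of all
    five rectangles); ``dx, dy`` offset the anchor in degrees (y downward);
    ``sd`` is the isotropic standard deviation in degrees.
    """

    weight: float
    feature: str
    dx: float
    dy: float
    sd: float


Cell = tuple[str, int]  # (phase, presentation_s)


@dataclass
class GeneratorConfig:
    """All generative parameters of a synthetic session.

    Temporal quantities are in milliseconds; log-normal models are given as
    (median, sigma-of-log).  ``spatial`` is keyed by (phase, presentation_s,
    ordinal group) where the ordinal group is 1, 2 or ``"late"`` (3rd and
    later fixations).  ``sdt`` is keyed by (study_time_s, test_time_s).
    """

    n_participants: int = 31
    trials_per_block: int = 24
    seed: int = 0
    layout_jitter: float = 0.25
    spatial: dict[tuple[str, int, object], tuple[MixtureComponent, ...]] = field(default_factory=dict)
    latency_ms: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"study": (290.0, 0.35), "test": (230.0, 0.35)}
    )
    duration_ms: dict[tuple[str, int, object], tuple[float, float]] = field(default_factory=dict)
    saccade_transit_ms: float = 30.0
    sdt: dict[tuple[int, int], tuple[float, float]] = field(
        default_factory=lambda: {
            (1, 1): (1.0, 0.25),
            (1, 5): (1.0, 0.25),
            (5, 1): (1.67, 0.0),
            (5, 5): (1.67, 0.0),
        }
    )
    subject_sd_dprime: float = 0.3
    subject_sd_criterion: float = 0.15
    rt_ms: tuple[float, float] = (1400.0, 0.3)
    rt_cap_ms: float = 5000.0

    @property
    def n_stimuli(self) -> int:
        return 4 * self.trials_per_block

    def validate(self) -> None:
        if self.trials_per_block % 8 != 0:
            raise ConfigError("trials_per_block must be a multiple of 8 to balance the design")
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        for key, comps in self.spatial.items():
            total = sum(c.weight for c in comps)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"mixture weights for {key} sum to {total}, expected 1")
            if any(c.sd <= 0 for c in comps):
                raise ConfigError(f"mixture for {key} has non-positive sd")
        for (d, _c) in self.sdt.values():
            if not np.isfinite(d):
                raise ConfigError("d' must be finite")


def _default_spatial() -> dict:
    o1 = (MixtureComponent(1.0, "bridge", 0.0, 0.9, 1.0),)
    o2_study = (MixtureComponent(1.0, "bridge", 0.0, 0.5, 0.9),)
    o2_test = (
        MixtureComponent(0.85, "bridge", 0.0, 1.4, 0.9),
        MixtureComponent(0.15, "mouth", 0.0, 0.0, 1.0),
    )
    late = (
        MixtureComponent(0.55, "face", 0.0, 0.0, 2.3),
        MixtureComponent(0.25, "mouth", 0.0, 0.5, 1.5),
        MixtureComponent(0.20, "bridge", 0.0, -1.0, 1.8),
    )
    spatial = {}
    for t in (1, 5):
        spatial[("study", t, 1)] = o1
        spatial[("test", t, 1)] = o1
        spatial[("study", t, 2)] = o2_study
        spatial[("test", t, 2)] = o2_test
        spatial[("study", t, "late")] = late
        spatial[("test", t, "late")] = late
    return spatial


def _default_durations() -> dict:
    dur = {}
    for phase in ("study", "test"):
        for t in (1, 5):
            dur[(phase, t, 1)] = (220.0, 0.55)
            dur[(phase, t, 2)] = (200.0, 0.55)
            dur[(phase, t, "late")] = (200.0, 0.55)
    # Short study time elicits briefer second fixations (~50 ms below the
    # other conditions).
    dur[("study", 1, 2)] = (150.0, 0.55)
    return dur


def default_config(**overrides) -> GeneratorConfig:
    cfg = GeneratorConfig(spatial=_default_spatial(), duration_ms=_default_durations())
    cfg = dataclasses.replace(cfg, **overrides)
    cfg.validate()
    return cfg


def null_config(base: GeneratorConfig | None = None, **overrides) -> GeneratorConfig:
    """A configuration in which every condition cell shares one spatial,
    temporal and SDT parameterization (for calibration runs)."""
    base = base or default_config()
    spatial = {}
    for t in (1, 5):
        for phase in ("study", "test"):
            spatial[(phase, t, 1)] = base.spatial[("study", 5, 1)]
            spatial[(phase, t, 2)] = base.spatial[("study", 5, 2)]
            spatial[(phase, t, "late")] = base.spatial[("study", 5, "late")]
    durations = {key: (200.0, 0.55) for key in base.duration_ms}
    cfg = dataclasses.replace(
        base,
        spatial=spatial,
        duration_ms=durations,
        latency_ms={"study": (230.0, 0.35), "test": (230.0, 0.35)},
        sdt={k: (1.0, 0.0) for k in base.sdt},
        subject_sd_dprime=0.0,
        subject_sd_criterion=0.0,
    )
    cfg = dataclasses.replace(cfg, **overrides)
    cfg.validate()
    return cfg


@dataclass
class GroundTruth:
    """Realized generative parameters and per-trial latent evidence."""

    config: GeneratorConfig
    evidence: pd.DataFrame  # trial_id, evidence, threshold
    subject_effects: pd.DataFrame  # participant_id, d_offset, c_offset


# ---------------------------------------------------------------------------
# Experiment generation
# ---------------------------------------------------------------------------


def _balanced_assignment(rng, ids: np.ndarray, genders: np.ndarray) -> np.ndarray:
    """Assign start sides balanced within gender."""
    sides = np.empty(len(ids), dtype=object)
    for g in np.unique(genders):
        idx = np.flatnonzero(genders == g)
        half = len(idx) // 2
        perm = rng.permutation(idx)
        sides[perm[:half]] = "left"
        sides[perm[half:]] = "right"
    return sides


def _split_balanced(rng, idx: np.ndarray, genders: np.ndarray, sides: np.ndarray):
    """Split indices into two halves balanced over gender x side."""
    first, second = [], []
    for g in np.unique(genders):
        for s in ("left", "right"):
            sub = np.flatnonzero((genders == g) & (sides == s))
            sub = rng.permutation(sub)
            half = len(sub) // 2
            first.extend(sub[:half])
            second.extend(sub[half:])
    return idx[np.sort(first)], idx[np.sort(second)]


def _anchor_positions(layout: FaceLayout) -> dict[str, tuple[float, float]]:
    anchors = {name: layout.rects[name].center for name in layout.rects}
    cx = float(np.mean([p[0] for p in anchors.values()]))
    cy = float(np.mean([p[1] for p in anchors.values()]))
    anchors["face"] = (cx, cy)
    return anchors


def _sample_mixture(rng, comps: Sequence[MixtureComponent], anchors_xy: np.ndarray) -> np.ndarray:
    """Draw one point per row of ``anchors_xy`` (n, n_features-indexed dict
    handled by caller); anchors_xy has shape (n, n_comps, 2)."""
    n = anchors_xy.shape[0]
    weights = np.array([c.weight for c in comps])
    choice = rng.choice(len(comps), size=n, p=weights)
    means = anchors_xy[np.arange(n), choice, :]
    sds = np.array([c.sd for c in comps])[choice]
    return means + rng.standard_normal((n, 2)) * sds[:, None]


def _participant_trials(rng, cfg: GeneratorConfig, pid: str, pidx: int):
    """Design table rows for one participant (no fixations/responses yet)."""
    tpb = cfg.trials_per_block
    study_times, test_times = BLOCK_ORDERS[pidx % 4]
    stim_ids = np.array([f"s{i:03d}" for i in range(cfg.n_stimuli)])
    genders = np.where(np.arange(cfg.n_stimuli) % 2 == 0, "female", "male")

    # Study set: tpb female + tpb male, split into subsets A and B.
    female = rng.permutation(np.flatnonzero(genders == "female"))
    male = rng.permutation(np.flatnonzero(genders == "male"))
    study_idx = np.concatenate([female[:tpb], male[:tpb]])
    new_pool = np.concatenate([female[tpb : tpb + tpb], male[tpb : tpb + tpb]])
    a_idx = np.concatenate([female[: tpb // 2], male[: tpb // 2]])
    b_idx = np.concatenate([female[tpb // 2 : tpb], male[tpb // 2 : tpb]])

    # sides balanced within gender *within each study block's subset* so that
    # every block is fully crossed on time x side x gender
    sides = {}
    for subset in (a_idx, b_idx):
        sides.update(zip(subset, _balanced_assignment(rng, subset, genders[subset])))
    new_sides = dict(zip(new_pool, _balanced_assignment(rng, new_pool, genders[new_pool])))
    study_time_of = {}

    rows = []

    def add_block(block_index, phase, time_s, old_idx, new_idx):
        entries = []
        for i in old_idx:
            exposure = "study" if phase == "study" else "old"
            entries.append((i, exposure, sides[i]))
        for i in new_idx:
            entries.append((i, "new", new_sides[i]))
        order = rng.permutation(len(entries))
        for k in order:
            i, exposure, side = entries[k]
            rows.append(
                {
                    "participant_id": pid,
                    "block_index": block_index,
                    "phase": phase,
                    "presentation_s": time_s,
                    "stimulus_id": stim_ids[i],
                    "exposure": exposure,
                    "start_side": side,
                }
            )

    # Study phase: subset A in block 1, subset B in block 2.
    for b, (subset, t) in enumerate(zip((a_idx, b_idx), study_times), start=1):
        for i in subset:
            study_time_of[i] = t
        add_block(b, "study", t, subset, [])

    # Test phase: blocks 3-4 hold subset A's old faces, 5-6 subset B's.
    new_halves = _split_balanced(
        rng, new_pool, genders[new_pool], np.array([new_sides[i] for i in new_pool], dtype=object)
    )
    new_quarters = []
    for half in new_halves:
        q1, q2 = _split_balanced(
            rng, half, genders[half], np.array([new_sides[i] for i in half], dtype=object)
        )
        new_quarters.extend([q1, q2])
    old_halves = {}
    for name, subset in (("A", a_idx), ("B", b_idx)):
        s = np.array([sides[i] for i in subset], dtype=object)
        old_halves[name] = _split_balanced(rng, subset, genders[subset], s)
    for b, t in enumerate(test_times, start=1):
        h1, h2 = old_halves["A" if b <= 2 else "B"]
        olds = h1 if b % 2 == 1 else h2
        add_block(2 + b, "test", t, olds, new_quarters[b - 1])

    df = pd.DataFrame(rows)
    df["trial_index"] = np.arange(1, len(df) + 1)
    df["trial_id"] = pid + ":" + df["trial_index"].astype(str).str.zfill(3)
    df["study_time_s"] = df["stimulus_id"].map(
        {stim_ids[i]: t for i, t in study_time_of.items()}
    )
    return df


def _responses(rng, cfg: GeneratorConfig, trials: pd.DataFrame, d_off: float, c_off: float):
    """Draw old/new responses and RTs for the test-phase rows of ``trials``."""
    n_all = len(trials)
    evidence = np.full(n_all, np.nan)
    threshold = np.full(n_all, np.nan)
    response = np.array(["none"] * n_all, dtype=object)
    rt = np.full(n_all, np.nan)
    correct = np.full(n_all, np.nan, dtype=object)

    test = (trials["phase"] == "test").to_numpy()
    idx = np.flatnonzero(test)
    if len(idx) == 0:
        return evidence, threshold, response, rt, correct
    sub = trials.iloc[idx]
    # The SDT cell of a test block is defined by the study time of its old
    # faces and its own presentation time; new trials inherit the block cell.
    block_study_time = (
        sub[sub["exposure"] == "old"].groupby("block_index")["study_time_s"].first()
    )
    st = sub["study_time_s"].to_numpy(dtype=float)
    st = np.where(np.isnan(st), sub["block_index"].map(block_study_time).to_numpy(dtype=float), st)
    pt = sub["presentation_s"].to_numpy(dtype=float)
    d = np.array([cfg.sdt[(int(s), int(t))][0] for s, t in zip(st, pt)]) + d_off
    c = np.array([cfg.sdt[(int(s), int(t))][1] for s, t in zip(st, pt)]) + c_off
    is_old = (sub["exposure"] == "old").to_numpy()
    ev = rng.standard_normal(len(idx)) + np.where(is_old, d, 0.0)
    thr = c + d / 2.0
    resp = np.where(ev > thr, "old", "new")
    evidence[idx] = ev
    threshold[idx] = thr
    response[idx] = resp
    rt[idx] = np.minimum(
        cfg.rt_ms[0] * np.exp(rng.normal(0.0, cfg.rt_ms[1], size=len(idx))), cfg.rt_cap_ms
    )
    correct[idx] = (resp == "old") == is_old
    return evidence, threshold, response, rt, correct


def _block_fixations(rng, cfg, block: pd.DataFrame, anchors: Mapping[str, dict]):
    """Generate fixation rows for one block (shared phase/time), vectorized
    across its trials."""
    n = len(block)
    if n == 0:
        return []
    phase = block["phase"].iloc[0]
    time_s = int(block["presentation_s"].iloc[0])
    stim_offset = 1000.0 * time_s
    rt = block["rt_ms"].to_numpy(dtype=float)
    trial_end = np.where(np.isnan(rt), stim_offset, rt)
    if phase == "study":
        trial_end = np.full(n, stim_offset)

    med_l, sd_l = cfg.latency_ms[phase]
    latency = med_l * np.exp(rng.normal(0.0, sd_l, size=n))
    transit = cfg.saccade_transit_ms

    kmax = max(3, int(np.ceil(trial_end.max() / 120.0)) + 3)
    while True:
        groups = [1, 2] + ["late"] * (kmax - 2)
        med = np.array([cfg.duration_ms[(phase, time_s, g)][0] for g in groups])
        sig = np.array([cfg.duration_ms[(phase, time_s, g)][1] for g in groups])
        durations = med * np.exp(rng.normal(0.0, 1.0, size=(n, kmax)) * sig)
        starts = np.empty((n, kmax))
        starts[:, 0] = latency + transit
        if kmax > 1:
            starts[:, 1:] = (
                (latency + transit)[:, None]
                + np.cumsum(durations[:, :-1] + transit, axis=1)
            )
        ends = starts + durations
        if (ends[:, -1] >= trial_end).all():
            break
        kmax *= 2  # pragma: no cover - only for extreme duration draws

    keep = starts < trial_end[:, None]
    counts = keep.sum(axis=1)

    # Locations per ordinal group.
    sids = block["stimulus_id"].to_numpy()
    locs = np.empty((n, kmax, 2))
    for col, group in enumerate(groups):
        comps = cfg.spatial[(phase, time_s, group)]
        anc = np.array([[anchors[sid][c.feature] for c in comps] for sid in sids])
        anc = anc + np.array([[c.dx, c.dy] for c in comps])[None, :, :]
        locs[:, col, :] = _sample_mixture(rng, comps, anc)

    rows = []
    tids = block["trial_id"].to_numpy()
    pid = block["participant_id"].iloc[0]
    for i in range(n):
        k = counts[i]
        for j in range(k):
            interrupted = bool(ends[i, j] > stim_offset or ends[i, j] > trial_end[i])
            rows.append(
                (
                    pid,
                    tids[i],
                    j + 1,
                    locs[i, j, 0],
                    locs[i, j, 1],
                    starts[i, j],
                    ends[i, j],
                    latency[i] if j == 0 else np.nan,
                    interrupted,
                )
            )
    return rows


_FIX_OUT_COLS = list(FIXATION_COLUMNS) + ["saccade_onset_ms", "interrupted"]


def generate_experiment(
    config: GeneratorConfig, include_fixations: bool = True
) -> tuple[Dataset, GroundTruth]:
    """Generate a full synthetic session for every participant.

    Fully deterministic given ``config`` (including its seed).  With
    ``include_fixations=False`` only the design table and responses are
    produced (useful for purely behavioural simulations).
    """
    config.validate()
    layouts = generate_layouts(config.n_stimuli, config.seed, config.layout_jitter)
    anchors = {sid: _anchor_positions(lay) for sid, lay in layouts.items()}

    all_trials = []
    all_fix = []
    evid_rows = []
    subj_rows = []
    for pidx in range(config.n_participants):
        pid = f"p{pidx:02d}"
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1, pidx]))
        trials = _participant_trials(rng, config, pid, pidx)
        d_off = rng.normal(0.0, config.subject_sd_dprime) if config.subject_sd_dprime else 0.0
        c_off = rng.normal(0.0, config.subject_sd_criterion) if config.subject_sd_criterion else 0.0
        subj_rows.append({"participant_id": pid, "d_offset": d_off, "c_offset": c_off})
        ev, thr, resp, rt, correct = _responses(rng, config, trials, d_off, c_off)
        trials["response"] = resp
        trials["rt_ms"] = rt
        trials["correct"] = correct
        evid_rows.append(
            pd.DataFrame(
                {"trial_id": trials["trial_id"], "evidence": ev, "threshold": thr}
            ).dropna(subset=["evidence"])
        )
        if include_fixations:
            for _, block in trials.groupby("block_index", sort=True):
                all_fix.extend(_block_fixations(rng, config, block, anchors))
        all_trials.append(trials)

    if all_trials:
        trials_df = pd.concat(all_trials, ignore_index=True)
    else:
        trials_df = pd.DataFrame(columns=list(TRIAL_COLUMNS) + ["trial_id", "study_time_s"])
    fix_df = pd.DataFrame(all_fix, columns=_FIX_OUT_COLS)
    truth = GroundTruth(
        config=config,
        evidence=pd.concat(evid_rows, ignore_index=True) if evid_rows else pd.DataFrame(),
        subject_effects=pd.DataFrame(subj_rows),
    )
    return Dataset(trials=trials_df, fixations=fix_df, layouts=layouts), truth


def generate_null_experiment(config: GeneratorConfig | None = None, **overrides) -> Dataset:
    """As :func:`generate_experiment` but with one shared parameterization
    across all condition cells; returns only the dataset."""
    cfg = null_config(config, **overrides)
    ds, _ = generate_experiment(cfg)
    return ds
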