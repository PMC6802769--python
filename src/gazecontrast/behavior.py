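"""Signal-detection and reaction-time scoring of the old/new task.

Per participant and per (study-time x test-time) cell:

* hit/miss counts from old trials (the study time of an old face is the
  presentation time of that same face in the study phase),
* false alarms / correct rejections from the *new* trials of the same test
  block(s) that held the cell's old trials (new faces belong to no study
  condition, so each false-alarm rate is block-paired with its hit rate),
* extreme rates corrected away from 0/1 before the z-transform
  (``0 -> 1/(2n)``, ``n/n -> 1 - 1/(2n)``), with flags recording whether the
  adjustment fired,
* ``d' = z(hit) - z(fa)`` and ``c = -(z(hit) + z(fa)) / 2``,
* median reaction time over correct old trials (medians, not means, because
  response-time distributions are right-skewed).

Group-level comparisons: a 2x2 within-subject ANOVA computed from sums of
squares (two-level factors need no sphericity correction), one-sample and
paired t-tests with Cohen's d / bias-corrected Hedges' g.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataError

__all__ = [
    "tally_outcomes",
    "goodman_correct",
    "compute_dprime",
    "compute_criterion",
    "sdt_scores",
    "median_rt",
    "rm_anova_2x2",
    "one_sample_t",
    "paired_t",
    "TTestResult",
    "AnovaEffect",
]


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float
    effect_size: float
    zero_variance: bool = False


class AnovaEffect(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float


# ---------------------------------------------------------------------------
# Tallying
# ---------------------------------------------------------------------------


def _study_time_of_old(trials: pd.DataFrame, old: pd.DataFrame) -> pd.Series:
    study = trials[trials["phase"] == "study"]
    lookup = study.set_index(["participant_id", "stimulus_id"])["presentation_s"]
    idx = pd.MultiIndex.from_frame(old[["participant_id", "stimulus_id"]])
    st = pd.Series(lookup.reindex(idx).to_numpy(), index=old.index, dtype=float)
    if "study_time_s" in old.columns:
        st = st.fillna(pd.to_numeric(old["study_time_s"], errors="coerce"))
    if st.isna().any():
        sid = old.loc[st.isna(), "stimulus_id"].iloc[0]
        raise DataError(f"old face {sid!r} has no known study-phase presentation time")
    return st.astype(int)


def tally_outcomes(trials: pd.DataFrame) -> pd.DataFrame:
    """Hit/miss/FA/CR counts per participant x (study_time, test_time) cell.

    Conserves trials: summed cell counts equal the number of test trials.
    """
    test = trials[trials["phase"] == "test"]
    old = test[test["exposure"] == "old"].copy()
    new = test[test["exposure"] == "new"]
    old["study_time"] = _study_time_of_old(trials, old)

    rows = []
    for (pid, st, tt), grp in old.groupby(["participant_id", "study_time", "presentation_s"]):
        blocks = set(grp["block_index"])
        nn = new[(new["participant_id"] == pid) & (new["block_index"].isin(blocks))]
        hits = int((grp["response"] == "old").sum())
        fas = int((nn["response"] == "old").sum())
        rows.append(
            {
                "participant_id": pid,
                "study_time": int(st),
                "test_time": int(tt),
                "hits": hits,
                "misses": len(grp) - hits,
                "false_alarms": fas,
                "correct_rejections": len(nn) - fas,
                "n_old": len(grp),
                "n_new": len(nn),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rates and SDT indices
# ---------------------------------------------------------------------------


def goodman_correct(count: int, n_trials: int) -> tuple[float, bool]:
    """Proportion with floor/ceiling replacement: 0 -> 1/(2n) and
    n -> 1 - 1/(2n), so the z-transform stays finite.  Returns (rate,
    adjustment_fired)."""
    if n_trials < 1:
        raise DataError("rate undefined for zero trials")
    if not 0 <= count <= n_trials:
        raise DataError(f"count {count} outside [0, {n_trials}]")
    if count == 0:
        return 1.0 / (2 * n_trials), True
    if count == n_trials:
        return 1.0 - 1.0 / (2 * n_trials), True
    return count / n_trials, False


def _check_rate(rate: float, name: str) -> None:
    if not 0.0 < rate < 1.0:
        raise ValueError(f"{name}={rate} is at floor/ceiling; apply a rate correction first")


def compute_dprime(hit_rate: float, fa_rate: float) -> float:
    """d' = z(hit rate) - z(false alarm rate)."""
    _check_rate(hit_rate, "hit_rate")
    _check_rate(fa_rate, "fa_rate")
    return float(stats.norm.ppf(hit_rate) - stats.norm.ppf(fa_rate))


def compute_criterion(hit_rate: float, fa_rate: float) -> float:
    """c = -(z(hit rate) + z(false alarm rate)) / 2; 0 is the neutral
    (ideal-observer) placement."""
    _check_rate(hit_rate, "hit_rate")
    _check_rate(fa_rate, "fa_rate")
    return float(-(stats.norm.ppf(hit_rate) + stats.norm.ppf(fa_rate)) / 2.0)


def sdt_scores(counts: pd.DataFrame) -> pd.DataFrame:
    """Corrected rates, adjustment flags, d' and c for each tallied cell."""
    out = counts.copy()
    hit_rate, fa_rate, hit_adj, fa_adj, dprime, crit = [], [], [], [], [], []
    for _, row in counts.iterrows():
        h, ha = goodman_correct(int(row["hits"]), int(row["n_old"]))
        f, fa = goodman_correct(int(row["false_alarms"]), int(row["n_new"]))
        hit_rate.append(h)
        fa_rate.append(f)
        hit_adj.append(ha)
        fa_adj.append(fa)
        dprime.append(compute_dprime(h, f))
        crit.append(compute_criterion(h, f))
    out["hit_rate"] = hit_rate
    out["fa_rate"] = fa_rate
    out["hit_adjusted"] = hit_adj
    out["fa_adjusted"] = fa_adj
    out["d_prime"] = dprime
    out["criterion_c"] = crit
    return out


def median_rt(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x cell median reaction time over *correct old* trials
    (new faces belong to no study-time condition).  Empty cells yield NaN."""
    test = trials[trials["phase"] == "test"]
    old = test[test["exposure"] == "old"].copy()
    old["study_time"] = _study_time_of_old(trials, old)
    correct = old[old["correct"].astype("boolean").fillna(False)]
    med = (
        correct.groupby(["participant_id", "study_time", "presentation_s"])["rt_ms"]
        .median()
        .rename("median_rt_ms")
        .reset_index()
        .rename(columns={"presentation_s": "test_time"})
    )
    # reindex over all cells present in the design so empty cells appear as NaN
    cells = old.groupby(["participant_id", "study_time", "presentation_s"]).size().index
    full = pd.DataFrame(list(cells), columns=["participant_id", "study_time", "test_time"])
    return full.merge(med, how="left", on=["participant_id", "study_time", "test_time"])


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


def rm_anova_2x2(
    data: pd.DataFrame,
    dv: str,
    factor_a: str,
    factor_b: str,
    subject: str = "participant_id",
) -> dict[str, AnovaEffect]:
    """Two-way fully within-subject ANOVA with two levels per factor,
    computed from sums of squares.  Listwise-complete subjects only.
    Returns effects keyed ``factor_a``, ``factor_b`` and ``"interaction"``.
    """
    wide = data.pivot_table(index=subject, columns=[factor_a, factor_b], values=dv)
    wide = wide.dropna()
    n = len(wide)
    if n < 2:
        raise DataError("rm_anova_2x2 needs at least 2 complete-case participants")
    a_levels = sorted({c[0] for c in wide.columns})
    b_levels = sorted({c[1] for c in wide.columns})
    if len(a_levels) != 2 or len(b_levels) != 2 or wide.shape[1] != 4:
        raise DataError("rm_anova_2x2 requires a complete 2x2 within-subject design")

    y = np.stack(
        [[wide[(a, b)].to_numpy() for b in b_levels] for a in a_levels]
    )  # (2, 2, n)
    grand = y.mean()
    m_a = y.mean(axis=(1, 2))
    m_b = y.mean(axis=(0, 2))
    m_s = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=2)
    m_as = y.mean(axis=1)
    m_bs = y.mean(axis=0)

    def effect(ss_eff, ss_err, df1, df2):
        if ss_err <= 0:
            if ss_eff <= 0:
                return AnovaEffect(0.0, df1, df2, 1.0, 0.0)
            return AnovaEffect(np.inf, df1, df2, 0.0, 1.0)
        f = (ss_eff / df1) / (ss_err / df2)
        p = float(stats.f.sf(f, df1, df2))
        return AnovaEffect(float(f), df1, df2, p, float(ss_eff / (ss_eff + ss_err)))

    ss_a = 2 * n * np.sum((m_a - grand) ** 2)
    ss_as = 2 * np.sum((m_as - m_a[:, None] - m_s[None, :] + grand) ** 2)
    ss_b = 2 * n * np.sum((m_b - grand) ** 2)
    ss_bs = 2 * np.sum((m_bs - m_b[:, None] - m_s[None, :] + grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        y
        - m_ab[:, :, None]
        - m_as[:, None, :]
        - m_bs[None, :, :]
        + m_a[:, None, None]
        + m_b[None, :, None]
        + m_s[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    return {
        factor_a: effect(ss_a, ss_as, 1, n - 1),
        factor_b: effect(ss_b, ss_bs, 1, n - 1),
        "interaction": effect(ss_ab, ss_abs, 1, n - 1),
    }


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """Two-tailed one-sample t-test with Cohen's d."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = len(v)
    if n < 2:
        raise DataError("one_sample_t needs n >= 2")
    sd = v.std(ddof=1)
    if sd == 0:
        if np.isclose(v.mean(), mu0):
            return TTestResult(0.0, n - 1, 1.0, 0.0, True)
        return TTestResult(np.inf * np.sign(v.mean() - mu0), n - 1, 0.0, np.inf, True)
    t, p = stats.ttest_1samp(v, mu0)
    d = (v.mean() - mu0) / sd
    return TTestResult(float(t), n - 1, float(p), float(d), False)


def paired_t(a, b) -> TTestResult:
    """Two-tailed paired t-test with bias-corrected Hedges' g.  Pairs with a
    missing value in either member are dropped."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DataError("paired_t requires equal-length samples")
    keep = ~(np.isnan(a) | np.isnan(b))
    diff = a[keep] - b[keep]
    n = len(diff)
    if n < 2:
        raise DataError("paired_t needs n >= 2 complete pairs")
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.isclose(diff.mean(), 0):
            return TTestResult(0.0, n - 1, 1.0, 0.0, True)
        return TTestResult(np.inf * np.sign(diff.mean()), n - 1, 0.0, np.inf, True)
    t, p = stats.ttest_rel(a[keep], b[keep])
    d = diff.mean() / sd
    g = d * (1.0 - 3.0 / (4.0 * (n - 1) - 1.0))
    return TTestResult(float(t), n - 1, float(p), float(g), False)
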