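"""SDT scoring, rate correction, tallying, and group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gazecontrast import behavior, simulate
from gazecontrast.behavior import (
    compute_criterion,
    compute_dprime,
    goodman_correct,
    median_rt,
    one_sample_t,
    paired_t,
    rm_anova_2x2,
    sdt_scores,
    tally_outcomes,
)
from gazecontrast.data import DataError


class TestGoodman:
    @pytest.mark.parametrize(
        "count, n, rate, adjusted",
        [
            (6, 12, 0.5, False),
            (12, 12, 23 / 24, True),
            (0, 12, 1 / 24, True),
            (1, 12, 1 / 12, False),
            (11, 12, 11 / 12, False),
        ],
    )
    def test_correction_values(self, count, n, rate, adjusted):
        got, flag = goodman_correct(count, n)
        assert got == pytest.approx(rate, abs=1e-15)
        assert flag is adjusted

    def test_zero_trials_rejected(self):
        with pytest.raises(DataError):
            goodman_correct(0, 0)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(1, 500), st.integers(1, 500))
    def test_never_fires_strictly_inside(self, n, k):
        count = min(k, n - 1) if n > 1 else 1
        count = max(1, count)
        _, flag = goodman_correct(count, n)
        assert flag is (count == n)


class TestSdtIndices:
    def test_dprime_one_from_standard_quantiles(self):
        # Phi(0.5) = 0.69146: symmetric rates an SD apart give d' = 1, c = 0
        assert compute_dprime(0.69146, 0.30854) == pytest.approx(1.0, abs=1e-4)
        assert compute_criterion(0.69146, 0.30854) == pytest.approx(0.0, abs=1e-6)

    def test_equal_rates_give_zero_dprime(self):
        assert compute_dprime(0.3, 0.3) == 0.0

    def test_criterion_matches_quantile_table(self):
        assert compute_criterion(0.9, 0.9) == pytest.approx(-stats.norm.ppf(0.9), abs=1e-9)

    @pytest.mark.parametrize("rate", [0.0, 1.0])
    def test_extreme_rates_instruct_correction(self, rate):
        with pytest.raises(ValueError, match="correction"):
            compute_dprime(rate, 0.5)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(0.001, 0.999))
    def test_criterion_zero_when_fa_complements_hit(self, hit):
        assert compute_criterion(hit, 1.0 - hit) == pytest.approx(0.0, abs=1e-9)


class TestTally:
    @staticmethod
    def _manual_trials():
        """One participant, one study block (short), one test block pairing
        12 old (all responded old) with 12 new (3 responded old)."""
        rows = []
        for i in range(12):
            rows.append(
                dict(participant_id="p0", block_index=1, trial_index=i + 1, phase="study",
                     presentation_s=1, stimulus_id=f"s{i:03d}", exposure="study",
                     start_side="left", response="none", rt_ms=np.nan, correct=np.nan,
                     trial_id=f"p0:{i+1:03d}")
            )
        for i in range(24):
            is_old = i < 12
            resp = "old" if (is_old or i < 15) else "new"
            rows.append(
                dict(participant_id="p0", block_index=3, trial_index=13 + i, phase="test",
                     presentation_s=5, stimulus_id=f"s{i:03d}" if is_old else f"n{i:03d}",
                     exposure="old" if is_old else "new", start_side="left", response=resp,
                     rt_ms=1000.0, correct=(resp == "old") == is_old, trial_id=f"p0:{13+i:03d}")
            )
        return pd.DataFrame(rows)

    def test_manual_counts(self):
        counts = tally_outcomes(self._manual_trials())
        assert len(counts) == 1
        row = counts.iloc[0]
        assert (row.hits, row.misses, row.false_alarms, row.correct_rejections) == (12, 0, 3, 9)
        assert (row.study_time, row.test_time) == (1, 5)

    def test_unknown_study_time_is_data_error(self):
        trials = self._manual_trials()
        trials = trials[trials.phase == "test"]  # drop study phase entirely
        with pytest.raises(DataError, match="study-phase presentation time"):
            tally_outcomes(trials)

    def test_full_design_counts_and_conservation(self, small_experiment):
        ds, _, cfg = small_experiment
        counts = tally_outcomes(ds.trials)
        half = cfg.trials_per_block // 2
        assert (counts["n_old"] == half).all() and (counts["n_new"] == half).all()
        n_test = (ds.trials.phase == "test").sum()
        total = (counts.hits + counts.misses + counts.false_alarms + counts.correct_rejections).sum()
        assert total == n_test

    def test_scores_attach_rates_and_flags(self, small_experiment):
        ds, _, _ = small_experiment
        scores = sdt_scores(tally_outcomes(ds.trials))
        assert ((scores.hit_rate > 0) & (scores.hit_rate < 1)).all()
        assert np.isfinite(scores.d_prime).all() and np.isfinite(scores.criterion_c).all()
        fired = scores.hit_adjusted | scores.fa_adjusted
        at_edge = (scores.hits == scores.n_old) | (scores.false_alarms == 0)
        at_edge |= (scores.hits == 0) | (scores.false_alarms == scores.n_new)
        assert (fired == at_edge).all()


class TestMedianRt:
    def test_median_of_correct_old_trials(self):
        trials = TestTally._manual_trials()
        trials.loc[trials.exposure == "old", "rt_ms"] = (
            [1000.0, 1200.0, 5000.0] + [1200.0] * 9
        )
        out = median_rt(trials)
        assert out["median_rt_ms"].iloc[0] == 1200.0

    def test_empty_cell_yields_missing(self):
        trials = TestTally._manual_trials()
        trials.loc[trials.exposure == "old", "response"] = "new"  # all misses
        trials.loc[trials.exposure == "old", "correct"] = False
        out = median_rt(trials)
        assert out["median_rt_ms"].isna().all()


class TestAnova:
    @staticmethod
    def _long(values: np.ndarray) -> pd.DataFrame:
        n = values.shape[0]
        rows = []
        for s in range(n):
            for i, a in enumerate((1, 5)):
                for j, b in enumerate((1, 5)):
                    rows.append(
                        dict(participant_id=f"p{s}", study_time=a, test_time=b, dv=values[s, i, j])
                    )
        return pd.DataFrame(rows)

    def test_identical_cells_give_zero_f(self):
        vals = np.tile(np.random.default_rng(0).normal(size=(8, 1, 1)), (1, 2, 2))
        eff = rm_anova_2x2(self._long(vals), "dv", "study_time", "test_time")
        for e in eff.values():
            assert e.F == 0.0 and e.p == 1.0

    def test_pure_main_effect_without_noise_overflows_gracefully(self):
        vals = np.zeros((6, 2, 2))
        vals[:, 1, :] = 1.0  # additive constant on one factor level
        eff = rm_anova_2x2(self._long(vals), "dv", "study_time", "test_time")
        assert eff["study_time"].F == np.inf and eff["study_time"].p == 0.0
        assert eff["interaction"].F == 0.0

    def test_matches_pingouin_on_random_data(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        data = self._long(rng.normal(size=(12, 2, 2)))
        ours = rm_anova_2x2(data, "dv", "study_time", "test_time")
        ref = pingouin.rm_anova(
            data=data, dv="dv", within=["study_time", "test_time"], subject="participant_id"
        )
        for _, row in ref.iterrows():
            name = {"study_time": "study_time", "test_time": "test_time",
                    "study_time * test_time": "interaction"}[row["Source"]]
            assert ours[name].F == pytest.approx(row["F"], rel=1e-8)
            assert ours[name].p == pytest.approx(row["p_unc"], rel=1e-6)

    def test_insufficient_participants_rejected(self):
        with pytest.raises(DataError):
            rm_anova_2x2(self._long(np.zeros((1, 2, 2))), "dv", "study_time", "test_time")


class TestTTests:
    def test_constant_at_mu0_gives_t_zero(self):
        res = one_sample_t([2.0, 2.0, 2.0], mu0=2.0)
        assert res.t == 0.0 and res.p == 1.0 and res.zero_variance

    def test_identical_pairs_give_t_zero(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.zero_variance

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(42)
        a, b = rng.normal(size=10), rng.normal(size=10)
        res = paired_t(a, b)
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        assert res.t == pytest.approx(t_manual, abs=1e-10)
        g_manual = (d.mean() / d.std(ddof=1)) * (1 - 3 / (4 * 9 - 1))
        assert res.effect_size == pytest.approx(g_manual, abs=1e-12)
        one = one_sample_t(a, mu0=0.2)
        t1 = (a.mean() - 0.2) / (a.std(ddof=1) / np.sqrt(10))
        assert one.t == pytest.approx(t1, abs=1e-10)
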