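"""Permutation machinery: relabelling, observed contrasts, Monte Carlo vs
exact enumeration, FDR, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from gazecontrast import density
from gazecontrast.data import ConfigError, DataError, Dataset
from gazecontrast.density import GridSpec, fixation_density_2d
from gazecontrast.permutation import (
    ContrastSpec,
    _assemble,
    _chunk_coefs,
    apply_fdr,
    exact_enumeration_contrast,
    fdr_mask,
    monte_carlo_contrast,
    observed_contrast,
    permute_labels,
    render_significance,
)
from helpers import tiny_contrast_dataset

STUDY = {"phase": "study"}
TEST = {"phase": "test"}


def spec(**kw) -> ContrastSpec:
    base = dict(condition_a=STUDY, condition_b=TEST, ordinal=2, n_iterations=500, seed=0)
    base.update(kw)
    return ContrastSpec(**base)


class TestRelabelling:
    def test_permute_labels_preserves_counts(self):
        rng = np.random.default_rng(0)
        labels = np.array(["a"] * 3 + ["b"] * 5)
        out = permute_labels(labels, rng)
        assert sorted(out) == sorted(labels)

    def test_chunk_coefs_preserve_counts_every_draw(self):
        ds = tiny_contrast_dataset(n_participants=3, n_per_condition=3)
        blocks, _ = _assemble(ds, spec())
        coefs = _chunk_coefs(blocks, spec(), chunk_index=0, chunk_size=200)
        pos = 0
        for b in blocks:
            n = b.n_a + b.n_b
            sub = coefs[pos : pos + n]
            assert ((sub > 0).sum(axis=0) == b.n_a).all()
            pos += n

    def test_relabelling_frequencies_uniform(self):
        """Each fixation receives label a with frequency n_a/(n_a+n_b)."""
        ds = tiny_contrast_dataset(n_participants=1, n_per_condition=3)
        blocks, _ = _assemble(ds, spec())
        n_draws = 10_000
        coefs = np.concatenate(
            [_chunk_coefs(blocks, spec(), ci, 1000) for ci in range(10)], axis=1
        )
        freq = (coefs > 0).mean(axis=1)
        p = 0.5
        tol = 3 * np.sqrt(p * (1 - p) / n_draws)
        assert (np.abs(freq - p) <= tol).all()

    def test_empty_condition_a_identity_on_b(self, small_grid):
        ds = tiny_contrast_dataset(n_participants=2, n_per_condition=2)
        # remove all of condition a's fixations for one participant
        fx = ds.fixations
        drop = (fx.participant_id == "p0") & fx.trial_id.str.contains(":a")
        ds = Dataset(ds.trials, fx[~drop], ds.layouts)
        blocks, _ = _assemble(ds, spec())
        b0 = [b for b in blocks if b.pid == "p0"][0]
        assert b0.n_a == 0
        coefs = _chunk_coefs([b0], spec(), 0, 50)
        assert (coefs < 0).all()  # relabelling is the identity on b

    def test_participant_without_fixations_skipped(self, small_grid):
        ds = tiny_contrast_dataset(n_participants=2, n_per_condition=2)
        fx = ds.fixations[ds.fixations.participant_id != "p1"]
        ds = Dataset(ds.trials, fx, ds.layouts)
        res = monte_carlo_contrast(ds, spec(n_iterations=50), small_grid)
        assert res.skipped_participants == ["p1"] and res.n_participants == 1


class TestObserved:
    def test_identical_conditions_zero_difference(self, small_grid):
        ds = tiny_contrast_dataset(n_participants=2, n_per_condition=3)
        fx = ds.fixations.copy()
        # force condition b's fixations to coincide with a's
        a_mask = fx.trial_id.str.contains(":a")
        fx.loc[~a_mask, ["x", "y"]] = fx.loc[a_mask, ["x", "y"]].to_numpy()
        ds = Dataset(ds.trials, fx, ds.layouts)
        diff, prof = observed_contrast(ds, spec(), small_grid)
        assert np.abs(diff).max() < 1e-12 and np.abs(prof).max() < 1e-12

    def test_swapping_conditions_negates(self, small_grid):
        ds = tiny_contrast_dataset()
        d1, p1 = observed_contrast(ds, spec(), small_grid)
        d2, p2 = observed_contrast(
            ds, spec(condition_a=TEST, condition_b=STUDY), small_grid
        )
        np.testing.assert_allclose(d1, -d2, atol=1e-14)
        np.testing.assert_allclose(p1, -p2, atol=1e-13)

    def test_two_fixation_instance_matches_manual_gaussians(self, small_grid):
        ds = tiny_contrast_dataset(n_participants=1, n_per_condition=1)
        fx = ds.fixations
        xa, ya = fx[fx.trial_id.str.contains(":a")][["x", "y"]].iloc[0]
        xb, yb = fx[fx.trial_id.str.contains(":b")][["x", "y"]].iloc[0]
        diff, prof = observed_contrast(ds, spec(scale_a=1.0, scale_b=0.5), small_grid)
        ka = fixation_density_2d([xa], [ya], small_grid).values
        kb = fixation_density_2d([xb], [yb], small_grid).values
        manual = ka - 0.5 * kb
        np.testing.assert_allclose(diff, manual, atol=1e-10)
        np.testing.assert_allclose(prof, manual.sum(axis=1), atol=1e-10)

    def test_overlapping_selectors_rejected(self, small_grid):
        ds = tiny_contrast_dataset()
        with pytest.raises(ConfigError, match="disjoint"):
            observed_contrast(ds, spec(condition_b=STUDY), small_grid)


class TestMonteCarlo:
    def test_deterministic_under_seed_and_row_order(self, small_grid):
        ds = tiny_contrast_dataset(n_participants=3, n_per_condition=3)
        res1 = monte_carlo_contrast(ds, spec(), small_grid)
        shuffled = Dataset(
            ds.trials.sample(frac=1, random_state=1).reset_index(drop=True),
            ds.fixations.sample(frac=1, random_state=2).reset_index(drop=True),
            ds.layouts,
        )
        res2 = monte_carlo_contrast(shuffled, spec(), small_grid)
        np.testing.assert_allclose(res1.p_profile, res2.p_profile, atol=0)
        np.testing.assert_allclose(res1.observed_profile, res2.observed_profile, atol=1e-12)

    def test_p_bounds_and_sign_convention(self, small_grid):
        ds = tiny_contrast_dataset()
        res = monte_carlo_contrast(ds, spec(n_iterations=200), small_grid)
        assert (res.p_profile >= 1 / 200 - 1e-15).all() and (res.p_profile <= 1.0).all()
        assert (res.p_profile[res.observed_profile == 0] == 1.0).all()

    def test_profiles_equal_rowsums_of_2d_iterations(self, small_grid):
        """Profile null iterations are the exact horizontal sums of the 2D
        null iterations from the same relabelling stream."""
        ds = tiny_contrast_dataset(n_participants=2, n_per_condition=2)
        res = monte_carlo_contrast(
            ds, spec(n_iterations=100), small_grid, maps="both", keep_iterations=True
        )
        from_2d = res.null_grids.reshape(small_grid.ny, small_grid.nx, -1).sum(axis=1)
        np.testing.assert_allclose(from_2d, res.null_profiles, atol=1e-12)

    def test_injected_shift_localizes_minimum_p(self, small_grid):
        """With condition b shifted down 1 degree, the smallest supported
        p-values lie on the contrast lobes, not in the far tail."""
        ds = tiny_contrast_dataset(n_participants=6, n_per_condition=8, shift_b=1.0, seed=5)
        res = monte_carlo_contrast(ds, spec(n_iterations=1000), small_grid)
        dens = res.profile_a + res.profile_b
        sup = dens > 0.05 * dens.max()
        best = np.argmin(np.where(sup, res.p_profile, 2.0))
        y = small_grid.y_centers[best]
        assert -4.5 < y < 0.5  # within the fixation cloud, around the lobes

    def test_small_iteration_count_warns_about_q(self, small_grid):
        ds = tiny_contrast_dataset()
        with pytest.warns(UserWarning, match="cannot resolve"):
            monte_carlo_contrast(ds, spec(n_iterations=10, q=0.05), small_grid)

    def test_no_participants_with_fixations_is_error(self, small_grid):
        ds = tiny_contrast_dataset()
        empty = Dataset(ds.trials, ds.fixations.iloc[0:0], ds.layouts)
        with pytest.raises(DataError):
            monte_carlo_contrast(empty, spec(), small_grid)


class TestExactEnumeration:
    def test_single_pair_probabilities(self, small_grid):
        """One participant, one fixation per condition: two assignments, so
        directional p is 0.5 (all supported rows are one of two values) or 1."""
        ds = tiny_contrast_dataset(n_participants=1, n_per_condition=1, shift_b=2.0)
        res = exact_enumeration_contrast(ds, spec(), small_grid)
        assert res.n_iterations == 2
        assert set(np.round(res.p_profile, 12)) <= {0.5, 1.0}

    def test_symmetric_configuration_p_one_at_axis(self):
        """Two coincident fixations: every relabelling gives a zero
        difference, so p = 1 everywhere."""
        ds = tiny_contrast_dataset(n_participants=1, n_per_condition=1)
        fx = ds.fixations.copy()
        fx[["x", "y"]] = [[3.0, -2.0], [3.0, -2.0]]
        ds = Dataset(ds.trials, fx, ds.layouts)
        grid = GridSpec(x_min=0, x_max=6.4, y_min=-5.2, y_max=1.2, resolution=0.1)
        res = exact_enumeration_contrast(ds, spec(), grid)
        assert (res.p_profile == 1.0).all()

    def test_combinatorial_bound_refused_with_count(self, small_grid):
        ds = tiny_contrast_dataset(n_participants=4, n_per_condition=12)
        with pytest.raises(DataError, match="assignments"):
            exact_enumeration_contrast(ds, spec(), small_grid)

    def test_monte_carlo_within_binomial_tolerance(self, small_grid):
        ds = tiny_contrast_dataset(n_participants=2, n_per_condition=3, seed=3)
        ex = exact_enumeration_contrast(ds, spec(), small_grid)
        mc = monte_carlo_contrast(ds, spec(n_iterations=4000), small_grid)
        tol = 3 * np.sqrt(ex.p_profile * (1 - ex.p_profile) / 4000) + 1 / 4000
        assert (np.abs(mc.p_profile - ex.p_profile) <= tol).mean() > 0.99


class TestFdr:
    def test_all_ones_empty_masks(self):
        masks = fdr_mask({"m1": np.ones(50), "m2": np.ones((5, 5))})
        assert not masks["m1"].any() and not masks["m2"].any()
        assert masks["m2"].shape == (5, 5)

    def test_bh_step_up_hand_computed(self):
        """10,000 pixels, one at the permutation floor 1/39000, the rest at 1:
        BH compares the smallest p against q/m = 5e-6 < 1/39000... so instead
        use q such that the pixel passes: with the rest at 0.9 the smallest p
        is compared to 0.05 * 1/10000 = 5e-6 — hand computation shows the
        single extreme pixel is flagged only when p <= q k / m."""
        m = 10_000
        p = np.full(m, 0.9)
        p[1234] = 1 / 39_000
        masks = fdr_mask({"m": p}, q=0.05)
        # 1/39000 = 2.56e-5 > 0.05/10000 = 5e-6 -> not flagged
        assert not masks["m"].any()
        masks = fdr_mask({"m": p}, q=0.3)
        # 1/39000 < 0.3/10000 = 3e-5 -> flagged, and only that pixel
        assert masks["m"][1234] and masks["m"].sum() == 1

    def test_family_pooling_changes_threshold(self, small_grid):
        """Pooling a second all-null map into the family makes the BH
        cutoff stricter for the first map."""
        pa = np.full(100, 1.0)
        pa[:3] = 0.001  # BH step-up: p_(3) = 0.001 <= 0.05 * 3/100
        alone = fdr_mask({"a": pa}, q=0.05)["a"].sum()
        pooled = fdr_mask({"a": pa, "b": np.ones(900)}, q=0.05)["a"].sum()
        assert alone == 3 and pooled == 0

    def test_apply_fdr_groups_by_family(self, small_grid):
        ds = tiny_contrast_dataset(n_participants=3, n_per_condition=4)
        r1 = monte_carlo_contrast(ds, spec(family_id="f1"), small_grid)
        r2 = monte_carlo_contrast(ds, spec(family_id="f1", seed=1), small_grid)
        r3 = monte_carlo_contrast(ds, spec(family_id="f2"), small_grid)
        apply_fdr([r1, r2, r3], q=0.05)
        for r in (r1, r2, r3):
            assert r.mask_profile is not None
            assert r.mask_profile.shape == r.p_profile.shape


class TestRendering:
    def test_curves_scaled_to_unit_max_and_bands(self, small_grid):
        ds = tiny_contrast_dataset(n_participants=3, n_per_condition=4)
        res = monte_carlo_contrast(ds, spec(), small_grid)
        res.mask_profile = np.zeros(small_grid.ny, dtype=bool)
        res.mask_profile[10:15] = True
        fig = render_significance(res)
        ax = fig.axes[0]
        top = max(line.get_xdata().max() for line in ax.lines)
        assert top == pytest.approx(1.0, abs=1e-12)
        assert len(ax.patches) == 1  # one contiguous highlight band
        import matplotlib.pyplot as plt

        plt.close(fig)

    def test_empty_mask_no_bands(self, small_grid):
        ds = tiny_contrast_dataset(n_participants=2, n_per_condition=2)
        res = monte_carlo_contrast(ds, spec(), small_grid)
        res.mask_profile = np.zeros(small_grid.ny, dtype=bool)
        fig = render_significance(res)
        assert len(fig.axes[0].patches) == 0
        import matplotlib.pyplot as plt

        plt.close(fig)
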