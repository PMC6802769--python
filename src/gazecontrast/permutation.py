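"""Monte Carlo permutation contrasts on fixation-density maps and profiles.

Null hypothesis: within each participant, fixation locations of the
analysed ordinal are exchangeable between the two contrasted conditions.
Each iteration relabels every participant's pooled fixations uniformly at
random (preserving the per-condition counts), rebuilds the scaled group
difference map, and the collection of iterations forms the null
distribution.  Vertical-profile iterations are the exact horizontal sums of
the 2D iterations: density kernels are separable, so each fixation's
profile contribution equals the row sum of its 2D kernel, and the same
relabelling coefficients are applied to both bases (one shared RNG stream,
never re-simulated).

p-values are directional and pixel-wise: for an observed positive
difference, the fraction of iterations at least as large; for a negative
one, the fraction at least as small; zero observed difference gives p = 1.
The estimator is the pure count / n_iterations, floored at 1/n_iterations.
Significance is controlled by Benjamini-Hochberg FDR pooled over all pixels
of all maps sharing a family.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .data import ConfigError, DataError, Dataset, select_trials
from .density import GridSpec, profile_basis, _kernel_1d, _TRUNC_SD

__all__ = [
    "ContrastSpec",
    "PermutationResult",
    "permute_labels",
    "observed_contrast",
    "monte_carlo_contrast",
    "exact_enumeration_contrast",
    "fdr_mask",
    "apply_fdr",
    "render_significance",
]


@dataclass(frozen=True)
class ContrastSpec:
    """Specification of one permutation contrast.

    ``condition_a`` / ``condition_b`` are trial selectors (column -> value);
    they must select disjoint trial sets.  ``scale_a`` / ``scale_b`` rescale
    the per-participant condition maps before differencing (e.g. 0.5 on a
    pooled old+new test condition with twice the trials of study).
    ``family_id`` groups maps that share a single FDR correction.
    """

    condition_a: Mapping[str, object]
    condition_b: Mapping[str, object]
    ordinal: int = 2
    scale_a: float = 1.0
    scale_b: float = 1.0
    n_iterations: int = 39_000
    seed: int = 0
    family_id: str = "default"
    q: float = 0.05
    two_sided: bool = False
    label: str = ""

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if self.scale_a <= 0 or self.scale_b <= 0:
            raise ConfigError("scales must be positive")


@dataclass
class PermutationResult:
    spec: ContrastSpec
    grid: GridSpec
    observed_profile: np.ndarray
    profile_a: np.ndarray
    profile_b: np.ndarray
    p_profile: np.ndarray
    sign_profile: np.ndarray
    n_iterations: int
    seed: int
    n_participants: int
    skipped_participants: list[str] = field(default_factory=list)
    observed_grid: np.ndarray | None = None
    p_grid: np.ndarray | None = None
    sign_grid: np.ndarray | None = None
    null_profiles: np.ndarray | None = None  # (ny, n_iterations) when retained
    null_grids: np.ndarray | None = None  # (ny*nx, n_iterations) when retained
    mask_profile: np.ndarray | None = None
    mask_grid: np.ndarray | None = None
    exact: bool = False


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    pid: str
    n_a: int
    n_b: int
    x: np.ndarray  # condition-a fixations first, then condition-b
    y: np.ndarray


def _assemble(dataset: Dataset, spec: ContrastSpec) -> tuple[list[_Block], list[str]]:
    ta = select_trials(dataset.trials, spec.condition_a)
    tb = select_trials(dataset.trials, spec.condition_b)
    overlap = set(ta["trial_id"]) & set(tb["trial_id"])
    if overlap:
        raise ConfigError(
            f"contrast conditions overlap on {len(overlap)} trial(s); selectors must be disjoint"
        )
    fx = dataset.fixations
    fx = fx[fx["ordinal"] == spec.ordinal]
    fa = fx[fx["trial_id"].isin(set(ta["trial_id"]))]
    fb = fx[fx["trial_id"].isin(set(tb["trial_id"]))]
    blocks: list[_Block] = []
    skipped: list[str] = []
    pids = sorted(set(ta["participant_id"]) | set(tb["participant_id"]))
    sort_cols = ["trial_id", "ordinal", "x", "y"]
    for pid in pids:
        # deterministic within-participant order so results are invariant to
        # the row order of the input tables
        pa = fa[fa["participant_id"] == pid].sort_values(sort_cols, kind="mergesort")
        pb = fb[fb["participant_id"] == pid].sort_values(sort_cols, kind="mergesort")
        if len(pa) + len(pb) == 0:
            skipped.append(pid)
            continue
        blocks.append(
            _Block(
                pid=pid,
                n_a=len(pa),
                n_b=len(pb),
                x=np.concatenate([pa["x"].to_numpy(float), pb["x"].to_numpy(float)]),
                y=np.concatenate([pa["y"].to_numpy(float), pb["y"].to_numpy(float)]),
            )
        )
    if not blocks:
        raise DataError("no participant has fixations in either contrasted condition")
    return blocks, skipped


def permute_labels(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random relabelling preserving per-condition counts."""
    labels = np.asarray(labels)
    return labels[rng.permutation(len(labels))]


def _base_coefs(blocks: Sequence[_Block], spec: ContrastSpec) -> np.ndarray:
    p = len(blocks)
    parts = [
        np.concatenate(
            [np.full(b.n_a, spec.scale_a / p), np.full(b.n_b, -spec.scale_b / p)]
        )
        for b in blocks
    ]
    return np.concatenate(parts)


def _chunk_coefs(
    blocks: Sequence[_Block], spec: ContrastSpec, chunk_index: int, chunk_size: int
) -> np.ndarray:
    """Relabelling coefficients for one chunk of iterations.

    Deterministic in (spec.seed, chunk_index), independently per
    participant: within each participant the pooled fixations are assigned
    to condition a uniformly at random with counts preserved.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 2, int(chunk_index)]))
    p = len(blocks)
    parts = []
    for b in blocks:
        n = b.n_a + b.n_b
        r = rng.random((n, chunk_size))
        order = np.argsort(r, axis=0)
        mask = np.zeros((n, chunk_size), dtype=bool)
        if b.n_a > 0:
            np.put_along_axis(mask, order[: b.n_a], True, axis=0)
        parts.append(np.where(mask, spec.scale_a / p, -spec.scale_b / p))
    return np.concatenate(parts, axis=0)


def _basis_2d(x: np.ndarray, y: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Per-fixation flattened 2D kernel contributions, shape (n, ny*nx)."""
    sigma, res = grid.sigma, grid.resolution
    radius = _TRUNC_SD * sigma
    xc, yc = grid.x_centers, grid.y_centers
    out = np.zeros((len(x), grid.ny * grid.nx))
    for k, (xi, yi) in enumerate(zip(x, y)):
        i0 = max(0, int(np.floor((yi - radius - grid.y_min) / res)))
        i1 = min(grid.ny, int(np.ceil((yi + radius - grid.y_min) / res)) + 1)
        j0 = max(0, int(np.floor((xi - radius - grid.x_min) / res)))
        j1 = min(grid.nx, int(np.ceil((xi + radius - grid.x_min) / res)) + 1)
        if i0 >= i1 or j0 >= j1:
            continue
        patch = np.outer(_kernel_1d(yc[i0:i1], yi, sigma), _kernel_1d(xc[j0:j1], xi, sigma))
        flat = out[k].reshape(grid.ny, grid.nx)
        flat[i0:i1, j0:j1] = patch
    return out


_MAX_BASIS_ELEMENTS = 80_000_000  # guards the dense (n_fixations x n_pixels) basis


def _weighted_density(x, y, coef, grid: GridSpec) -> np.ndarray:
    """Coefficient-weighted sum of fixation kernels on the grid (ny, nx);
    patch accumulation, no dense per-fixation basis."""
    sigma, res = grid.sigma, grid.resolution
    radius = _TRUNC_SD * sigma
    xc, yc = grid.x_centers, grid.y_centers
    out = np.zeros(grid.shape)
    for xi, yi, w in zip(x, y, coef):
        i0 = max(0, int(np.floor((yi - radius - grid.y_min) / res)))
        i1 = min(grid.ny, int(np.ceil((yi + radius - grid.y_min) / res)) + 1)
        j0 = max(0, int(np.floor((xi - radius - grid.x_min) / res)))
        j1 = min(grid.nx, int(np.ceil((xi + radius - grid.x_min) / res)) + 1)
        if i0 >= i1 or j0 >= j1:
            continue
        out[i0:i1, j0:j1] += w * np.outer(
            _kernel_1d(yc[i0:i1], yi, sigma), _kernel_1d(xc[j0:j1], xi, sigma)
        )
    return out


def _directional_p(obs, cnt_ge, cnt_le, n_iter, two_sided):
    p = np.ones_like(obs, dtype=float)
    pos = obs > 0
    neg = obs < 0
    p[pos] = cnt_ge[pos] / n_iter
    p[neg] = cnt_le[neg] / n_iter
    if two_sided:
        p = np.minimum(1.0, 2.0 * p)
        p[obs == 0] = 1.0
    p = np.clip(p, 1.0 / n_iter, 1.0)
    p[obs == 0] = 1.0
    return p


# ---------------------------------------------------------------------------
# Observed contrast
# ---------------------------------------------------------------------------


def observed_contrast(
    dataset: Dataset, spec: ContrastSpec, grid: GridSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled group difference: mean over participants of
    (scale_a * map_a - scale_b * map_b).  Returns (grid (ny, nx), profile)."""
    blocks, _ = _assemble(dataset, spec)
    coef = _base_coefs(blocks, spec)
    x = np.concatenate([b.x for b in blocks])
    y = np.concatenate([b.y for b in blocks])
    diff = _weighted_density(x, y, coef, grid)
    return diff, diff.sum(axis=1)


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------


def monte_carlo_contrast(
    dataset: Dataset,
    spec: ContrastSpec,
    grid: GridSpec | None = None,
    maps: str = "profile",
    keep_iterations: bool = False,
    chunk_size: int = 500,
) -> PermutationResult:
    """Run the permutation contrast.

    ``maps``: ``"profile"`` computes vertical-profile p-values only (fast
    matmul path); ``"2d"`` or ``"both"`` additionally computes pixel-wise
    p-values on the 2D map from the same relabelling stream.
    """
    if maps not in ("profile", "2d", "both"):
        raise ConfigError("maps must be one of 'profile', '2d', 'both'")
    grid = grid or GridSpec()
    if 1.0 / spec.n_iterations > spec.q:
        warnings.warn(
            f"n_iterations={spec.n_iterations} cannot resolve p below q={spec.q}",
            stacklevel=2,
        )
    blocks, skipped = _assemble(dataset, spec)
    x = np.concatenate([b.x for b in blocks])
    y = np.concatenate([b.y for b in blocks])
    n_fix = len(x)

    prof_basis = profile_basis(x, y, grid)
    coef0 = _base_coefs(blocks, spec)
    obs_prof = coef0 @ prof_basis

    want_2d = maps in ("2d", "both")
    basis2d = None
    if want_2d:
        if n_fix * grid.ny * grid.nx > _MAX_BASIS_ELEMENTS:
            raise ConfigError(
                "2D permutation basis exceeds the memory guard; use a coarser "
                "grid, a smaller extent, or profile maps"
            )
        basis2d = _basis_2d(x, y, grid)
        obs_grid = coef0 @ basis2d
    else:
        obs_grid = _weighted_density(x, y, coef0, grid).ravel()

    n_iter = spec.n_iterations
    # Ties between permuted and observed statistics are exact in theory (the
    # identity relabelling reproduces the observed map) but only approximate
    # in floating point across different summation orders; count them as
    # ties within a scale-relative tolerance so p-values do not depend on
    # evaluation order.
    tol_p = 1e-9 * max(np.abs(obs_prof).max(), 1e-300)
    tol_g = 1e-9 * max(np.abs(obs_grid).max(), 1e-300)
    cnt_ge_p = np.zeros(grid.ny)
    cnt_le_p = np.zeros(grid.ny)
    cnt_ge_g = np.zeros(grid.ny * grid.nx) if want_2d else None
    cnt_le_g = np.zeros(grid.ny * grid.nx) if want_2d else None
    kept_prof = [] if keep_iterations else None
    kept_grid = [] if (keep_iterations and want_2d) else None

    n_chunks = math.ceil(n_iter / chunk_size)
    for ci in range(n_chunks):
        size = min(chunk_size, n_iter - ci * chunk_size)
        coefs = _chunk_coefs(blocks, spec, ci, size)
        null_prof = prof_basis.T @ coefs  # (ny, size)
        cnt_ge_p += (null_prof >= (obs_prof - tol_p)[:, None]).sum(axis=1)
        cnt_le_p += (null_prof <= (obs_prof + tol_p)[:, None]).sum(axis=1)
        if kept_prof is not None:
            kept_prof.append(null_prof)
        if want_2d:
            null_grid = basis2d.T @ coefs  # (ny*nx, size)
            cnt_ge_g += (null_grid >= (obs_grid - tol_g)[:, None]).sum(axis=1)
            cnt_le_g += (null_grid <= (obs_grid + tol_g)[:, None]).sum(axis=1)
            if kept_grid is not None:
                kept_grid.append(null_grid)

    p_prof = _directional_p(obs_prof, cnt_ge_p, cnt_le_p, n_iter, spec.two_sided)

    prof_a, prof_b = _condition_profiles(blocks, spec, prof_basis)
    result = PermutationResult(
        spec=spec,
        grid=grid,
        observed_profile=obs_prof,
        profile_a=prof_a,
        profile_b=prof_b,
        p_profile=p_prof,
        sign_profile=np.sign(obs_prof),
        n_iterations=n_iter,
        seed=spec.seed,
        n_participants=len(blocks),
        skipped_participants=skipped,
        observed_grid=obs_grid.reshape(grid.ny, grid.nx),
        exact=False,
    )
    if want_2d:
        result.p_grid = _directional_p(obs_grid, cnt_ge_g, cnt_le_g, n_iter, spec.two_sided).reshape(
            grid.ny, grid.nx
        )
        result.sign_grid = np.sign(obs_grid).reshape(grid.ny, grid.nx)
    if kept_prof is not None:
        result.null_profiles = np.concatenate(kept_prof, axis=1)
    if kept_grid is not None:
        result.null_grids = np.concatenate(kept_grid, axis=1)
    return result


def _condition_profiles(blocks, spec, prof_basis):
    """Group-average scaled profiles of each condition (for rendering)."""
    p = len(blocks)
    ca = np.concatenate(
        [
            np.concatenate([np.full(b.n_a, spec.scale_a / p), np.zeros(b.n_b)])
            for b in blocks
        ]
    )
    cb = np.concatenate(
        [
            np.concatenate([np.zeros(b.n_a), np.full(b.n_b, spec.scale_b / p)])
            for b in blocks
        ]
    )
    return ca @ prof_basis, cb @ prof_basis


# ---------------------------------------------------------------------------
# Exact enumeration (test oracle)
# ---------------------------------------------------------------------------

_ENUM_BOUND = 1_000_000


def exact_enumeration_contrast(
    dataset: Dataset,
    spec: ContrastSpec,
    grid: GridSpec | None = None,
    maps: str = "profile",
    block_size: int | None = None,
) -> PermutationResult:
    """Exhaustive enumeration of all within-participant relabellings.

    Exact directional p per pixel; refuses when the total number of label
    assignments across participants exceeds one million.
    """
    grid = grid or GridSpec()
    blocks, skipped = _assemble(dataset, spec)
    sizes = [math.comb(b.n_a + b.n_b, b.n_a) for b in blocks]
    total = math.prod(sizes)
    if total > _ENUM_BOUND:
        raise DataError(
            f"exact enumeration would require {total} assignments (bound {_ENUM_BOUND})"
        )

    want_2d = maps in ("2d", "both")
    p_count = len(blocks)
    stats_per_part = []  # list of (n_stat, m_p) arrays
    for b in blocks:
        n = b.n_a + b.n_b
        basis = profile_basis(b.x, b.y, grid)
        if want_2d:
            basis = np.concatenate([basis, _basis_2d(b.x, b.y, grid)], axis=1)
        combos = list(itertools.combinations(range(n), b.n_a))
        coefs = np.full((n, len(combos)), -spec.scale_b / p_count)
        for j, combo in enumerate(combos):
            coefs[list(combo), j] = spec.scale_a / p_count
        stats_per_part.append(basis.T @ coefs)

    coef0 = _base_coefs(blocks, spec)
    x = np.concatenate([b.x for b in blocks])
    y = np.concatenate([b.y for b in blocks])
    full_basis = profile_basis(x, y, grid)
    if want_2d:
        full_basis = np.concatenate([full_basis, _basis_2d(x, y, grid)], axis=1)
    obs = coef0 @ full_basis

    n_stat = obs.shape[0]
    # scale-relative tie tolerance, per map type (profile and 2D values
    # live on different scales)
    tol = np.empty(n_stat)
    tol[: grid.ny] = 1e-9 * max(np.abs(obs[: grid.ny]).max(), 1e-300)
    if n_stat > grid.ny:
        tol[grid.ny :] = 1e-9 * max(np.abs(obs[grid.ny :]).max(), 1e-300)
    cnt_ge = np.zeros(n_stat)
    cnt_le = np.zeros(n_stat)
    shape = tuple(sizes)
    if block_size is None:
        block_size = max(1, 5_000_000 // max(1, n_stat))
    for start in range(0, total, block_size):
        idx = np.arange(start, min(start + block_size, total))
        multi = np.unravel_index(idx, shape)
        stat = np.zeros((n_stat, len(idx)))
        for s_p, ix in zip(stats_per_part, multi):
            stat += s_p[:, ix]
        cnt_ge += (stat >= (obs - tol)[:, None]).sum(axis=1)
        cnt_le += (stat <= (obs + tol)[:, None]).sum(axis=1)

    p_all = np.ones(n_stat)
    pos, neg = obs > 0, obs < 0
    p_all[pos] = cnt_ge[pos] / total
    p_all[neg] = cnt_le[neg] / total
    if spec.two_sided:
        p_all = np.minimum(1.0, 2.0 * p_all)
        p_all[obs == 0] = 1.0

    prof_a, prof_b = _condition_profiles(blocks, spec, profile_basis(x, y, grid))
    result = PermutationResult(
        spec=spec,
        grid=grid,
        observed_profile=obs[: grid.ny],
        profile_a=prof_a,
        profile_b=prof_b,
        p_profile=p_all[: grid.ny],
        sign_profile=np.sign(obs[: grid.ny]),
        n_iterations=total,
        seed=spec.seed,
        n_participants=len(blocks),
        skipped_participants=skipped,
        exact=True,
    )
    if want_2d:
        result.observed_grid = obs[grid.ny :].reshape(grid.ny, grid.nx)
        result.p_grid = p_all[grid.ny :].reshape(grid.ny, grid.nx)
        result.sign_grid = np.sign(result.observed_grid)
    return result


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def fdr_mask(
    p_maps: Mapping[str, np.ndarray], q: float = 0.05, method: str = "bh"
) -> dict[str, np.ndarray]:
    """Benjamini-Hochberg (or Benjamini-Yekutieli with ``method='by'``)
    step-up over the pooled pixels of all maps in one family; returns a
    boolean mask per map."""
    if not p_maps:
        raise ConfigError("fdr_mask needs at least one p map")
    keys = list(p_maps)
    flat = [np.asarray(p_maps[k], dtype=float).ravel() for k in keys]
    pooled = np.concatenate(flat)
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    reject, *_ = multipletests(pooled, alpha=q, method=sm_method)
    out = {}
    pos = 0
    for k, arr in zip(keys, flat):
        out[k] = reject[pos : pos + len(arr)].reshape(np.asarray(p_maps[k]).shape)
        pos += len(arr)
    return out


def apply_fdr(
    results: Sequence[PermutationResult], q: float = 0.05, method: str = "bh"
) -> None:
    """Fill the FDR masks of results sharing a family: one pooled correction
    per family_id over all profile (and, where present, 2D) pixels."""
    by_family: dict[str, list[PermutationResult]] = {}
    for r in results:
        by_family.setdefault(r.spec.family_id, []).append(r)
    for family, members in by_family.items():
        p_maps: dict[str, np.ndarray] = {}
        for i, r in enumerate(members):
            p_maps[f"{i}:profile"] = r.p_profile
            if r.p_grid is not None:
                p_maps[f"{i}:grid"] = r.p_grid
        masks = fdr_mask(p_maps, q=q, method=method)
        for i, r in enumerate(members):
            r.mask_profile = masks[f"{i}:profile"]
            if r.p_grid is not None:
                r.mask_grid = masks[f"{i}:grid"]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_significance(result: PermutationResult, ax=None, labels=("condition A", "condition B")):
    """Vertical-profile curves of the two conditions, scaled relative to the
    maximum density between them, with FDR-significant y rows highlighted
    across the full horizontal extent."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 6))
    yc = result.grid.y_centers
    top = max(result.profile_a.max(), result.profile_b.max())
    scale = 1.0 / top if top > 0 else 1.0
    ax.plot(result.profile_a * scale, yc, label=labels[0])
    ax.plot(result.profile_b * scale, yc, label=labels[1])
    mask = result.mask_profile
    if mask is not None and mask.any():
        res = result.grid.resolution
        edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))
        for lo, hi in zip(edges[::2], edges[1::2]):
            ax.axhspan(yc[lo] - res / 2, yc[hi - 1] + res / 2, color="gold", alpha=0.3)
    ax.invert_yaxis()  # canonical y grows downward on the face
    ax.set_xlabel("relative density")
    ax.set_ylabel("vertical position (deg, downward)")
    ax.legend(loc="lower right", fontsize="small")
    return ax.figure
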