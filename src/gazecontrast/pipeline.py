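"""End-to-end orchestration: simulate -> validate -> behavior -> temporal ->
density -> permutation contrasts -> AOI -> manifest.

All stage outputs are CSV/TSV/JSON (+ PNG figures); a manifest records the
seed, configuration and SHA-256 hash of every file so a rerun with the same
seed can be checked for bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aoi as aoi_mod
from . import behavior, density, permutation, simulate, temporal
from .data import (
    ConfigError,
    Dataset,
    read_fixation_table,
    read_layouts,
    read_trials_table,
    validate_dataset,
    write_fixation_table,
    write_layouts,
    write_trials_table,
)

__all__ = ["RunConfig", "PipelineError", "default_contrasts", "run_pipeline", "load_dataset"]

log = logging.getLogger("gazecontrast")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str = "gazecontrast_run"
    seed: int = 0
    n_participants: int = 31
    trials_per_block: int = 24
    n_iterations: int = 2000
    q: float = 0.05
    ordinal: int = 2
    grid: density.GridSpec = field(default_factory=density.GridSpec)
    stages: tuple[str, ...] = (
        "simulate",
        "validate",
        "behavior",
        "temporal",
        "density",
        "permtest",
        "aoi",
    )


def default_contrasts(n_iterations: int = 2000, seed: int = 0, ordinal: int = 2, q: float = 0.05):
    """The shipped contrast battery: study vs (pooled old+new) test within
    each presentation time, short vs long within each phase, the crossed
    phase x time contrasts, and old vs new within test.  Pooled test
    conditions are scaled by 1/2 (they hold twice the trials of study)."""
    mk = lambda a, b, sa, sb, fam, label: permutation.ContrastSpec(
        condition_a=a,
        condition_b=b,
        ordinal=ordinal,
        scale_a=sa,
        scale_b=sb,
        n_iterations=n_iterations,
        seed=seed,
        family_id=fam,
        q=q,
        label=label,
    )
    out = []
    for t in (1, 5):
        out.append(
            mk(
                {"phase": "study", "presentation_s": t},
                {"phase": "test", "presentation_s": t},
                1.0,
                0.5,
                "study_vs_test",
                f"study_vs_test_{t}s",
            )
        )
    out.append(
        mk(
            {"phase": "study", "presentation_s": 1},
            {"phase": "study", "presentation_s": 5},
            1.0,
            1.0,
            "short_vs_long",
            "short_vs_long_study",
        )
    )
    out.append(
        mk(
            {"phase": "test", "presentation_s": 1},
            {"phase": "test", "presentation_s": 5},
            0.5,
            0.5,
            "short_vs_long",
            "short_vs_long_test",
        )
    )
    out.append(
        mk(
            {"phase": "study", "presentation_s": 1},
            {"phase": "test", "presentation_s": 5},
            1.0,
            0.5,
            "crossed",
            "study1s_vs_test5s",
        )
    )
    out.append(
        mk(
            {"phase": "study", "presentation_s": 5},
            {"phase": "test", "presentation_s": 1},
            1.0,
            0.5,
            "crossed",
            "study5s_vs_test1s",
        )
    )
    out.append(
        mk(
            {"phase": "test", "exposure": "old"},
            {"phase": "test", "exposure": "new"},
            1.0,
            1.0,
            "old_vs_new",
            "old_vs_new_test",
        )
    )
    return out


def load_dataset(data_dir: str | Path) -> Dataset:
    """Read fixations.tsv / trials.tsv / layouts.json from a directory."""
    d = Path(data_dir)
    for name in ("fixations.tsv", "trials.tsv", "layouts.json"):
        if not (d / name).exists():
            raise ConfigError(f"missing input file: {d / name}")
    return Dataset(
        trials=read_trials_table(d / "trials.tsv"),
        fixations=read_fixation_table(d / "fixations.tsv"),
        layouts=read_layouts(d / "layouts.json"),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest.

    On stage failure a ``.partial`` marker is left in the output directory
    and :class:`PipelineError` is raised naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".partial"
    marker.write_text("run in progress\n")
    manifest: dict = {
        "seed": config.seed,
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
        "files": {},
    }
    ds: Dataset | None = None
    stage = "init"
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            t0 = time.perf_counter()
            cfg = simulate.default_config(
                n_participants=config.n_participants,
                trials_per_block=config.trials_per_block,
                seed=config.seed,
            )
            ds, truth = simulate.generate_experiment(cfg)
            write_fixation_table(ds.fixations, out / "fixations.tsv")
            write_trials_table(ds.trials, out / "trials.tsv")
            write_layouts(ds.layouts, out / "layouts.json")
            (out / "truth.json").write_text(
                json.dumps(
                    {
                        "sdt": {f"{k[0]}x{k[1]}": v for k, v in cfg.sdt.items()},
                        "latency_ms": cfg.latency_ms,
                        "subject_effects": truth.subject_effects.to_dict("records"),
                    },
                    indent=1,
                    default=float,
                )
            )
            manifest["stages"]["simulate"] = {"seconds": time.perf_counter() - t0}
        if ds is None:
            stage = config.stages[0] if config.stages else "load"
            ds = load_dataset(out)

        if "validate" in config.stages:
            stage = "validate"
            violations = validate_dataset(ds)
            if violations:
                raise ConfigError(f"{len(violations)} dataset violations; first: {violations[0]}")
            manifest["stages"]["validate"] = {"violations": 0}

        if "behavior" in config.stages:
            stage = "behavior"
            scores = behavior.sdt_scores(behavior.tally_outcomes(ds.trials))
            rts = behavior.median_rt(ds.trials)
            scores = scores.merge(rts, on=["participant_id", "study_time", "test_time"], how="left")
            scores.to_csv(out / "behavior.csv", index=False)
            anova_d = behavior.rm_anova_2x2(scores, "d_prime", "study_time", "test_time")
            anova_c = behavior.rm_anova_2x2(scores, "criterion_c", "study_time", "test_time")
            group = []
            for name, eff in {"d_prime": anova_d, "criterion_c": anova_c}.items():
                for factor, e in eff.items():
                    group.append({"dv": name, "effect": factor, **e._asdict()})
            pd.DataFrame(group).to_csv(out / "behavior_group.csv", index=False)
            manifest["stages"]["behavior"] = {
                "n_cells": len(scores),
                "hit_adjusted": int(scores["hit_adjusted"].sum()),
                "fa_adjusted": int(scores["fa_adjusted"].sum()),
            }

        if "temporal" in config.stages:
            stage = "temporal"
            latencies = temporal.latency_table(ds)
            latencies.to_csv(out / "latency.csv", index=False)
            per_trial, blocks = temporal.latency_by_trial_series(ds)
            per_trial.to_csv(out / "latency_series.csv", index=False)
            blocks.to_csv(out / "latency_blocks.csv", index=False)
            durations = temporal.duration_by_condition(ds, ordinal=config.ordinal)
            durations.to_csv(out / "durations.csv", index=False)
            _, excl = temporal.filter_uninterrupted(ds.fixations, ds.trials, ordinal=config.ordinal)
            excl.to_csv(out / "duration_exclusions.csv", index=False)
            _plot_series(per_trial, blocks, out / "latency_series.png")
            manifest["stages"]["temporal"] = {"n_conditions": len(latencies)}

        if "density" in config.stages:
            stage = "density"
            for t in (1, 5):
                for phase, scale in (("study", 1.0), ("test", 0.5)):
                    maps = density.participant_condition_map(
                        ds, {"phase": phase, "presentation_s": t}, config.ordinal, config.grid
                    )
                    grp = density.group_average(maps, scale, label=f"{phase}_{t}s")
                    np.savetxt(out / f"density_{phase}_{t}s.csv", grp.values, delimiter=",")
                    np.savetxt(
                        out / f"profile_{phase}_{t}s.csv",
                        density.vertical_profile(grp),
                        delimiter=",",
                    )
            manifest["stages"]["density"] = {"grid": dataclasses.asdict(config.grid)}

        if "permtest" in config.stages:
            stage = "permtest"
            specs = default_contrasts(config.n_iterations, config.seed, config.ordinal, config.q)
            results = [
                permutation.monte_carlo_contrast(ds, spec, config.grid, maps="profile")
                for spec in specs
            ]
            permutation.apply_fdr(results, q=config.q)
            prov = []
            for spec, res in zip(specs, results):
                base = out / f"permtest_{spec.label}"
                np.savetxt(f"{base}_p.csv", res.p_profile, delimiter=",")
                np.savetxt(f"{base}_mask.csv", res.mask_profile.astype(int), delimiter=",", fmt="%d")
                fig = permutation.render_significance(
                    res, labels=(str(spec.condition_a), str(spec.condition_b))
                )
                fig.savefig(f"{base}.png", dpi=100)
                import matplotlib.pyplot as plt

                plt.close(fig)
                prov.append(
                    {
                        "label": spec.label,
                        "family": spec.family_id,
                        "seed": spec.seed,
                        "n_iterations": spec.n_iterations,
                        "n_participants": res.n_participants,
                        "n_significant_rows": int(res.mask_profile.sum()),
                        "skipped_participants": res.skipped_participants,
                    }
                )
            (out / "permtest_provenance.json").write_text(json.dumps(prov, indent=1))
            manifest["stages"]["permtest"] = {"n_contrasts": len(specs)}

        if "aoi" in config.stages:
            stage = "aoi"
            table = aoi_mod.truncation_contrast(ds)
            table.to_csv(out / "aoi.csv", index=False)
            _plot_aoi(table, out / "aoi.png")
            manifest["stages"]["aoi"] = {"n_aois": len(table)}
    except Exception as exc:  # noqa: BLE001 - stage context is the contract
        raise PipelineError(stage, exc) from exc

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != ".partial":
            manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    marker.unlink(missing_ok=True)
    return manifest


def _plot_series(per_trial: pd.DataFrame, blocks: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.errorbar(
        per_trial["trial_index"],
        per_trial["mean_latency_ms"],
        yerr=per_trial["se_ms"],
        fmt=".-",
        lw=0.7,
        ms=3,
    )
    bounds = per_trial.groupby("block_index")["trial_index"].max()
    for b, x in bounds.items():
        phase_change = (
            b in per_trial["block_index"].values
            and (per_trial.loc[per_trial["block_index"] == b, "phase"].iloc[0] == "study")
            and b == per_trial.loc[per_trial["phase"] == "study", "block_index"].max()
        )
        ax.axvline(x + 0.5, color="red", lw=2.0 if phase_change else 0.8)
    for _, row in blocks.iterrows():
        sel = per_trial[per_trial["block_index"] == row["block_index"]]
        ax.hlines(
            row["mean_latency_ms"], sel["trial_index"].min(), sel["trial_index"].max(),
            color="magenta", lw=1.5,
        )
    ax.set_xlabel("trial into experiment")
    ax.set_ylabel("latency to first saccade (ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_aoi(table: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = np.arange(len(table))
    ax.bar(x - 0.2, table["mean_full"], width=0.4, color="white", edgecolor="black", label="full window")
    ax.bar(x + 0.2, table["mean_short"], width=0.4, color="gray", edgecolor="black", label="first second")
    ax.set_xticks(x, table["aoi"])
    ax.set_ylabel("proportion of dwell time")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
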