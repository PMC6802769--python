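"""Shared constructors for hand-built test datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd

from gazecontrast import simulate
from gazecontrast.data import Dataset


def tiny_contrast_dataset(
    n_participants: int = 2,
    n_per_condition: int = 4,
    shift_b: float = 0.6,
    seed: int = 1,
    ordinal: int = 2,
) -> Dataset:
    """A minimal two-condition dataset (study vs test phase) with a handful
    of fixations per participant, suitable for exact permutation
    enumeration.  Condition b's fixations are shifted down by ``shift_b``
    degrees so the contrast is non-null."""
    rng = np.random.default_rng(seed)
    layouts = simulate.generate_layouts(1, seed=0, jitter=0.0)
    rows_t, rows_f = [], []
    for p in range(n_participants):
        pid = f"p{p}"
        for cond, phase in (("a", "study"), ("b", "test")):
            for i in range(n_per_condition):
                tid = f"{pid}:{cond}{i}"
                rows_t.append(
                    dict(
                        participant_id=pid,
                        block_index=1 if phase == "study" else 3,
                        trial_index=i + 1,
                        phase=phase,
                        presentation_s=1,
                        stimulus_id="s000",
                        exposure="study" if phase == "study" else "new",
                        start_side="left",
                        response="none" if phase == "study" else "new",
                        rt_ms=np.nan if phase == "study" else 900.0,
                        correct=np.nan,
                        trial_id=tid,
                    )
                )
                rows_f.append(
                    dict(
                        participant_id=pid,
                        trial_id=tid,
                        ordinal=ordinal,
                        x=float(rng.normal(3.2, 1.0)),
                        y=float(rng.normal(-2.0 + (shift_b if cond == "b" else 0.0), 1.0)),
                        start_ms=300.0 + i,
                        end_ms=500.0 + i,
                        interrupted=False,
                    )
                )
    return Dataset(pd.DataFrame(rows_t), pd.DataFrame(rows_f), layouts)
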