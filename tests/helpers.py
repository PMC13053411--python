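"""Shared builders used across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

from attentraits import designs


def make_trials(rows: list[dict]) -> pd.DataFrame:
    """Build a trial table from per-trial dicts, filling sane defaults."""
    defaults = dict(
        participant_id=0,
        block_id=0,
        block_type=designs.LEARNING_TLL,
        trial_index=0,
        cue="ready",
        condition="frequent",
        target_location=0,
        distractor_location=np.nan,
        distractor_present=False,
        rt_ms=800.0,
        correct=True,
        responded=True,
        key_valid=True,
    )
    filled = []
    for i, row in enumerate(rows):
        d = dict(defaults)
        d["trial_index"] = i
        d.update(row)
        filled.append(d)
    return pd.DataFrame(filled)


def two_condition_schedule(
    n_per_condition: int,
    block_type: str = designs.LEARNING_TLL,
    high: str = "infrequent",
    low: str = "frequent",
) -> pd.DataFrame:
    """A minimal balanced two-condition schedule frame for the simulator."""
    n = 2 * n_per_condition
    cond = [high, low] * n_per_condition
    return pd.DataFrame(
        {
            "block_id": 0,
            "block_type": block_type,
            "trial_index": range(n),
            "cue": "ready",
            "condition": cond,
            "target_location": 0,
            "distractor_location": np.nan,
            "distractor_present": False,
        }
    )


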