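"""Trial- and participant-level exclusion rules.

Accuracy analyses drop trials with an RT outside the 250–2,225 ms response
window (bounds inclusive: the rule removes RTs *outside* the window), with no
response, or with an inappropriate key press. RT analyses additionally drop
incorrect trials. Participant screening dismisses anyone whose block accuracy
falls below 70%, or whose mean block RT leaves the 250–1,500 ms band, on two
consecutive blocks; the replication protocol disables this screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "FilterReport",
    "ScreeningCriteria",
    "filter_trials",
    "screen_participants",
]

DEFAULT_RT_WINDOW = (250.0, 2225.0)


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_accuracy: int
    n_rt: int
    n_excluded_accuracy: int
    n_excluded_rt_additional: int
    reasons: dict[str, int] = field(default_factory=dict)

    @property
    def fraction_excluded_accuracy(self) -> float:
        return self.n_excluded_accuracy / self.n_input if self.n_input else 0.0

    @property
    def fraction_excluded_rt_additional(self) -> float:
        return self.n_excluded_rt_additional / self.n_accuracy if self.n_accuracy else 0.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_accuracy": self.n_accuracy,
            "n_rt": self.n_rt,
            "n_excluded_accuracy": self.n_excluded_accuracy,
            "fraction_excluded_accuracy": self.fraction_excluded_accuracy,
            "n_excluded_rt_additional": self.n_excluded_rt_additional,
            "fraction_excluded_rt_additional": self.fraction_excluded_rt_additional,
            "reasons": dict(self.reasons),
        }


def filter_trials(
    trials: pd.DataFrame,
    rt_window: tuple[float, float] = DEFAULT_RT_WINDOW,
) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Split a trial table into accuracy- and RT-analysis sets.

    Returns ``(accuracy_set, rt_set, report)`` with input row order preserved;
    ``rt_set`` is a subset of ``accuracy_set``. Exclusion reasons are counted
    with priority no-response > invalid key > RT window, so each excluded
    trial is counted once.
    """
    low, high = rt_window
    if not low < high:
        raise ConfigurationError("rt_window must satisfy low < high")

    responded = trials["responded"].to_numpy(dtype=bool)
    key_valid = trials["key_valid"].to_numpy(dtype=bool)
    rt = trials["rt_ms"].to_numpy(dtype=float)
    in_window = (rt >= low) & (rt <= high)
    in_window = np.where(np.isnan(rt), False, in_window)

    keep_acc = responded & key_valid & in_window
    no_response = ~responded
    invalid_key = responded & ~key_valid
    out_of_window = responded & key_valid & ~in_window

    accuracy_set = trials.loc[keep_acc]
    correct = accuracy_set["correct"].to_numpy(dtype=bool)
    rt_set = accuracy_set.loc[correct]

    report = FilterReport(
        n_input=len(trials),
        n_accuracy=len(accuracy_set),
        n_rt=len(rt_set),
        n_excluded_accuracy=int((~keep_acc).sum()),
        n_excluded_rt_additional=int((~correct).sum()),
        reasons={
            "no_response": int(no_response.sum()),
            "invalid_key": int(invalid_key.sum()),
            "rt_window": int(out_of_window.sum()),
            "incorrect": int((~correct).sum()),
        },
    )
    return accuracy_set, rt_set, report


@dataclass(frozen=True)
class ScreeningCriteria:
    """Participant dismissal rules; ``enabled=False`` retains everyone."""

    min_block_accuracy: float = 0.70
    rt_band: tuple[float, float] = (250.0, 1500.0)
    consecutive_blocks: int = 2
    enabled: bool = True


def screen_participants(
    trials: pd.DataFrame, criteria: ScreeningCriteria = ScreeningCriteria()
) -> tuple[list, dict]:
    """Apply block-wise performance screening.

    A participant is excluded iff a criterion (block accuracy below the
    minimum, or mean block RT outside the band) holds on
    ``consecutive_blocks`` consecutive blocks. Block accuracy and mean RT are
    computed over responded trials. Returns ``(retained_ids, excluded)``
    where ``excluded`` maps participant id to the violated criterion.
    """
    ids = list(pd.unique(trials["participant_id"]))
    if not criteria.enabled:
        return ids, {}

    retained, excluded = [], {}
    low, high = criteria.rt_band
    for pid, sub in trials.groupby("participant_id", sort=False):
        acc_fail, rt_fail = [], []
        for _, block in sub.groupby("block_id", sort=True):
            resp = block.loc[block["responded"]]
            if len(resp) == 0:
                acc_fail.append(True)
                rt_fail.append(True)
                continue
            acc_fail.append(resp["correct"].mean() < criteria.min_block_accuracy)
            mean_rt = resp["rt_ms"].mean()
            rt_fail.append(not low <= mean_rt <= high)
        reason = None
        if _has_run(acc_fail, criteria.consecutive_blocks):
            reason = "accuracy"
        elif _has_run(rt_fail, criteria.consecutive_blocks):
            reason = "rt"
        if reason is None:
            retained.append(pid)
        else:
            excluded[pid] = reason
    return retained, excluded


def _has_run(flags: list[bool], length: int) -> bool:
    run = 0
    for f in flags:
        run = run + 1 if f else 0
        if run >= length:
            return True
    return False
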