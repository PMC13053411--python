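"""Per-participant condition effects and group-level paired tests.

Effect scores follow the difference conventions that make a positive RT score
the cost of the unlikely condition: validity = invalid − valid, frequency =
infrequent − frequent, distractor presence = present − absent. Accuracy uses
the same orderings, so accuracy effects are typically negative (the costly
condition is less accurate). Normalized scores divide the difference by the
sum of the two condition means (a dimensionless difference-of-sums score that
removes baseline speed/accuracy differences between participants).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import designs
from .errors import AnalysisError, ConfigurationError

__all__ = [
    "Contrast",
    "STANDARD_CONTRASTS",
    "normalized_score",
    "effect_scores",
    "GroupComparison",
    "paired_test",
    "group_comparisons",
    "recode_carryover",
]


@dataclass(frozen=True)
class Contrast:
    """A two-condition comparison within a set of block types.

    ``field`` selects the trial column holding the condition label;
    ``high``/``low`` are the levels entering the difference as high − low.
    """

    name: str
    block_types: tuple[str, ...]
    field: str
    high: object
    low: object


VALIDITY = Contrast("validity", (designs.CUED,), "condition", "invalid", "valid")
TL_FREQUENCY = Contrast(
    "tl_frequency", (designs.LEARNING_TLL,), "condition", "infrequent", "frequent"
)
DL_FREQUENCY = Contrast(
    "dl_frequency", (designs.LEARNING_DLL,), "condition", "infrequent", "frequent"
)
PRESENCE_TLL = Contrast(
    "distractor_presence_tll", (designs.LEARNING_TLL,), "distractor_present", True, False
)
PRESENCE_DLL = Contrast(
    "distractor_presence_dll", (designs.LEARNING_DLL,), "distractor_present", True, False
)
CARRYOVER_TLL = Contrast(
    "carryover_tl_frequency", (designs.EXTINCTION,), "condition", "infrequent", "frequent"
)
CARRYOVER_DLL = Contrast(
    "carryover_dl_frequency", (designs.EXTINCTION,), "condition", "infrequent", "frequent"
)

STANDARD_CONTRASTS = {
    c.name: c
    for c in (
        VALIDITY,
        TL_FREQUENCY,
        DL_FREQUENCY,
        PRESENCE_TLL,
        PRESENCE_DLL,
        CARRYOVER_TLL,
        CARRYOVER_DLL,
    )
}

_MEASURE_COLUMN = {"rt": "rt_ms", "accuracy": "correct"}


def normalized_score(a: float, b: float) -> float:
    """Difference-of-sums score (b − a) / (b + a).

    Antisymmetric in its arguments and bounded in (−1, 1) for positive
    inputs. Returns NaN (with a warning) when the denominator is zero.
    """
    denom = a + b
    if denom == 0:
        warnings.warn("normalized score undefined: condition means sum to zero")
        return float("nan")
    return (b - a) / denom


def _condition_stats(sub: pd.DataFrame, contrast: Contrast, column: str):
    values = sub[column].to_numpy(dtype=float)
    labels = sub[contrast.field].to_numpy(dtype=object)
    hi = values[labels == contrast.high]
    lo = values[labels == contrast.low]
    return hi, lo


def effect_scores(
    accuracy_set: pd.DataFrame,
    rt_set: pd.DataFrame,
    contrasts: list[Contrast],
) -> pd.DataFrame:
    """Per-participant effect scores for each contrast and measure.

    One row per participant × contrast × measure with the condition means,
    trial counts, raw difference (high − low), and normalized score. A
    participant with zero usable trials in either condition gets NaN scores
    (missing, not zero).
    """
    rows = []
    for measure, data in (("accuracy", accuracy_set), ("rt", rt_set)):
        column = _MEASURE_COLUMN[measure]
        for contrast in contrasts:
            sub = data.loc[data["block_type"].isin(contrast.block_types)]
            for pid, part in sub.groupby("participant_id", sort=True):
                hi, lo = _condition_stats(part, contrast, column)
                if len(hi) == 0 or len(lo) == 0:
                    mean_hi = mean_lo = raw = norm = float("nan")
                else:
                    mean_hi, mean_lo = float(hi.mean()), float(lo.mean())
                    raw = mean_hi - mean_lo
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        norm = normalized_score(mean_lo, mean_hi)
                rows.append(
                    {
                        "participant_id": pid,
                        "contrast": contrast.name,
                        "measure": measure,
                        "mean_high": mean_hi,
                        "mean_low": mean_lo,
                        "n_high": len(hi),
                        "n_low": len(lo),
                        "raw_difference": raw,
                        "normalized_score": norm,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    """One-sample paired comparison of per-participant scores against zero."""

    contrast: str
    measure: str
    n: int
    df: int
    t: float
    p_raw: float
    p_bonferroni: float
    family_size: int
    mean: float
    se: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def paired_test(
    scores,
    family_size: int = 1,
    contrast: str = "",
    measure: str = "",
) -> GroupComparison:
    """Two-sided one-sample t test on per-participant difference scores.

    Bonferroni correction multiplies the p value by ``family_size`` and caps
    it at 1. Missing scores are dropped; fewer than two usable scores is an
    error.
    """
    x = np.asarray(scores, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        raise AnalysisError("paired test requires at least 2 non-missing scores")
    if family_size < 1:
        raise ConfigurationError("family_size must be a positive integer")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    se = sd / np.sqrt(n)
    df = n - 1
    if se == 0:
        t = 0.0 if mean == 0 else float(np.inf) * np.sign(mean)
        p = 1.0 if mean == 0 else 0.0
    else:
        t = mean / se
        p = 2.0 * float(stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf(0.975, df))
    return GroupComparison(
        contrast=contrast,
        measure=measure,
        n=n,
        df=df,
        t=float(t),
        p_raw=p,
        p_bonferroni=min(1.0, p * family_size),
        family_size=family_size,
        mean=mean,
        se=float(se),
        ci_low=mean - tcrit * float(se),
        ci_high=mean + tcrit * float(se),
    )


def group_comparisons(
    scores: pd.DataFrame, family_size: int = 1, value: str = "normalized_score"
) -> pd.DataFrame:
    """Run the paired test for every contrast × measure in a score table."""
    rows = []
    for (contrast, measure), sub in scores.groupby(["contrast", "measure"], sort=True):
        vals = sub[value].to_numpy(dtype=float)
        if np.sum(~np.isnan(vals)) < 2:
            continue
        res = paired_test(vals, family_size, contrast=contrast, measure=measure)
        d = res.to_dict()
        d["value"] = value
        rows.append(d)
    return pd.DataFrame(rows)


def recode_carryover(
    extinction_trials: pd.DataFrame,
    prior_frequent_location: int,
    mode: str = "target",
    first_half: bool = False,
) -> pd.DataFrame:
    """Relabel extinction trials by the previously learned frequent location.

    After target-location learning (``mode='target'``) a trial is "frequent"
    when the target occupies the prior frequent location; after
    distractor-location learning (``mode='distractor'``) when the distractor
    does. ``first_half`` restricts to the first half of each participant's
    trials in the subset (used to test how quickly a carried-over bias
    extinguishes). The relabeled table feeds ``effect_scores`` unchanged.
    """
    if mode not in ("target", "distractor"):
        raise ConfigurationError("mode must be 'target' or 'distractor'")
    if prior_frequent_location is None:
        raise AnalysisError("prior frequent location is required for carryover coding")
    out = extinction_trials.copy()
    if first_half:
        out = out.sort_values("trial_index")
        keep = out.groupby("participant_id", sort=False).cumcount() < np.ceil(
            out.groupby("participant_id", sort=False)["trial_index"].transform("size") / 2
        )
        out = out.loc[keep]
    column = "target_location" if mode == "target" else "distractor_location"
    loc = out[column].to_numpy(dtype=float)
    out["condition"] = np.where(loc == prior_frequent_location, "frequent", "infrequent")
    return out
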