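"""Permutation split-half reliability with Spearman–Brown correction.

A single split draws, independently for every participant, a random half of
their trials; the condition-effect score is computed separately on each half;
the two half-score vectors are Pearson-correlated across participants; and the
half-length correlation is corrected to full length with the Spearman–Brown
prophecy formula r_full = 2 r_half / (1 + r_half). Repeating the split many
times (5,000 by default) yields a distribution of corrected coefficients whose
mean estimates internal consistency and whose 2.5/97.5 percentile interval
classifies the measure: *reliable* when the interval excludes zero,
*unreliable* otherwise.

Splits are stratified within condition by default — each condition's trials
are halved separately — so both halves always contain both conditions and the
effect score is defined on every half. Joint splitting (all of a participant's
trials pooled before halving) is available for comparison; halves that lose a
condition produce missing half-scores and the affected participants drop out
of that split's correlation. When a participant has an odd number of trials in
a cell, the extra trial goes to a randomly chosen half, independently per
split, so neither half is systematically longer.

The Spearman–Brown formula is applied unchanged to negative half-correlations
(no clamping): a measure with no true individual differences produces a split
distribution straddling zero, and negative corrected values are part of that
distribution. r_half = −1 leaves the correction undefined and propagates as a
missing value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import Contrast, _MEASURE_COLUMN
from .errors import AnalysisError

__all__ = ["SplitHalfResult", "spearman_brown", "permutation_splithalf"]


def spearman_brown(r_half):
    """Spearman–Brown prophecy: full-length reliability from a half-length
    correlation, 2 r / (1 + r). Undefined (NaN) at r = −1."""
    r = np.asarray(r_half, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(r == -1.0, np.nan, 2.0 * r / (1.0 + r))
    return float(out) if np.isscalar(r_half) else out


@dataclass(frozen=True)
class SplitHalfResult:
    contrast: str
    measure: str
    n_participants: int
    n_splits: int
    r_sb: np.ndarray = field(repr=False)
    mean_r_sb: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    classification: str = "unreliable"
    dropped_participants: tuple = ()

    @property
    def reliable(self) -> bool:
        return self.classification == "reliable"

    def summary(self) -> dict:
        return {
            "contrast": self.contrast,
            "measure": self.measure,
            "n": self.n_participants,
            "n_splits": self.n_splits,
            "reliability": self.classification,
            "mean_r_sb": self.mean_r_sb,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_dropped": len(self.dropped_participants),
        }


def _half_means(values: np.ndarray, n_splits: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Mean of a random half of ``values`` (and of its complement), per split.

    Vectorized over splits: each row of a uniform matrix induces a random
    permutation; the first k entries form half A. For odd counts k is
    m//2 plus an independent random bit per split.
    """
    m = len(values)
    order = np.argsort(rng.random((n_splits, m)), axis=1)
    sorted_vals = values[order]
    csum = np.cumsum(sorted_vals, axis=1)
    total = csum[:, -1]
    if m % 2 == 0:
        k = np.full(n_splits, m // 2)
    else:
        k = m // 2 + rng.integers(0, 2, size=n_splits)
    sum_a = csum[np.arange(n_splits), k - 1]
    mean_a = sum_a / k
    mean_b = (total - sum_a) / (m - k)
    return mean_a, mean_b


def _joint_half_scores(
    hi: np.ndarray, lo: np.ndarray, n_splits: int, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Half-scores under joint (non-stratified) splitting; NaN where a half
    lacks one of the conditions."""
    values = np.concatenate([hi, lo])
    is_hi = np.concatenate([np.ones(len(hi)), np.zeros(len(lo))])
    m = len(values)
    order = np.argsort(rng.random((n_splits, m)), axis=1)
    v = values[order]
    h = is_hi[order]
    cs_hi_val = np.cumsum(v * h, axis=1)
    cs_hi_cnt = np.cumsum(h, axis=1)
    cs_val = np.cumsum(v, axis=1)
    if m % 2 == 0:
        k = np.full(n_splits, m // 2)
    else:
        k = m // 2 + rng.integers(0, 2, size=n_splits)
    rows = np.arange(n_splits)
    n_hi_a = cs_hi_cnt[rows, k - 1]
    n_hi_b = cs_hi_cnt[:, -1] - n_hi_a
    n_lo_a = k - n_hi_a
    n_lo_b = (m - k) - n_hi_b
    sum_hi_a = cs_hi_val[rows, k - 1]
    sum_hi_b = cs_hi_val[:, -1] - sum_hi_a
    sum_lo_a = cs_val[rows, k - 1] - sum_hi_a
    sum_lo_b = (cs_val[:, -1] - cs_val[rows, k - 1]) - sum_hi_b
    with np.errstate(divide="ignore", invalid="ignore"):
        score_a = sum_hi_a / n_hi_a - sum_lo_a / n_lo_a
        score_b = sum_hi_b / n_hi_b - sum_lo_b / n_lo_b
    score_a[(n_hi_a == 0) | (n_lo_a == 0)] = np.nan
    score_b[(n_hi_b == 0) | (n_lo_b == 0)] = np.nan
    return score_a, score_b


def _rowwise_pearson(H1: np.ndarray, H2: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row pair; NaN-aware (pairwise deletion
    within a row), NaN where fewer than 3 complete pairs or zero variance."""
    valid = ~(np.isnan(H1) | np.isnan(H2))
    n = valid.sum(axis=1)
    x = np.where(valid, H1, 0.0)
    y = np.where(valid, H2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = x.sum(axis=1) / n
        my = y.sum(axis=1) / n
        xc = np.where(valid, H1 - mx[:, None], 0.0)
        yc = np.where(valid, H2 - my[:, None], 0.0)
        num = (xc * yc).sum(axis=1)
        den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        r = num / den
    r[(n < 2) | ~np.isfinite(r)] = np.nan
    return r


def permutation_splithalf(
    trials: pd.DataFrame,
    contrast: Contrast,
    measure: str,
    n_splits: int = 5000,
    seed: int = 0,
    stratified: bool = True,
    min_trials: int = 2,
) -> SplitHalfResult:
    """Permutation split-half reliability of an individual-difference measure.

    Parameters
    ----------
    trials:
        The analysis-ready trial set for the requested measure (the accuracy
        set for ``measure='accuracy'``, the RT set for ``measure='rt'``).
    contrast:
        The two-condition effect whose per-participant score is assessed.
    measure:
        ``'rt'`` (trial RT in ms) or ``'accuracy'`` (trial correctness).
    n_splits:
        Number of random splits (5,000 reproduces the standard analysis).
    stratified:
        Split each condition's trials separately (default) or pool all trials
        before halving.

    Participants with fewer than ``min_trials`` usable trials in either
    condition are dropped with a warning.
    """
    if measure not in _MEASURE_COLUMN:
        raise AnalysisError(f"unknown measure {measure!r}")
    if n_splits < 1:
        raise AnalysisError("n_splits must be positive")
    column = _MEASURE_COLUMN[measure]
    sub = trials.loc[trials["block_type"].isin(contrast.block_types)]

    per_participant: list[tuple[object, np.ndarray, np.ndarray]] = []
    dropped = []
    for pid, part in sub.groupby("participant_id", sort=True):
        labels = part[contrast.field].to_numpy(dtype=object)
        values = part[column].to_numpy(dtype=float)
        hi = values[labels == contrast.high]
        lo = values[labels == contrast.low]
        if len(hi) < min_trials or len(lo) < min_trials:
            dropped.append(pid)
            continue
        per_participant.append((pid, hi, lo))
    if dropped:
        warnings.warn(
            f"{len(dropped)} participant(s) dropped from split-half analysis of "
            f"{contrast.name}/{measure}: fewer than {min_trials} trials per condition"
        )
    n_participants = len(per_participant)
    if n_participants < 2:
        raise AnalysisError(
            f"split-half analysis of {contrast.name}/{measure} needs at least 2 "
            f"participants with usable trials, found {n_participants}"
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    H1 = np.empty((n_splits, n_participants))
    H2 = np.empty((n_splits, n_participants))
    for j, (_, hi, lo) in enumerate(per_participant):
        if stratified:
            hi_a, hi_b = _half_means(hi, n_splits, rng)
            lo_a, lo_b = _half_means(lo, n_splits, rng)
            H1[:, j] = hi_a - lo_a
            H2[:, j] = hi_b - lo_b
        else:
            H1[:, j], H2[:, j] = _joint_half_scores(hi, lo, n_splits, rng)

    r_half = _rowwise_pearson(H1, H2)
    r_sb = spearman_brown(r_half)
    if np.all(np.isnan(r_sb)):
        raise AnalysisError(
            f"all {n_splits} splits produced undefined correlations for "
            f"{contrast.name}/{measure}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_r = float(np.nanmean(r_sb))
        ci_low = float(np.nanpercentile(r_sb, 2.5))
        ci_high = float(np.nanpercentile(r_sb, 97.5))
    classification = "reliable" if (ci_low > 0 or ci_high < 0) else "unreliable"
    return SplitHalfResult(
        contrast=contrast.name,
        measure=measure,
        n_participants=n_participants,
        n_splits=n_splits,
        r_sb=r_sb,
        mean_r_sb=mean_r,
        ci_low=ci_low,
        ci_high=ci_high,
        classification=classification,
        dropped_participants=tuple(dropped),
    )
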