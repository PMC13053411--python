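"""Split-half reliability: correction formula, oracle split, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attentraits import designs
from attentraits.behavior_sim import PopulationParams, draw_participants, emit_trials
from attentraits.effects import TL_FREQUENCY
from attentraits.errors import AnalysisError
from attentraits.preprocessing import filter_trials
from attentraits.reliability import permutation_splithalf, spearman_brown

from helpers import two_condition_schedule


@pytest.mark.parametrize(
    "r,expected",
    [(0.0, 0.0), (1.0, 1.0), (0.5, 2 / 3), (-0.2, -0.5)],
)
def test_spearman_brown_values(r, expected):
    assert spearman_brown(r) == pytest.approx(expected)


def test_spearman_brown_undefined_at_minus_one():
    assert np.isnan(spearman_brown(-1.0))


@settings(max_examples=100, derandomize=True)
@given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
def test_spearman_brown_strictly_increasing(r1, r2):
    if r1 < r2:
        assert spearman_brown(r1) < spearman_brown(r2)
    if 0 < r1 <= 1:
        assert r1 < spearman_brown(r1) <= 1.0


def _simulate_two_condition_rt(
    n_participants, trials_per_condition, between, within, seed, mean=40.0
):
    pop = PopulationParams(
        n_participants=n_participants,
        mean_effects={"tl_frequency": mean},
        between_sd={"tl_frequency": between},
        within_rt_sd=within,
        lapse_rate=0.0,
        baseline_rt_sd=50.0,
        master_seed=seed,
    )
    schedule = two_condition_schedule(trials_per_condition)
    frames = [emit_trials(p, schedule, pop) for p in draw_participants(pop)]
    trials = pd.concat(frames, ignore_index=True)
    _, rt_set, _ = filter_trials(trials)
    return rt_set


def test_noiseless_heterogeneous_effects_are_perfectly_reliable():
    rt_set = _simulate_two_condition_rt(20, 20, between=25.0, within=0.0, seed=0)
    res = permutation_splithalf(rt_set, TL_FREQUENCY, "rt", n_splits=50, seed=1)
    assert res.mean_r_sb == pytest.approx(1.0)
    assert res.classification == "reliable"


def brute_single_split(per_participant, seed):
    """Independent single-split computation.

    Replays the documented split protocol (one uniform row per condition,
    argsort order, first half = half A; odd cells flip a coin for the extra
    trial) but computes every mean, the Pearson correlation, and the
    Spearman-Brown correction with plain Python arithmetic.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    half1, half2 = [], []
    for hi, lo in per_participant:
        scores = []
        for v in (hi, lo):
            m = len(v)
            order = np.argsort(rng.random((1, m)), axis=1)[0]
            k = m // 2 if m % 2 == 0 else m // 2 + int(rng.integers(0, 2, size=1)[0])
            half_a = [v[i] for i in order[:k]]
            half_b = [v[i] for i in order[k:]]
            scores.append((sum(half_a) / len(half_a), sum(half_b) / len(half_b)))
        (hi_a, hi_b), (lo_a, lo_b) = scores
        half1.append(hi_a - lo_a)
        half2.append(hi_b - lo_b)
    n = len(half1)
    m1, m2 = sum(half1) / n, sum(half2) / n
    num = sum((a - m1) * (b - m2) for a, b in zip(half1, half2))
    den = (
        sum((a - m1) ** 2 for a in half1) * sum((b - m2) ** 2 for b in half2)
    ) ** 0.5
    r = num / den
    return 2 * r / (1 + r)


def test_single_split_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    rows = []
    per_participant = []
    for pid in range(8):
        hi = rng.normal(900, 60, 11)  # odd count exercises the coin flip
        lo = rng.normal(850, 60, 10)
        per_participant.append((list(hi), list(lo)))
        for v in hi:
            rows.append(dict(participant_id=pid, condition="infrequent", rt_ms=v))
        for v in lo:
            rows.append(dict(participant_id=pid, condition="frequent", rt_ms=v))
    from helpers import make_trials

    trials = make_trials(rows)
    res = permutation_splithalf(trials, TL_FREQUENCY, "rt", n_splits=1, seed=99)
    expected = brute_single_split(per_participant, seed=99)
    assert res.r_sb[0] == pytest.approx(expected, abs=1e-12)


def test_zero_between_variance_is_classified_unreliable():
    rt_set = _simulate_two_condition_rt(40, 60, between=0.0, within=150.0, seed=3)
    res = permutation_splithalf(rt_set, TL_FREQUENCY, "rt", n_splits=300, seed=4)
    assert res.classification == "unreliable"
    assert res.ci_low < 0 < res.ci_high


def test_more_within_noise_does_not_increase_reliability():
    """Monotonicity in expectation: averaged over replicates, higher trial
    noise gives lower mean corrected reliability."""
    means = {}
    for within in (60.0, 300.0):
        vals = []
        for rep in range(4):
            rt_set = _simulate_two_condition_rt(
                30, 40, between=25.0, within=within, seed=50 + rep
            )
            vals.append(
                permutation_splithalf(
                    rt_set, TL_FREQUENCY, "rt", n_splits=100, seed=rep
                ).mean_r_sb
            )
        means[within] = np.mean(vals)
    assert means[300.0] < means[60.0]


def test_participants_with_too_few_trials_are_dropped():
    from helpers import make_trials

    rows = []
    for pid in range(4):
        n_hi = 1 if pid == 0 else 6
        for i in range(n_hi):
            rows.append(dict(participant_id=pid, condition="infrequent",
                             rt_ms=900.0 + 30.0 * pid + i))
        for i in range(6):
            rows.append(dict(participant_id=pid, condition="frequent",
                             rt_ms=850.0 + 10.0 * pid + i))
    trials = make_trials(rows)
    with pytest.warns(UserWarning, match="dropped"):
        res = permutation_splithalf(trials, TL_FREQUENCY, "rt", n_splits=10, seed=0)
    assert res.n_participants == 3
    assert res.dropped_participants == (0,)


def test_too_few_participants_raises():
    from helpers import make_trials

    rows = [dict(participant_id=0, condition=c, rt_ms=800.0 + i)
            for i, c in enumerate(["frequent"] * 3 + ["infrequent"] * 3)]
    with pytest.raises(AnalysisError):
        permutation_splithalf(
            make_trials(rows), TL_FREQUENCY, "rt", n_splits=5, seed=0
        )


def test_joint_splitting_flag_runs_and_agrees_qualitatively():
    rt_set = _simulate_two_condition_rt(25, 30, between=30.0, within=80.0, seed=8)
    strat = permutation_splithalf(rt_set, TL_FREQUENCY, "rt", n_splits=200, seed=9)
    joint = permutation_splithalf(
        rt_set, TL_FREQUENCY, "rt", n_splits=200, seed=9, stratified=False
    )
    assert joint.n_participants == strat.n_participants
    # both approaches detect the true heterogeneity and agree closely
    assert strat.mean_r_sb > 0.3 and joint.mean_r_sb > 0.3
    assert abs(strat.mean_r_sb - joint.mean_r_sb) < 0.15


def test_split_distribution_invariant_to_participant_order_in_expectation():
    rt_set = _simulate_two_condition_rt(15, 20, between=25.0, within=100.0, seed=12)
    shuffled = rt_set.sample(frac=1.0, random_state=0)
    a = permutation_splithalf(rt_set, TL_FREQUENCY, "rt", n_splits=400, seed=5)
    b = permutation_splithalf(shuffled, TL_FREQUENCY, "rt", n_splits=400, seed=6)
    assert abs(a.mean_r_sb - b.mean_r_sb) < 0.15
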