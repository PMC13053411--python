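"""Schedule generation: exact composition, invariants, determinism."""

from collections import Counter

import numpy as np
import pytest

from attentraits import designs
from attentraits.designs import (
    BASELINE,
    EXTINCTION,
    LEARNING_DLL,
    LEARNING_TLL,
    build_schedule,
    build_session,
    e1_enhance,
    e1_suppress,
    e2,
    e3,
    even_partition,
)
from attentraits.errors import ConfigurationError

VERTICAL_MERIDIAN = {0, 4}


@pytest.mark.parametrize(
    "spec,n_trials,expected",
    [
        (e1_enhance(), 160, {"valid": 112, "invalid": 32, "neutral": 16}),
        (e1_suppress(), 160, {"frequent": 112, "infrequent": 32, "absent": 16}),
        (e1_enhance(), 10, {"valid": 7, "invalid": 2, "neutral": 1}),
    ],
)
def test_exact_condition_composition(spec, n_trials, expected):
    schedule = build_schedule(spec, participant_seed=5, n_trials=n_trials)
    assert Counter(t.condition for t in schedule) == expected


def test_infrequent_location_multiset_is_most_even_partition():
    """32 infrequent trials over 5 non-frequent locations -> {7,7,6,6,6}.

    Brute-force oracle: the most-even integer partition of 32 into 5 parts is
    the unique multiset minimizing the spread, computed by enumeration.
    """
    from itertools import combinations_with_replacement

    candidates = [
        p
        for p in combinations_with_replacement(range(33), 5)
        if sum(p) == 32
    ]
    best = list(min(candidates, key=lambda p: max(p) - min(p)))
    schedule = build_schedule(e1_suppress(), participant_seed=9, n_trials=160)
    locs = [t.distractor_location for t in schedule if t.condition == "infrequent"]
    assert sorted(Counter(locs).values()) == best == [6, 6, 6, 7, 7]


def test_even_partition_properties():
    rng = np.random.default_rng(0)
    for total, k in [(32, 5), (10, 3), (0, 4), (7, 7), (100, 6)]:
        counts = even_partition(total, np.ones(k), rng)
        assert counts.sum() == total
        assert counts.max() - counts.min() <= 1


def test_session_block_structure_six_item():
    sess = build_session(e2(), participant_seed=1)
    by_type = Counter(t.block_type for t in sess)
    assert by_type[LEARNING_TLL] == 318  # 3 x 106
    assert by_type[LEARNING_DLL] == 318
    assert by_type[BASELINE] == 50
    baseline = [t for t in sess if t.block_type == BASELINE]
    assert sum(t.distractor_present for t in baseline) == 25
    extinction = [t for t in sess if t.block_type == EXTINCTION]
    assert len(extinction) == 200
    assert all(t.distractor_present for t in extinction)


def test_session_counterbalancing_swaps_learning_groups():
    a = build_session(e2(), participant_seed=4, tll_first=True)
    b = build_session(e2(), participant_seed=4, tll_first=False)
    first_learning_a = next(t for t in a if t.block_type.startswith("learning"))
    first_learning_b = next(t for t in b if t.block_type.startswith("learning"))
    assert first_learning_a.block_type == LEARNING_TLL
    assert first_learning_b.block_type == LEARNING_DLL


def test_seeded_determinism():
    assert build_session(e3(), 42) == build_session(e3(), 42)
    assert build_schedule(e1_enhance(), 42) == build_schedule(e1_enhance(), 42)
    assert build_session(e3(), 42) != build_session(e3(), 43)


@pytest.mark.parametrize("seed", range(6))
def test_schedule_invariants(seed):
    """Targets and distractors never collide; labels match locations; the
    eight-item cued design avoids the vertical meridian."""
    for spec in (e1_enhance(), e1_suppress(), e2(), e3()):
        sess = build_session(spec, participant_seed=seed)
        for t in sess:
            if t.distractor_present:
                assert t.distractor_location is not None
                assert t.distractor_location != t.target_location
            else:
                assert t.distractor_location is None
            if spec.experiment_id.startswith("E1"):
                assert t.target_location not in VERTICAL_MERIDIAN
                if t.distractor_location is not None:
                    assert t.distractor_location not in VERTICAL_MERIDIAN
            if t.block_type == LEARNING_DLL and t.condition == "frequent":
                assert t.distractor_location == spec.frequent_distractor_location
            if t.block_type == LEARNING_DLL and t.condition == "infrequent":
                assert t.distractor_location != spec.frequent_distractor_location
            if t.block_type == LEARNING_TLL and t.condition == "frequent":
                assert t.target_location == spec.frequent_target_location


def test_cued_trials_match_cue_side():
    right, left = {1, 2, 3}, {5, 6, 7}
    for t in build_schedule(e1_enhance(), participant_seed=2, n_trials=160):
        if t.condition == "valid":
            assert t.target_location in (right if t.cue == "R" else left)
        elif t.condition == "invalid":
            assert t.target_location in (left if t.cue == "R" else right)
        else:
            assert t.cue == "N"


def test_e1_suppress_target_avoids_frequent_distractor_location():
    spec = e1_suppress(frequent_distractor_location=3)
    sess = build_session(spec, participant_seed=0)
    assert all(t.target_location != 3 for t in sess)


def test_invalid_specs_raise_configuration_errors():
    with pytest.raises(ConfigurationError, match="sum"):
        designs.DesignSpec(
            experiment_id="bad",
            array_size=4,
            allowed_locations=(0, 1, 2, 3),
            block_sequence=((LEARNING_TLL, 10),),
            condition_probabilities={LEARNING_TLL: {"frequent": 0.6, "infrequent": 0.5}},
        )
    with pytest.raises(ConfigurationError, match="distinct"):
        e3(frequent_target_location=1, frequent_distractor_location=1)
    with pytest.raises(ConfigurationError, match="block_type"):
        designs.DesignSpec(
            experiment_id="bad",
            array_size=4,
            allowed_locations=(0, 1, 2, 3),
            block_sequence=(("warmup", 10),),
        )
    with pytest.raises(ConfigurationError, match="non-negative"):
        build_schedule(e2(), participant_seed=-1)
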