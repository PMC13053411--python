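"""Trial-schedule generators for the singleton-search experiments.

Each experiment is described by a :class:`DesignSpec`: a circular search array
(locations indexed clockwise from the 12 o'clock position), per-block-type
condition probability tables, distractor-presence rates, and an ordered block
sequence. Schedules are built by *exact composition*: the per-condition trial
counts are the integer apportionment of the printed proportions (largest
remainder rule, ties and fractional remainders resolved by the participant
seed), after which trial order is shuffled. This makes condition counts exact
and reproducible rather than Bernoulli-sampled.

Block types
-----------
``cued``
    Endogenous spatial cueing: a letter cue (L/R) predicts the target side
    with 70% validity; N cues (10%) are non-informative. No distractors.
``learning_TLL``
    Target-location statistical learning: the target appears at one frequent
    location half the time; a color-singleton distractor is present on a fixed
    proportion of trials, balanced across target conditions.
``learning_DLL``
    Distractor-location statistical learning: the distractor appears at one
    frequent location; conditions are frequent / infrequent / absent.
``baseline``
    Random target and distractor locations, distractor present on half the
    trials.
``extinction``
    Random locations with the distractor present on 100% of trials, used to
    wash out learned location biases between learning-block groups.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "BASELINE",
    "CUED",
    "LEARNING_TLL",
    "LEARNING_DLL",
    "EXTINCTION",
    "BLOCK_TYPES",
    "TrialSpec",
    "DesignSpec",
    "e1_enhance",
    "e1_suppress",
    "e1",
    "e2",
    "e3",
    "even_partition",
    "build_schedule",
    "build_session",
]

BASELINE = "baseline"
CUED = "cued"
LEARNING_TLL = "learning_TLL"
LEARNING_DLL = "learning_DLL"
EXTINCTION = "extinction"
BLOCK_TYPES = (BASELINE, CUED, LEARNING_TLL, LEARNING_DLL, EXTINCTION)

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial (no behavioral outcome attached)."""

    trial_index: int
    block_id: int
    block_type: str
    cue: str | None
    condition: str | None
    target_location: int
    distractor_location: int | None
    distractor_present: bool


@dataclass(frozen=True)
class DesignSpec:
    """An experiment's probability structure, geometry, and block sequence.

    ``condition_probabilities`` maps block type -> {condition label ->
    probability}; the probabilities on each such axis must sum to one.
    ``distractor_present_rate`` maps block type -> probability that a salient
    distractor is shown. Frequent locations may be ``None`` for designs (or
    block types) without a location manipulation.
    """

    experiment_id: str
    array_size: int
    allowed_locations: tuple[int, ...]
    block_sequence: tuple[tuple[str, int], ...]
    condition_probabilities: dict[str, dict[str, float]] = field(default_factory=dict)
    distractor_present_rate: dict[str, float] = field(default_factory=dict)
    frequent_target_location: int | None = None
    frequent_distractor_location: int | None = None
    # E1-style rule: the target never appears at the frequent distractor location.
    target_excludes_frequent_distractor: bool = False
    # E3-style rule: frequent target and distractor locations must differ.
    require_distinct_frequent: bool = False
    # Letter cues (E1) versus an uninformative ready signal (E2/E3).
    cue_scheme: str = "ready"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.array_size < 2:
            raise ConfigurationError("array_size must be at least 2")
        if not self.allowed_locations:
            raise ConfigurationError("allowed_locations must be non-empty")
        bad = [l for l in self.allowed_locations if not 0 <= l < self.array_size]
        if bad:
            raise ConfigurationError(
                f"allowed_locations {bad} outside array of size {self.array_size}"
            )
        if not self.block_sequence:
            raise ConfigurationError("block_sequence must be non-empty")
        for block_type, n in self.block_sequence:
            if block_type not in BLOCK_TYPES:
                raise ConfigurationError(f"unknown block_type {block_type!r}")
            if n <= 0:
                raise ConfigurationError(f"non-positive trial count for {block_type}")
        for block_type, probs in self.condition_probabilities.items():
            total = sum(probs.values())
            if abs(total - 1.0) > _PROB_TOL:
                raise ConfigurationError(
                    f"condition probabilities for {block_type!r} sum to {total!r},"
                    " not 1"
                )
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError(
                    f"negative condition probability in {block_type!r}"
                )
        for block_type, rate in self.distractor_present_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(
                    f"distractor_present_rate for {block_type!r} must be in [0, 1]"
                )
        for loc_name in ("frequent_target_location", "frequent_distractor_location"):
            loc = getattr(self, loc_name)
            if loc is not None and loc not in self.allowed_locations:
                raise ConfigurationError(
                    f"{loc_name}={loc} is not an allowed location"
                )
        if (
            self.require_distinct_frequent
            and self.frequent_target_location is not None
            and self.frequent_target_location == self.frequent_distractor_location
        ):
            raise ConfigurationError(
                "frequent target and distractor locations must be distinct"
            )

    def with_frequent_locations(
        self, target: int | None = None, distractor: int | None = None
    ) -> "DesignSpec":
        """Return a copy with the per-participant frequent locations set."""
        return dataclasses.replace(
            self,
            frequent_target_location=(
                target if target is not None else self.frequent_target_location
            ),
            frequent_distractor_location=(
                distractor
                if distractor is not None
                else self.frequent_distractor_location
            ),
        )


# ---------------------------------------------------------------------------
# Experiment presets
# ---------------------------------------------------------------------------

# Eight-item array: index 0 is 12 o'clock, 4 is 6 o'clock (the vertical
# meridian); 1-3 lie on the right side, 5-7 on the left.
_E1_ALLOWED = (1, 2, 3, 5, 6, 7)
_E1_RIGHT = (1, 2, 3)
_E1_LEFT = (5, 6, 7)


def e1_enhance() -> DesignSpec:
    """Endogenous-cueing task: two 80-trial blocks, 70/20/10 cue validity."""
    return DesignSpec(
        experiment_id="E1_ENHANCE",
        array_size=8,
        allowed_locations=_E1_ALLOWED,
        block_sequence=((CUED, 80), (CUED, 80)),
        condition_probabilities={CUED: {"valid": 0.7, "invalid": 0.2, "neutral": 0.1}},
        distractor_present_rate={CUED: 0.0},
        cue_scheme="letters",
    )


def e1_suppress(frequent_distractor_location: int = 1) -> DesignSpec:
    """Distractor-location learning task: 70% frequent / 20% infrequent /
    10% distractor-absent over two 80-trial blocks."""
    return DesignSpec(
        experiment_id="E1_SUPPRESS",
        array_size=8,
        allowed_locations=_E1_ALLOWED,
        block_sequence=((LEARNING_DLL, 80), (LEARNING_DLL, 80)),
        condition_probabilities={
            LEARNING_DLL: {"frequent": 0.7, "infrequent": 0.2, "absent": 0.1}
        },
        distractor_present_rate={LEARNING_DLL: 0.9},
        frequent_distractor_location=frequent_distractor_location,
        target_excludes_frequent_distractor=True,
        cue_scheme="letters",
    )


def e1(frequent_distractor_location: int = 1) -> DesignSpec:
    """Both E1 tasks in one session (cued blocks then learning blocks)."""
    return DesignSpec(
        experiment_id="E1",
        array_size=8,
        allowed_locations=_E1_ALLOWED,
        block_sequence=(
            (CUED, 80),
            (CUED, 80),
            (LEARNING_DLL, 80),
            (LEARNING_DLL, 80),
        ),
        condition_probabilities={
            CUED: {"valid": 0.7, "invalid": 0.2, "neutral": 0.1},
            LEARNING_DLL: {"frequent": 0.7, "infrequent": 0.2, "absent": 0.1},
        },
        distractor_present_rate={CUED: 0.0, LEARNING_DLL: 0.9},
        frequent_distractor_location=frequent_distractor_location,
        target_excludes_frequent_distractor=True,
        cue_scheme="letters",
    )


def e2(frequent_location: int = 0) -> DesignSpec:
    """Six-item statistical-learning session.

    Block order: baseline, three target-location learning blocks, extinction,
    three distractor-location learning blocks, extinction (swap the learning
    groups via ``build_session(..., tll_first=False)``). The frequent location
    is shared between the target and distractor manipulations. Infrequent
    target/distractor locations each receive 10% (an even 50% split over the
    five non-frequent locations).
    """
    return DesignSpec(
        experiment_id="E2",
        array_size=6,
        allowed_locations=tuple(range(6)),
        block_sequence=(
            (BASELINE, 50),
            (LEARNING_TLL, 106),
            (LEARNING_TLL, 106),
            (LEARNING_TLL, 106),
            (EXTINCTION, 100),
            (LEARNING_DLL, 106),
            (LEARNING_DLL, 106),
            (LEARNING_DLL, 106),
            (EXTINCTION, 100),
        ),
        condition_probabilities={
            LEARNING_TLL: {"frequent": 0.5, "infrequent": 0.5},
            LEARNING_DLL: {"frequent": 1 / 3, "infrequent": 1 / 3, "absent": 1 / 3},
        },
        distractor_present_rate={
            BASELINE: 0.5,
            LEARNING_TLL: 0.5,
            LEARNING_DLL: 2 / 3,
            EXTINCTION: 1.0,
        },
        frequent_target_location=frequent_location,
        frequent_distractor_location=frequent_location,
    )


def e3(
    frequent_target_location: int = 0, frequent_distractor_location: int = 2
) -> DesignSpec:
    """Four-item singleton-search session (also the E4/E5 design).

    As in the six-item session but with an extinction block preceding the
    first learning group, four array locations, and distinct frequent target
    and distractor locations per participant.
    """
    return DesignSpec(
        experiment_id="E3",
        array_size=4,
        allowed_locations=tuple(range(4)),
        block_sequence=(
            (BASELINE, 50),
            (EXTINCTION, 100),
            (LEARNING_TLL, 106),
            (LEARNING_TLL, 106),
            (LEARNING_TLL, 106),
            (EXTINCTION, 100),
            (LEARNING_DLL, 106),
            (LEARNING_DLL, 106),
            (LEARNING_DLL, 106),
        ),
        condition_probabilities={
            LEARNING_TLL: {"frequent": 0.5, "infrequent": 0.5},
            LEARNING_DLL: {"frequent": 1 / 3, "infrequent": 1 / 3, "absent": 1 / 3},
        },
        distractor_present_rate={
            BASELINE: 0.5,
            LEARNING_TLL: 0.5,
            LEARNING_DLL: 2 / 3,
            EXTINCTION: 1.0,
        },
        frequent_target_location=frequent_target_location,
        frequent_distractor_location=frequent_distractor_location,
        require_distinct_frequent=True,
    )


PRESETS = {
    "E1": e1,
    "E1_ENHANCE": e1_enhance,
    "E1_SUPPRESS": e1_suppress,
    "E2": e2,
    "E3": e3,
    "E4": e3,
    "E5": e3,
}


# ---------------------------------------------------------------------------
# Composition helpers
# ---------------------------------------------------------------------------


def even_partition(total: int, weights, rng: np.random.Generator) -> np.ndarray:
    """Apportion ``total`` into integer counts proportional to ``weights``.

    Largest-remainder apportionment: each cell gets the floor of its exact
    quota and the leftover units go to the cells with the largest fractional
    remainders, ties broken at random by ``rng``. For equal weights this is
    the most-even partition (counts differ by at most one), with the +1 cells
    chosen by the seed.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ConfigurationError("partition weights must be non-negative, not all 0")
    quota = total * w / w.sum()
    counts = np.floor(quota).astype(int)
    remainder = total - counts.sum()
    if remainder:
        frac = quota - counts
        # random keys break ties among equal remainders
        order = np.lexsort((rng.random(len(w)), -frac))
        counts[order[:remainder]] += 1
    return counts


def _spread_over(total: int, cells: list, rng: np.random.Generator) -> list:
    """Expand a most-even partition of ``total`` over ``cells`` into a
    shuffled list of cell values of length ``total``."""
    counts = even_partition(total, np.ones(len(cells)), rng)
    out = [c for c, k in zip(cells, counts) for _ in range(int(k))]
    rng.shuffle(out)
    return out


# ---------------------------------------------------------------------------
# Block builders
# ---------------------------------------------------------------------------


def _choice_excluding(rng, options: tuple, exclude: set) -> int:
    usable = [o for o in options if o not in exclude]
    if not usable:
        raise ConfigurationError("no usable locations after exclusions")
    return int(usable[rng.integers(len(usable))])


def _build_cued_block(spec: DesignSpec, n_trials: int, rng) -> list[dict]:
    probs = spec.condition_probabilities[CUED]
    labels = list(probs)
    counts = even_partition(n_trials, [probs[c] for c in labels], rng)
    trials: list[dict] = []
    for label, count in zip(labels, counts):
        count = int(count)
        if label == "neutral":
            locs = _spread_over(count, list(spec.allowed_locations), rng)
            for loc in locs:
                trials.append(dict(cue="N", condition="neutral", target_location=loc))
            continue
        # half L cues, half R cues within the condition
        n_left = int(even_partition(count, [1, 1], rng)[0])
        for cue, n_cue in (("L", n_left), ("R", count - n_left)):
            target_side = (
                (_E1_LEFT if cue == "L" else _E1_RIGHT)
                if label == "valid"
                else (_E1_RIGHT if cue == "L" else _E1_LEFT)
            )
            side = [l for l in target_side if l in spec.allowed_locations]
            for loc in _spread_over(n_cue, side, rng):
                trials.append(dict(cue=cue, condition=label, target_location=loc))
    for t in trials:
        t.update(distractor_location=None, distractor_present=False)
    return trials


def _build_dll_block(spec: DesignSpec, n_trials: int, rng) -> list[dict]:
    if spec.frequent_distractor_location is None:
        raise ConfigurationError(
            "distractor-location learning requires frequent_distractor_location"
        )
    probs = spec.condition_probabilities[LEARNING_DLL]
    labels = list(probs)
    counts = dict(zip(labels, even_partition(n_trials, [probs[c] for c in labels], rng)))
    freq_loc = spec.frequent_distractor_location
    infrequent_locs = [l for l in spec.allowed_locations if l != freq_loc]
    cue_present, cue_absent = (
        ("X", "N") if spec.cue_scheme == "letters" else ("ready", "ready")
    )

    trials: list[dict] = []
    for _ in range(int(counts.get("frequent", 0))):
        trials.append(
            dict(cue=cue_present, condition="frequent", distractor_location=freq_loc)
        )
    for loc in _spread_over(int(counts.get("infrequent", 0)), infrequent_locs, rng):
        trials.append(
            dict(cue=cue_present, condition="infrequent", distractor_location=loc)
        )
    for _ in range(int(counts.get("absent", 0))):
        trials.append(dict(cue=cue_absent, condition="absent", distractor_location=None))

    target_exclude_base = (
        {freq_loc} if spec.target_excludes_frequent_distractor else set()
    )
    for t in trials:
        exclude = set(target_exclude_base)
        if t["distractor_location"] is not None:
            exclude.add(t["distractor_location"])
        t["target_location"] = _choice_excluding(rng, spec.allowed_locations, exclude)
        t["distractor_present"] = t["distractor_location"] is not None
    return trials


def _build_tll_block(spec: DesignSpec, n_trials: int, rng) -> list[dict]:
    if spec.frequent_target_location is None:
        raise ConfigurationError(
            "target-location learning requires frequent_target_location"
        )
    probs = spec.condition_probabilities[LEARNING_TLL]
    labels = list(probs)
    counts = dict(zip(labels, even_partition(n_trials, [probs[c] for c in labels], rng)))
    freq_loc = spec.frequent_target_location
    infrequent_locs = [l for l in spec.allowed_locations if l != freq_loc]
    present_rate = spec.distractor_present_rate.get(LEARNING_TLL, 0.0)

    trials: list[dict] = []
    for label in ("frequent", "infrequent"):
        count = int(counts.get(label, 0))
        if label == "frequent":
            locs = [freq_loc] * count
        else:
            locs = _spread_over(count, infrequent_locs, rng)
        # distractor presence balanced within each target condition
        n_present = int(even_partition(count, [present_rate, 1 - present_rate], rng)[0])
        present_flags = [True] * n_present + [False] * (count - n_present)
        rng.shuffle(present_flags)
        for loc, present in zip(locs, present_flags):
            dloc = (
                _choice_excluding(rng, spec.allowed_locations, {loc})
                if present
                else None
            )
            trials.append(
                dict(
                    cue="ready",
                    condition=label,
                    target_location=loc,
                    distractor_location=dloc,
                    distractor_present=present,
                )
            )
    return trials


def _build_random_block(spec: DesignSpec, block_type: str, n_trials: int, rng) -> list[dict]:
    present_rate = spec.distractor_present_rate.get(block_type, 0.5)
    n_present = int(even_partition(n_trials, [present_rate, 1 - present_rate], rng)[0])
    flags = [True] * n_present + [False] * (n_trials - n_present)
    rng.shuffle(flags)
    trials = []
    for present in flags:
        tloc = _choice_excluding(rng, spec.allowed_locations, set())
        dloc = (
            _choice_excluding(rng, spec.allowed_locations, {tloc}) if present else None
        )
        trials.append(
            dict(
                cue="ready",
                condition=None,
                target_location=tloc,
                distractor_location=dloc,
                distractor_present=present,
            )
        )
    return trials


_BLOCK_BUILDERS = {
    CUED: _build_cued_block,
    LEARNING_DLL: _build_dll_block,
    LEARNING_TLL: _build_tll_block,
}


def _build_block(
    spec: DesignSpec, block_type: str, n_trials: int, block_id: int, start_index: int, rng
) -> list[TrialSpec]:
    if block_type in _BLOCK_BUILDERS:
        raw = _BLOCK_BUILDERS[block_type](spec, n_trials, rng)
    elif block_type in (BASELINE, EXTINCTION):
        raw = _build_random_block(spec, block_type, n_trials, rng)
    else:  # pragma: no cover - guarded by DesignSpec.validate
        raise ConfigurationError(f"unknown block_type {block_type!r}")
    rng.shuffle(raw)
    return [
        TrialSpec(
            trial_index=start_index + i,
            block_id=block_id,
            block_type=block_type,
            **t,
        )
        for i, t in enumerate(raw)
    ]


# ---------------------------------------------------------------------------
# Public builders
# ---------------------------------------------------------------------------


def build_schedule(
    spec: DesignSpec,
    participant_seed: int,
    block_type: str | None = None,
    n_trials: int | None = None,
) -> list[TrialSpec]:
    """Build one homogeneous randomized schedule with exact condition counts.

    By default the block type is the first in the design's sequence and
    ``n_trials`` is the total number of trials of that type in the sequence
    (e.g. 160 for the two 80-trial cued blocks), so per-condition counts match
    the printed session totals. Same seed, same schedule.
    """
    if participant_seed < 0:
        raise ConfigurationError("participant_seed must be a non-negative integer")
    if block_type is None:
        block_type = spec.block_sequence[0][0]
    if n_trials is None:
        n_trials = sum(n for bt, n in spec.block_sequence if bt == block_type)
    rng = np.random.default_rng(np.random.SeedSequence(participant_seed))
    return _build_block(spec, block_type, n_trials, block_id=0, start_index=0, rng=rng)


def build_session(
    spec: DesignSpec, participant_seed: int, tll_first: bool = True
) -> list[TrialSpec]:
    """Build the full block sequence for one participant.

    ``tll_first=False`` swaps the target-location and distractor-location
    learning groups (the counterbalancing used across participants). The two
    extinction blocks (100% distractor present) keep their positions.
    """
    if participant_seed < 0:
        raise ConfigurationError("participant_seed must be a non-negative integer")
    rng = np.random.default_rng(np.random.SeedSequence(participant_seed))
    swap = {LEARNING_TLL: LEARNING_DLL, LEARNING_DLL: LEARNING_TLL}
    trials: list[TrialSpec] = []
    index = 0
    for block_id, (block_type, n) in enumerate(spec.block_sequence):
        bt = block_type if tll_first else swap.get(block_type, block_type)
        block = _build_block(spec, bt, n, block_id=block_id, start_index=index, rng=rng)
        trials.extend(block)
        index += n
    return trials
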