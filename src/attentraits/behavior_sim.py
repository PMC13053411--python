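"""Synthetic trial-level RT and accuracy generator.

The generator implements the latent-trait measurement model that underlies
individual-differences analyses of attention tasks: each participant carries a
vector of latent condition effects (how much an invalid cue slows them, how
much an infrequent distractor location costs them, how much a salient
distractor captures them) drawn from a multivariate normal across the
population, and every trial adds independent within-participant noise on top
of a participant-specific baseline.

Reaction time is additive-normal::

    RT = baseline + sum(applicable latent effects) + Normal(0, within_rt_sd)

clipped by the response deadline (a draw beyond the deadline becomes a
non-response). Accuracy is Bernoulli with a logistic (log-odds) model so that
condition effects compose additively on a bounded scale. A small lapse
process replaces trials with fast guesses, invalid key presses, or
non-responses so that downstream trial filters are exercised.

Latent effect keys
------------------
``validity``            invalid minus valid cued-trial cost (ms / log-odds)
``tl_frequency``        infrequent minus frequent target-location cost
``dl_frequency``        infrequent minus frequent distractor-location cost
``presence_tll``        distractor present-vs-absent cost in TLL blocks
``presence_dll``        same in DLL blocks
``presence``            fallback presence cost for any other block type

Accuracy effects use the same keys with positive values meaning *lower*
accuracy in the costly condition.

Per-participant sub-streams are derived as
``SeedSequence(master_seed, spawn_key=(participant_id, k))`` (k=0 for the
latent draw, k=1 for trial noise), so a participant's data do not depend on
how many other participants are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import designs
from .errors import ConfigurationError

__all__ = [
    "EFFECT_KEYS",
    "TRIAL_COLUMNS",
    "PopulationParams",
    "ParticipantParams",
    "draw_participants",
    "emit_trials",
    "schedule_to_frame",
    "simulate_experiment",
]

EFFECT_KEYS = (
    "validity",
    "tl_frequency",
    "dl_frequency",
    "presence_tll",
    "presence_dll",
    "presence",
)

TRIAL_COLUMNS = [
    "participant_id",
    "block_id",
    "block_type",
    "trial_index",
    "cue",
    "condition",
    "target_location",
    "distractor_location",
    "distractor_present",
    "rt_ms",
    "correct",
    "responded",
    "key_valid",
]


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


@dataclass(frozen=True)
class PopulationParams:
    """Population-level generative parameters.

    ``latent_correlation`` is the correlation matrix of the per-participant
    latent effects listed in ``latent_names`` (shared between the RT and
    accuracy latent vectors, which are drawn independently of each other);
    omitted effects are uncorrelated.
    """

    n_participants: int = 30
    mean_effects: dict[str, float] = field(default_factory=dict)  # ms
    between_sd: dict[str, float] = field(default_factory=dict)  # ms
    mean_accuracy_effects: dict[str, float] = field(default_factory=dict)  # log-odds
    between_sd_accuracy: dict[str, float] = field(default_factory=dict)  # log-odds
    latent_names: tuple[str, ...] = ()
    latent_correlation: tuple[tuple[float, ...], ...] | None = None
    baseline_rt_mean: float = 800.0
    baseline_rt_sd: float = 80.0
    within_rt_sd: float = 200.0
    baseline_accuracy: float = 0.9
    baseline_accuracy_sd_logodds: float = 0.3
    lapse_rate: float = 0.02
    response_deadline_ms: float = 2225.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be positive")
        for name, d in (("between_sd", self.between_sd),
                        ("between_sd_accuracy", self.between_sd_accuracy)):
            if any(v < 0 for v in d.values()):
                raise ConfigurationError(f"{name} values must be non-negative")
        if not 0.0 < self.baseline_accuracy < 1.0:
            raise ConfigurationError("baseline_accuracy must be in (0, 1)")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ConfigurationError("lapse_rate must be in [0, 1]")
        if self.within_rt_sd < 0 or self.baseline_rt_sd < 0:
            raise ConfigurationError("SDs must be non-negative")
        unknown = [
            k
            for d in (self.mean_effects, self.between_sd,
                      self.mean_accuracy_effects, self.between_sd_accuracy)
            for k in d
            if k not in EFFECT_KEYS
        ]
        if unknown:
            raise ConfigurationError(f"unknown effect keys: {sorted(set(unknown))}")
        # validate the latent correlation matrix once, eagerly
        self.correlation_matrix()

    def correlation_matrix(self) -> tuple[tuple[str, ...], np.ndarray]:
        names = tuple(self.latent_names)
        if self.latent_correlation is None:
            return names, np.eye(len(names))
        R = np.asarray(self.latent_correlation, dtype=float)
        if R.shape != (len(names), len(names)):
            raise ConfigurationError(
                "latent_correlation shape does not match latent_names"
            )
        if not np.allclose(R, R.T, atol=1e-12) or not np.allclose(
            np.diag(R), 1.0, atol=1e-12
        ):
            raise ConfigurationError(
                "latent_correlation must be symmetric with unit diagonal"
            )
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ConfigurationError("latent_correlation is not positive semi-definite")
        return names, R


@dataclass(frozen=True)
class ParticipantParams:
    """Latent per-participant parameters (deterministic given the master seed)."""

    participant_id: int
    rt_effects: dict[str, float]
    accuracy_effects: dict[str, float]
    baseline_rt: float
    baseline_logodds: float


def _participant_rng(pop: PopulationParams, participant_id: int, stream: int):
    seq = np.random.SeedSequence(pop.master_seed, spawn_key=(participant_id, stream))
    return np.random.default_rng(seq)


def _correlated_draw(names, L, rng, means, sds) -> dict[str, float]:
    z = rng.standard_normal(len(names)) if names else np.empty(0)
    corr_z = L @ z if names else z
    out: dict[str, float] = {}
    for key in EFFECT_KEYS:
        mean = means.get(key, 0.0)
        sd = sds.get(key, 0.0)
        if key in names:
            out[key] = mean + sd * float(corr_z[names.index(key)])
        elif sd > 0:
            out[key] = mean + sd * float(rng.standard_normal())
        elif mean != 0.0:
            out[key] = mean
    return out


def draw_participants(pop: PopulationParams) -> list[ParticipantParams]:
    """Draw the latent participant parameters for the whole sample."""
    names, R = pop.correlation_matrix()
    # PSD-safe factor (eigen decomposition handles singular R, e.g. rho = 1)
    if len(names):
        w, V = np.linalg.eigh(R)
        L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    else:
        L = np.empty((0, 0))
    participants = []
    for pid in range(pop.n_participants):
        rng = _participant_rng(pop, pid, stream=0)
        rt_eff = _correlated_draw(names, L, rng, pop.mean_effects, pop.between_sd)
        acc_eff = _correlated_draw(
            names, L, rng, pop.mean_accuracy_effects, pop.between_sd_accuracy
        )
        baseline_rt = pop.baseline_rt_mean + pop.baseline_rt_sd * rng.standard_normal()
        baseline_lo = _logit(pop.baseline_accuracy) + (
            pop.baseline_accuracy_sd_logodds * rng.standard_normal()
        )
        participants.append(
            ParticipantParams(
                participant_id=pid,
                rt_effects=rt_eff,
                accuracy_effects=acc_eff,
                baseline_rt=float(baseline_rt),
                baseline_logodds=float(baseline_lo),
            )
        )
    return participants


def example_population(n_participants: int = 27, master_seed: int = 0) -> PopulationParams:
    """A representative population for the four-item statistical-learning task.

    Mean condition effects follow the group RT/accuracy differences typical of
    this paradigm (target-location frequency ~38 ms, distractor-location
    frequency ~20 ms, distractor presence ~40–65 ms, with the corresponding
    accuracy costs on the log-odds scale). Between-subject SDs are
    reconstructions from group-level standard errors (se × sqrt(n) minus the
    trial-noise share), not directly observed quantities; within-trial RT noise
    defaults to 200 ms.
    """
    return PopulationParams(
        n_participants=n_participants,
        mean_effects={
            "tl_frequency": 38.0,
            "dl_frequency": 20.0,
            "presence_tll": 65.0,
            "presence_dll": 39.0,
        },
        between_sd={
            "tl_frequency": 35.0,
            "dl_frequency": 25.0,
            "presence_tll": 40.0,
            "presence_dll": 40.0,
        },
        mean_accuracy_effects={
            "tl_frequency": 0.25,
            "dl_frequency": 0.03,
            "presence_tll": 0.45,
            "presence_dll": 0.45,
        },
        between_sd_accuracy={
            "tl_frequency": 0.20,
            "dl_frequency": 0.15,
            "presence_tll": 0.30,
            "presence_dll": 0.30,
        },
        latent_names=("tl_frequency", "dl_frequency", "presence_tll", "presence_dll"),
        baseline_accuracy=0.88,
        master_seed=master_seed,
    )


def schedule_to_frame(schedule: list[designs.TrialSpec]) -> pd.DataFrame:
    """Tabulate a schedule (outcome columns absent)."""
    return pd.DataFrame(
        {
            "block_id": [t.block_id for t in schedule],
            "block_type": [t.block_type for t in schedule],
            "trial_index": [t.trial_index for t in schedule],
            "cue": [t.cue for t in schedule],
            "condition": [t.condition for t in schedule],
            "target_location": [t.target_location for t in schedule],
            "distractor_location": [
                np.nan if t.distractor_location is None else t.distractor_location
                for t in schedule
            ],
            "distractor_present": [t.distractor_present for t in schedule],
        }
    )


def _effect_terms(frame: pd.DataFrame, effects: dict[str, float]) -> np.ndarray:
    """Per-trial sum of the latent effects that apply to each trial."""
    block = frame["block_type"].to_numpy()
    cond = frame["condition"].to_numpy(dtype=object)
    present = frame["distractor_present"].to_numpy(dtype=bool)
    total = np.zeros(len(frame))
    total += np.where(
        (block == designs.CUED) & (cond == "invalid"), effects.get("validity", 0.0), 0.0
    )
    total += np.where(
        (block == designs.LEARNING_TLL) & (cond == "infrequent"),
        effects.get("tl_frequency", 0.0),
        0.0,
    )
    total += np.where(
        (block == designs.LEARNING_DLL) & (cond == "infrequent"),
        effects.get("dl_frequency", 0.0),
        0.0,
    )
    fallback = effects.get("presence", 0.0)
    presence_cost = np.where(
        block == designs.LEARNING_TLL,
        effects.get("presence_tll", fallback),
        np.where(
            block == designs.LEARNING_DLL, effects.get("presence_dll", fallback), fallback
        ),
    )
    total += np.where(present, presence_cost, 0.0)
    return total


def emit_trials(
    participant: ParticipantParams,
    schedule: list[designs.TrialSpec] | pd.DataFrame,
    pop: PopulationParams,
) -> pd.DataFrame:
    """Simulate outcomes for one participant over a schedule.

    Returns the tidy trial table (one row per trial). ``rt_ms`` is NaN iff
    the trial ended without a response.
    """
    if isinstance(schedule, pd.DataFrame):
        frame = schedule.copy()
    else:
        if not schedule:
            raise ConfigurationError("schedule must be non-empty")
        frame = schedule_to_frame(schedule)
    n = len(frame)
    rng = _participant_rng(pop, participant.participant_id, stream=1)

    rt_mean = participant.baseline_rt + _effect_terms(frame, participant.rt_effects)
    rt = rt_mean + rng.normal(0.0, pop.within_rt_sd, size=n)
    rt = np.maximum(rt, 1.0)

    logodds = participant.baseline_logodds - _effect_terms(
        frame, participant.accuracy_effects
    )
    p_correct = 1.0 / (1.0 + np.exp(-logodds))
    correct = rng.random(n) < p_correct

    responded = rt <= pop.response_deadline_ms
    key_valid = np.ones(n, dtype=bool)

    # lapse process: fast guess / invalid key / non-response
    lapse = rng.random(n) < pop.lapse_rate
    lapse_kind = rng.integers(0, 3, size=n)
    fast = lapse & (lapse_kind == 0)
    rt[fast] = rng.uniform(80.0, 240.0, size=int(fast.sum()))
    correct[fast] = rng.random(int(fast.sum())) < 0.5
    responded[fast] = True
    invalid = lapse & (lapse_kind == 1)
    key_valid[invalid] = False
    noresp = lapse & (lapse_kind == 2)
    responded[noresp] = False

    rt = np.where(responded, rt, np.nan)
    correct = np.where(responded, correct, False)
    key_valid = key_valid & responded

    out = frame.copy()
    out.insert(0, "participant_id", participant.participant_id)
    out["rt_ms"] = rt
    out["correct"] = correct.astype(bool)
    out["responded"] = responded.astype(bool)
    out["key_valid"] = key_valid.astype(bool)
    return out[TRIAL_COLUMNS]


def simulate_experiment(
    pop: PopulationParams,
    spec: designs.DesignSpec,
    counterbalance: bool = True,
) -> pd.DataFrame:
    """Simulate the full sample: schedules, frequent locations, and outcomes.

    Frequent target/distractor locations are drawn per participant from their
    own seeded stream (distinct locations when the design requires it); the
    learning-group order alternates across participants when
    ``counterbalance`` is set.
    """
    participants = draw_participants(pop)
    frames = []
    for part in participants:
        rng = _participant_rng(pop, part.participant_id, stream=2)
        locs = list(spec.allowed_locations)
        spec_i = spec
        needs_target = any(bt == designs.LEARNING_TLL for bt, _ in spec.block_sequence)
        if needs_target or spec.frequent_target_location is not None:
            t_loc = int(locs[rng.integers(len(locs))])
            if spec.require_distinct_frequent:
                rest = [l for l in locs if l != t_loc]
                d_loc = int(rest[rng.integers(len(rest))])
            elif spec.frequent_distractor_location is not None:
                d_loc = t_loc if spec.experiment_id == "E2" else int(
                    locs[rng.integers(len(locs))]
                )
            else:
                d_loc = None
            spec_i = spec.with_frequent_locations(t_loc, d_loc)
        elif spec.frequent_distractor_location is not None:
            d_loc = int(locs[rng.integers(len(locs))])
            spec_i = spec.with_frequent_locations(distractor=d_loc)
        participant_seed = int(
            np.random.SeedSequence(
                pop.master_seed, spawn_key=(part.participant_id, 3)
            ).generate_state(1)[0]
        )
        block_types = {bt for bt, _ in spec.block_sequence}
        has_both = designs.LEARNING_TLL in block_types and designs.LEARNING_DLL in block_types
        tll_first = (
            (part.participant_id % 2 == 0) if (counterbalance and has_both) else True
        )
        schedule = designs.build_session(spec_i, participant_seed, tll_first=tll_first)
        frames.append(emit_trials(part, schedule, pop))
    return pd.concat(frames, ignore_index=True)
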