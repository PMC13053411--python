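"""End-to-end orchestration: simulate → screen → filter → effects →
reliability → gated inference → sensitivity, with persisted artifacts.

A :class:`RunConfig` names an experiment preset, the generative population,
the contrasts to analyze, the correlation pairs to test behind the
reliability gate, and any sensitivity simulations. :func:`run` executes the
stages in order and returns a :class:`RunReport`; with an output directory it
also persists the trial table, effect-score table, group comparisons,
split-half summaries, correlation table, and a JSON report whose numbers are
all recomputable from those CSVs. Identical config + seeds give identical
reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import designs, effects
from .behavior_sim import PopulationParams, example_population, simulate_experiment
from .errors import ConfigurationError
from .inference import (
    DEFAULT_KAPPA,
    BayesCorrelationResult,
    gated_correlation,
)
from .preprocessing import (
    DEFAULT_RT_WINDOW,
    ScreeningCriteria,
    filter_trials,
    screen_participants,
)
from .reliability import SplitHalfResult, permutation_splithalf
from .sensitivity import SensitivitySpec, run_sensitivity

__all__ = ["CorrelationSpec", "RunConfig", "RunReport", "run", "load_config"]

logger = logging.getLogger("attentraits")

_PACKAGE_VERSION = "0.1.0"


@dataclass(frozen=True)
class CorrelationSpec:
    """One reliability-gated correlation: two contrasts on one measure."""

    contrast_x: str
    contrast_y: str
    measure: str = "rt"
    override: bool = False


@dataclass(frozen=True)
class RunConfig:
    experiment: str = "E3"
    population: PopulationParams = field(default_factory=example_population)
    screening: ScreeningCriteria = field(default_factory=ScreeningCriteria)
    contrasts: tuple[str, ...] = (
        "tl_frequency",
        "dl_frequency",
        "distractor_presence_tll",
        "distractor_presence_dll",
    )
    correlation_pairs: tuple[CorrelationSpec, ...] = (
        CorrelationSpec("tl_frequency", "dl_frequency", "rt"),
        CorrelationSpec("distractor_presence_tll", "distractor_presence_dll", "rt"),
    )
    correlation_value: str = "raw_difference"
    n_splits: int = 5000
    splithalf_seed: int = 0
    kappa: float = DEFAULT_KAPPA
    family_size: int = 1
    rt_window: tuple[float, float] = DEFAULT_RT_WINDOW
    sensitivity: tuple[SensitivitySpec, ...] = ()

    def __post_init__(self) -> None:
        if self.experiment not in designs.PRESETS:
            raise ConfigurationError(
                f"unknown experiment preset {self.experiment!r}; "
                f"choose from {sorted(designs.PRESETS)}"
            )
        for name in self.contrasts:
            if name not in effects.STANDARD_CONTRASTS:
                raise ConfigurationError(f"unknown contrast {name!r}")
        for pair in self.correlation_pairs:
            for name in (pair.contrast_x, pair.contrast_y):
                if name not in self.contrasts:
                    raise ConfigurationError(
                        f"correlation pair references contrast {name!r} "
                        "not in the analyzed contrasts"
                    )
            if pair.measure not in ("rt", "accuracy"):
                raise ConfigurationError(f"unknown measure {pair.measure!r}")


@dataclass
class RunReport:
    config_hash: str
    filter_report: dict
    screening: dict
    group_comparisons: pd.DataFrame
    splithalf: dict[tuple[str, str], SplitHalfResult]
    correlations: list[BayesCorrelationResult]
    sensitivity: list[dict]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "screening": self.screening,
            "filter_report": self.filter_report,
            "group_comparisons": self.group_comparisons.to_dict(orient="records"),
            "splithalf": [res.summary() for res in self.splithalf.values()],
            "correlations": [res.to_dict() for res in self.correlations],
            "sensitivity": self.sensitivity,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=_jsonable, indent=2, **kwargs)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute the full analysis pipeline for one configured run."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    spec = designs.PRESETS[config.experiment]()
    logger.info("simulating %s: %d participants", config.experiment,
                config.population.n_participants)
    trials = simulate_experiment(config.population, spec)

    retained, excluded = screen_participants(trials, config.screening)
    logger.info("screening: %d retained, %d excluded", len(retained), len(excluded))
    trials = trials.loc[trials["participant_id"].isin(retained)]

    accuracy_set, rt_set, filter_report = filter_trials(trials, config.rt_window)
    logger.info(
        "filtering: %d -> accuracy %d, rt %d",
        filter_report.n_input, filter_report.n_accuracy, filter_report.n_rt,
    )

    contrast_objs = [effects.STANDARD_CONTRASTS[name] for name in config.contrasts]
    scores = effects.effect_scores(accuracy_set, rt_set, contrast_objs)
    comparisons = pd.concat(
        [
            effects.group_comparisons(scores, config.family_size, value="normalized_score"),
            effects.group_comparisons(scores, config.family_size, value="raw_difference"),
        ],
        ignore_index=True,
    )

    splithalf: dict[tuple[str, str], SplitHalfResult] = {}
    for i, contrast in enumerate(contrast_objs):
        for j, (measure, data) in enumerate((("rt", rt_set), ("accuracy", accuracy_set))):
            seed = int(
                np.random.SeedSequence(
                    config.splithalf_seed, spawn_key=(i, j)
                ).generate_state(1)[0]
            )
            splithalf[(contrast.name, measure)] = permutation_splithalf(
                data, contrast, measure, n_splits=config.n_splits, seed=seed
            )

    correlations = []
    for pair in config.correlation_pairs:
        sx = splithalf[(pair.contrast_x, pair.measure)]
        sy = splithalf[(pair.contrast_y, pair.measure)]
        wide = (
            scores.loc[scores["measure"] == pair.measure]
            .pivot(index="participant_id", columns="contrast",
                   values=config.correlation_value)
            .loc[:, [pair.contrast_x, pair.contrast_y]]
            .dropna()
        )
        correlations.append(
            gated_correlation(
                sx, sy,
                wide[pair.contrast_x].to_numpy(),
                wide[pair.contrast_y].to_numpy(),
                override=pair.override,
                kappa=config.kappa,
            )
        )

    sensitivity_summaries = []
    for sens_spec in config.sensitivity:
        result = run_sensitivity(sens_spec)
        sensitivity_summaries.append(result.summary())

    report = RunReport(
        config_hash=_config_hash(config),
        filter_report=filter_report.to_dict(),
        screening={
            "n_retained": len(retained),
            "excluded": {str(k): v for k, v in excluded.items()},
        },
        group_comparisons=comparisons,
        splithalf=splithalf,
        correlations=correlations,
        sensitivity=sensitivity_summaries,
        provenance={
            "config_hash": _config_hash(config),
            "experiment": config.experiment,
            "master_seed": config.population.master_seed,
            "splithalf_seed": config.splithalf_seed,
            "n_splits": config.n_splits,
            "version": _PACKAGE_VERSION,
        },
    )

    if out is not None:
        trials.to_csv(out / "trials.csv", index=False)
        scores.to_csv(out / "effect_scores.csv", index=False)
        comparisons.to_csv(out / "group_comparisons.csv", index=False)
        pd.DataFrame([r.summary() for r in splithalf.values()]).to_csv(
            out / "splithalf_summary.csv", index=False
        )
        pd.DataFrame([c.to_dict() for c in correlations]).to_csv(
            out / "correlations.csv", index=False
        )
        (out / "report.json").write_text(report.to_json())
    return report


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

_NESTED_FIELDS = {
    "population": PopulationParams,
    "screening": ScreeningCriteria,
}


def _build_dataclass(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    converted = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        converted[key] = value
    return cls(**converted)


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    for key, cls in _NESTED_FIELDS.items():
        if key in data and isinstance(data[key], dict):
            data[key] = _build_dataclass(cls, data[key])
    if "sensitivity" in data:
        data["sensitivity"] = tuple(
            _build_dataclass(SensitivitySpec, s) if isinstance(s, dict) else s
            for s in data["sensitivity"]
        )
    if "correlation_pairs" in data:
        data["correlation_pairs"] = tuple(
            _build_dataclass(CorrelationSpec, p) if isinstance(p, dict) else p
            for p in data["correlation_pairs"]
        )
    return _build_dataclass(RunConfig, data)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON) file with schema validation."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError("run config must be a mapping")
    return config_from_dict(data)
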