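"""Plain-text (YAML) experiment configuration.

A config file may set any field of the task, the agent hyperparameters and
the run, plus a lesion schedule per condition, e.g.::

    task:
      n_words: 4
      preference_strength: 0.75
    hyper:
      alpha_action: 4
      eta: 1.0
    run:
      n_trials: 100
      n_seeds: 50
      seed_base: 1234
    conditions:
      single:
        - {target: extrinsic_A, omega: 0.8, onset_trial: 1}
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .engine import Hyperparameters
from .experiments import ConditionSpec, DEFAULT_SEED_BASE, standard_conditions
from .lesions import LesionEntry, LesionSchedule
from .task_model import TaskConfig

__all__ = ["ExperimentConfig", "load_config"]


@dataclass
class ExperimentConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    hyper: Hyperparameters = field(default_factory=Hyperparameters)
    n_trials: int = 100
    n_seeds: int = 50
    seed_base: int = DEFAULT_SEED_BASE
    conditions: dict[str, ConditionSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.conditions:
            self.conditions = standard_conditions(
                self.n_trials, self.n_seeds, self.seed_base
            )


def load_config(path: str | None) -> ExperimentConfig:
    if path is None:
        return ExperimentConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    task = TaskConfig(**raw.get("task", {}))
    hyper = Hyperparameters(**raw.get("hyper", {}))
    run = raw.get("run", {})
    n_trials = int(run.get("n_trials", 100))
    n_seeds = int(run.get("n_seeds", 50))
    seed_base = int(run.get("seed_base", DEFAULT_SEED_BASE))
    conditions = {}
    for name, entries in (raw.get("conditions") or {}).items():
        schedule = LesionSchedule(
            [
                LesionEntry(e["target"], float(e["omega"]), int(e["onset_trial"]))
                for e in (entries or [])
            ]
        )
        conditions[name] = ConditionSpec(name, schedule, n_trials, n_seeds, seed_base)
    return ExperimentConfig(
        task=task,
        hyper=hyper,
        n_trials=n_trials,
        n_seeds=n_seeds,
        seed_base=seed_base,
        conditions=conditions,
    )
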