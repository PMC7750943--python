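"""Orchestration of the lesion experiment.

Four conditions are simulated over paired random seeds: control (no
lesion), single (likelihood precision lowered to 0.8 at trial 1),
severe dual (additionally transition precision 0.7 at trial 20) and mild
dual (transition precision 0.9 at trial 20).  Seed ``k`` of every condition
draws the identical per-trial random stream, so conditions are paired
counterfactuals: absent the lesion, a lesioned session would reproduce the
control session bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import Hyperparameters, run_trial
from .lesions import EXTRINSIC_A, INTRINSIC_B, LesionEntry, LesionSchedule, apply_schedule
from .task_model import AUDITORY, FB_CORRECT, LISTEN, SILENCE, WORD, Environment, TaskConfig, build_model

__all__ = [
    "ConditionSpec",
    "SessionResult",
    "standard_conditions",
    "run_session",
    "run_condition",
    "summarize_performance",
    "performance_table",
]

DEFAULT_SEED_BASE = 1234


@dataclass
class ConditionSpec:
    name: str
    schedule: LesionSchedule
    n_trials: int = 100
    n_seeds: int = 50
    seed_base: int = DEFAULT_SEED_BASE


def standard_conditions(
    n_trials: int = 100, n_seeds: int = 50, seed_base: int = DEFAULT_SEED_BASE
) -> dict[str, ConditionSpec]:
    """The four study conditions with their lesion schedules."""
    mk = lambda name, entries: ConditionSpec(
        name, LesionSchedule(entries), n_trials, n_seeds, seed_base
    )
    return {
        "control": mk("control", []),
        "single": mk("single", [LesionEntry(EXTRINSIC_A, 0.8, 1)]),
        "severe_dual": mk(
            "severe_dual",
            [LesionEntry(EXTRINSIC_A, 0.8, 1), LesionEntry(INTRINSIC_B, 0.7, 20)],
        ),
        "mild_dual": mk(
            "mild_dual",
            [LesionEntry(EXTRINSIC_A, 0.8, 1), LesionEntry(INTRINSIC_B, 0.9, 20)],
        ),
    }


@dataclass
class SessionResult:
    """Per-seed record of one session.

    ``a_blocks``/``b_blocks`` are the post-trial Dirichlet counts of the two
    lesionable blocks (word→cue listening likelihood; word transitions);
    ``a_ref_blocks``/``b_ref_blocks`` the reference priors in force at each
    trial (updated when a lesion resets a block).  ``traces`` holds the
    word-factor depolarisation per trial, shape (T, n_iterations, n_words).
    """

    seed: int
    targets: np.ndarray
    spoken: np.ndarray
    correct: np.ndarray
    a_blocks: np.ndarray
    b_blocks: np.ndarray
    a_ref_blocks: np.ndarray
    b_ref_blocks: np.ndarray
    traces: list[np.ndarray] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.correct.size

    def percent_correct(self) -> float:
        return float(self.correct.mean() * 100.0)


def _aud_block(counts, n_words: int) -> np.ndarray:
    # counts accumulate at report = silence during listening
    return counts.a[AUDITORY][1:, :, SILENCE, LISTEN].copy()


def _word_block(counts) -> np.ndarray:
    return counts.b[WORD][:, :, 0].copy()


def run_session(
    schedule: LesionSchedule,
    config: TaskConfig,
    hyper: Hyperparameters,
    session_seed: int,
    n_trials: int,
    record_traces: bool = True,
) -> SessionResult:
    """Run one seeded session of ``n_trials`` trials under a lesion schedule.

    Each trial uses an independent counter-based substream
    ``default_rng([session_seed, trial])`` so that the target draw and the
    action-sampling draws align exactly across conditions sharing the seed.
    """
    model, counts = build_model(config, hyper)
    env = Environment(config)
    n = config.n_words

    targets = np.zeros(n_trials, dtype=int)
    spoken = np.zeros(n_trials, dtype=int)
    correct = np.zeros(n_trials, dtype=bool)
    a_blocks = np.zeros((n_trials, n, n))
    b_blocks = np.zeros((n_trials, n, n))
    a_refs = np.zeros((n_trials, n, n))
    b_refs = np.zeros((n_trials, n, n))
    traces: list[np.ndarray] = []

    a_ref = _aud_block(counts, n)
    b_ref = _word_block(counts)

    for t in range(1, n_trials + 1):
        counts, applied = apply_schedule(counts, t, schedule, hyper.prior_scale)
        for entry in applied:
            if entry.target == EXTRINSIC_A:
                a_ref = _aud_block(counts, n)
            else:
                b_ref = _word_block(counts)
        rng = np.random.default_rng([session_seed, t])
        record = run_trial(model, counts, env, hyper, rng)
        counts = record.counts
        i = t - 1
        targets[i] = env.target
        spoken[i] = env.actions[0]
        correct[i] = record.correct
        a_blocks[i] = _aud_block(counts, n)
        b_blocks[i] = _word_block(counts)
        a_refs[i] = a_ref
        b_refs[i] = b_ref
        if record_traces:
            traces.append(record.depolarization[WORD])

    return SessionResult(
        seed=session_seed,
        targets=targets,
        spoken=spoken,
        correct=correct,
        a_blocks=a_blocks,
        b_blocks=b_blocks,
        a_ref_blocks=a_refs,
        b_ref_blocks=b_refs,
        traces=traces,
    )


def run_condition(
    spec: ConditionSpec,
    config: TaskConfig | None = None,
    hyper: Hyperparameters | None = None,
    record_traces: bool = True,
    progress=None,
) -> list[SessionResult]:
    """Run every seeded session of one condition."""
    config = config or TaskConfig()
    hyper = hyper or Hyperparameters()
    sessions = []
    for k in range(spec.n_seeds):
        sessions.append(
            run_session(
                spec.schedule,
                config,
                hyper,
                spec.seed_base + k,
                spec.n_trials,
                record_traces=record_traces,
            )
        )
        if progress is not None:
            progress(spec.name, k + 1, spec.n_seeds)
    return sessions


def summarize_performance(sessions: list[SessionResult]) -> dict:
    """Terminal mean percent correct and the per-trial cumulative trajectory.

    The trajectory at trial ``t`` is the running proportion correct up to
    ``t``, averaged over sessions, with a normal-approximation 95% CI across
    sessions (absent for a single session).
    """
    if not sessions:
        raise ValueError("no sessions")
    correct = np.stack([s.correct for s in sessions]).astype(float)
    n_seeds, n_trials = correct.shape
    per_session_pc = correct.mean(axis=1) * 100.0
    cumulative = correct.cumsum(axis=1) / np.arange(1, n_trials + 1)
    mean_traj = cumulative.mean(axis=0) * 100.0
    if n_seeds >= 2:
        se = cumulative.std(axis=0, ddof=1) / np.sqrt(n_seeds) * 100.0
        ci = 1.96 * se
    else:
        ci = None
    return {
        "terminal_percent_correct": float(per_session_pc.mean()),
        "terminal_ci95": (
            float(1.96 * per_session_pc.std(ddof=1) / np.sqrt(n_seeds))
            if n_seeds >= 2
            else None
        ),
        "trajectory": mean_traj,
        "trajectory_ci95": ci,
    }


def performance_table(results: dict[str, list[SessionResult]]) -> pd.DataFrame:
    """Long-format per-trial performance table across conditions."""
    rows = []
    for name, sessions in results.items():
        summ = summarize_performance(sessions)
        traj = summ["trajectory"]
        ci = summ["trajectory_ci95"]
        for t in range(traj.size):
            rows.append(
                {
                    "condition": name,
                    "trial": t + 1,
                    "mean_percent_correct": traj[t],
                    "ci95": ci[t] if ci is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)
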