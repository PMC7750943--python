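"""Auditory word-repetition task: generative model and environment.

Each trial has three epochs — listen, repeat, feedback.  The environment
draws a target word uniformly, presents it as an auditory cue, and returns
"correct" feedback iff the word spoken at the repeat epoch matches the
target.  The agent's generative model mirrors this structure with three
hidden-state factors:

* **word** — the target word (``n_words`` states, identity transitions;
  the intrinsic/B lesion site),
* **report** — what the agent has spoken (silence + ``n_words`` states,
  set deterministically by the chosen action),
* **epoch** — listen → repeat → feedback, advancing deterministically.

Outcome modalities are auditory (silence + heard word; the word→cue map
during listening is the extrinsic/A lesion site), proprioceptive (echoes
the report) and feedback (null / correct / incorrect).  The environment
itself always uses the intact deterministic maps: lesions exist only in the
agent's model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .engine import DirichletParams, GenerativeModel, Hyperparameters
from .lesions import apply_precision_lesion

__all__ = [
    "AUDITORY",
    "PROPRIO",
    "FEEDBACK",
    "WORD",
    "REPORT",
    "EPOCH",
    "LISTEN",
    "REPEAT",
    "FB_EPOCH",
    "FB_NULL",
    "FB_CORRECT",
    "FB_INCORRECT",
    "SILENCE",
    "TaskConfig",
    "Environment",
    "build_model",
    "environment_step",
    "model_to_json",
    "model_from_json",
]

# modality / factor / epoch / outcome indices
AUDITORY, PROPRIO, FEEDBACK = 0, 1, 2
WORD, REPORT, EPOCH = 0, 1, 2
LISTEN, REPEAT, FB_EPOCH = 0, 1, 2
FB_NULL, FB_CORRECT, FB_INCORRECT = 0, 1, 2
SILENCE = 0


@dataclass
class TaskConfig:
    """Task parameters: vocabulary size, preference for correct feedback (nats),
    and trial length (listen → repeat → feedback)."""

    n_words: int = 4
    preference_strength: float = 0.525
    T: int = 3

    def __post_init__(self) -> None:
        if self.n_words < 2:
            raise ValueError("n_words must be >= 2")
        if self.preference_strength <= 0:
            raise ValueError("preference_strength must be > 0")
        if self.T != 3:
            raise ValueError("the word-repetition trial has exactly 3 epochs")


def build_model(
    config: TaskConfig, hyper: Hyperparameters
) -> tuple[GenerativeModel, DirichletParams]:
    """Construct the agent's generative model and its Dirichlet priors.

    The word→cue block of the auditory likelihood and the word-factor
    transitions are built intact (one-hot) and then lowered to precision
    ``hyper.omega_A`` / ``hyper.omega_B`` if below 1; Dirichlet priors are
    ``prior_scale`` times the (possibly lesioned) categorical arrays.
    """
    n = config.n_words
    nr = n + 1  # silence + words

    # word -> heard-word map during listening (rows 1..n; silence row unused)
    cue_map = np.eye(n)
    if hyper.omega_A < 1.0:
        cue_map = apply_precision_lesion(cue_map, hyper.omega_A)

    A_aud = np.zeros((nr, n, nr, 3))
    A_aud[1:, :, :, LISTEN] = cue_map[:, :, None]
    A_aud[SILENCE, :, :, REPEAT] = 1.0
    A_aud[SILENCE, :, :, FB_EPOCH] = 1.0

    A_prop = np.zeros((nr, n, nr, 3))
    for r in range(nr):
        A_prop[r, :, r, :] = 1.0

    A_fb = np.zeros((3, n, nr, 3))
    A_fb[FB_NULL, :, :, LISTEN] = 1.0
    A_fb[FB_NULL, :, :, REPEAT] = 1.0
    for w in range(n):
        for r in range(nr):
            spoken_right = r == w + 1  # silence (r == 0) is a failed repetition
            A_fb[FB_CORRECT if spoken_right else FB_INCORRECT, w, r, FB_EPOCH] = 1.0

    word_trans = np.eye(n)
    if hyper.omega_B < 1.0:
        word_trans = apply_precision_lesion(word_trans, hyper.omega_B)
    B_word = word_trans[:, :, None]

    B_report = np.zeros((nr, nr, nr))
    for u in range(nr):
        B_report[u, :, u] = 1.0

    B_epoch = np.zeros((3, 3, 1))
    B_epoch[REPEAT, LISTEN, 0] = 1.0
    B_epoch[FB_EPOCH, REPEAT, 0] = 1.0
    B_epoch[FB_EPOCH, FB_EPOCH, 0] = 1.0

    c = config.preference_strength
    C = [np.zeros(nr), np.zeros(nr), np.array([0.0, c, -c])]

    D = [np.full(n, 1.0 / n), _one_hot(nr, SILENCE), _one_hot(3, LISTEN)]

    # one sustained action per policy: stay silent or speak word j
    policies = np.zeros((nr, 2, 3), dtype=int)
    policies[:, :, REPORT] = np.arange(nr)[:, None]

    model = GenerativeModel(
        A=[A_aud, A_prop, A_fb],
        B=[B_word, B_report, B_epoch],
        C=C,
        D=D,
        policies=policies,
        T=config.T,
    )
    model.validate()
    counts = DirichletParams(
        a=[hyper.prior_scale * a for a in model.A],
        b=[hyper.prior_scale * b for b in model.B],
    )
    return model, counts


def _one_hot(n: int, i: int) -> np.ndarray:
    v = np.zeros(n)
    v[i] = 1.0
    return v


class Environment:
    """The generative process: intact, deterministic, never lesioned."""

    def __init__(self, config: TaskConfig):
        self.config = config
        self.target: int | None = None
        self.actions: list[int] = []
        self.correct: bool = False

    def begin_trial(self, rng: np.random.Generator) -> None:
        self.target = int(rng.integers(self.config.n_words))
        self.actions = []
        self.correct = False

    def register_action(self, control) -> None:
        control = np.atleast_1d(np.asarray(control, dtype=int))
        spoken = int(control[REPORT]) if control.size > 1 else int(control[0])
        if not (0 <= spoken <= self.config.n_words):
            raise ValueError(f"action {spoken} out of range")
        self.actions.append(spoken)
        if len(self.actions) == 1:
            # correctness is decided by the word spoken at the repeat epoch
            self.correct = spoken == self.target + 1

    def observe(self, t: int) -> tuple[int, int, int]:
        if self.target is None:
            raise RuntimeError("begin_trial must be called first")
        if t > len(self.actions):
            raise RuntimeError(f"cannot observe step {t}: missing actions")
        if t == 0:
            return (1 + self.target, SILENCE, FB_NULL)
        report = self.actions[t - 1]
        if t == 1:
            return (SILENCE, report, FB_NULL)
        fb = FB_CORRECT if self.correct else FB_INCORRECT
        return (SILENCE, report, fb)


def environment_step(env: Environment, action, rng=None) -> tuple[int, int, int]:
    """Register an action and return the next epoch's observations."""
    env.register_action(action)
    return env.observe(len(env.actions))


# --------------------------------------------------------------------------
# JSON model export / import (fixture support)
# --------------------------------------------------------------------------


def model_to_json(model: GenerativeModel) -> str:
    def pack(arrs):
        return [{"shape": list(a.shape), "data": np.asarray(a).ravel().tolist()} for a in arrs]

    return json.dumps(
        {
            "A": pack(model.A),
            "B": pack(model.B),
            "C": pack(model.C),
            "D": pack(model.D),
            "policies": {
                "shape": list(model.policies.shape),
                "data": model.policies.ravel().tolist(),
            },
            "T": model.T,
        }
    )


def model_from_json(text: str) -> GenerativeModel:
    raw = json.loads(text)

    def unpack(items):
        return [np.array(it["data"], dtype=float).reshape(it["shape"]) for it in items]

    policies = np.array(raw["policies"]["data"], dtype=int).reshape(
        raw["policies"]["shape"]
    )
    model = GenerativeModel(
        A=unpack(raw["A"]),
        B=unpack(raw["B"]),
        C=unpack(raw["C"]),
        D=unpack(raw["D"]),
        policies=policies,
        T=int(raw["T"]),
    )
    model.validate()
    return model
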