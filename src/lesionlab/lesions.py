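"""Precision-based in-silico lesions.

A lesion lowers the precision of a categorical mapping: in every column the
"plausible" (maximal) entry is set to the precision ``omega`` and the
remaining mass is spread uniformly over the implausible entries.  Lowering
the precision of the likelihood A models damage to extrinsic
(between-region) connections; lowering the precision of the transitions B
models damage to intrinsic (within-region) connections.  A lesion also
resets the targeted block's Dirichlet counts to ``prior_scale`` times the
lesioned matrix — a structural insult destroys the synaptic evidence
accumulated at that site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import DirichletParams, normalize_columns

__all__ = [
    "EXTRINSIC_A",
    "INTRINSIC_B",
    "LesionEntry",
    "LesionSchedule",
    "apply_precision_lesion",
    "apply_schedule",
]

EXTRINSIC_A = "extrinsic_A"
INTRINSIC_B = "intrinsic_B"


@dataclass(frozen=True)
class LesionEntry:
    target: str  # extrinsic_A or intrinsic_B
    omega: float
    onset_trial: int  # 1-based

    def __post_init__(self) -> None:
        if self.target not in (EXTRINSIC_A, INTRINSIC_B):
            raise ValueError(f"unknown lesion target {self.target!r}")
        if not (0.0 < self.omega <= 1.0):
            raise ValueError("omega must be in (0, 1]")
        if self.onset_trial < 1:
            raise ValueError("onset_trial must be >= 1")


@dataclass
class LesionSchedule:
    entries: list[LesionEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = [
            e if isinstance(e, LesionEntry) else LesionEntry(*e) for e in self.entries
        ]
        onsets = [e.onset_trial for e in self.entries]
        if onsets != sorted(onsets):
            raise ValueError("schedule entries must be sorted by onset_trial")

    def at_trial(self, trial: int) -> list[LesionEntry]:
        return [e for e in self.entries if e.onset_trial == trial]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def apply_precision_lesion(matrix: np.ndarray, omega: float) -> np.ndarray:
    """Lower the precision of a categorical matrix, column by column.

    The unique maximal ("plausible") entry of each column becomes ``omega``
    and every implausible entry ``(1 - omega) / (N - 1)``; columns stay
    normalised exactly.  With one-hot input and ``omega = 1`` the matrix is
    returned unchanged.
    """
    if not (0.0 < omega <= 1.0):
        raise ValueError("omega must be in (0, 1]")
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    out = np.full_like(matrix, (1.0 - omega) / (n - 1))
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        top = np.flatnonzero(col == col.max())
        if top.size != 1:
            raise ValueError(f"column {j} has tied maxima; plausible entry ambiguous")
        out[top[0], j] = omega
    return out


def apply_schedule(
    counts: DirichletParams,
    trial_index: int,
    schedule: LesionSchedule,
    prior_scale: float,
) -> tuple[DirichletParams, list[LesionEntry]]:
    """Apply every lesion whose onset is ``trial_index`` to the agent's counts.

    The lesion operates on the current Dirichlet mean of the targeted block
    (the word→cue listening block of the auditory likelihood, or the
    word-factor transition block) and resets that block's counts to
    ``prior_scale`` times the lesioned matrix; every other block is left
    untouched.  Returns the (possibly new) counts and the entries applied.
    """
    if trial_index < 1:
        raise ValueError("trial_index must be >= 1")
    applied = schedule.at_trial(trial_index)
    if not applied:
        return counts, []
    from . import task_model as tm  # local import avoids a module cycle

    new = counts.copy()
    for entry in applied:
        if entry.target == EXTRINSIC_A:
            # current mean word->cue map, read where evidence accumulates
            # (report = silence during listening)
            block = new.a[tm.AUDITORY][1:, :, tm.SILENCE, tm.LISTEN]
            mean = normalize_columns(block)
            lesioned = apply_precision_lesion(mean, entry.omega)
            new.a[tm.AUDITORY][:, :, :, tm.LISTEN] = 0.0
            new.a[tm.AUDITORY][1:, :, :, tm.LISTEN] = (
                prior_scale * lesioned[:, :, None]
            )
        else:
            mean = normalize_columns(new.b[tm.WORD][:, :, 0])
            lesioned = apply_precision_lesion(mean, entry.omega)
            new.b[tm.WORD][:, :, 0] = prior_scale * lesioned
    return new, applied
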