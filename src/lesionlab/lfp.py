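"""Simulated local field potentials from belief-update iteration traces.

The pre-normalisation log-belief of a state unit across update iterations is
treated as its membrane depolarisation (post-synaptic potential).  The raw
LFP is the first-order difference (gradient) of that depolarisation,
concatenated across time steps and trials, linearly upsampled twofold and
bandpass filtered (zero-phase, second-order Butterworth, 4-32 Hz by
default).  Positive deflections are read as excitatory responses, negative
as inhibitory; per-trial totals of the two summarise the
excitatory/inhibitory balance.

Timing convention: 16 update iterations span one 250 ms epoch, i.e. 64
samples/s raw, 128 samples/s after upsampling — the 4-32 Hz band then sits
strictly below the Nyquist frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = ["LFPTrace", "simulate_lfp", "synaptic_balance", "UPSAMPLE", "RAW_RATE"]

RAW_RATE = 64.0  # iterations per second (16 per 250 ms epoch)
UPSAMPLE = 2


@dataclass
class LFPTrace:
    signal: np.ndarray  # filtered amplitude, arbitrary units
    sample_rate: float  # Hz
    trial_boundaries: np.ndarray  # start sample of each trial
    unit_selector: np.ndarray  # recorded unit per trial


def bandpass(
    signal: np.ndarray, band: tuple[float, float], sample_rate: float, order: int = 2
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth bandpass."""
    lo, hi = band
    nyq = sample_rate / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"band {band} must lie strictly inside (0, {nyq}) Hz")
    b, a = butter(order, [lo, hi], btype="bandpass", fs=sample_rate)
    # Gustafsson initialisation keeps the zero-phase pass exactly symmetric
    # under time reversal
    return filtfilt(b, a, signal, method="gust")


def simulate_lfp(
    trial_traces: list[np.ndarray],
    unit_selector: np.ndarray,
    band: tuple[float, float] = (4.0, 32.0),
    sample_rate: float = RAW_RATE * UPSAMPLE,
) -> LFPTrace:
    """Simulate an LFP from per-trial depolarisation traces.

    ``trial_traces[k]`` has shape ``(T, n_iterations, n_units)`` — the
    recorded factor's pre-normalisation log-beliefs at each real time step —
    and ``unit_selector[k]`` names the unit (state index) recorded on trial
    ``k``, typically the trial's true target word.
    """
    unit_selector = np.asarray(unit_selector, dtype=int)
    if len(trial_traces) != unit_selector.size:
        raise ValueError("one unit per trial trace required")
    segments = []
    boundaries = []
    pos = 0
    for trace, unit in zip(trial_traces, unit_selector):
        T, n_it, _ = trace.shape
        dep = trace[:, :, unit].reshape(T * n_it)
        grad = np.diff(dep, prepend=dep[0])  # first sample carries no input
        segments.append(grad)
        boundaries.append(pos)
        pos += T * n_it * UPSAMPLE
    raw = np.concatenate(segments)
    n = raw.size
    x_up = np.linspace(0.0, n - 1, n * UPSAMPLE)
    up = np.interp(x_up, np.arange(n), raw)
    filtered = bandpass(up, band, sample_rate)
    return LFPTrace(
        signal=filtered,
        sample_rate=sample_rate,
        trial_boundaries=np.asarray(boundaries, dtype=int),
        unit_selector=unit_selector,
    )


def synaptic_balance(lfp: LFPTrace) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial excitatory (sum of positive samples) and inhibitory
    (summed magnitude of negative samples) totals."""
    bounds = np.append(lfp.trial_boundaries, lfp.signal.size)
    exc = np.empty(lfp.trial_boundaries.size)
    inh = np.empty(lfp.trial_boundaries.size)
    for k in range(lfp.trial_boundaries.size):
        seg = lfp.signal[bounds[k] : bounds[k + 1]]
        exc[k] = seg[seg > 0].sum()
        inh[k] = -seg[seg < 0].sum()
    return exc, inh
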