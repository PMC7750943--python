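"""Experience-dependent plasticity measured as Dirichlet KL divergence.

The synaptic substrate of learning is the Dirichlet concentration
(pseudo-count) array of each connection block.  Plasticity on trial ``t`` is
the KL divergence from the block's reference prior (its state at the first
trial, or after the latest lesion reset) to its posterior after trial ``t``,
summed over columns (each column is an independent Dirichlet, so the sum is
the joint divergence).  The rate of change is a least-squares slope over a
centred 10-trial window, which smooths out trial-to-trial noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln

__all__ = [
    "PlasticityTrace",
    "dirichlet_kl",
    "dirichlet_kl_matrix",
    "plasticity_trace",
    "smoothed_gradient",
]


@dataclass
class PlasticityTrace:
    kl_per_trial: np.ndarray  # nats, one entry per trial
    gradient: np.ndarray  # nats/trial, smoothed slope
    parameter_id: str


def dirichlet_kl(posterior_counts: np.ndarray, prior_counts: np.ndarray) -> float:
    """Closed-form KL divergence between two Dirichlet distributions (nats).

    KL(Dir(a) || Dir(b)) = lnG(sum a) - sum lnG(a) - lnG(sum b) + sum lnG(b)
                           + sum (a - b) (psi(a) - psi(sum a))
    """
    a = np.asarray(posterior_counts, dtype=float)
    b = np.asarray(prior_counts, dtype=float)
    if a.shape != b.shape:
        raise ValueError("concentration vectors must have equal length")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("concentrations must be > 0")
    a0, b0 = a.sum(), b.sum()
    return float(
        gammaln(a0)
        - gammaln(a).sum()
        - gammaln(b0)
        + gammaln(b).sum()
        + ((a - b) * (digamma(a) - digamma(a0))).sum()
    )


def dirichlet_kl_matrix(posterior: np.ndarray, prior: np.ndarray) -> float:
    """KL summed over the columns of a count matrix (joint over independent columns)."""
    posterior = np.asarray(posterior, dtype=float)
    prior = np.asarray(prior, dtype=float)
    return sum(
        dirichlet_kl(posterior[:, j], prior[:, j]) for j in range(posterior.shape[1])
    )


def plasticity_trace(session, parameter_id: str, window: int = 10) -> PlasticityTrace:
    """Per-trial KL trace of a connection block over one session.

    ``parameter_id`` selects the extrinsic (auditory likelihood) or intrinsic
    (word transition) block; the prior is the block's reference at each trial
    (post-lesion-reset), the posterior its counts after the trial.
    """
    from .lesions import EXTRINSIC_A, INTRINSIC_B

    if parameter_id == EXTRINSIC_A:
        post, ref = session.a_blocks, session.a_ref_blocks
    elif parameter_id == INTRINSIC_B:
        post, ref = session.b_blocks, session.b_ref_blocks
    else:
        raise ValueError(f"unknown parameter_id {parameter_id!r}")
    # intact one-hot blocks contain structural zeros; floor them so the
    # divergence stays defined (a zero that never accumulates contributes ~0)
    eps = 1e-6
    post = np.clip(post, eps, None)
    ref = np.clip(ref, eps, None)
    n_trials = post.shape[0]
    kl = np.array(
        [dirichlet_kl_matrix(post[t], ref[t]) for t in range(n_trials)]
    )
    return PlasticityTrace(
        kl_per_trial=kl,
        gradient=smoothed_gradient(kl, window=min(window, kl.size)),
        parameter_id=parameter_id,
    )


def smoothed_gradient(trace: np.ndarray, window: int = 10) -> np.ndarray:
    """Least-squares slope of the trace in a centred window around each trial.

    The window is truncated at the boundaries; the slope is in nats/trial.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if n < 2:
        raise ValueError("trace must contain at least 2 points")
    if window < 2 or window > n:
        raise ValueError("window must be in [2, len(trace)]")
    half_lo = (window - 1) // 2
    half_hi = window - 1 - half_lo
    grad = np.empty(n)
    for t in range(n):
        lo = max(0, t - half_lo)
        hi = min(n, t + half_hi + 1)
        x = np.arange(lo, hi, dtype=float)
        y = trace[lo:hi]
        xm, ym = x.mean(), y.mean()
        denom = ((x - xm) ** 2).sum()
        grad[t] = ((x - xm) * (y - ym)).sum() / denom if denom > 0 else 0.0
    return grad
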