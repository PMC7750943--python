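import numpy as np
import pytest

from lesionlab.engine import GenerativeModel


def make_chain_model(A, B, D, C=None, T=2, n_policies=None):
    """Single-factor, single-modality chain model for oracle tests.

    A: (n_obs, n_states); B: (n_states, n_states, n_controls); D: (n_states,).
    Policies enumerate one sustained control per policy unless n_policies given.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if B.ndim == 2:
        B = B[:, :, None]
    D = np.asarray(D, dtype=float)
    n_controls = B.shape[2]
    if C is None:
        C = np.zeros(A.shape[0])
    policies = np.zeros((n_controls, T - 1, 1), dtype=int)
    policies[:, :, 0] = np.arange(n_controls)[:, None]
    return GenerativeModel(
        A=[A],
        B=[B],
        C=[np.asarray(C, dtype=float)],
        D=[D],
        policies=policies,
        T=T,
    )


def enumerate_posterior(A, B, D, observations, controls):
    """Exact smoothing posterior by brute-force enumeration of state sequences.

    ``observations``: outcome index per observed time step (may be shorter
    than T); ``controls``: control index per transition. Returns a list of
    per-time marginal posteriors.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if B.ndim == 2:
        B = B[:, :, None]
    D = np.asarray(D, float)
    n = D.size
    T = len(controls) + 1
    import itertools

    marg = [np.zeros(n) for _ in range(T)]
    for seq in itertools.product(range(n), repeat=T):
        p = D[seq[0]]
        for tau in range(1, T):
            p *= B[seq[tau], seq[tau - 1], controls[tau - 1]]
        for tau, o in enumerate(observations):
            p *= A[o, seq[tau]]
        for tau in range(T):
            marg[tau][seq[tau]] += p
    z = marg[0].sum()
    return [m / z for m in marg]


@pytest.fixture
def rng():
    return np.random.default_rng(7)
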