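"""Discrete active-inference engine.

A single trial of a categorical (POMDP-style) generative model is solved by
variational message passing over hidden-state factors: at every time step the
agent combines likelihood evidence (``ln A`` applied to observed outcomes),
a forward message through the policy's transition matrices ``B`` (or the
initial prior ``D`` at the first step) and a backward message through the
transpose-normalised ``B``.  Posterior beliefs are the iterated
normalised-exponential (softmax) of the summed messages; the
pre-normalisation log-beliefs are recorded per iteration as a
"depolarisation" trace, the substrate of the simulated local field
potentials.

Policies are scored by their variational free energy ``F`` (evidence
accumulated so far) plus expected free energy ``G`` (risk relative to prior
preferences plus likelihood ambiguity over predicted states); actions are
sampled from a precision-sharpened softmax of the marginal action
probabilities.  Learning is Dirichlet pseudo-count accumulation on the
likelihood (``a``) and transition (``b``) concentration arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LOG_FLOOR",
    "GenerativeModel",
    "DirichletParams",
    "Hyperparameters",
    "BeliefState",
    "PolicyEvaluation",
    "TrialRecord",
    "softmax",
    "normalize_columns",
    "infer_states",
    "expected_free_energy",
    "action_distribution_from_marginal",
    "select_policy_and_action",
    "update_dirichlet",
    "run_trial",
]

# uniform floor inside every logarithm: lesioned matrices carry small but
# nonzero entries, so zero handling must be identical everywhere
LOG_FLOOR = 1e-16


def log_stable(x: np.ndarray) -> np.ndarray:
    return np.log(np.asarray(x, dtype=float) + LOG_FLOOR)


def softmax(v: np.ndarray, axis: int = 0) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    v = v - v.max(axis=axis, keepdims=True)
    e = np.exp(v)
    return e / e.sum(axis=axis, keepdims=True)


def normalize_columns(m: np.ndarray) -> np.ndarray:
    """Normalise so that sums over the leading axis are 1."""
    m = np.asarray(m, dtype=float)
    s = m.sum(axis=0, keepdims=True)
    return m / np.where(s == 0.0, 1.0, s)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class GenerativeModel:
    """Categorical generative model (A, B, C, D, policy set).

    A[m] has shape ``(num_outcomes[m], *num_states)``; B[f] has shape
    ``(num_states[f], num_states[f], num_controls[f])``; C[m] is a
    log-preference vector in nats; D[f] an initial-state prior.  ``policies``
    is an integer array ``(n_policies, T - 1, n_factors)`` of control indices.
    """

    A: list[np.ndarray]
    B: list[np.ndarray]
    C: list[np.ndarray]
    D: list[np.ndarray]
    policies: np.ndarray
    T: int

    @property
    def n_factors(self) -> int:
        return len(self.B)

    @property
    def n_modalities(self) -> int:
        return len(self.A)

    @property
    def num_states(self) -> tuple[int, ...]:
        return tuple(b.shape[0] for b in self.B)

    def validate(self, atol: float = 1e-10) -> None:
        for m, a in enumerate(self.A):
            if np.any(a < 0):
                raise ValueError(f"A[{m}] has negative entries")
            sums = a.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=atol):
                raise ValueError(f"A[{m}] columns do not sum to 1")
        for f, b in enumerate(self.B):
            if np.any(b < 0):
                raise ValueError(f"B[{f}] has negative entries")
            if not np.allclose(b.sum(axis=0), 1.0, atol=atol):
                raise ValueError(f"B[{f}] columns do not sum to 1")
        for f, d in enumerate(self.D):
            if np.any(d < 0) or not np.isclose(d.sum(), 1.0, atol=atol):
                raise ValueError(f"D[{f}] is not a normalised distribution")
        if self.policies.ndim != 3 or self.policies.shape[1] != self.T - 1:
            raise ValueError("policies must have shape (n_policies, T-1, n_factors)")


@dataclass
class DirichletParams:
    """Concentration (pseudo-count) arrays over A and B — the plasticity substrate."""

    a: list[np.ndarray]
    b: list[np.ndarray]

    def copy(self) -> "DirichletParams":
        return DirichletParams(
            a=[x.copy() for x in self.a], b=[x.copy() for x in self.b]
        )

    def expected_A(self) -> list[np.ndarray]:
        return [normalize_columns(x) for x in self.a]

    def expected_B(self) -> list[np.ndarray]:
        return [normalize_columns(x) for x in self.b]


@dataclass
class Hyperparameters:
    """Agent hyperparameters.

    omega_A / omega_B are the precisions of the likelihood and transition
    mappings (1 = intact); alpha_action is the action-selection precision;
    eta the pseudo-count learning rate; prior_scale the Dirichlet prior
    concentration multiplier; n_iterations the number of belief-update
    sweeps per time step.
    """

    omega_A: float = 1.0
    omega_B: float = 1.0
    alpha_action: float = 4.0
    eta: float = 0.8
    prior_scale: float = 2.0
    n_iterations: int = 16
    # which posteriors feed Dirichlet learning: "smoothed" (final BMA for both a
    # and b), "online" (filtered, at the time of each epoch, for both) or
    # "hybrid" (a from smoothed, b from online — Hebbian transitions)
    learning_beliefs: str = "hybrid"

    def __post_init__(self) -> None:
        if self.alpha_action <= 0:
            raise ValueError("alpha_action must be > 0")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be > 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.learning_beliefs not in ("online", "smoothed", "hybrid"):
            raise ValueError("learning_beliefs must be 'online', 'smoothed' or 'hybrid'")


@dataclass
class BeliefState:
    """Posterior beliefs for one policy.

    ``s[tau][f]`` is the posterior over factor ``f`` at time ``tau``;
    ``F`` the variational free energy of the policy; ``iteration_trace[f]``
    an array ``(n_iterations, T, num_states[f])`` of pre-normalisation
    log-beliefs (depolarisations); ``F_trace`` the free energy after each
    sweep.
    """

    s: list[list[np.ndarray]]
    F: float
    iteration_trace: list[np.ndarray]
    F_trace: np.ndarray


@dataclass
class PolicyEvaluation:
    G: np.ndarray
    policy_posterior: np.ndarray
    action_distribution: np.ndarray
    actions: np.ndarray  # candidate control tuples, one row per action_distribution entry


@dataclass
class TrialRecord:
    observations: list[tuple[int, ...]]
    actions: np.ndarray  # (T-1, n_factors) realised control indices
    correct: bool
    counts: DirichletParams
    smoothed_beliefs: list[list[np.ndarray]]
    depolarization: list[np.ndarray]  # per factor: (T, n_iterations, num_states[f])
    policy_eval: PolicyEvaluation | None = None


# --------------------------------------------------------------------------
# state inference
# --------------------------------------------------------------------------


def _evidence(lnA_o: np.ndarray, s: list[np.ndarray], f: int) -> np.ndarray:
    """Contract ln A (indexed by the observed outcome) over all factors but f."""
    x = np.moveaxis(lnA_o, f, 0)
    for g in range(len(s) - 1, -1, -1):
        if g == f:
            continue
        axis = g + 1 if g < f else g
        x = np.tensordot(x, s[g], axes=([axis], [0]))
    return x


def _outer_ravel(vectors: list[np.ndarray]) -> np.ndarray:
    if not vectors:  # single-factor model: nothing to contract
        return np.ones(1)
    out = vectors[0]
    for v in vectors[1:]:
        out = np.multiply.outer(out, v)
    return out.ravel()


def infer_states(
    model: GenerativeModel,
    observations: list[tuple[int, ...]],
    policy: np.ndarray,
    n_iterations: int = 16,
    track_free_energy: bool = False,
) -> BeliefState:
    """Infer posterior states under one policy given outcomes observed so far.

    Runs ``n_iterations`` full sweeps over time steps and factors; each
    factor/time update is the softmax of likelihood evidence + forward
    message + backward message, with the pre-normalisation log-belief
    recorded for the depolarisation trace.
    """
    T, n_f = model.T, model.n_factors
    policy = np.atleast_2d(np.asarray(policy, dtype=int))
    if policy.shape != (T - 1, n_f):
        if T > 1:
            raise ValueError(
                f"policy must have shape ({T - 1}, {n_f}), got {policy.shape}"
            )
    t_obs = len(observations)
    if t_obs > T:
        raise ValueError("more observations than time steps")
    for obs in observations:
        for m, o in enumerate(obs):
            if not (0 <= o < model.A[m].shape[0]):
                raise ValueError(f"observation {o} out of range for modality {m}")

    Ns = model.num_states
    lnD = [log_stable(d) for d in model.D]
    # evidence terms fixed per (tau, modality): ln A sliced at the observed outcome
    lnA_obs = [
        [log_stable(model.A[m][obs[m]]) for m in range(model.n_modalities)]
        for obs in observations
    ]
    # backward messages go through the transpose-normalised B
    Bt = [normalize_columns(np.swapaxes(model.B[f], 0, 1)) for f in range(n_f)]

    s = [[np.full(Ns[f], 1.0 / Ns[f]) for f in range(n_f)] for _ in range(T)]
    trace = [np.zeros((n_iterations, T, Ns[f])) for f in range(n_f)]
    F_trace = np.zeros(n_iterations)

    # flattened views of ln A per (observed tau, modality, factor): evidence is
    # then a single matrix-vector product with the other factors' outer product
    flat = [
        [
            [np.moveaxis(lnA_obs[tau][m], f, 0).reshape(Ns[f], -1) for f in range(n_f)]
            for m in range(model.n_modalities)
        ]
        for tau in range(t_obs)
    ]

    for it in range(n_iterations):
        # likelihood evidence per (time, factor) under the other factors' beliefs
        ev = [[np.zeros(Ns[f]) for f in range(n_f)] for _ in range(T)]
        for tau in range(t_obs):
            for f in range(n_f):
                others = _outer_ravel([s[tau][g] for g in range(n_f) if g != f])
                acc = flat[tau][0][f] @ others
                for m in range(1, model.n_modalities):
                    acc = acc + flat[tau][m][f] @ others
                ev[tau][f] = acc
        delta = 0.0
        for f in range(n_f):
            # backward messages carry future evidence only, so unobserved
            # futures leave the present untouched (no echo of the posterior)
            beta = [np.zeros(Ns[f]) for _ in range(T)]
            for tau in range(T - 2, -1, -1):
                u = policy[tau, f]
                msg = Bt[f][:, :, u] @ softmax(ev[tau + 1][f] + beta[tau + 1])
                beta[tau] = log_stable(msg / msg.sum())
            # forward messages pass through the filtered (evidence-so-far)
            # posterior, so future evidence is never counted twice
            fwd = np.zeros(Ns[f])
            for tau in range(T):
                if tau == 0:
                    fwd_ln = lnD[f]
                else:
                    u = policy[tau - 1, f]
                    fwd_ln = log_stable(model.B[f][:, :, u] @ softmax(ev[tau - 1][f] + fwd))
                v = ev[tau][f] + fwd_ln + beta[tau]
                fwd = fwd_ln
                trace[f][it, tau] = v
                new = softmax(v)
                delta = max(delta, float(np.abs(new - s[tau][f]).max()))
                s[tau][f] = new
        if track_free_energy:
            F_trace[it] = _free_energy(model, s, lnA_obs, policy)
        if delta < 1e-12 and it < n_iterations - 1:
            # fixed point reached: pad the remaining sweeps with the converged
            # messages (later sweeps would reproduce them bit for bit)
            for f in range(n_f):
                trace[f][it + 1 :] = trace[f][it]
            if track_free_energy:
                F_trace[it + 1 :] = F_trace[it]
            break

    if not track_free_energy:
        F_trace[-1] = _free_energy(model, s, lnA_obs, policy)
    return BeliefState(s=s, F=float(F_trace[-1]), iteration_trace=trace, F_trace=F_trace)


def _free_energy(
    model: GenerativeModel,
    s: list[list[np.ndarray]],
    lnA_obs: list[list[np.ndarray]],
    policy: np.ndarray,
) -> float:
    """Variational free energy: complexity against the forward prior minus accuracy."""
    F = 0.0
    for tau in range(model.T):
        for f in range(model.n_factors):
            q = s[tau][f]
            if tau == 0:
                prior = model.D[f]
            else:
                u = policy[tau - 1, f]
                prior = model.B[f][:, :, u] @ s[tau - 1][f]
            F += float(q @ (log_stable(q) - log_stable(prior)))
        if tau < len(lnA_obs):
            for m in range(model.n_modalities):
                # accuracy under the mean-field posterior
                x = lnA_obs[tau][m]
                for g in range(model.n_factors - 1, -1, -1):
                    x = np.tensordot(x, s[tau][g], axes=([g], [0]))
                F -= float(x)
    return F


# --------------------------------------------------------------------------
# policy evaluation and action selection
# --------------------------------------------------------------------------


def expected_free_energy(
    model: GenerativeModel,
    policy: np.ndarray,
    beliefs: BeliefState,
    t_current: int = 0,
) -> float:
    """Expected free energy of a policy, summed over future time steps.

    ``G = sum_tau KL(Q(o_tau) || softmax(C)) + E_Q[H(A)]`` — risk of the
    predicted outcome distribution relative to prior preferences plus the
    expected ambiguity (conditional entropy) of the likelihood mapping.
    Lower is better.
    """
    policy = np.atleast_2d(np.asarray(policy, dtype=int))
    G = 0.0
    prefs = [softmax(c) for c in model.C]
    # conditional outcome entropy per hidden-state combination
    H = [-(a * log_stable(a)).sum(axis=0) for a in model.A]
    for tau in range(t_current + 1, model.T):
        s_pred = beliefs.s[tau]
        for m in range(model.n_modalities):
            qo = model.A[m]
            for g in range(model.n_factors - 1, -1, -1):
                qo = np.tensordot(qo, s_pred[g], axes=([g + 1], [0]))
            G += float(qo @ (log_stable(qo) - log_stable(prefs[m])))
            h = H[m]
            for g in range(model.n_factors - 1, -1, -1):
                h = np.tensordot(h, s_pred[g], axes=([g], [0]))
            G += float(h)
    return G


def action_distribution_from_marginal(
    marginal: np.ndarray, alpha_action: float
) -> np.ndarray:
    """Sharpen marginal action probabilities with the action precision alpha."""
    marginal = np.asarray(marginal, dtype=float)
    if np.all(marginal <= 0):
        raise ValueError("all-zero action marginals")
    return softmax(alpha_action * log_stable(marginal))


def select_policy_and_action(
    G: np.ndarray,
    F: np.ndarray,
    policies: np.ndarray,
    t: int,
    alpha_action: float,
    rng: np.random.Generator,
    allowed: np.ndarray | None = None,
) -> tuple[np.ndarray, PolicyEvaluation]:
    """Sample the next action from the precision-sharpened policy marginals.

    ``policy_posterior = softmax(-(G + F))`` over the allowed policies;
    marginal action probabilities sum the posterior over policies sharing
    the same control tuple at step ``t``; the action distribution raises the
    marginal to the power alpha (softmax of ``alpha * ln marginal``) and is
    sampled by inverse CDF in declared action order.
    """
    if alpha_action <= 0:
        raise ValueError("alpha_action must be > 0")
    G = np.asarray(G, dtype=float)
    F = np.asarray(F, dtype=float)
    n_pol = policies.shape[0]
    if n_pol < 1:
        raise ValueError("need at least one policy")
    logits = -(G + F)
    if allowed is not None:
        logits = np.where(allowed, logits, -np.inf)
    q_pi = softmax(logits)

    controls = policies[:, t, :]
    actions, inverse = np.unique(controls, axis=0, return_inverse=True)
    marginal = np.zeros(actions.shape[0])
    np.add.at(marginal, inverse, q_pi)
    if np.all(marginal <= 0):
        raise ValueError("all-zero action marginals")
    action_dist = action_distribution_from_marginal(marginal, alpha_action)
    idx = int(np.searchsorted(np.cumsum(action_dist), rng.random(), side="right"))
    idx = min(idx, actions.shape[0] - 1)
    ev = PolicyEvaluation(
        G=G, policy_posterior=q_pi, action_distribution=action_dist, actions=actions
    )
    return actions[idx], ev


# --------------------------------------------------------------------------
# learning
# --------------------------------------------------------------------------


def _outer(vectors: list[np.ndarray]) -> np.ndarray:
    out = vectors[0]
    for v in vectors[1:]:
        out = np.multiply.outer(out, v)
    return out


def update_dirichlet(
    counts: DirichletParams,
    beliefs: list[list[np.ndarray]],
    observations: list[tuple[int, ...]],
    actions: np.ndarray,
    eta: float,
    transition_beliefs: list[list[np.ndarray]] | None = None,
) -> DirichletParams:
    """Accumulate pseudo-counts from one trial's posteriors.

    Likelihood counts gain ``eta * outer(s_tau)`` at each observed outcome;
    transition counts gain ``eta * outer(s_tau, s_tau-1)`` under the realised
    control.  ``transition_beliefs`` optionally supplies a different belief
    sequence for the transition updates (e.g. the filtered posteriors at the
    moment each transition was experienced).  Counts only ever increase, so
    they never fall below the prior.
    """
    if eta < 0:
        raise ValueError("eta must be >= 0")
    new = counts.copy()
    if eta == 0:
        return new
    for tau, obs in enumerate(observations):
        joint = _outer(beliefs[tau])
        for m, o in enumerate(obs):
            new.a[m][o] += eta * joint
    sb = beliefs if transition_beliefs is None else transition_beliefs
    actions = np.atleast_2d(np.asarray(actions, dtype=int))
    for tau in range(1, len(sb)):
        for f in range(len(new.b)):
            u = actions[tau - 1, f]
            new.b[f][:, :, u] += eta * np.outer(sb[tau][f], sb[tau - 1][f])
    return new


# --------------------------------------------------------------------------
# one trial of the perception-action-learning loop
# --------------------------------------------------------------------------


def run_trial(
    model_template: GenerativeModel,
    counts: DirichletParams,
    env,
    hyper: Hyperparameters,
    rng: np.random.Generator,
) -> TrialRecord:
    """Run one closed-loop trial against an environment.

    The working likelihood/transitions are the normalised Dirichlet means of
    the current counts.  The environment must provide ``begin_trial(rng)``,
    ``observe(t) -> tuple`` and ``register_action(control)``; correctness is
    read from its ``correct`` attribute after the final step.  Dirichlet
    counts are updated from the posteriors selected by
    ``hyper.learning_beliefs`` (smoothed, filtered, or the hybrid of the
    two).  Returns the trial's observations, realised actions, the updated
    counts, the Bayesian-model-average posteriors and the per-factor
    depolarisation traces.
    """
    model = replace(model_template, A=counts.expected_A(), B=counts.expected_B())
    T, n_f = model.T, model.n_factors
    n_pol = model.policies.shape[0]
    Ns = model.num_states
    n_it = hyper.n_iterations

    env.begin_trial(rng)
    observations: list[tuple[int, ...]] = []
    taken = np.zeros((T - 1, n_f), dtype=int)
    allowed = np.ones(n_pol, dtype=bool)
    beliefs_by_policy: list[BeliefState | None] = [None] * n_pol
    depol = [np.zeros((T, n_it, Ns[f])) for f in range(n_f)]
    online: list[list[np.ndarray]] = []  # filtered posterior about tau=t at step t
    q_pi = np.full(n_pol, 1.0 / n_pol)
    last_eval: PolicyEvaluation | None = None

    for t in range(T):
        observations.append(tuple(env.observe(t)))
        G = np.full(n_pol, np.inf)
        F = np.full(n_pol, np.inf)
        for p in range(n_pol):
            if not allowed[p]:
                continue
            bel = infer_states(model, observations, model.policies[p], n_it)
            beliefs_by_policy[p] = bel
            F[p] = bel.F
            G[p] = expected_free_energy(model, model.policies[p], bel, t_current=t)
        q_pi = softmax(np.where(allowed, -(G + F), -np.inf))
        # BMA depolarisation and filtered (online) posterior at the current step
        for f in range(n_f):
            acc = np.zeros((n_it, Ns[f]))
            for p in range(n_pol):
                if allowed[p] and q_pi[p] > 0:
                    acc += q_pi[p] * beliefs_by_policy[p].iteration_trace[f][:, t, :]
            depol[f][t] = acc
        online_t = []
        for f in range(n_f):
            acc = np.zeros(Ns[f])
            for p in range(n_pol):
                if allowed[p] and q_pi[p] > 0:
                    acc += q_pi[p] * beliefs_by_policy[p].s[t][f]
            online_t.append(acc / acc.sum())
        online.append(online_t)
        if t < T - 1:
            control, last_eval = select_policy_and_action(
                G, F, model.policies, t, hyper.alpha_action, rng, allowed
            )
            taken[t] = control
            allowed &= np.all(model.policies[:, t, :] == control, axis=1)
            if not allowed.any():
                raise RuntimeError("no policy consistent with sampled action")
            env.register_action(control)

    # Bayesian model average of the final, fully informed posteriors
    smoothed = []
    for tau in range(T):
        per_factor = []
        for f in range(n_f):
            acc = np.zeros(Ns[f])
            for p in range(n_pol):
                if allowed[p] and q_pi[p] > 0:
                    acc += q_pi[p] * beliefs_by_policy[p].s[tau][f]
            per_factor.append(acc / acc.sum())
        smoothed.append(per_factor)

    mode = hyper.learning_beliefs
    beliefs_a = online if mode == "online" else smoothed
    beliefs_b = online if mode in ("online", "hybrid") else smoothed
    new_counts = update_dirichlet(
        counts, beliefs_a, observations, taken, hyper.eta, transition_beliefs=beliefs_b
    )
    return TrialRecord(
        observations=observations,
        actions=taken,
        correct=bool(env.correct),
        counts=new_counts,
        smoothed_beliefs=smoothed,
        depolarization=depol,
        policy_eval=last_eval,
    )
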