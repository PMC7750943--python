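# Methods

## The task and the generative process

Each trial has three epochs: *listen* (an auditory cue — the target word,
drawn uniformly from a vocabulary of `n_words = 4`), *repeat* (the agent
speaks a word or stays silent) and *feedback* (correct iff the spoken word is
the target; silence counts as incorrect). The environment is deterministic
and is never lesioned: lesions exist only in the agent's model of it.

## The agent's generative model

Hidden states factorise into three factors:

* **word** — the target (4 states). Its transitions are the identity; this
  block is the *intrinsic* (within-region) lesion site, ω_B.
* **report** — what has been spoken (silence + 4 words), set
  deterministically by the chosen action.
* **epoch** — listen → repeat → feedback, deterministic.

Outcome modalities: *auditory* (silence + 4 words; during listening the
word→cue map is the *extrinsic* lesion site, ω_A; silence otherwise),
*proprioceptive* (echoes the report) and *feedback* (null/correct/incorrect,
a deterministic function of word × report at the feedback epoch). Listing the
report as a hidden factor is what lets feedback and proprioception depend on
the agent's action through a purely state-conditioned likelihood.

Preferences place `+preference_strength` nats on correct and the negative on
incorrect feedback. Policies are the five sustained responses (stay silent,
speak word 1..4): the task has a single decision point, so richer policy
spaces would only duplicate evaluations.

## Belief updating

For each policy, posteriors over each factor and time step are updated by
iterated normalised-exponential message passing (16 sweeps per time step;
the scheme reaches its fixed point in 2–3 sweeps on this model, and the
remaining sweeps repeat the converged messages). Each update combines

1. likelihood evidence: `ln A` indexed at the observed outcomes, contracted
   with the other factors' current beliefs (mean-field);
2. a forward message through the policy's `B` from the *filtered*
   (evidence-so-far) posterior at τ−1, or `ln D` at τ = 1;
3. a backward message through the transpose-normalised `B` carrying the
   *future evidence only* (a β-recursion).

Passing the forward message through the filtered posterior, and restricting
the backward message to future evidence, keeps the fixed point equal to the
exact smoothing posterior on small models (verified against brute-force
enumeration to 1e-3 total variation); feeding smoothed posteriors forward
instead double-counts evidence and over-sharpens. The pre-normalisation
log-beliefs of every update are recorded as depolarisations for the LFP
simulation. Logs are floored as `ln(p + 1e-16)` throughout so that lesioned
(small but nonzero) and structural-zero entries are handled uniformly.

Policies are scored by `F + G`: the variational free energy of the evidence
so far plus the expected free energy of future steps,
`G = Σ_τ KL(Q(o_τ) ‖ softmax(C)) + E_Q[H(A)]` (risk plus ambiguity), with
unit policy precision. The action marginal (policy posterior summed over
policies sharing the next action) is sharpened by the action precision,
`P(u) ∝ m(u)^α` with α = 4, and sampled by inverse CDF in declared action
order for reproducibility.

## Learning and its substrate

Learning is Dirichlet pseudo-count accumulation with rate η: likelihood
counts gain `η · s_τ` at each observed outcome, transition counts gain
`η · s_τ ⊗ s_{τ−1}` under the realised action. The agent's working A and B
are the normalised count means, recomputed at the start of every trial.

Which posteriors feed the updates is a genuine design choice; the package
implements three modes and defaults to **hybrid**:

* likelihood (**A**) counts learn from the trial's final smoothed
  (Bayesian-model-average) posteriors — end-of-trial consolidation, in which
  feedback retro-corrects the interpretation of the cue, to the extent that
  the backward messages can carry it through the current **B**;
* transition (**B**) counts learn from the filtered posteriors at the moment
  each transition was experienced — a Hebbian reading in which the synapse
  sees pre- and post-synaptic activity when the transition happens, before
  later evidence arrives.

This asymmetry is what gives the lesion conditions their character. In the
control model all posteriors are exact, so both channels receive clean
signals and nothing drifts. After an extrinsic lesion the cue posterior is
smeared (0.8 on the target), so the Hebbian transition updates gradually
erode the word-transition block; the eroded **B** in turn weakens the
feedback's backward correction of the likelihood channel, and performance
settles well below control. A *mild* second intrinsic lesion resets the
eroded transition block to a fresh, only slightly imprecise prior (ω_B = 0.9)
— wiping the accumulated corruption and paradoxically improving performance —
while a *severe* reset (ω_B = 0.7) leaves beliefs too volatile to maintain
the target across the trial and performance collapses toward chance. With
fully smoothed learning the feedback sanitises every update, all four
conditions heal back to control levels, and no lesion has a lasting effect;
with fully filtered learning the likelihood channel loses the feedback
signal entirely and every lesioned condition collapses. The hybrid is the
regime in which a single precision change produces a *persistent but
bounded* deficit.

## Lesions

`apply_precision_lesion` maps each column's unique maximal entry to ω and
the rest to `(1−ω)/(N−1)` — the unique simple form that is the identity at
ω = 1 on one-hot columns and fully ambiguous at ω = 1/N. A scheduled lesion
operates on the current Dirichlet mean of the targeted block and resets that
block's counts to `prior_scale ×` the lesioned matrix (structural damage
destroys the evidence accumulated at the site, and re-opens it to
plasticity). Only the auditory word→cue listening block and the
word-transition block are ever lesioned.

## Plasticity metric

Per trial, the KL divergence between Dirichlet distributions (closed form
with digamma/gammaln) is summed over the columns of the measured block —
columns are independent Dirichlets, so the sum is the joint divergence. The
reference ("prior") is the block at the first trial, rebased to the
post-reset counts after a lesion. The rate of change is the least-squares
slope in a centred 10-trial window, truncated at boundaries. KL magnitudes
(unlike behaviour) scale with the overall concentration scale of (η,
prior_scale); at the calibrated scale the single-lesion extrinsic gradient
is of order 0.05–0.1 nats/trial early and decays below that after trial 20.

## Simulated LFPs

The depolarisation of the word-factor unit coding the trial's true target is
differenced across update iterations, concatenated across epochs and trials
(16 iterations per 250 ms epoch, 64 Hz), linearly upsampled ×2 to 128 Hz and
bandpass filtered 4–32 Hz with a second-order zero-phase Butterworth
(Gustafsson initialisation, which makes the zero-phase pass exactly
symmetric under time reversal). Positive samples are read as excitatory
post-synaptic responses and negative as inhibitory; per-trial totals of each
summarise the excitatory/inhibitory balance. Because the bandpass removes
the mean, the two totals are near-balanced by construction; the informative
quantities are their joint magnitude and their changes across conditions.

## Calibration

The main text constants of the study (vocabulary size, preference strength,
learning rate, prior concentration) are not all published, so they were
fixed once by the protocol the experiment design prescribes: a desk-scale
grid over `preference_strength` and `η` (at `n_words = 4`,
`prior_scale = 2`), scored *only* on the control and single-lesion terminal
performance (targets ≈ 95% and ≈ 62%). The frozen values are
`preference_strength = 0.525` nats and `η = 0.8`; behaviour depends on η and
`prior_scale` only through their ratio, so the prior scale stayed at its
default. The dual-lesion conditions are untouched, out-of-sample predictions
of the frozen model. At 50 seeds × 100 trials the frozen model gives control
≈ 94–95%, single ≈ 63–64%, severe dual ≈ 47–49% and mild dual ≈ 72–74%,
preserving the paradoxical ordering control > mild > single > severe; the
dual effect sizes are directionally correct but smaller in magnitude than in
the study that motivated the design, whose richer (unpublished) generative
model plausibly separates the conditions further.

## Numerical and reproducibility conventions

Randomness: each session derives per-trial counter-based streams
`default_rng([session_seed, trial])`, so the target draw and the action
draws align exactly across conditions sharing a seed — conditions are paired
counterfactuals, and removing a scheduled lesion reproduces the unlesioned
trajectory bit for bit up to the onset trial. Fixed seeds give bit-identical
sessions. Ties in action sampling are resolved by inverse-CDF order over the
declared action indices. Belief iterations stop early only at an exact fixed
point (max change < 1e-12), padding the depolarisation trace with the
converged value.

## Problem sizes

The full experiment is 4 conditions × 50 seeds × 100 trials (≈ 3–4 minutes
on one CPU). The traced (LFP) analyses use 8 seeds per condition, enough for
the paired qualitative contrasts, which are consistent across seeds. Unit
and property tests run on 1–3 state toy models against enumeration and
Monte-Carlo oracles.

## Known limitations

* The generative model is minimal (one decision point, one word per trial,
  no phonology or semantics); absolute dual-lesion magnitudes depend on
  structure the model does not contain.
* Lesions address only the two designated blocks; preferences, initial
  priors and inhibitory extrinsic connections are out of scope.
* The LFP mapping from update iterations to milliseconds is conventional
  (16 iterations ≙ 250 ms); only band-relative statements are meaningful.
* The plasticity metric's absolute scale is set by the concentration scale
  and is comparable across conditions, not across reparameterisations.
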