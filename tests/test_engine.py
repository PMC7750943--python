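"""Engine unit tests: state inference against exact enumeration, expected
free energy against an independent brute-force computation, action
selection, and Dirichlet learning."""

import numpy as np
import pytest

from lesionlab.engine import (
    Hyperparameters,
    action_distribution_from_marginal,
    expected_free_energy,
    infer_states,
    select_policy_and_action,
    softmax,
    update_dirichlet,
    DirichletParams,
)
from lesionlab.task_model import TaskConfig, Environment, build_model
from lesionlab.engine import run_trial

from conftest import enumerate_posterior, make_chain_model


class TestInferStates:
    def test_degenerate_single_state(self):
        model = make_chain_model(
            A=np.ones((2, 1)), B=np.ones((1, 1)), D=np.ones(1), T=2
        )
        bel = infer_states(model, [(0,), (1,)], model.policies[0], 8)
        for tau in range(2):
            assert np.allclose(bel.s[tau][0], [1.0])
        assert np.isfinite(bel.F)

    def test_uniform_likelihood_gives_uniform_posterior(self):
        A = np.full((2, 2), 0.5)
        B = np.eye(2)
        model = make_chain_model(A=A, B=B, D=[0.5, 0.5], T=2)
        bel = infer_states(model, [(0,), (1,)], model.policies[0], 16)
        for tau in range(2):
            assert np.allclose(bel.s[tau][0], [0.5, 0.5], atol=1e-8)

    @pytest.mark.parametrize(
        "A,B,D,obs",
        [
            (np.eye(2), np.eye(2), [0.5, 0.5], [0, 0]),
            (np.eye(2), [[0.9, 0.1], [0.1, 0.9]], [0.5, 0.5], [0, 1]),
            ([[0.8, 0.2], [0.2, 0.8]], [[0.9, 0.1], [0.1, 0.9]], [0.6, 0.4], [0]),
            (
                [[0.7, 0.1, 0.2], [0.2, 0.8, 0.1], [0.1, 0.1, 0.7]],
                np.eye(3),
                [1 / 3] * 3,
                [1, 2],
            ),
        ],
    )
    def test_matches_enumeration_oracle(self, A, B, D, obs):
        """Posterior within 1e-3 total variation of exhaustive enumeration."""
        A, B, D = np.asarray(A, float), np.asarray(B, float), np.asarray(D, float)
        T = 2 if len(obs) <= 2 else len(obs)
        model = make_chain_model(A=A, B=B, D=D, T=T)
        policy = model.policies[0]
        bel = infer_states(model, [(o,) for o in obs], policy, 32)
        exact = enumerate_posterior(A, B, D, obs, controls=[0] * (T - 1))
        for tau in range(T):
            tv = 0.5 * np.abs(bel.s[tau][0] - exact[tau]).sum()
            assert tv < 1e-3, f"tau={tau}: {bel.s[tau][0]} vs {exact[tau]}"

    def test_free_energy_non_increasing_over_iterations(self):
        cfg = TaskConfig()
        model, _ = build_model(cfg, Hyperparameters(omega_A=0.8))
        bel = infer_states(
            model, [(1, 0, 0)], model.policies[1], 16, track_free_energy=True
        )
        diffs = np.diff(bel.F_trace)
        assert np.all(diffs <= 1e-6), bel.F_trace

    def test_rejects_out_of_range_observation(self):
        model = make_chain_model(A=np.eye(2), B=np.eye(2), D=[0.5, 0.5], T=2)
        with pytest.raises(ValueError):
            infer_states(model, [(5,)], model.policies[0], 4)


class TestExpectedFreeEnergy:
    def _toy(self, C):
        # 2 states, 2 actions: action u moves to state u deterministically
        B = np.zeros((2, 2, 2))
        B[0, :, 0] = 1.0
        B[1, :, 1] = 1.0
        return make_chain_model(A=np.eye(2), B=B, D=[0.5, 0.5], C=C, T=2)

    def test_uniform_preference_symmetry(self):
        model = self._toy(C=[0.0, 0.0])
        obs = [(0,)]
        Gs = []
        for p in range(2):
            bel = infer_states(model, obs, model.policies[p], 16)
            Gs.append(expected_free_energy(model, model.policies[p], bel, 0))
        assert Gs[0] == pytest.approx(Gs[1], abs=1e-9)

    def test_preferred_outcome_has_lower_G(self):
        model = self._toy(C=[2.0, -2.0])
        obs = [(0,)]
        bel0 = infer_states(model, obs, model.policies[0], 16)
        bel1 = infer_states(model, obs, model.policies[1], 16)
        G_pref = expected_free_energy(model, model.policies[0], bel0, 0)
        G_avoid = expected_free_energy(model, model.policies[1], bel1, 0)
        assert G_pref < G_avoid

    def test_matches_brute_force_oracle(self):
        """Risk + ambiguity computed term by term by an independent path."""
        A = np.array([[0.9, 0.3], [0.1, 0.7]])
        B = np.zeros((2, 2, 2))
        B[:, :, 0] = [[0.8, 0.4], [0.2, 0.6]]
        B[:, :, 1] = [[0.1, 0.5], [0.9, 0.5]]
        C = np.array([1.0, -1.0])
        model = make_chain_model(A=A, B=B, D=[0.7, 0.3], C=C, T=2)
        obs = [(0,)]
        for p in range(2):
            bel = infer_states(model, obs, model.policies[p], 32)
            G = expected_free_energy(model, model.policies[p], bel, 0)
            # independent computation from the same predictive beliefs
            s_pred = bel.s[1][0]
            qo = A @ s_pred
            pref = np.exp(C) / np.exp(C).sum()
            risk = sum(
                qo[o] * (np.log(qo[o] + 1e-16) - np.log(pref[o] + 1e-16))
                for o in range(2)
            )
            H_cols = [-sum(A[o, s] * np.log(A[o, s] + 1e-16) for o in range(2)) for s in range(2)]
            ambiguity = sum(s_pred[s] * H_cols[s] for s in range(2))
            assert G == pytest.approx(risk + ambiguity, abs=1e-6)


class TestActionSelection:
    def test_large_alpha_selects_argmax(self, rng):
        G = np.array([1.0, 0.2, 3.0])
        F = np.zeros(3)
        policies = np.arange(3).reshape(3, 1, 1)
        for _ in range(20):
            action, ev = select_policy_and_action(G, F, policies, 0, 512.0, rng)
            assert action[0] == 1
        assert ev.action_distribution[1] == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_policies_split_evenly(self):
        G = np.array([1.0, 1.0])
        F = np.array([0.3, 0.3])
        policies = np.arange(2).reshape(2, 1, 1)
        rng = np.random.default_rng(123)
        picks = np.array(
            [
                select_policy_and_action(G, F, policies, 0, 4.0, rng)[0][0]
                for _ in range(10_000)
            ]
        )
        assert abs((picks == 0).mean() - 0.5) < 0.02

    def test_alpha_sharpening_hand_computation(self):
        # (0.8, 0.2) at alpha=4 -> (0.4096, 0.0016)/0.4112
        dist = action_distribution_from_marginal(np.array([0.8, 0.2]), 4.0)
        assert dist == pytest.approx([0.99611, 0.00389], abs=1e-4)

    def test_policy_posterior_is_softmax_of_negative_G_plus_F(self, rng):
        G = np.array([0.5, 1.5])
        F = np.array([0.2, 0.1])
        policies = np.arange(2).reshape(2, 1, 1)
        _, ev = select_policy_and_action(G, F, policies, 0, 4.0, rng)
        assert np.allclose(ev.policy_posterior, softmax(-(G + F)))


class TestDirichletLearning:
    def _counts(self):
        a = [np.ones((2, 2))]
        b = [np.ones((2, 2, 1))]
        return DirichletParams(a=a, b=b)

    def test_eta_zero_leaves_counts_unchanged(self):
        counts = self._counts()
        beliefs = [[np.array([0.5, 0.5])], [np.array([0.5, 0.5])]]
        new = update_dirichlet(counts, beliefs, [(0,), (1,)], np.zeros((1, 1), int), 0.0)
        assert np.array_equal(new.a[0], counts.a[0])
        assert np.array_equal(new.b[0], counts.b[0])

    def test_certain_posterior_adds_unit_count(self):
        counts = self._counts()
        beliefs = [[np.array([0.0, 1.0])]]
        new = update_dirichlet(counts, beliefs, [(0,)], np.zeros((0, 1), int), 1.0)
        expected = counts.a[0].copy()
        expected[0, 1] += 1.0
        assert np.allclose(new.a[0], expected)

    def test_graded_posterior_outer_product(self):
        counts = self._counts()
        beliefs = [[np.array([0.8, 0.2])]]
        new = update_dirichlet(counts, beliefs, [(1,)], np.zeros((0, 1), int), 1.0)
        assert np.allclose(new.a[0][1], counts.a[0][1] + [0.8, 0.2])
        assert np.allclose(new.a[0][0], counts.a[0][0])

    def test_transition_counts_use_consecutive_posteriors(self):
        counts = self._counts()
        beliefs = [[np.array([1.0, 0.0])], [np.array([0.0, 1.0])]]
        new = update_dirichlet(counts, beliefs, [], np.zeros((1, 1), int), 1.0)
        expected = counts.b[0][:, :, 0] + np.outer([0.0, 1.0], [1.0, 0.0])
        assert np.allclose(new.b[0][:, :, 0], expected)

    def test_negative_eta_rejected(self):
        with pytest.raises(ValueError):
            update_dirichlet(self._counts(), [], [], np.zeros((0, 1), int), -1.0)


class TestRunTrial:
    def test_control_with_sharp_selection_is_always_correct(self):
        cfg = TaskConfig()
        hyp = Hyperparameters(alpha_action=512.0)
        model, counts = build_model(cfg, hyp)
        env = Environment(cfg)
        for seed in range(10):
            rec = run_trial(model, counts, env, hyp, np.random.default_rng(seed))
            assert rec.correct

    def test_fixed_seed_reproduces_trial_exactly(self):
        cfg = TaskConfig()
        hyp = Hyperparameters(omega_A=0.8)
        model, counts = build_model(cfg, hyp)
        recs = []
        for _ in range(2):
            env = Environment(cfg)
            recs.append(run_trial(model, counts, env, hyp, np.random.default_rng(42)))
        a, b = recs
        assert a.observations == b.observations
        assert np.array_equal(a.actions, b.actions)
        assert a.correct == b.correct
        for m in range(len(a.counts.a)):
            assert np.array_equal(a.counts.a[m], b.counts.a[m])
        for f in range(len(a.counts.b)):
            assert np.array_equal(a.counts.b[f], b.counts.b[f])
        for f in range(len(a.depolarization)):
            assert np.array_equal(a.depolarization[f], b.depolarization[f])

    def test_fully_ambiguous_cue_yields_chance_performance(self):
        """With the cue map lesioned to uniform, correctness sits at 1/n_words."""
        cfg = TaskConfig(n_words=4)
        hyp = Hyperparameters(omega_A=1.0 / 4, eta=0.0)
        model, counts = build_model(cfg, hyp)
        env = Environment(cfg)
        n, hits = 1000, 0
        for seed in range(n):
            rec = run_trial(model, counts, env, hyp, np.random.default_rng(seed))
            hits += rec.correct
        assert abs(hits / n - 0.25) < 0.03
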