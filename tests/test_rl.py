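"""PPO machinery: ratios, objectives, KL control, training behaviour."""

import numpy as np
import pytest

from molminer.docking import MockDockingBackend
from molminer.generator import Adam, GeneratorConfig, LSTMPolicy
from molminer.rewards import RewardSpec
from molminer.rl import (PPOConfig, RewardEvaluator, RolloutBatch,
                         collect_rollouts, entropy_collapsed,
                         mean_token_entropy, policy_kl, ppo_objective,
                         ppo_objective_and_grad, probability_ratio,
                         reinforce_gradient, train_iteration)
from molminer.strings import BREAK_TOKEN, TokenSequence, TokenVocabulary


def make_policy(vocab, seed=0, units=(8,), emb=4, max_len=10):
    cfg = GeneratorConfig(vocab_size=len(vocab), embedding_dim=emb,
                          cell_units=units, max_sequence_length=max_len,
                          dropout_embedding=0, dropout_weight=0,
                          dropout_hidden=0, dropout_output=0)
    return LSTMPolicy(vocab, cfg, seed=seed)


def sample_batch(policy, n, seed, rewards=None):
    rng = np.random.default_rng(seed)
    seqs, logps = policy.sample(n, rng)
    if rewards is None:
        rewards = np.random.default_rng(seed + 1).uniform(0, 2, n)
    return RolloutBatch(seqs, np.asarray(rewards, float), logps,
                        [None] * n)


@pytest.fixture()
def vocab3():
    return TokenVocabulary(("[C]", "[O]", BREAK_TOKEN))


class TestProbabilityRatio:
    def test_identical_policies_give_one(self, vocab3):
        pol = make_policy(vocab3)
        pol.snapshot_old()
        seqs, _ = pol.sample(5, np.random.default_rng(0))
        for s in seqs:
            assert probability_ratio(pol, s) == pytest.approx(1.0)

    def test_hand_computed_quotient(self, vocab3):
        pol = make_policy(vocab3)
        pol.snapshot_old()
        rng = np.random.default_rng(1)
        for k in pol.params:
            pol.params[k] = pol.params[k] + 0.05 * rng.normal(
                size=pol.params[k].shape)
        seq = TokenSequence([0, 1, vocab3.break_index])
        new, _ = pol.sequence_log_prob(seq)
        old, _ = pol.sequence_log_prob(seq, params=pol.old_params)
        assert probability_ratio(pol, seq) == pytest.approx(
            np.exp(new) / np.exp(old))

    def test_always_positive(self, vocab3):
        pol = make_policy(vocab3, seed=3)
        pol.snapshot_old()
        rng = np.random.default_rng(2)
        for k in pol.params:
            pol.params[k] = pol.params[k] + 0.2 * rng.normal(
                size=pol.params[k].shape)
        seqs, _ = pol.sample(10, rng)
        assert all(probability_ratio(pol, s) > 0 for s in seqs)

    def test_requires_snapshot(self, vocab3):
        pol = make_policy(vocab3)
        with pytest.raises(ValueError):
            probability_ratio(pol, TokenSequence([0]))


class TestReinforceGradient:
    def test_zero_rewards_zero_gradient(self, vocab3):
        pol = make_policy(vocab3)
        batch = sample_batch(pol, 6, seed=0, rewards=np.zeros(6))
        grads = reinforce_gradient(pol, batch)
        assert all(np.allclose(g, 0) for g in grads.values())

    def test_matches_finite_differences(self, vocab3, rng):
        """d/dTheta of mean R log p agrees with central differences."""
        pol = make_policy(vocab3)
        batch = sample_batch(pol, 4, seed=2)
        grads = reinforce_gradient(pol, batch)

        def objective():
            return float(np.mean([
                r * pol.sequence_log_prob(s)[0]
                for s, r in zip(batch.sequences, batch.rewards)]))

        eps = 1e-6
        for name, arr in pol.params.items():
            d = rng.normal(size=arr.shape)
            d /= np.linalg.norm(d)
            pol.params[name] = arr + eps * d
            fp = objective()
            pol.params[name] = arr - eps * d
            fm = objective()
            pol.params[name] = arr
            fd = (fp - fm) / (2 * eps)
            an = float((grads[name] * d).sum())
            assert abs(fd - an) / max(abs(fd), abs(an), 1e-10) < 1e-4, name


class TestPPOObjective:
    def test_unmoved_policy_objective(self, vocab3):
        """With Theta = Theta_old every ratio is 1 (inside the clip band),
        so the objective is mean R plus the entropy bonus."""
        pol = make_policy(vocab3)
        pol.snapshot_old()
        batch = sample_batch(pol, 8, seed=3)
        cfg = PPOConfig(entropy_coef=0.05)
        expected = batch.rewards.mean() + 0.05 * mean_token_entropy(
            pol, batch.sequences)
        assert ppo_objective(pol, batch, cfg) == pytest.approx(expected)

    def test_clip_active_above_band(self):
        """r = 1 + 2 eps with R > 0 contributes (1 + eps) R."""
        eps = 0.2
        r = 1 + 2 * eps
        R = 3.0
        term = min(r * R, np.clip(r, 1 - eps, 1 + eps) * R)
        assert term == pytest.approx((1 + eps) * R)

    def test_pessimism_inequality(self, vocab3):
        """Clipped objective never exceeds the unclipped surrogate plus
        entropy bonus, on random policy perturbations."""
        for seed in range(5):
            pol = make_policy(vocab3, seed=seed)
            pol.snapshot_old()
            rng = np.random.default_rng(seed)
            for k in pol.params:
                pol.params[k] = pol.params[k] + 0.1 * rng.normal(
                    size=pol.params[k].shape)
            batch = sample_batch(pol, 8, seed=seed + 10)
            # recompute logp_old under the snapshot (samples came from new)
            batch = RolloutBatch(
                batch.sequences, batch.rewards,
                [pol.sequence_log_prob(s, params=pol.old_params)[1]
                 for s in batch.sequences],
                batch.identities)
            cfg = PPOConfig(clip_epsilon=0.2, entropy_coef=0.01)
            obj = ppo_objective(pol, batch, cfg)
            r = np.array([probability_ratio(pol, s) for s in batch.sequences])
            surrogate = float((r * batch.rewards).mean()) + \
                0.01 * mean_token_entropy(pol, batch.sequences)
            assert obj <= surrogate + 1e-10

    def test_reduces_to_reinforce_in_limit(self, vocab3):
        """eps -> infinity with alpha = 0 gives the REINFORCE gradient."""
        pol = make_policy(vocab3, seed=4)
        pol.snapshot_old()
        batch = sample_batch(pol, 8, seed=5)
        cfg = PPOConfig(clip_epsilon=1e9, entropy_coef=0.0)
        _, g_ppo = ppo_objective_and_grad(pol, batch, cfg)
        g_rf = reinforce_gradient(pol, batch)
        for k in g_rf:
            assert np.allclose(g_ppo[k], g_rf[k], atol=1e-12)

    def test_baseline_gradient_matches_finite_differences(self, vocab3, rng):
        """With the optional batch-mean baseline, advantages may be
        negative; the clip gradient must stay consistent."""
        pol = make_policy(vocab3, seed=6)
        pol.snapshot_old()
        batch = sample_batch(pol, 6, seed=7)
        cfg = PPOConfig(clip_epsilon=0.2, entropy_coef=0.02,
                        use_baseline=True)
        _, grads = ppo_objective_and_grad(pol, batch, cfg)
        eps = 1e-6
        for name, arr in pol.params.items():
            d = rng.normal(size=arr.shape)
            d /= np.linalg.norm(d)
            pol.params[name] = arr + eps * d
            fp = ppo_objective(pol, batch, cfg)
            pol.params[name] = arr - eps * d
            fm = ppo_objective(pol, batch, cfg)
            pol.params[name] = arr
            fd = (fp - fm) / (2 * eps)
            an = float((grads[name] * d).sum())
            assert abs(fd - an) / max(abs(fd), abs(an), 1e-10) < 1e-4, name

    def test_negative_rewards_rejected(self, vocab3):
        pol = make_policy(vocab3)
        seqs, logps = pol.sample(2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            RolloutBatch(seqs, np.array([-1.0, 1.0]), logps, [None, None])


class TestEntropyAndKL:
    def test_uniform_policy_entropy_ln_v(self, vocab3):
        pol = make_policy(vocab3)
        pol.params["decoder_W"][:] = 0
        pol.params["decoder_b"][:] = 0
        pol.params["embedding"][:] = 0
        seqs = [TokenSequence([0, 1, vocab3.break_index])]
        assert mean_token_entropy(pol, seqs) == pytest.approx(np.log(3))

    def test_one_hot_policy_entropy_zero(self, vocab3):
        pol = make_policy(vocab3)
        pol.params["decoder_W"][:] = 0
        pol.params["embedding"][:] = 0
        pol.params["decoder_b"][:] = np.array([1e3, -1e3, -1e3])
        seqs = [TokenSequence([0, 0, 0])]
        assert mean_token_entropy(pol, seqs) == pytest.approx(0.0, abs=1e-9)

    def test_mixed_entropy_hand_sum(self, vocab3):
        pol = make_policy(vocab3)
        seqs, _ = pol.sample(3, np.random.default_rng(0))
        total = n = 0
        for s in seqs:
            for t in range(len(s.indices)):
                d = pol.next_token_distribution(s.indices[:t])
                total += -(d * np.log(d)).sum()
                n += 1
        assert mean_token_entropy(pol, seqs) == pytest.approx(total / n)

    def test_kl_zero_for_identical(self, vocab3):
        pol = make_policy(vocab3)
        pol.snapshot_old()
        seqs, _ = pol.sample(4, np.random.default_rng(1))
        assert policy_kl(pol, seqs) == pytest.approx(0.0, abs=1e-12)

    def test_kl_bernoulli_closed_form(self, vocab3):
        """Distributions (.5,.5) vs (.9,.1) over two effective tokens give
        the analytic KL of the Bernoulli pair."""
        pol = make_policy(vocab3)
        pol.params["decoder_W"][:] = 0
        pol.params["embedding"][:] = 0
        big = 1e3
        # new: uniform over tokens {0,1}, token 2 suppressed
        pol.params["decoder_b"][:] = np.array([0.0, 0.0, -big])
        pol.snapshot_old()
        p = 0.9
        pol.old_params["decoder_b"][:] = np.array(
            [np.log(p), np.log(1 - p), -big])
        seqs = [TokenSequence([0])]
        expected = 0.5 * np.log(0.5 / p) + 0.5 * np.log(0.5 / (1 - p))
        assert policy_kl(pol, seqs) == pytest.approx(expected, abs=1e-6)

    def test_kl_nonnegative(self, vocab3):
        for seed in range(5):
            pol = make_policy(vocab3, seed=seed)
            pol.snapshot_old()
            rng = np.random.default_rng(seed)
            for k in pol.params:
                pol.params[k] = pol.params[k] + 0.3 * rng.normal(
                    size=pol.params[k].shape)
            seqs, _ = pol.sample(5, rng)
            assert policy_kl(pol, seqs) >= 0.0


class TestTrainingLoop:
    def _evaluator(self):
        return RewardEvaluator(RewardSpec({"docking": 1.0}),
                               backend=MockDockingBackend())

    def test_epoch_cap_and_kl_stop(self, vocab_small, corpus_small):
        from molminer.generator import PretrainSchedule, pretrain
        cfg = GeneratorConfig(vocab_size=len(vocab_small), embedding_dim=8,
                              cell_units=(16,), max_sequence_length=60)
        pol, _ = pretrain(corpus_small[:100], vocab_small, cfg,
                          PretrainSchedule(epochs=2, batch_size=32,
                                           weight_decay=0.0), seed=0)
        ppo = PPOConfig(molecules_per_iteration=30, learning_rate=1e-3,
                        max_epochs=10)
        opt = Adam(pol.params, lr=ppo.learning_rate)
        row = train_iteration(pol, self._evaluator(), ppo, opt,
                              np.random.default_rng(0))
        assert row is not None
        assert 1 <= row.epochs_used <= 10
        if row.epochs_used < 10:
            assert row.kl > ppo.kl_threshold

    def test_tiny_lr_never_triggers_kl_stop(self, vocab3):
        pol = make_policy(vocab3)
        ppo = PPOConfig(molecules_per_iteration=20, learning_rate=1e-12,
                        max_epochs=3)
        opt = Adam(pol.params, lr=ppo.learning_rate)
        row = train_iteration(pol, self._evaluator(), ppo, opt,
                              np.random.default_rng(0))
        assert row.epochs_used == 3      # ran to the epoch cap
        assert row.kl < ppo.kl_threshold

    def test_mock_backend_reward_improves_over_iterations(
            self, corpus_small, vocab_small):
        """Smoke criterion: with the mock docking backend, mean reward at
        iteration 20 exceeds iteration 0 in at least 9 of 10 seeds."""
        from molminer.generator import PretrainSchedule, pretrain
        cfg = GeneratorConfig(vocab_size=len(vocab_small), embedding_dim=16,
                              cell_units=(32,), max_sequence_length=60)
        base, _ = pretrain(corpus_small, vocab_small, cfg,
                           PretrainSchedule(epochs=6, batch_size=32,
                                            max_lr=3e-3, weight_decay=0.0),
                           seed=0)
        evaluator = self._evaluator()
        wins = 0
        for seed in range(10):
            pol = base.clone()
            ppo = PPOConfig(molecules_per_iteration=60, learning_rate=2e-3,
                            entropy_coef=0.005, seed=seed)
            opt = Adam(pol.params, lr=ppo.learning_rate)
            rng = np.random.default_rng(seed)
            rows = [train_iteration(pol, evaluator, ppo, opt, rng, iteration=i)
                    for i in range(21)]
            rows = [r for r in rows if r is not None]
            wins += rows[20].mean_reward > rows[0].mean_reward
        assert wins >= 9

    def test_all_invalid_batch_skipped(self, vocab3):
        pol = make_policy(vocab3)
        # force immediate break: every sample decodes empty
        pol.params["decoder_W"][:] = 0
        pol.params["embedding"][:] = 0
        pol.params["decoder_b"][:] = -50.0
        pol.params["decoder_b"][vocab3.break_index] = 50.0
        ppo = PPOConfig(molecules_per_iteration=10)
        opt = Adam(pol.params, lr=1e-3)
        with pytest.warns(UserWarning, match="empty"):
            row = train_iteration(pol, self._evaluator(), ppo, opt,
                                  np.random.default_rng(0))
        assert row is None


class TestStopRule:
    def test_flat_entropy_never_fires(self):
        assert not entropy_collapsed([2.0] * 30, 0.5, 10)

    def test_injected_drop_fires(self):
        series = [2.0] * 15 + [0.9]       # below 50% of trailing max
        assert entropy_collapsed(series, 0.5, 10)

    def test_gradual_decline_within_window_tolerated(self):
        series = list(np.linspace(2.0, 1.8, 20))
        assert not entropy_collapsed(series, 0.5, 10)


class TestRewardEvaluator:
    def test_invalid_molecules_get_zero(self):
        ev = RewardEvaluator(RewardSpec({"docking": 1.0}),
                             backend=MockDockingBackend())
        rewards, details = ev.evaluate(["CCO", None, "c1ccccc1"])
        assert rewards[1] == 0.0 and details[1] is None
        assert rewards[0] > 0.0

    def test_duplicate_docking_terms_averaged(self):
        class AlternatingBackend:
            def __init__(self):
                self.calls = 0

            def score(self, mol, task):
                self.calls += 1
                score = -7.0 if self.calls % 2 else -9.0
                import numpy as np
                from molminer.docking import DockingResult
                return DockingResult(score=score, pose=np.zeros((1, 3)))

        ev = RewardEvaluator(RewardSpec({"docking": 1.0}),
                             backend=AlternatingBackend())
        rewards, _ = ev.evaluate(["CCO", "OCC"])
        assert rewards[0] == rewards[1] == pytest.approx(8.0)

    def test_missing_dependency_rejected(self):
        with pytest.raises(ValueError):
            RewardEvaluator(RewardSpec({"docking": 1.0}))
        with pytest.raises(ValueError):
            RewardEvaluator(RewardSpec({"drug_likeliness": 1.0}))
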