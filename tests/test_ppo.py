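"""PPO machinery: advantages, clipped loss, rollouts, gradient structure."""

import numpy as np
import pytest

from smolgen import ppo
from smolgen.ppo import (
    PPOConfig, Trajectory, clipped_policy_loss, collect_rollouts,
    compute_advantages,
)


def _toy_trajectory(values, reward, L=None):
    L = L or len(values)
    return Trajectory(
        ids=np.zeros(L + 1, dtype=np.int64), gen_start=1, gen_len=L,
        smiles="C", log_probs=np.zeros(L), values=np.asarray(values, float),
        reward=reward)


# ---------------------------------------------------------------------------
# advantages


def test_terminal_reward_telescopes_with_zero_values():
    traj = _toy_trajectory([0.0, 0.0, 0.0, 0.0], reward=0.7)
    adv = compute_advantages(traj, PPOConfig(discount=1.0, gae_lambda=1.0))
    assert np.allclose(adv, 0.7)


def test_perfect_critic_yields_zero_advantages():
    traj = _toy_trajectory([0.6, 0.6, 0.6], reward=0.6)
    adv = compute_advantages(traj, PPOConfig(discount=1.0, gae_lambda=1.0))
    assert np.allclose(adv, 0.0)


def test_gae_matches_hand_recursion():
    """3-token trajectory, gamma=0.9, lambda=0.5, values (0.2, 0.1, 0.4), r=1."""
    gamma, lam = 0.9, 0.5
    values, reward = [0.2, 0.1, 0.4], 1.0
    # brute-force recursion, written independently of the implementation
    deltas = [0.0 + gamma * values[1] - values[0],
              0.0 + gamma * values[2] - values[1],
              reward + 0.0 - values[2]]
    a2 = deltas[2]
    a1 = deltas[1] + gamma * lam * a2
    a0 = deltas[0] + gamma * lam * a1
    traj = _toy_trajectory(values, reward)
    adv = compute_advantages(traj, PPOConfig(discount=gamma, gae_lambda=lam))
    assert np.allclose(adv, [a0, a1, a2])
    assert np.allclose(traj.returns, adv + np.array(values))


def test_single_token_trajectory_is_terminal_only():
    traj = _toy_trajectory([0.3], reward=0.9)
    adv = compute_advantages(traj, PPOConfig(discount=1.0, gae_lambda=0.95))
    assert adv.shape == (1,)
    assert adv[0] == pytest.approx(0.6)


# ---------------------------------------------------------------------------
# clipped surrogate


@pytest.mark.parametrize("ratio,advantage,eps,expected", [
    (1.0, 0.7, 0.2, -0.7),    # on-policy: plain policy gradient
    (2.0, 1.0, 0.2, -1.2),    # ratio clipped at 1.2
    (0.5, -1.0, 0.2, 0.8),    # min(-0.5, -0.8) = -0.8, negated
])
def test_clipped_policy_loss_values(ratio, advantage, eps, expected):
    assert clipped_policy_loss(ratio, advantage, eps) == pytest.approx(expected)


def test_non_positive_ratio_rejected():
    with pytest.raises(ValueError):
        clipped_policy_loss(0.0, 1.0)


def test_config_invariants():
    with pytest.raises(ValueError):
        PPOConfig(clip_eps=1.5)
    with pytest.raises(ValueError):
        PPOConfig(rollout_batch=0)


# ---------------------------------------------------------------------------
# rollouts


def test_constant_reward_passes_through(tiny_lm):
    trajs = collect_rollouts(tiny_lm, lambda s: np.ones(len(s)), n=16, seed=3)
    assert len(trajs) == 16
    assert all(t.reward == 1.0 for t in trajs)


def test_rollout_rewards_in_unit_interval(tiny_lm, surrogate_adapter):
    from smolgen import rewards
    fn = rewards.adapter_reward_fn(surrogate_adapter, "pocketA")
    trajs = collect_rollouts(tiny_lm, fn, n=16, seed=3)
    assert all(0.0 < t.reward < 1.0 for t in trajs)


def test_rollouts_are_seed_deterministic(tiny_lm):
    def run():
        return collect_rollouts(tiny_lm, lambda s: np.zeros(len(s)), n=8, seed=7)
    a, b = run(), run()
    for ta, tb in zip(a, b):
        assert (ta.ids == tb.ids).all()
        assert np.allclose(ta.log_probs, tb.log_probs)


def test_rollout_log_probs_are_proper(tiny_lm):
    """Behavior log-probs are finite and negative for every generated token."""
    trajs = collect_rollouts(tiny_lm, lambda s: np.zeros(len(s)), n=8, seed=11)
    for t in trajs:
        assert t.gen_len == len(t.log_probs) == len(t.values)
        assert np.isfinite(t.log_probs).all()
        assert (t.log_probs < 0).all()


# ---------------------------------------------------------------------------
# gradient structure


def test_zero_advantage_gives_zero_policy_gradient(tiny_lm):
    """With A = 0 the clipped surrogate is exactly flat in the policy."""
    import copy
    from smolgen.ppo import _log_probs_tensor, _sampling_masks, _true_lengths

    model = copy.deepcopy(tiny_lm)
    ids = model.sample_ids(8, seed=5)
    lengths = _true_lengths(ids, model.vocab)
    masks = _sampling_masks(model, ids, gen_start=1)
    lp, _ = _log_probs_tensor(model, ids, lengths, masks)
    targets = np.clip(ids[:, 1:], 0, model.config.padded_vocab - 1)
    tok_lp = lp.take_last(targets)
    old = tok_lp.data.copy()
    adv = np.zeros_like(old)
    ratio = (tok_lp - old).exp()
    loss = -(ratio * adv).minimum(
        ratio.clip(0.8, 1.2) * adv).sum()
    loss.backward()
    for p in model.parameters():
        if p.grad is not None:
            assert np.abs(p.grad).max() == 0.0


def test_kl_pinning_keeps_policy_at_reference(pretrained):
    """A dominating KL penalty freezes the policy at the pre-RL reference."""
    import copy
    model, _ = pretrained

    def run(kl_coef):
        tuned, _ = ppo.finetune(
            copy.deepcopy(model),
            lambda s: np.random.default_rng(0).random(len(s)),
            PPOConfig(total_epochs=2, rollout_batch=32, kl_coef=kl_coef,
                      seed=3, entropy_coef=0.0))
        ids = model.sample_ids(16, seed=99)
        lp_ref = model.masked_log_probs(ids[:, :-1]).data
        lp_new = tuned.masked_log_probs(ids[:, :-1]).data
        kl = (np.exp(lp_ref) * (lp_ref - lp_new)).sum(axis=-1)
        return float(np.mean(kl))

    pinned, free = run(1e4), run(0.0)
    assert pinned < 0.05
    assert pinned < free


def test_token_frequency_snapshots_are_distributions(ppo_uplift_runs, study_vocab):
    for history in ppo_uplift_runs:
        for freq in history.token_freq:
            assert freq.sum() == pytest.approx(1.0)
            assert freq[:3].sum() == 0.0  # no mass on control tokens


def test_reward_trend_is_upward_across_seeds(ppo_uplift_runs):
    """Median-over-seeds epoch rewards trend upward on the surrogate task."""
    rewards_by_epoch = np.median(
        [h.mean_reward for h in ppo_uplift_runs], axis=0)
    assert rewards_by_epoch[-3:].mean() > rewards_by_epoch[0]


def test_history_exports(ppo_uplift_runs, tmp_path):
    import json
    import pandas as pd
    history = ppo_uplift_runs[0]
    history.to_csv(tmp_path / "rl.csv")
    frame = pd.read_csv(tmp_path / "rl.csv")
    assert list(frame.columns) == ["epoch", "mean_reward",
                                   "mean_surrogate_score", "best_flag"]
    assert frame["best_flag"].sum() == 1
    history.token_freq_json(tmp_path / "freq.json")
    payload = json.loads((tmp_path / "freq.json").read_text())
    assert len(payload["freq_per_epoch"]) == len(history.mean_reward)
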