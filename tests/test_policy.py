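"""Softmax policy, action sampling, returns, and the reward-gated rule."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spikedream import (
    Adam,
    Agent,
    EligibilityAccumulators,
    NeuronParams,
    PolicyReadout,
    compute_policy,
    discounted_return,
    policy_update_step,
    sample_action,
)


class TestComputePolicy:
    def test_equal_logits_give_uniform(self):
        readout = PolicyReadout(r_pi=np.zeros((4, 6)))
        pi = compute_policy(np.random.default_rng(0).uniform(size=6), readout)
        np.testing.assert_allclose(pi, 0.25)

    def test_two_action_closed_form(self):
        # logits (0, ln 2) -> probabilities (1/3, 2/3)
        readout = PolicyReadout(r_pi=np.array([[0.0], [np.log(2.0)]]))
        pi = compute_policy(np.ones(1), readout)
        np.testing.assert_allclose(pi, [1 / 3, 2 / 3], rtol=1e-12)

    def test_shift_invariance_and_stability(self, rng):
        r_pi = rng.normal(size=(3, 5))
        s_bar = rng.uniform(size=5)
        base = compute_policy(s_bar, PolicyReadout(r_pi=r_pi))
        shifted = compute_policy(s_bar, PolicyReadout(r_pi=r_pi + 7.0 / s_bar.sum() * 0))
        np.testing.assert_allclose(base, shifted)
        huge = compute_policy(s_bar, PolicyReadout(r_pi=r_pi * 1e4))
        assert np.all(np.isfinite(huge))
        assert huge.sum() == pytest.approx(1.0)


class TestSampleAction:
    def test_degenerate_distribution(self, rng):
        for _ in range(20):
            onehot = sample_action(np.array([1.0, 0.0, 0.0]), rng)
            np.testing.assert_array_equal(onehot, [1, 0, 0])

    def test_empirical_frequencies_chi_square(self):
        rng = np.random.default_rng(99)
        pi = np.array([0.2, 0.3, 0.5])
        draws = np.array([sample_action(pi, rng) for _ in range(10_000)])
        counts = draws.sum(axis=0)
        _, pvalue = stats.chisquare(counts, f_exp=pi * 10_000)
        assert pvalue > 0.01

    def test_seeded_reproducibility(self):
        pi = np.array([0.4, 0.6])
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        s1 = [int(sample_action(pi, rng1).argmax()) for _ in range(30)]
        s2 = [int(sample_action(pi, rng2).argmax()) for _ in range(30)]
        assert s1 == s2

    def test_nan_distribution_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_action(np.array([np.nan, 0.5]), rng)


class TestDiscountedReturn:
    def test_worked_example(self):
        np.testing.assert_allclose(
            discounted_return([0.0, 0.0, 1.0], 0.99), [0.9801, 0.99, 1.0], rtol=1e-12
        )

    def test_zero_rewards(self):
        np.testing.assert_array_equal(discounted_return(np.zeros(7), 0.99), np.zeros(7))

    def test_matches_double_sum_oracle(self, rng):
        r = rng.normal(size=50)
        gamma = 0.97
        fast = discounted_return(r, gamma)
        slow = [
            sum(r[t2] * gamma ** (t2 - t) for t2 in range(t, 50)) for t in range(50)
        ]
        np.testing.assert_allclose(fast, slow, rtol=1e-12)


def random_episode(rng, n=10, t_steps=30, a=3):
    """Arbitrary frozen traces standing in for a recorded agent episode."""
    return {
        "p": rng.uniform(0, 0.25, size=(t_steps, n)),
        "e": rng.uniform(0, 1, size=(t_steps, n)),
        "s_bar": rng.uniform(0, 1, size=(t_steps, n)),
        "pi": rng.dirichlet(np.ones(a), size=t_steps),
        "actions": np.eye(a)[rng.integers(a, size=t_steps)],
        "rewards": rng.normal(0, 1, size=t_steps),
    }


def direct_nested_sum(ep, r_pi, gamma):
    """Direct evaluation of Σ_t r^t Σ_{t'≤t} γ^{t−t'}(…) over stored traces."""
    t_steps, n = ep["p"].shape
    a = r_pi.shape[0]
    d_w = np.zeros((n, n))
    d_r = np.zeros((a, n))
    for t in range(t_steps):
        r_t = ep["rewards"][t]
        for t2 in range(t + 1):
            disc = gamma ** (t - t2)
            adv = ep["actions"][t2] - ep["pi"][t2]
            delta = r_pi.T @ adv
            d_w += r_t * disc * np.outer(delta * ep["p"][t2], ep["e"][t2])
            d_r += r_t * disc * np.outer(adv, ep["s_bar"][t2])
    return d_w, d_r


def online_accumulated(ep, r_pi, gamma):
    t_steps, n = ep["p"].shape
    readout = PolicyReadout(r_pi=r_pi, gamma=gamma)
    acc = EligibilityAccumulators.zeros(n, r_pi.shape[0])
    d_w = np.zeros((n, n))
    d_r = np.zeros_like(r_pi)
    for t in range(t_steps):
        g_w, g_r = policy_update_step(
            acc, ep["p"][t], ep["e"][t], ep["s_bar"][t], ep["pi"][t],
            ep["actions"][t], ep["rewards"][t], readout,
        )
        d_w += g_w
        d_r += g_r
    return d_w, d_r


class TestPolicyUpdate:
    def test_zero_reward_episode_gives_zero_update(self, rng):
        ep = random_episode(rng)
        ep["rewards"][:] = 0.0
        r_pi = rng.normal(size=(3, 10))
        d_w, d_r = online_accumulated(ep, r_pi, 0.99)
        assert not d_w.any() and not d_r.any()

    def test_saturated_matching_policy_gives_zero_update(self, rng):
        ep = random_episode(rng)
        ep["pi"] = ep["actions"].astype(float)  # π already puts mass 1 on the action
        d_w, d_r = online_accumulated(ep, rng.normal(size=(3, 10)), 0.99)
        assert not d_w.any() and not d_r.any()

    def test_recursion_equals_direct_nested_sum(self, rng):
        ep = random_episode(rng, n=10, t_steps=30)
        r_pi = rng.normal(size=(3, 10))
        d_w, d_r = online_accumulated(ep, r_pi, 0.99)
        ref_w, ref_r = direct_nested_sum(ep, r_pi, 0.99)
        np.testing.assert_allclose(d_w, ref_w, rtol=1e-10)
        np.testing.assert_allclose(d_r, ref_r, rtol=1e-10)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.floats(min_value=0.5, max_value=1.0),
        st.integers(min_value=1, max_value=12),
    )
    def test_recursion_direct_sum_property(self, seed, gamma, t_steps):
        rng = np.random.default_rng(seed)
        ep = random_episode(rng, n=4, t_steps=t_steps, a=2)
        r_pi = rng.normal(size=(2, 4))
        d_w, d_r = online_accumulated(ep, r_pi, gamma)
        ref_w, ref_r = direct_nested_sum(ep, r_pi, gamma)
        np.testing.assert_allclose(d_w, ref_w, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(d_r, ref_r, rtol=1e-9, atol=1e-12)


class TestPolicyImprovement:
    def test_bandit_policy_saturates_on_rewarded_arm(self):
        """One-state bandit with constant activity: π(rewarded arm) → 1."""
        n, a = 6, 2
        s_bar = np.full(n, 0.3)
        p = np.full(n, 0.1)
        e = np.full(n, 0.2)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            readout = PolicyReadout.zeros(a, n)
            opt = Adam(lr=0.01)
            for _ in range(400):
                acc = EligibilityAccumulators.zeros(n, a)
                pi = compute_policy(s_bar, readout)
                action = sample_action(pi, rng)
                reward = float(action[0] == 1.0)
                d_w, d_r = policy_update_step(acc, p, e, s_bar, pi, action, reward, readout)
                opt.step({"r_pi": readout.r_pi}, {"r_pi": d_r})
            assert compute_policy(s_bar, readout)[0] > 0.9

    def test_expected_update_matches_enumeration_gradient(self):
        """E[ΔR^π] equals the likelihood-ratio gradient of the expected return.

        Two-step, two-action MDP with frozen activity traces and γ = 1: the
        exact gradient of J(R) = E[r^0 + r^1] is computed by enumerating all
        four action sequences and differentiating with central differences;
        the expectation of the online update over the same enumeration must
        agree.
        """
        rng = np.random.default_rng(7)
        n, a = 4, 2
        s_bars = rng.uniform(0.1, 1.0, size=(2, n))
        p = rng.uniform(0.05, 0.25, size=(2, n))
        e = rng.uniform(0.1, 1.0, size=(2, n))
        reward_table = {  # r^1 depends on the full action sequence; r^0 on a0
            (0, 0): 1.0, (0, 1): -0.5, (1, 0): 0.2, (1, 1): 0.0,
        }
        r0 = {0: 0.3, 1: -0.1}
        r_pi = rng.normal(0, 0.5, size=(a, n))

        def episode_quantities(r_mat):
            readout = PolicyReadout(r_pi=r_mat, gamma=1.0)
            pis = [compute_policy(s_bars[t], readout) for t in range(2)]
            return readout, pis

        def expected_return(r_mat):
            _, pis = episode_quantities(r_mat)
            j = 0.0
            for a0, a1 in itertools.product(range(a), repeat=2):
                prob = pis[0][a0] * pis[1][a1]
                j += prob * (r0[a0] + reward_table[(a0, a1)])
            return j

        # expectation of the online update over all four trajectories
        readout, pis = episode_quantities(r_pi)
        expected_update = np.zeros_like(r_pi)
        for a0, a1 in itertools.product(range(a), repeat=2):
            prob = pis[0][a0] * pis[1][a1]
            acc = EligibilityAccumulators.zeros(n, a)
            total = np.zeros_like(r_pi)
            rewards = [r0[a0], reward_table[(a0, a1)]]
            for t, act in enumerate((a0, a1)):
                onehot = np.eye(a)[act]
                _, d_r = policy_update_step(
                    acc, p[t], e[t], s_bars[t], pis[t], onehot, rewards[t], readout
                )
                total += d_r
            expected_update += prob * total

        h = 1e-6
        for idx in [(0, 0), (1, 2), (0, 3)]:
            bumped = r_pi.copy()
            bumped[idx] += h
            up = expected_return(bumped)
            bumped[idx] -= 2 * h
            dn = expected_return(bumped)
            fd = (up - dn) / (2 * h)
            assert expected_update[idx] == pytest.approx(fd, rel=1e-5, abs=1e-9)


class TestAgentClass:
    def test_learn_matches_generic_update_path(self, rng):
        """Agent episode learning equals Σ_t policy_update_step + one Adam step."""
        params = NeuronParams(n=12)
        agent = Agent(params, d_state=3, n_actions=3, seed=21)
        ref = Agent(params, d_state=3, n_actions=3, seed=21)
        ref_opt = Adam(lr=ref.opt.lr)
        init = rng.normal(0, 0.3, size=(3, 12))
        agent.readout.r_pi += init
        ref.readout.r_pi += init
        rng_a, rng_b = np.random.default_rng(4), np.random.default_rng(4)
        total_w = np.zeros((12, 12))
        total_r = np.zeros((3, 12))
        for t in range(20):
            xi = np.random.default_rng(100 + t).uniform(0, 2, size=3)
            action, pi = agent.act(xi, rng_a)
            action_b, pi_b = ref.act(xi, rng_b)
            np.testing.assert_array_equal(action, action_b)
            reward = [0.0, 0.0, 1.0, -1.0][t % 4]
            agent.learn(action, reward)
            p, e, s_bar, _ = ref._last
            d_w, d_r = policy_update_step(
                ref.acc, p, e, s_bar, pi_b, action_b, reward, ref.readout
            )
            total_w += d_w
            total_r += d_r
        agent.end_episode()
        ref_opt.step(
            {"w": ref.net.weights.w_rec, "r_pi": ref.readout.r_pi},
            {"w": total_w, "r_pi": total_r},
        )
        np.testing.assert_allclose(
            agent.net.weights.w_rec, ref.net.weights.w_rec, atol=1e-13
        )
        np.testing.assert_allclose(agent.readout.r_pi, ref.readout.r_pi, atol=1e-13)

    def test_gamma_bounds_validated(self):
        with pytest.raises(ValueError):
            PolicyReadout(r_pi=np.zeros((2, 3)), gamma=0.0)
        with pytest.raises(ValueError):
            PolicyReadout(r_pi=np.zeros((2, 3)), gamma=1.2)
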