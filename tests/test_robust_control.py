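import numpy as np
import pytest

from pbnctrl.dirichlet_uncertainty import contamination_prior, sample_tpm
from pbnctrl.markov_engine import CostSpec, build_tpm, controlled_tpm, default_partition
from pbnctrl.nominal_dp import policy_value, value_iteration
from pbnctrl.robust_control import (
    Hyperstate,
    NodeBudgetError,
    agr_costs_batch,
    agr_rollout,
    gr_policy,
    mcr_policy,
    obr_action,
    obr_rollout,
)

from oracles import enumerate_policy_values, naive_obr_action


class TestOBRAction:
    def test_one_step_uniform_prior_by_hand(self):
        # 2 states, uniform prior: a=0 costs 0.5*2.0 = 1.0, a=1 costs 1.1
        spec = CostSpec(np.array([True, False]), lam=0.2)
        a, v = obr_action(Hyperstate(1, np.ones((2, 2))), spec, K=1, control_gene=1)
        assert a == 0 and v == pytest.approx(1.0)

    def test_agrees_with_naive_recursion(self, rng):
        spec = CostSpec(default_partition(3, 1), lam=0.2)
        for _ in range(3):
            alpha = rng.gamma(2.0, size=(8, 8)) + 0.05
            for i in (1, 4, 8):
                for K in (1, 2, 3):
                    a_fast, v_fast = obr_action(Hyperstate(i, alpha), spec, K, 3)
                    a_ref, v_ref = naive_obr_action(i - 1, alpha, spec, K, 3)
                    assert a_fast == a_ref
                    assert v_fast == pytest.approx(v_ref, abs=1e-12)

    def test_degenerate_prior_recovers_nominal_policy(self, three_gene):
        _, P, spec = three_gene
        Pa = controlled_tpm(P, 3)
        _, mu = value_iteration(Pa, spec)
        alpha = 1e6 * P + 1e-6
        for i in range(1, 9):
            for K in (1, 3, 5):
                a, _ = obr_action(Hyperstate(i, alpha), spec, K, 3)
                assert a == mu[i - 1]

    def test_value_nondecreasing_in_depth(self, rng):
        spec = CostSpec(default_partition(3, 1), lam=0.2)
        alpha = rng.gamma(1.0, size=(8, 8)) + 0.1
        vals = [obr_action(Hyperstate(2, alpha), spec, K, 3)[1] for K in range(1, 6)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_node_budget_guard(self):
        spec = CostSpec(default_partition(5, flavor="cycd-rb-down"), lam=0.2)
        with pytest.raises(NodeBudgetError):
            obr_action(Hyperstate(1, np.ones((32, 32))), spec, K=6, control_gene=3,
                       node_budget=10_000)


class TestRollouts:
    def test_zero_cost_when_everything_desirable(self, three_gene, rng):
        _, P, _ = three_gene
        spec = CostSpec(np.zeros(8, dtype=bool), lam=0.2)
        alpha = np.ones((8, 8))
        rec = obr_rollout(1, alpha, P, 5, spec, K=2, control_gene=3, rng=rng)
        assert rec.total_cost == 0.0
        assert (rec.actions == 0).all()

    def test_posterior_mass_grows_by_one_per_epoch(self, three_gene, rng):
        _, P, spec = three_gene
        alpha = np.ones((8, 8))
        rec = agr_rollout(3, alpha, P, 7, spec, control_gene=3, rng=rng)
        assert rec.alpha.sum() == pytest.approx(alpha.sum() + 7)
        assert rec.epochs == 7

    def test_zero_epoch_edge(self, three_gene, rng):
        _, P, spec = three_gene
        alpha = np.ones((8, 8))
        rec = agr_rollout(3, alpha, P, 0, spec, control_gene=3, rng=rng)
        assert rec.total_cost == 0.0
        assert np.allclose(rec.alpha, alpha)

    def test_rollouts_reproducible(self, three_gene):
        _, P, spec = three_gene
        alpha = np.ones((8, 8))
        a = agr_rollout(2, alpha, P, 6, spec, 3, np.random.default_rng(5))
        b = agr_rollout(2, alpha, P, 6, spec, 3, np.random.default_rng(5))
        assert np.array_equal(a.states, b.states)
        assert a.total_cost == b.total_cost

    def test_record_accounting(self, three_gene, rng):
        _, P, spec = three_gene
        alpha = np.ones((8, 8))
        rec = agr_rollout(1, alpha, P, 6, spec, 3, rng)
        g = spec.destination_costs()
        expect = sum(
            spec.lam**k * g[rec.actions[k], rec.states[k + 1] - 1]
            for k in range(6)
        )
        assert rec.total_cost == pytest.approx(expect)
        frame = rec.to_frame()
        assert list(frame.columns) == [
            "epoch", "state", "action", "next_state", "discounted_cost",
        ]

    def test_degenerate_prior_rollout_matches_nominal_cost(self, three_gene):
        """With the prior pinned on the truth, mean rollout cost approaches
        the nominal optimum (up to Monte-Carlo error and the lam^epochs tail)."""
        _, P, spec = three_gene
        Pa = controlled_tpm(P, 3)
        J_star, _ = value_iteration(Pa, spec)
        alpha = 1e9 * P + 1e-9
        rng = np.random.default_rng(11)
        B = 4000
        z0 = rng.integers(1, 9, size=B)
        costs = agr_costs_batch(z0, alpha, P, 7, spec, 3, rng)
        se = costs.std(ddof=1) / np.sqrt(B)
        tail = spec.lam**7 * 2.1 / (1 - spec.lam)
        assert costs.mean() == pytest.approx(J_star.mean(), abs=3 * se + tail)


class TestBatchedAGR:
    def test_batched_matches_looped_in_distribution(self, three_gene):
        _, P, spec = three_gene
        alpha = contamination_prior(P, 1.0, 0.1, np.random.default_rng(2))
        loop_costs = [
            agr_rollout(1 + (k % 8), alpha, P, 5, spec, 3,
                        np.random.default_rng(100 + k)).total_cost
            for k in range(400)
        ]
        z0 = 1 + (np.arange(2000) % 8)
        batch_costs = agr_costs_batch(z0, alpha, P, 5, spec, 3,
                                      np.random.default_rng(7))
        se = np.sqrt(np.var(loop_costs) / len(loop_costs)
                     + batch_costs.var() / batch_costs.size)
        assert np.mean(loop_costs) == pytest.approx(batch_costs.mean(), abs=4 * se)


class TestGRPolicy:
    def test_eps_zero_equals_nominal_policy(self, three_gene, rng):
        _, P, spec = three_gene
        Pa = controlled_tpm(P, 3)
        _, mu_star = value_iteration(Pa, spec)
        for kappa in (0.1, 1.0, 10.0):
            alpha = contamination_prior(P, kappa, 0.0, rng)
            assert np.array_equal(gr_policy(alpha, spec, 3), mu_star)

    def test_scale_invariance(self, rng):
        spec = CostSpec(default_partition(3, 1), lam=0.2)
        alpha = rng.uniform(0.5, 2.0, size=(8, 8))
        mu = gr_policy(alpha, spec, 3)
        assert np.array_equal(gr_policy(17.0 * alpha, spec, 3), mu)


class TestMCRPolicy:
    def test_singleton_sample_gives_nominal_policy(self, three_gene):
        _, P, spec = three_gene
        _, mu_star = value_iteration(controlled_tpm(P, 3), spec)
        assert np.array_equal(mcr_policy(P[None], spec, 3), mu_star)

    def test_identical_samples_same_as_singleton(self, three_gene):
        _, P, spec = three_gene
        single = mcr_policy(P[None], spec, 3)
        repeated = mcr_policy(np.stack([P] * 5), spec, 3)
        assert np.array_equal(single, repeated)

    def test_winner_is_best_candidate_but_maybe_not_global(self, rng):
        """MCR must beat every other candidate on prior average, yet can be
        beaten by a policy outside the candidate set."""
        spec = CostSpec(default_partition(3, 1), lam=0.2)
        alpha = rng.uniform(0.2, 1.0, size=(8, 8))
        samples = sample_tpm(alpha, rng, size=5)
        mu_mcr = mcr_policy(samples, spec, 3)

        def prior_avg(mu):
            return np.mean([
                policy_value(controlled_tpm(P, 3), mu, spec).mean()
                for P in samples
            ])

        candidates = {
            tuple(value_iteration(controlled_tpm(P, 3), spec)[1]) for P in samples
        }
        mcr_cost = prior_avg(mu_mcr)
        for cand in candidates:
            assert mcr_cost <= prior_avg(np.array(cand)) + 1e-10
        table = enumerate_policy_values(controlled_tpm(samples[0], 3), spec)
        global_best = min(
            prior_avg(np.array(mu)) for mu in table
        )
        assert mcr_cost >= global_best - 1e-10
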