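"""Robust intervention policies under TPM uncertainty.

Four designs, all driven by the Dirichlet hyperparameter matrix ``alpha``:

* **OBR** (optimal Bayesian robust): the Bayes-adaptive recursion.  The
  decision state is the hyperstate ``(i, alpha)``; a depth-``K``
  successive approximation

      J_K(i, a) = min_a  sum_j  P̄_ij(a) [ g_j(a) + lam J_{K-1}(j, a + γ) ]

  expands the full action/observation tree, re-deriving the posterior mean
  along every branch.  Work grows as ``(2|S|)^K``, which is why the depth
  is kept small and a node budget guards against accidental blowups.
* **MCR** (model-constrained robust): the best prior-average performer
  among the policies each optimal for some sampled member of the
  uncertainty class.
* **GR** (globally robust): the policy optimal for the prior-mean TPM.
* **AGR** (adaptive GR): GR recomputed from the posterior mean after every
  observed transition.

Rollouts simulate these policies against a fixed ground-truth TPM,
accumulating discounted costs and conjugate posterior updates.  A batched
AGR engine runs many (TPM, path) pairs simultaneously for the Monte-Carlo
harness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dirichlet_uncertainty import mean_tpm, validate_alpha
from .markov_engine import CostSpec, controlled_tpm, flip_map
from .nominal_dp import (
    policy_value_batch,
    value_iteration,
    value_iteration_batch,
)

__all__ = [
    "Hyperstate",
    "RolloutRecord",
    "obr_action",
    "obr_rollout",
    "gr_policy",
    "agr_rollout",
    "agr_costs_batch",
    "mcr_policy",
    "NodeBudgetError",
]


class NodeBudgetError(RuntimeError):
    """Raised when the OBR tree would exceed the configured node budget."""


@dataclass(frozen=True)
class Hyperstate:
    """Physical state (1-based) plus the Dirichlet hyperparameter matrix."""

    i: int
    alpha: np.ndarray

    def __post_init__(self) -> None:
        validate_alpha(self.alpha)
        if not 1 <= self.i <= self.alpha.shape[0]:
            raise ValueError("state outside 1..|S|")


@dataclass
class RolloutRecord:
    """One simulated trajectory: states, actions, costs, final posterior."""

    states: np.ndarray  # length epochs + 1, 1-based
    actions: np.ndarray  # length epochs
    discounted_costs: np.ndarray  # lam^k g at each epoch
    total_cost: float
    alpha: np.ndarray  # posterior after the last update

    @property
    def epochs(self) -> int:
        return self.actions.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(self.epochs),
                "state": self.states[:-1],
                "action": self.actions,
                "next_state": self.states[1:],
                "discounted_cost": self.discounted_costs,
            }
        )


def obr_action(
    h: Hyperstate,
    spec: CostSpec,
    K: int,
    control_gene: int,
    node_budget: int = 2_000_000,
) -> tuple[int, float]:
    """Depth-``K`` Bayes-adaptive lookahead; returns (action, J_K value).

    The recursion starts from ``J_0 = 0``, so ``J_K`` is nondecreasing in
    ``K`` for nonnegative costs.  Ties prefer no intervention.  The
    hyperparameter matrix is updated in place along each branch and
    restored on unwinding, so no per-node copies are made.
    """
    if K < 1:
        raise ValueError("lookahead depth K must be >= 1")
    alpha = validate_alpha(h.alpha).copy()
    S = alpha.shape[0]
    n = S.bit_length() - 1
    if (2 * S) ** max(K - 1, 0) > node_budget:
        raise NodeBudgetError(
            f"depth {K} on {S} states needs ~{(2 * S) ** (K - 1)} interior nodes, "
            f"over the budget of {node_budget}"
        )
    flip = flip_map(n, control_gene)
    row_sums = alpha.sum(axis=1)
    g = spec.destination_costs()  # (2, S)
    lam = spec.lam

    def recurse(k: int, i0: int) -> tuple[int, float]:
        best_a, best_v = 0, np.inf
        for a in (0, 1):
            row = i0 if a == 0 else int(flip[i0])
            pbar = alpha[row] / row_sums[row]
            val = float(pbar @ g[a])
            if k > 1:
                fut = 0.0
                for j in range(S):
                    if pbar[j] == 0.0:
                        continue
                    alpha[row, j] += 1.0
                    row_sums[row] += 1.0
                    fut += pbar[j] * recurse(k - 1, j)[1]
                    alpha[row, j] -= 1.0
                    row_sums[row] -= 1.0
                val += lam * fut
            if val < best_v:
                best_a, best_v = a, val
        return best_a, best_v

    return recurse(K, h.i - 1)


def _step(
    P_true: np.ndarray, row: int, rng: np.random.Generator
) -> int:
    """Sample a successor (0-based) from one TPM row."""
    return int(rng.choice(P_true.shape[0], p=P_true[row]))


def _rollout(
    z0: int,
    alpha0: np.ndarray,
    P_true: np.ndarray,
    epochs: int,
    spec: CostSpec,
    control_gene: int,
    rng: np.random.Generator,
    choose_action,
) -> RolloutRecord:
    alpha = validate_alpha(alpha0).copy()
    S = alpha.shape[0]
    n = S.bit_length() - 1
    flip = flip_map(n, control_gene)
    g = spec.destination_costs()
    states = [z0]
    actions: list[int] = []
    costs: list[float] = []
    z = z0 - 1
    for k in range(epochs):
        a = choose_action(z + 1, alpha)
        row = z if a == 0 else int(flip[z])
        j = _step(P_true, row, rng)
        c = spec.lam**k * g[a, j]
        alpha[row, j] += 1.0
        states.append(j + 1)
        actions.append(a)
        costs.append(float(c))
        z = j
    return RolloutRecord(
        states=np.array(states),
        actions=np.array(actions),
        discounted_costs=np.array(costs),
        total_cost=float(np.sum(costs)),
        alpha=alpha,
    )


def obr_rollout(
    z0: int,
    alpha0: np.ndarray,
    P_true: np.ndarray,
    epochs: int,
    spec: CostSpec,
    K: int,
    control_gene: int,
    rng: np.random.Generator,
    node_budget: int = 2_000_000,
) -> RolloutRecord:
    """Adaptive OBR episode against a fixed ground-truth TPM.

    At each epoch the depth-``K`` lookahead picks an action for the current
    hyperstate, the true chain transitions, the discounted cost accrues,
    and the posterior gains one count.  Truncation after ``epochs`` steps
    discards a tail bounded by ``lam^epochs g_max / (1 - lam)``.
    """
    if epochs < 0:
        raise ValueError("epochs must be >= 0")

    def choose(z: int, alpha: np.ndarray) -> int:
        return obr_action(Hyperstate(z, alpha), spec, K, control_gene, node_budget)[0]

    return _rollout(z0, alpha0, P_true, epochs, spec, control_gene, rng, choose)


def gr_policy(
    alpha: np.ndarray, spec: CostSpec, control_gene: int
) -> np.ndarray:
    """Globally robust policy: optimal for the prior-mean TPM."""
    Pa = controlled_tpm(mean_tpm(alpha), control_gene)
    return value_iteration(Pa, spec)[1]


def agr_rollout(
    z0: int,
    alpha0: np.ndarray,
    P_true: np.ndarray,
    epochs: int,
    spec: CostSpec,
    control_gene: int,
    rng: np.random.Generator,
) -> RolloutRecord:
    """Adaptive GR episode: each action is GR for the current posterior mean."""
    if epochs < 0:
        raise ValueError("epochs must be >= 0")

    def choose(z: int, alpha: np.ndarray) -> int:
        return int(gr_policy(alpha, spec, control_gene)[z - 1])

    return _rollout(z0, alpha0, P_true, epochs, spec, control_gene, rng, choose)


def agr_costs_batch(
    z0: np.ndarray,
    alpha0: np.ndarray,
    P_true: np.ndarray,
    epochs: int,
    spec: CostSpec,
    control_gene: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Total discounted AGR rollout costs for a batch of episodes.

    ``z0`` is a (B,) vector of 1-based initial states; ``P_true`` is
    (B, S, S) (or (S, S), broadcast); every episode starts from the shared
    prior ``alpha0`` and evolves its own posterior.  Equivalent in
    distribution to looping :func:`agr_rollout`, but the per-epoch value
    iterations run batched across all episodes.
    """
    alpha0 = validate_alpha(alpha0)
    S = alpha0.shape[0]
    n = S.bit_length() - 1
    z = np.asarray(z0, dtype=np.int64) - 1
    B = z.size
    P_true = np.broadcast_to(np.asarray(P_true, dtype=float), (B, S, S))
    flip = flip_map(n, control_gene)
    g = spec.destination_costs()
    alpha = np.broadcast_to(alpha0, (B, S, S)).copy()
    total = np.zeros(B)
    J = np.zeros((B, S))
    rows_idx = np.arange(B)
    for k in range(epochs):
        Pbar = alpha / alpha.sum(axis=2, keepdims=True)
        Pa = np.stack([Pbar, Pbar[:, flip, :]], axis=1)
        J, mu = value_iteration_batch(Pa, spec, J0=J)
        a = mu[rows_idx, z]
        row = np.where(a == 1, flip[z], z)
        cdf = np.cumsum(P_true[rows_idx, row, :], axis=1)
        u = rng.random(B)
        nxt = (u[:, None] < cdf).argmax(axis=1)
        total += spec.lam**k * g[a, nxt]
        alpha[rows_idx, row, nxt] += 1.0
        z = nxt
    return total


def _policy_order_key(mu: np.ndarray) -> tuple:
    return tuple(int(x) for x in mu)


def mcr_policy(
    samples: np.ndarray,
    spec: CostSpec,
    control_gene: int,
    eta: np.ndarray | None = None,
) -> np.ndarray:
    """Model-constrained robust policy from a sample representation of the prior.

    The candidate set is the deduplicated collection of policies optimal
    for each sampled TPM; the winner minimises the sample-averaged,
    eta-averaged discounted cost.  Ties go to the lexicographically first
    policy, making the output deterministic.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 2:
        samples = samples[None]
    if samples.size == 0:
        raise ValueError("need at least one sampled TPM")
    B, S, _ = samples.shape
    Pa = np.stack([samples, samples[:, flip_map(S.bit_length() - 1, control_gene), :]], axis=1)
    _, policies = value_iteration_batch(Pa, spec)
    candidates = sorted(
        {_policy_order_key(mu) for mu in policies}
    )
    best_mu, best_cost = None, np.inf
    for cand in candidates:
        mu = np.array(cand, dtype=np.int8)
        J = policy_value_batch(Pa, mu, spec)  # (B, S)
        avg = J.mean(axis=0)
        cost = float(avg.mean()) if eta is None else float(avg @ eta)
        if cost < best_cost:
            best_mu, best_cost = mu, cost
    return best_mu
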