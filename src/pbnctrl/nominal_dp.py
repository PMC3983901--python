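"""Discounted infinite-horizon dynamic programming with a known TPM.

Solves ``J*(i) = min_a sum_j P_ij(a) [g_j(a) + lam J*(j)]`` by value
iteration and evaluates stationary deterministic policies exactly via the
linear system ``(I - lam P_mu) J = g_mu``.  State spaces here are tiny
(at most 32 states), so dense algebra is used throughout.  A batched value
iteration over stacks of controlled TPMs backs the Monte-Carlo harness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .markov_engine import CostSpec

__all__ = [
    "value_iteration",
    "value_iteration_batch",
    "policy_value",
    "policy_value_batch",
    "average_cost",
    "write_policy_tsv",
    "read_policy_tsv",
    "write_cost_tsv",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    pass


def _greedy(Q: np.ndarray) -> np.ndarray:
    """Minimizing action per state with ties broken toward no intervention."""
    return (Q[..., 1, :] < Q[..., 0, :]).astype(np.int8)


def value_iteration(
    Pa: np.ndarray,
    spec: CostSpec,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    J0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal cost vector and greedy stationary policy.

    Iterates the Bellman operator until the sup-norm residual is below
    ``tol (1 - lam) / (2 lam)``, which guarantees ``||J - J*||_inf <= tol``.
    """
    J, mu = value_iteration_batch(Pa[None], spec, tol=tol, max_iter=max_iter,
                                  J0=None if J0 is None else J0[None])
    return J[0], mu[0]


def value_iteration_batch(
    Pa: np.ndarray,
    spec: CostSpec,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    J0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Value iteration over a stack of controlled TPMs of shape (B, 2, S, S)."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    lam = spec.lam
    B, _, S, _ = Pa.shape
    G = np.einsum("basj,aj->bas", Pa, spec.destination_costs())  # (B, 2, S)
    J = np.zeros((B, S)) if J0 is None else np.array(J0, dtype=float)
    thresh = tol * (1 - lam) / (2 * lam)
    for _ in range(max_iter):
        Q = G + lam * np.einsum("basj,bj->bas", Pa, J)
        J_new = Q.min(axis=1)
        resid = np.abs(J_new - J).max()
        J = J_new
        if resid <= thresh:
            return J, _greedy(Q)
    raise ConvergenceError(
        f"value iteration did not converge in {max_iter} iterations "
        f"(residual {resid:.3e})"
    )


def policy_value(Pa: np.ndarray, mu: np.ndarray, spec: CostSpec) -> np.ndarray:
    """Exact discounted cost of a stationary deterministic policy."""
    return policy_value_batch(Pa[None], mu, spec)[0]


def policy_value_batch(Pa: np.ndarray, mu: np.ndarray, spec: CostSpec) -> np.ndarray:
    """Evaluate one policy on a stack of controlled TPMs (B, 2, S, S) -> (B, S)."""
    B, _, S, _ = Pa.shape
    mu = np.asarray(mu)
    if mu.shape != (S,) or not np.isin(mu, (0, 1)).all():
        raise ValueError("policy must map every state to an action in {0, 1}")
    idx = np.arange(S)
    P_mu = Pa[:, mu, idx, :]  # (B, S, S)
    g = spec.destination_costs()[mu]  # (S, S) destination costs per origin row
    g_mu = np.einsum("bsj,sj->bs", P_mu, g)
    A = np.eye(S)[None] - spec.lam * P_mu
    return np.linalg.solve(A, g_mu[..., None])[..., 0]


def write_policy_tsv(mu: np.ndarray, path) -> None:
    pd.DataFrame(
        {"state": np.arange(1, mu.size + 1), "action": mu.astype(int)}
    ).to_csv(path, sep="\t", index=False)


def read_policy_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df.sort_values("state")["action"].to_numpy(dtype=np.int8)


def write_cost_tsv(J: np.ndarray, path) -> None:
    pd.DataFrame({"state": np.arange(1, J.size + 1), "J": J}).to_csv(
        path, sep="\t", index=False
    )


def average_cost(J: np.ndarray, eta: np.ndarray | None = None) -> float:
    """Expected cost under an initial-state distribution (uniform by default)."""
    J = np.asarray(J, dtype=float)
    if eta is None:
        return float(J.mean(axis=-1))
    eta = np.asarray(eta, dtype=float)
    if eta.shape != J.shape[-1:] or (eta < 0).any() or abs(eta.sum() - 1) > 1e-10:
        raise ValueError("eta must be a probability vector over the states")
    return float(J @ eta)
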