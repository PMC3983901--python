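"""Dirichlet priors over uncertain transition probability matrices.

The uncertainty class is the set of row-stochastic |S|x|S| matrices; a
prior over it takes each row of the uncontrolled TPM to be an independent
Dirichlet vector, the conjugate family for multinomial transition counts.
The whole prior is then a single positive hyperparameter matrix ``alpha``:
observing a transition ``i -> j`` (mapped through the control model, so an
intervened step records against row ``ĩ``) increments one entry of
``alpha`` by one.  Prior mean, per-entry variance, sampling, and the
epsilon-contamination construction used to seed priors around a known TPM
all live here.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .markov_engine import assert_stochastic, flip_map

__all__ = [
    "validate_alpha",
    "mean_tpm",
    "variance_tpm",
    "posterior_update",
    "batch_update",
    "counts_from_path",
    "sample_tpm",
    "contamination_prior",
    "log_density",
]


def validate_alpha(alpha: np.ndarray) -> np.ndarray:
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 2 or alpha.shape[0] != alpha.shape[1]:
        raise ValueError("hyperparameter matrix must be square")
    if not np.isfinite(alpha).all() or (alpha <= 0).any():
        raise ValueError("hyperparameter entries must be finite and strictly positive")
    return alpha


def mean_tpm(alpha: np.ndarray) -> np.ndarray:
    """Prior/posterior mean TPM: ``P̄_ij = α_ij / Σ_l α_il``."""
    alpha = validate_alpha(alpha)
    return alpha / alpha.sum(axis=1, keepdims=True)


def variance_tpm(alpha: np.ndarray) -> np.ndarray:
    """Per-entry variance ``P̄_ij (1 - P̄_ij) / (Σ_l α_il + 1)``."""
    alpha = validate_alpha(alpha)
    mean = alpha / alpha.sum(axis=1, keepdims=True)
    return mean * (1 - mean) / (alpha.sum(axis=1, keepdims=True) + 1)


def posterior_update(
    alpha: np.ndarray, i: int, a: int, j: int, control_gene: int
) -> np.ndarray:
    """Conjugate update for one observed transition ``(i, a) -> j`` (1-based states).

    The count lands on row ``i`` for action 0 and on the bit-flipped row
    ``ĩ`` for action 1, so the posterior stays a prior over the
    *uncontrolled* matrix.  Returns a new matrix; ``alpha`` is unmodified.
    """
    alpha = validate_alpha(alpha)
    S = alpha.shape[0]
    n = S.bit_length() - 1
    if a not in (0, 1):
        raise ValueError("action must be 0 or 1")
    if not (1 <= i <= S and 1 <= j <= S):
        raise ValueError("states must lie in 1..|S|")
    row = i - 1 if a == 0 else int(flip_map(n, control_gene)[i - 1])
    out = alpha.copy()
    out[row, j - 1] += 1.0
    return out


def batch_update(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Posterior from a transition-count matrix: ``α' = α + β``."""
    alpha = validate_alpha(alpha)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != alpha.shape:
        raise ValueError("count matrix shape must match the hyperparameter matrix")
    if (beta < 0).any() or not np.equal(np.mod(beta, 1), 0).all():
        raise ValueError("counts must be nonnegative integers")
    return alpha + beta


def counts_from_path(
    states: np.ndarray, actions: np.ndarray, n: int, control_gene: int
) -> np.ndarray:
    """Transition counts β from a rollout, mapped through the control model.

    ``states`` has length ``T + 1`` (1-based), ``actions`` length ``T``;
    an intervened transition from ``i`` counts against row ``ĩ``.
    """
    states = np.asarray(states)
    actions = np.asarray(actions)
    if states.size != actions.size + 1:
        raise ValueError("need one more state than actions")
    S = 2**n
    flip = flip_map(n, control_gene)
    beta = np.zeros((S, S))
    for i, a, j in zip(states[:-1], actions, states[1:]):
        row = i - 1 if a == 0 else int(flip[i - 1])
        beta[row, j - 1] += 1
    return beta


def sample_tpm(
    alpha: np.ndarray, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Draw TPMs with independent Dirichlet rows; shape (S, S) or (size, S, S).

    Sampling goes through log-space gamma variates
    (``log G_a = log G_{a+1} + log(U) / a``) so that the very small
    concentrations produced by tight contamination priors (e.g. κ = 0.1)
    cannot underflow to an all-zero row.
    """
    alpha = validate_alpha(alpha)
    shape = alpha.shape if size is None else (size, *alpha.shape)
    a = np.broadcast_to(alpha, shape)
    boosted = rng.standard_gamma(a + 1.0)
    with np.errstate(divide="ignore"):
        log_g = np.log(boosted) + np.log(rng.random(shape)) / a
    log_g -= log_g.max(axis=-1, keepdims=True)
    g = np.exp(log_g)
    P = g / g.sum(axis=-1, keepdims=True)
    return P


def contamination_prior(
    P_hat: np.ndarray,
    kappa: float,
    eps: float,
    rng: np.random.Generator,
    floor: float = 1e-12,
) -> np.ndarray:
    """Epsilon-contamination hyperparameters ``α = κ((1-ε) P̂ + ε Q)``.

    ``Q`` has rows drawn uniformly on the simplex, so the prior mean is
    exactly ``(1-ε) P̂ + ε Q``; ``κ`` sets the tightness around it.  A tiny
    additive ``floor`` keeps every entry strictly positive when ``P̂`` has
    exact zeros (only possible at ε = 0 with p = 0 networks); with
    ``floor = 0`` such a construction is rejected.
    """
    P_hat = np.asarray(P_hat, dtype=float)
    assert_stochastic(P_hat)
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if not 0 <= eps <= 1:
        raise ValueError("eps must lie in [0, 1]")
    if floor < 0:
        raise ValueError("floor must be nonnegative")
    S = P_hat.shape[0]
    Q = rng.dirichlet(np.ones(S), size=S)
    alpha = kappa * ((1 - eps) * P_hat + eps * Q) + floor
    if (alpha <= 0).any():
        raise ValueError(
            "contamination prior produced nonpositive hyperparameters; "
            "pass a positive floor (e.g. 1e-12) to keep the Dirichlet proper"
        )
    return alpha


def log_density(alpha: np.ndarray, P: np.ndarray) -> float:
    """Log density of the independent-Dirichlet-rows prior at ``P``.

    ``log c(α) + Σ_ij (α_ij - 1) log P_ij`` with
    ``log c(α) = Σ_i [log Γ(Σ_j α_ij) - Σ_j log Γ(α_ij)]``.  The support is
    taken to be the open simplex: any ``P_ij = 0`` with ``α_ij != 1``
    reports ``-inf`` explicitly.
    """
    alpha = validate_alpha(alpha)
    P = np.asarray(P, dtype=float)
    if P.shape != alpha.shape:
        raise ValueError("P shape must match the hyperparameter matrix")
    assert_stochastic(P)
    log_c = float(np.sum(gammaln(alpha.sum(axis=1))) - np.sum(gammaln(alpha)))
    zero = P == 0
    if (zero & (alpha != 1)).any():
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(zero, 0.0, (alpha - 1) * np.log(np.where(zero, 1.0, P)))
    return log_c + float(terms.sum())
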