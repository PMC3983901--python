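"""Markov-chain machinery: transition matrices, control, and intervention costs.

An instantaneously random PBN with perturbation probability ``p`` is an
ergodic Markov chain on ``S = {1, ..., 2^n}``.  With probability
``(1-p)^n`` no gene is perturbed and a context selected by ``r`` fires;
otherwise the next state is the current GAP with the realised perturbation
flips applied (the network function does not fire that step):

    P_xy = (1-p)^n * sum_l r_l 1{F^l(x) = y}
           + 1{y != x} * p^d(x,y) * (1-p)^(n - d(x,y))

with ``d`` the Hamming distance between GAPs.  The binary control scheme
forcibly flips one control gene: action 1 replaces row ``i`` by row ``ĩ``,
where ``ĩ`` is ``i`` with the control bit inverted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pbn_model import PBNModel, successor_table

__all__ = [
    "build_tpm",
    "flip_map",
    "controlled_tpm",
    "CostSpec",
    "immediate_cost",
    "default_partition",
    "expected_stage_cost",
    "read_tpm_tsv",
    "write_tpm_tsv",
    "assert_stochastic",
]

_ROW_TOL = 1e-10


def assert_stochastic(P: np.ndarray, tol: float = _ROW_TOL) -> None:
    if (P < 0).any():
        raise ValueError("transition matrix has negative entries")
    err = np.abs(P.sum(axis=-1) - 1.0).max()
    if err > tol:
        raise ValueError(f"rows deviate from stochasticity by {err:.3e}")


def _hamming_matrix(n: int) -> np.ndarray:
    s = np.arange(2**n)
    xor = s[:, None] ^ s[None, :]
    # popcount per entry; n <= ~10 so a loop over bits is fine
    d = np.zeros_like(xor)
    for b in range(n):
        d += (xor >> b) & 1
    return d


def build_tpm(pbn: PBNModel) -> np.ndarray:
    """Exact |S|x|S| TPM of an instantaneously random PBN with perturbation."""
    n, S = pbn.n, pbn.n_states
    P = np.zeros((S, S))
    for ctx, r in zip(pbn.contexts, pbn.r):
        succ = successor_table(ctx) - 1
        P[np.arange(S), succ] += r
    P *= (1.0 - pbn.p) ** n

    if pbn.p > 0:
        d = _hamming_matrix(n)
        perturb = pbn.p**d * (1.0 - pbn.p) ** (n - d)
        np.fill_diagonal(perturb, 0.0)
        P += perturb
    assert_stochastic(P)
    return P


def flip_map(n: int, control_gene: int) -> np.ndarray:
    """0-based state permutation ``i -> ĩ`` flipping the control gene's bit.

    Gene ``c`` occupies bit ``n - c`` (gene 1 is the MSB).
    """
    if not 1 <= control_gene <= n:
        raise ValueError(f"control gene {control_gene} outside 1..{n}")
    return np.arange(2**n) ^ (1 << (n - control_gene))


def controlled_tpm(P: np.ndarray, control_gene: int) -> np.ndarray:
    """Stack the two action matrices: ``Pa[0] = P``, ``Pa[1][i] = P[ĩ]``."""
    S = P.shape[0]
    n = S.bit_length() - 1
    if 2**n != S:
        raise ValueError("state count must be a power of two")
    flip = flip_map(n, control_gene)
    return np.stack([P, P[flip]])


@dataclass(frozen=True)
class CostSpec:
    """Destination/action cost structure and discount factor.

    ``g_ij(a)`` depends only on the destination ``j`` and action ``a``:
    cost ``costs[0]`` for an undesirable destination under intervention,
    ``costs[1]`` without, ``costs[2]`` for a desirable destination under
    intervention, ``costs[3]`` otherwise.  Defaults (2.1, 2.0, 0.1, 0)
    price an undesirable outcome at 2 and an intervention at 0.1.
    """

    undesirable: np.ndarray  # boolean mask over S
    lam: float = 0.2
    costs: tuple[float, float, float, float] = (2.1, 2.0, 0.1, 0.0)

    def __post_init__(self) -> None:
        mask = np.asarray(self.undesirable, dtype=bool)
        object.__setattr__(self, "undesirable", mask)
        if not 0 < self.lam < 1:
            raise ValueError("discount factor must lie in (0, 1)")
        if any(c < 0 for c in self.costs):
            raise ValueError("costs must be nonnegative")

    @property
    def n_states(self) -> int:
        return self.undesirable.size

    @property
    def g_max(self) -> float:
        return max(self.costs)

    def destination_costs(self) -> np.ndarray:
        """(2, |S|) array: ``g[a, j]`` for each action and destination."""
        gU1, gU0, gD1, gD0 = self.costs
        u = self.undesirable
        return np.stack([np.where(u, gU0, gD0), np.where(u, gU1, gD1)])


def immediate_cost(spec: CostSpec, j: int, a: int) -> float:
    """Cost of landing in state ``j`` (1-based) under action ``a``."""
    if not 1 <= j <= spec.n_states:
        raise ValueError(f"state {j} outside 1..{spec.n_states}")
    return float(spec.destination_costs()[a, j - 1])


def default_partition(n: int, target_gene: int = 1, flavor: str = "target-down") -> np.ndarray:
    """Boolean mask of undesirable states.

    ``target-down``: the target gene is OFF.  ``cycd-rb-down``: genes 1 and 2
    (CycD and Rb in the cell-cycle ordering) are both OFF.
    """
    states = np.arange(2**n)
    if flavor == "target-down":
        return (states >> (n - target_gene)) & 1 == 0
    if flavor == "cycd-rb-down":
        return ((states >> (n - 1)) & 1 == 0) & ((states >> (n - 2)) & 1 == 0)
    raise ValueError(f"unknown partition flavor {flavor!r}")


def expected_stage_cost(Pa: np.ndarray, spec: CostSpec) -> np.ndarray:
    """(2, |S|) expected immediate cost ``sum_j P_ij(a) g_j(a)``."""
    g = spec.destination_costs()
    return np.einsum("asj,aj->as", Pa, g)


def write_tpm_tsv(P: np.ndarray, path) -> None:
    """Tab-separated TPM with 1-based state labels as header and index."""
    labels = [str(i + 1) for i in range(P.shape[0])]
    pd.DataFrame(P, index=labels, columns=labels).to_csv(path, sep="\t")


def read_tpm_tsv(path) -> np.ndarray:
    """Read and validate a TPM written by :func:`write_tpm_tsv`."""
    P = pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=float)
    if P.shape[0] != P.shape[1]:
        raise ValueError("TPM must be square")
    assert_stochastic(P, tol=1e-8)
    return P
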