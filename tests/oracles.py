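"""Independent reference implementations used only by the tests.

These are deliberately naive — literal transcriptions of the defining
equations, with no vectorisation or shared state — so they can serve as
oracles for the production code paths.
"""

import itertools

import numpy as np

from pbnctrl.markov_engine import CostSpec, flip_map
from pbnctrl.nominal_dp import policy_value


def naive_obr_action(i0: int, alpha: np.ndarray, spec: CostSpec, K: int,
                     control_gene: int) -> tuple[int, float]:
    """Literal depth-K Bayes-adaptive recursion; i0 is 0-based.

    Copies the full hyperparameter matrix at every branch and recomputes
    every posterior mean from scratch.
    """
    S = alpha.shape[0]
    n = S.bit_length() - 1
    flip = flip_map(n, control_gene)
    g = spec.destination_costs()
    lam = spec.lam

    def value(k: int, i: int, a_mat: np.ndarray, want_action: bool = False):
        if k == 0:
            return 0.0
        best_a, best_v = 0, np.inf
        for a in (0, 1):
            row = i if a == 0 else int(flip[i])
            pbar = a_mat[row] / a_mat[row].sum()
            v = float(pbar @ g[a])
            for j in range(S):
                gamma = np.zeros_like(a_mat)
                gamma[row, j] = 1.0
                v += lam * pbar[j] * value(k - 1, j, a_mat + gamma)
            if v < best_v:
                best_a, best_v = a, v
        return (best_a, best_v) if want_action else best_v

    return value(K, i0, np.array(alpha, dtype=float), want_action=True)


def enumerate_policy_values(Pa: np.ndarray, spec: CostSpec) -> dict:
    """Exact cost vector of every stationary deterministic policy."""
    S = Pa.shape[-1]
    out = {}
    for bits in itertools.product((0, 1), repeat=S):
        mu = np.array(bits, dtype=np.int8)
        out[bits] = policy_value(Pa, mu, spec)
    return out
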