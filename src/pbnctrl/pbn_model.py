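"""Boolean networks, instantaneously random PBNs, and state encoding.

A probabilistic Boolean network (PBN) over ``n`` binary genes switches at
every step among ``m`` constituent Boolean networks (*contexts*), selected
independently with probabilities ``r``, and additionally flips each gene
with a small perturbation probability ``p``.  This module houses the
network representation, the gene-activity-profile (GAP) encoding of states
into ``S = {1, ..., 2^n}``, a random-network generator used for synthetic
benchmarks, and the reduced mammalian cell-cycle fixture.

Conventions
-----------
* Gene 1 is the most significant bit of the state encoding:
  ``x = 1 + sum_i 2^(n-i) v_i``.
* Truth tables are indexed with the first listed predictor as the most
  significant bit of the input assignment.
* A gene with an empty predictor set is a constant; its truth table has a
  single entry (used for extracellular inputs such as CycD).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BooleanContext",
    "PBNModel",
    "encode_state",
    "decode_state",
    "next_state",
    "successor_table",
    "random_pbn",
    "beta_shape_params",
    "cell_cycle_pbn",
    "CYCA_PARSES",
    "load_network",
    "save_network",
    "load_fixture",
]


def encode_state(v: Sequence[int]) -> int:
    """Map a gene activity profile to its decimal state in ``1..2^n``.

    ``x = 1 + sum_{i=1..n} 2^(n-i) v_i`` with gene 1 as the most
    significant bit.
    """
    v = np.asarray(v)
    if v.ndim != 1 or not np.isin(v, (0, 1)).all():
        raise ValueError("gene activity profile must be a flat 0/1 vector")
    n = v.size
    return 1 + int(np.dot(v, 2 ** np.arange(n - 1, -1, -1)))


def decode_state(x: int, n: int) -> np.ndarray:
    """Inverse of :func:`encode_state`: state index to binary GAP."""
    if not 1 <= x <= 2**n:
        raise ValueError(f"state {x} outside 1..{2**n}")
    bits = (x - 1) >> np.arange(n - 1, -1, -1) & 1
    return bits.astype(np.int8)


@dataclass(frozen=True)
class BooleanContext:
    """One constituent Boolean network: per-gene predictor sets and truth tables.

    ``predictor_sets[i]`` lists the (1-based) inputs of gene ``i+1``;
    ``truth_tables[i]`` has length ``2^{j_i}`` and gives the gene's next
    value for every predictor assignment (first predictor = MSB).
    """

    n: int
    predictor_sets: tuple[tuple[int, ...], ...]
    truth_tables: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if len(self.predictor_sets) != self.n or len(self.truth_tables) != self.n:
            raise ValueError("need one predictor set and one truth table per gene")
        for i, (preds, table) in enumerate(zip(self.predictor_sets, self.truth_tables)):
            if any(not 1 <= g <= self.n for g in preds):
                raise ValueError(f"gene {i + 1}: predictor index outside 1..{self.n}")
            if len(table) != 2 ** len(preds):
                raise ValueError(
                    f"gene {i + 1}: truth table length {len(table)} != 2^{len(preds)}"
                )
            if any(b not in (0, 1) for b in table):
                raise ValueError(f"gene {i + 1}: truth table entries must be 0/1")


def next_state(ctx: BooleanContext, v: Sequence[int]) -> np.ndarray:
    """Synchronous update of a GAP under one context (all reads from ``v``)."""
    v = np.asarray(v)
    if v.size != ctx.n:
        raise ValueError("GAP length does not match gene count")
    if not np.isin(v, (0, 1)).all():
        raise ValueError("GAP entries must be 0/1")
    out = np.empty(ctx.n, dtype=np.int8)
    for i, (preds, table) in enumerate(zip(ctx.predictor_sets, ctx.truth_tables)):
        idx = 0
        for g in preds:
            idx = (idx << 1) | int(v[g - 1])
        out[i] = table[idx]
    return out


def successor_table(ctx: BooleanContext) -> np.ndarray:
    """Deterministic successor of every state: array of 1-based states, length 2^n."""
    n = ctx.n
    succ = np.empty(2**n, dtype=np.int64)
    for s in range(2**n):
        v = decode_state(s + 1, n)
        succ[s] = encode_state(next_state(ctx, v))
    return succ


@dataclass(frozen=True)
class PBNModel:
    """An instantaneously random PBN: contexts, selection probabilities, perturbation.

    The switching probability ``q`` is fixed at 1 (a fresh context is drawn
    every step), so the context indicator is marginalised out when the
    transition matrix is built.
    """

    n: int
    contexts: tuple[BooleanContext, ...]
    r: tuple[float, ...]
    p: float
    q: float = 1.0
    gene_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.q != 1.0:
            raise ValueError("only instantaneously random PBNs (q = 1) are supported")
        if not self.contexts:
            raise ValueError("need at least one context")
        if any(ctx.n != self.n for ctx in self.contexts):
            raise ValueError("all contexts must share the gene count")
        r = np.asarray(self.r, dtype=float)
        if r.size != len(self.contexts):
            raise ValueError("selection vector length must equal the context count")
        if (r < 0).any() or abs(r.sum() - 1.0) > 1e-12:
            raise ValueError("selection probabilities must be >= 0 and sum to 1")
        if not 0 <= self.p < 1:
            raise ValueError("perturbation probability must lie in [0, 1)")
        if self.gene_names is not None and len(self.gene_names) != self.n:
            raise ValueError("need one gene name per gene")

    @property
    def m(self) -> int:
        return len(self.contexts)

    @property
    def n_states(self) -> int:
        return 2**self.n


def beta_shape_params(mean: float, sd: float) -> tuple[float, float]:
    """Beta(a, b) shape parameters from a (mean, sd) specification.

    Requires ``sd^2 < mean (1 - mean)``; raises otherwise.
    """
    if not 0 < mean < 1:
        raise ValueError("bias mean must lie strictly in (0, 1)")
    if sd <= 0:
        raise ValueError("bias sd must be positive")
    nu = mean * (1 - mean) / sd**2 - 1
    if nu <= 0:
        raise ValueError(f"sd {sd} too large for mean {mean}: no valid beta shape")
    return mean * nu, (1 - mean) * nu


def random_pbn(
    n: int,
    m: int = 3,
    max_predictors: int = 2,
    bias_mean: float = 0.5,
    bias_sd: float = 0.01,
    p: float = 0.001,
    rng: np.random.Generator | int | None = None,
    bias_per: str = "context",
) -> PBNModel:
    """Generate a random PBN with ``m`` equally likely contexts.

    Each gene draws its in-degree uniformly from ``{1, ..., max_predictors}``
    and its predictor set uniformly without replacement (self-inputs allowed).
    Truth-table entries are Bernoulli(bias) with the bias itself drawn from a
    Beta distribution of the given mean and standard deviation — one draw per
    context by default (``bias_per='context'``) or per gene
    (``bias_per='gene'``).
    """
    if max_predictors > n:
        raise ValueError("max_predictors cannot exceed the gene count")
    if max_predictors < 1:
        raise ValueError("max_predictors must be >= 1")
    if bias_per not in ("context", "gene"):
        raise ValueError("bias_per must be 'context' or 'gene'")
    a, b = beta_shape_params(bias_mean, bias_sd)
    rng = np.random.default_rng(rng)

    contexts = []
    for _ in range(m):
        ctx_bias = rng.beta(a, b) if bias_per == "context" else None
        preds: list[tuple[int, ...]] = []
        tables: list[tuple[int, ...]] = []
        for _gene in range(n):
            j = int(rng.integers(1, max_predictors + 1))
            chosen = rng.choice(n, size=j, replace=False) + 1
            bias = ctx_bias if ctx_bias is not None else rng.beta(a, b)
            table = (rng.random(2**j) < bias).astype(int)
            preds.append(tuple(int(g) for g in chosen))
            tables.append(tuple(int(t) for t in table))
        contexts.append(BooleanContext(n, tuple(preds), tuple(tables)))

    return PBNModel(
        n=n,
        contexts=tuple(contexts),
        r=tuple([1.0 / m] * m),
        p=p,
    )


# --- reduced mammalian cell-cycle network -------------------------------

# The CycA rule of the reduced mutated cell-cycle network is printed with an
# ambiguous association in its second disjunct; all three defensible parses
# are available, selected by name.  "conjunction" reproduces the published
# optimal-cost benchmark and is the default.
CYCA_PARSES = ("conjunction", "precedence", "grouped")


def _cyca_rule(parse: str):
    if parse == "precedence":  # (~v2 & v3 & ~v5) | (~v2 & ~v4) | ~v5
        return lambda v2, v3, v4, v5: ((1 - v2) & v3 & (1 - v5)) | (
            (1 - v2) & (1 - v4)
        ) | (1 - v5)
    if parse == "grouped":  # (~v2 & v3 & ~v5) | (~v2 & (~v4 | ~v5))
        return lambda v2, v3, v4, v5: ((1 - v2) & v3 & (1 - v5)) | (
            (1 - v2) & ((1 - v4) | (1 - v5))
        )
    if parse == "conjunction":  # (~v2 & v3 & ~v5) | (~v2 & ~v4 & ~v5)
        return lambda v2, v3, v4, v5: ((1 - v2) & v3 & (1 - v5)) | (
            (1 - v2) & (1 - v4) & (1 - v5)
        )
    raise ValueError(f"unknown CycA parse {parse!r}; choose from {CYCA_PARSES}")


def _table(preds: tuple[int, ...], fn) -> tuple[int, ...]:
    """Enumerate a truth table over the predictor assignments (first pred = MSB)."""
    j = len(preds)
    out = []
    for idx in range(2**j):
        bits = [(idx >> (j - 1 - k)) & 1 for k in range(j)]
        out.append(int(fn(*bits)))
    return tuple(out)


def cell_cycle_pbn(cyca_parse: str = "conjunction", p: float = 0.01) -> PBNModel:
    """The 5-gene reduced mutated mammalian cell-cycle PBN.

    Genes, MSB to LSB: CycD, Rb, CycA, UbcH10, CycB.  The extracellular
    growth signal fixes CycD ON or OFF, giving two equally likely contexts.
    Within a context the signal value is substituted into every rule that
    reads CycD (only Rb does), so the context's dynamics never consult the
    stored CycD bit — a perturbation-flipped CycD relaxes back to the
    signal on the next update.  The p27 mutation is baked into the reduced
    rules, so the network can cycle with both CycD and Rb inactive — the
    undesirable proliferative behaviour that intervention tries to suppress.
    """
    cyca = _cyca_rule(cyca_parse)
    ubch10 = lambda v3, v4, v5: (v4 & v5) | (v3 & (1 - v5))
    cycb = lambda v3, v5: v3 & (1 - v5)

    def context(cycd_on: int) -> BooleanContext:
        # Rb = ~CycD & Rb & ~CycA & ~CycB with CycD fixed at the signal value:
        # identically 0 when the signal is ON, Rb & ~CycA & ~CycB when OFF.
        if cycd_on:
            rb_preds: tuple[int, ...] = ()
            rb_table: tuple[int, ...] = (0,)
        else:
            rb_preds = (2, 3, 5)
            rb_table = _table(rb_preds, lambda v2, v3, v5: v2 & (1 - v3) & (1 - v5))
        preds = ((), rb_preds, (2, 3, 4, 5), (3, 4, 5), (3, 5))
        tables = (
            (cycd_on,),
            rb_table,
            _table(preds[2], cyca),
            _table(preds[3], ubch10),
            _table(preds[4], cycb),
        )
        return BooleanContext(5, preds, tables)

    return PBNModel(
        n=5,
        contexts=(context(1), context(0)),
        r=(0.5, 0.5),
        p=p,
        gene_names=("CycD", "Rb", "CycA", "UbcH10", "CycB"),
    )


# --- JSON serialization --------------------------------------------------


def save_network(pbn: PBNModel, path) -> None:
    """Write a PBN to the package's JSON network schema."""
    doc = {
        "n": pbn.n,
        "p": pbn.p,
        "q": pbn.q,
        "r": list(pbn.r),
        "contexts": [
            {
                "predictors": [list(ps) for ps in ctx.predictor_sets],
                "truth_tables": [list(tt) for tt in ctx.truth_tables],
            }
            for ctx in pbn.contexts
        ],
    }
    if pbn.gene_names is not None:
        doc["gene_names"] = list(pbn.gene_names)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def _from_doc(doc: dict) -> PBNModel:
    contexts = tuple(
        BooleanContext(
            doc["n"],
            tuple(tuple(ps) for ps in ctx["predictors"]),
            tuple(tuple(tt) for tt in ctx["truth_tables"]),
        )
        for ctx in doc["contexts"]
    )
    return PBNModel(
        n=doc["n"],
        contexts=contexts,
        r=tuple(doc["r"]),
        p=doc["p"],
        q=doc.get("q", 1.0),
        gene_names=tuple(doc["gene_names"]) if "gene_names" in doc else None,
    )


def load_network(path) -> PBNModel:
    """Read a PBN from the JSON network schema."""
    with open(path) as fh:
        return _from_doc(json.load(fh))


def load_fixture(name: str) -> PBNModel:
    """Load a packaged network fixture, e.g. ``cell_cycle_reduced``."""
    text = resources.files("pbnctrl.data").joinpath(f"{name}.json").read_text()
    return _from_doc(json.loads(text))
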