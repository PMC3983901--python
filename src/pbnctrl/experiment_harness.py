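"""Monte-Carlo comparison of intervention policies across uncertain networks.

For each ground-truth network the harness samples an ensemble of TPMs from
its contamination prior and estimates up to seven discounted-cost
functionals, each averaged over uniformly random initial states:

* ``J_LB`` — mean over samples of each sample's *own* optimal cost: the
  unattainable lower bound on any robust policy.
* ``J_T`` — optimal cost on the true network (prior-independent).
* ``J_ET`` — the true network's optimal policy evaluated across samples.
* ``J_MCR`` — best sample-optimal policy on prior average.
* ``J_GR`` — prior-mean-optimal policy evaluated across samples.
* ``J_AGR`` — truncated adaptive-GR rollouts against sampled TPMs.
* ``J_OBR`` — truncated Bayes-adaptive rollouts (small state spaces only).

Sweeps repeat this per random network (synthetic study) or per
contamination setting of the cell-cycle network, reporting per-network
rows, column means, and Monte-Carlo standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .dirichlet_uncertainty import contamination_prior, mean_tpm, sample_tpm
from .markov_engine import CostSpec, build_tpm, controlled_tpm, default_partition
from .nominal_dp import (
    average_cost,
    policy_value_batch,
    value_iteration,
    value_iteration_batch,
)
from .pbn_model import cell_cycle_pbn, random_pbn
from .robust_control import agr_costs_batch, gr_policy, mcr_policy, obr_rollout

__all__ = [
    "ExperimentConfig",
    "estimate_costs",
    "synthetic_sweep",
    "cellcycle_sweep",
    "percent_decrease",
    "empirical_ccdf",
    "ALL_FUNCTIONALS",
]

ALL_FUNCTIONALS = ("J_LB", "J_T", "J_ET", "J_MCR", "J_GR", "J_AGR", "J_OBR")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything a sweep needs; defaults mirror the synthetic 3-gene study.

    Monte-Carlo sizes are deliberately configurable: the published study
    used 500 networks x 500 sampled TPMs x 100 paths (3-gene) and
    10,000 x 10,000 for the cell-cycle network; scaled-down desk sizes give
    the same estimators with wider standard errors.
    """

    # network generation
    n: int = 3
    m: int = 3
    max_predictors: int = 2
    bias_mean: float = 0.5
    bias_sd: float = 0.01
    p: float = 0.001
    # cost structure
    lam: float = 0.2
    costs: tuple[float, float, float, float] = (2.1, 2.0, 0.1, 0.0)
    partition_flavor: str = "target-down"
    target_gene: int = 1
    control_gene: int | None = None  # None -> least significant gene
    # prior
    kappa: float = 0.1
    eps: float = 0.1
    floor: float = 1e-12
    # Monte-Carlo sizes
    n_networks: int = 500
    n_samples: int = 500
    n_paths: int = 100
    epochs: int = 7
    K: int = 5
    include_obr: bool = False
    seed: int = 0

    @property
    def resolved_control_gene(self) -> int:
        return self.n if self.control_gene is None else self.control_gene

    def cost_spec(self, n: int | None = None) -> CostSpec:
        n = self.n if n is None else n
        return CostSpec(
            default_partition(n, self.target_gene, self.partition_flavor),
            lam=self.lam,
            costs=self.costs,
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "costs" in doc:
            doc["costs"] = tuple(doc["costs"])
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["costs"] = list(doc["costs"])
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _se(per_sample: np.ndarray) -> float:
    if per_sample.size < 2:
        return float("nan")
    return float(per_sample.std(ddof=1) / np.sqrt(per_sample.size))


def estimate_costs(
    P_hat: np.ndarray,
    alpha: np.ndarray,
    cfg: ExperimentConfig,
    rng: np.random.Generator,
    functionals: tuple[str, ...] | None = None,
    control_gene: int | None = None,
) -> dict[str, float]:
    """Estimate the cost functionals for one network and its prior.

    Returns ``{name: value, name_se: standard error, ...}``.  ``J_OBR`` is
    only computed when requested (it expands the full Bayes-adaptive tree
    at every epoch of every path, so it is restricted to small state
    spaces by the node budget).
    """
    if functionals is None:
        functionals = tuple(f for f in ALL_FUNCTIONALS if f != "J_OBR" or cfg.include_obr)
    S = P_hat.shape[0]
    n = S.bit_length() - 1
    cg = cfg.resolved_control_gene if control_gene is None else control_gene
    spec = cfg.cost_spec(n)
    out: dict[str, float] = {}

    need_samples = set(functionals) & {"J_LB", "J_ET", "J_MCR", "J_GR", "J_AGR", "J_OBR"}
    samples = sample_tpm(alpha, rng, size=cfg.n_samples) if need_samples else None
    if samples is not None:
        flip_Pa = np.stack(
            [samples, samples[:, np.arange(S) ^ (1 << (n - cg)), :]], axis=1
        )

    if "J_T" in functionals or "J_ET" in functionals:
        Pa_hat = controlled_tpm(P_hat, cg)
        J_star, mu_star = value_iteration(Pa_hat, spec)
    if "J_T" in functionals:
        out["J_T"] = average_cost(J_star)
        out["J_T_se"] = 0.0

    if "J_LB" in functionals:
        J_opt, _ = value_iteration_batch(flip_Pa, spec)
        per = J_opt.mean(axis=1)
        out["J_LB"], out["J_LB_se"] = float(per.mean()), _se(per)

    if "J_ET" in functionals:
        per = policy_value_batch(flip_Pa, mu_star, spec).mean(axis=1)
        out["J_ET"], out["J_ET_se"] = float(per.mean()), _se(per)

    if "J_MCR" in functionals:
        mu = mcr_policy(samples, spec, cg)
        per = policy_value_batch(flip_Pa, mu, spec).mean(axis=1)
        out["J_MCR"], out["J_MCR_se"] = float(per.mean()), _se(per)

    if "J_GR" in functionals:
        mu = gr_policy(alpha, spec, cg)
        per = policy_value_batch(flip_Pa, mu, spec).mean(axis=1)
        out["J_GR"], out["J_GR_se"] = float(per.mean()), _se(per)

    if "J_AGR" in functionals:
        reps = np.repeat(np.arange(cfg.n_samples), cfg.n_paths)
        z0 = rng.integers(1, S + 1, size=reps.size)
        costs = agr_costs_batch(z0, alpha, samples[reps], cfg.epochs, spec, cg, rng)
        per = costs.reshape(cfg.n_samples, cfg.n_paths).mean(axis=1)
        out["J_AGR"], out["J_AGR_se"] = float(per.mean()), _se(per)

    if "J_OBR" in functionals:
        per = np.empty(cfg.n_samples)
        for l, P in enumerate(samples):
            tot = 0.0
            for _ in range(cfg.n_paths):
                z0 = int(rng.integers(1, S + 1))
                rec = obr_rollout(
                    z0, alpha, P, cfg.epochs, spec, cfg.K, cg, rng
                )
                tot += rec.total_cost
            per[l] = tot / cfg.n_paths
        out["J_OBR"], out["J_OBR_se"] = float(per.mean()), _se(per)

    return out


def synthetic_sweep(
    cfg: ExperimentConfig, functionals: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Random-network study: one row per network plus a ``mean`` row.

    Networks, priors and Monte-Carlo draws all derive from ``cfg.seed``
    through independent substreams, so the sweep is a pure function of the
    configuration.  ``functionals`` restricts the estimated columns (all
    but ``J_OBR`` by default).
    """
    ss = np.random.SeedSequence(cfg.seed)
    rows = []
    for l, child in enumerate(ss.spawn(cfg.n_networks)):
        rng = np.random.default_rng(child)
        pbn = random_pbn(
            cfg.n, cfg.m, cfg.max_predictors, cfg.bias_mean, cfg.bias_sd, cfg.p, rng
        )
        P_hat = build_tpm(pbn)
        alpha = contamination_prior(P_hat, cfg.kappa, cfg.eps, rng, cfg.floor)
        row = {"network": l}
        row.update(estimate_costs(P_hat, alpha, cfg, rng, functionals=functionals))
        rows.append(row)
    df = pd.DataFrame(rows).set_index("network")
    df.loc["mean"] = df.mean(axis=0)
    return df


def cellcycle_sweep(
    cfg: ExperimentConfig,
    grid: tuple[tuple[float, float], ...] = (
        (0.1, 0.0), (1.0, 0.0), (5.0, 0.0),
        (0.1, 0.1), (1.0, 0.1), (5.0, 0.1),
        (0.1, 0.25), (1.0, 0.25), (5.0, 0.25),
    ),
    cyca_parse: str = "conjunction",
) -> pd.DataFrame:
    """Cell-cycle study: one row per (kappa, eps) contamination setting.

    The ground truth is the reduced cell-cycle PBN's exact TPM; the control
    gene is CycA and undesirable states have CycD and Rb both OFF.  The
    Bayes-adaptive tree is far too large at 32 states, so only the
    suboptimal policies are estimated.
    """
    pbn = cell_cycle_pbn(cyca_parse=cyca_parse)
    P_hat = build_tpm(pbn)
    cc = replace(
        cfg,
        n=5,
        partition_flavor="cycd-rb-down",
        control_gene=3,
        include_obr=False,
    )
    ss = np.random.SeedSequence(cfg.seed)
    rows = []
    for (kappa, eps), child in zip(grid, ss.spawn(len(grid))):
        rng = np.random.default_rng(child)
        alpha = contamination_prior(P_hat, kappa, eps, rng, cc.floor)
        row = {"kappa": kappa, "eps": eps}
        row.update(estimate_costs(P_hat, alpha, cc, rng, control_gene=3))
        rows.append(row)
    return pd.DataFrame(rows)


def percent_decrease(J_subopt: float, J_ref: float) -> float:
    """``100 (J_subopt - J_ref) / J_subopt``: gain from the better policy."""
    if J_subopt == 0:
        raise ZeroDivisionError("reference suboptimal cost is zero")
    return 100.0 * (J_subopt - J_ref) / J_subopt


def empirical_ccdf(values: np.ndarray, grid: np.ndarray) -> pd.DataFrame:
    """Empirical complementary CDF ``t -> fraction of values > t``."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    grid = np.asarray(grid, dtype=float)
    ccdf = (values[None, :] > grid[:, None]).mean(axis=1)
    return pd.DataFrame({"t": grid, "ccdf": ccdf})
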