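# Methods

## Model

An instantaneously random PBN re-selects its operating context at every
update (switching probability fixed at 1), so the context indicator can be
marginalised out of the dynamics. With per-gene perturbation probability
`p`, the chain takes the standard closed form: with probability `(1-p)^n`
no gene is perturbed and a context chosen by `r` fires its synchronous
Boolean update; otherwise the next state is the current profile with the
realised flips applied and the network function does not fire that step,

    P_xy = (1-p)^n Σ_l r_l 1{F^l(x) = y} + 1{y ≠ x} p^d(x,y) (1-p)^(n-d(x,y)),

where `d` is the Hamming distance between gene activity profiles. Every
off-diagonal entry is positive for `p > 0`, so the chain is ergodic. Gene 1
is the most significant bit of the state index throughout; truth tables
are indexed with the first listed predictor as the most significant input
bit.

Binary control on gene `c`: action 1 swaps row `i` for row `ĩ` (bit `c`
flipped). Costs depend on the destination and the action only — 2.0/2.1
for an undesirable destination without/with intervention, 0/0.1 for a
desirable one — and the criterion is expected total `λ`-discounted cost,
`λ = 0.2` by default. Small discount factors keep both value iteration and
the Bayes-adaptive tree shallow; clinically they encode that near-term
avoidance of the bad phenotype dominates.

## Uncertainty model and policies

Rows of the uncontrolled matrix carry independent Dirichlet priors, the
conjugate family for multinomial transition counts: the whole prior is one
positive matrix `α`, an observed transition `(i, a) → j` adds a unit count
at `(i, j)` for `a = 0` or `(ĩ, j)` for `a = 1`, and the prior mean is the
row-normalised `α`. Priors around a known matrix use the ε-contamination
construction `α = κ((1-ε) P̂ + ε Q)` with `Q` rows uniform on the simplex;
`κ` is the effective prior sample size per row and `ε` the contamination
level. A configurable additive floor (default 1e-12) keeps `α` strictly
positive when `P̂` contains exact zeros (possible on the diagonal when no
context fixes a state); at that magnitude it is numerically inert.

The Bayes-adaptive (OBR) action at hyperstate `(i, α)` comes from the
depth-`K` successive approximation

    J_k(i, α) = min_a Σ_j P̄_ij(a) [ g_j(a) + λ J_{k-1}(j, α + γ) ],  J_0 = 0,

expanding every action/observation branch and re-deriving the posterior
mean along it. Starting from the zero function makes `J_K` monotone
nondecreasing in `K`, which the tests exploit. Work grows as `(2|S|)^K`;
`K = 5` is the default for 8-state problems and a node budget refuses
configurations that would silently explode (which is also why the 32-state
cell-cycle study reports only the suboptimal policies). The production
implementation updates one mutable `α` in place along the recursion with
cached row sums; its only correctness reference is a literal, naive
transcription of the recursion kept in the test suite, which must agree to
1e-12.

MCR restricts attention to policies each optimal for some sampled member
of the uncertainty class and picks the best prior-average performer
(deduplicated candidates, lexicographic tie-break). GR solves the nominal
problem for the prior mean; AGR re-solves it for the posterior mean after
every observed transition. Rollouts accumulate `λ^k`-discounted
destination costs for a fixed number of epochs; the truncated tail is
bounded by `λ^epochs · g_max/(1-λ)` (≈ 3e-5 at 7 epochs), far below
Monte-Carlo error. Ties between actions always prefer no intervention,
making every policy a deterministic function of its inputs.

## Sampling

Dirichlet rows are sampled through log-space gamma variates
(`log G_a = log G_{a+1} + log(U)/a` per entry, normalised by softmax).
Direct gamma sampling underflows to exact zeros for the very small
concentrations that tight priors produce (`κ = 0.1` spreads total mass 0.1
over a 32-entry row), which can void whole rows; the log-space route is
exact for all shapes. Every experiment derives its streams from a single
master seed through `SeedSequence` spawning, so sweeps are pure functions
of their configuration.

## Synthetic network generator

Random PBNs follow the published study conditions: `m = 3` equally likely
contexts, at most 2 predictors per gene, truth-table bias drawn from a
Beta distribution with mean 0.5 and sd 0.01 (shape parameters computed
from the moments, a = b = 1249.5), perturbation `p = 0.001`, control gene
= least significant bit, target gene = most significant bit, undesirable =
target gene down. Two choices the study conditions leave open are fixed as
follows: each gene's in-degree is drawn uniformly from {1, …,
max_predictors} with the predictor set uniform without replacement
(self-inputs allowed) — the simplest distribution consistent with the
stated cap — and one bias value is drawn per context (a per-gene option
exists). With sd 0.01 the bias is effectively 0.5 always, so the
granularity choice has no practical effect.

What the generator emulates is the benchmark ensemble, not biology: real
regulatory networks have heavier-tailed in-degrees, canalising functions,
and strongly non-uniform wiring. Passing ensemble-level checks therefore
validates the estimators and the dynamic programming, not any biological
claim.

## Cell-cycle fixture

The 5-gene reduced mutated mammalian cell-cycle network (CycD, Rb, CycA,
UbcH10, CycB; p27 permanently off) is built from its printed Boolean
rules with two equally likely contexts given by the extracellular growth
signal, perturbation 0.01, CycA control, and undesirable states those with
CycD and Rb both down. Two reconstruction choices were fixed empirically
against the published optimal-cost benchmark (0.9685, reproduced here to
4 decimals at 0.968542):

* Within a context, the signal value is substituted into the *inputs* of
  the rules, not just into CycD's next value. Only Rb reads CycD, so the
  signal-ON context has Rb ≡ 0 and the signal-OFF context has
  Rb = Rb ∧ ¬CycA ∧ ¬CycB. Treating CycD as an ordinary stored bit that
  rules read back yields 1.0955 instead — incompatible with the benchmark
  under every perturbation and cost convention we enumerated (including
  all 2^16 × 3 negation/associativity variants of the printed rules).
* The CycA rule's ambiguously bracketed second disjunct is read as the
  three-literal conjunction ¬Rb ∧ ¬UbcH10 ∧ ¬CycB ("conjunction" parse,
  0.968542). The "grouped" parse ¬Rb ∧ (¬UbcH10 ∨ ¬CycB) lands within
  rounding of the same benchmark (0.968564) and is retained as an option;
  standard precedence (0.971236) is excluded.

## Monte-Carlo sizes and tolerances

The original studies used 500 networks × 500 sampled TPMs × 100 paths
(3-gene), 500 × 5,000 × 1,000 (4-gene), and 10,000 × 10,000 (cell cycle).
The packaged acceptance runs are scaled down: 3,000 sampled TPMs for the
cell-cycle GR estimate, 600 × 25 ten-epoch rollouts for AGR, 800–1,200
networks × 100–150 samples for the 3-gene ensemble, and 300–500 networks ×
200 samples for the 4-gene ensemble. Per-network costs are strongly
bimodal (networks are either controllable toward the desirable half or
not), with standard deviation ≈ 0.5 across networks; ensemble means
therefore carry standard errors of 0.01–0.03 at these sizes, and the
published per-row values themselves scatter by 0.02–0.05 between
regenerated ensembles (visible in the published tables, where a
κ-independent column varies across κ rows). Comparisons against published
ensemble means use ±0.05 windows sized from that scatter.

Numerical settings: value iteration stops when the sup-norm residual is
below `tol (1-λ)/(2λ)` with `tol = 1e-10` (≈ 15 iterations at λ = 0.2);
policy evaluation uses the exact linear solve, which cannot be singular
for λ < 1; batched rollouts warm-start each epoch's value iteration from
the previous epoch's values (affects iteration count only, not the fixed
point).

## Known limitations

* Context-sensitive dynamics (switching probability < 1), asynchronous
  updates, multi-valued nodes, and multi-gene or constrained action sets
  are out of scope.
* The OBR tree is exponential in `K`; no hash-table, branch-and-bound, or
  reinforcement-learning approximation is provided.
* The Dirichlet row-independence assumption is structural: dependent-row
  or hierarchical priors are not supported.
* One published cell-cycle table row (the tight uncontaminated prior,
  κ = 0.1, ε = 0) is internally inconsistent with its own column
  structure (it duplicates another row exactly, and its lower-bound entry
  breaks the column's monotonicity in κ); our estimates for that setting
  disagree with the printed row by ≈ 0.03 while matching the neighbouring
  rows, and the corresponding acceptance test records that disagreement
  rather than adjusting to it.
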