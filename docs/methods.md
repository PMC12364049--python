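# Methods

## The selection model

Given an expression matrix `X` (p cells × n genes) and a continuous
per-cell target `T` (e.g. pseudotime), gene selection is cast as a
quadratic unconstrained binary optimization (QUBO) over selection masks
`x ∈ {0,1}ⁿ`:

    E(x) = −α Σᵢ Iᵢ xᵢ + (1−α) Σ_{i≠j} R_ij xᵢ xⱼ  =  xᵀ Q x

* `Iᵢ` — **importance**: mutual information between gene *i* and the
  target, both discretized by quantile binning.
* `R_ij` — **redundancy**: mutual information between genes *i* and
  *j*; the diagonal is structurally zero (a gene is never redundant
  with itself).
* `α ∈ [0,1]` — balance between rewarding importance and penalizing
  redundancy.

`Q` is stored upper-triangular with diagonal `−α Iᵢ` and upper
off-diagonal `(1−α)(R_ij + R_ji)`; folding both ordered pairs into one
entry is what makes `xᵀQx` equal the double sum, and is the single
place a factor-2 discrepancy with other QUBO conventions can originate.

## Mutual-information estimation

Each feature and the target are discretized into `B` quantile bins
(default `B = 10`). Bins are half-open `(q_{L−1}, q_L]` with the lowest
bin closed on the left; duplicate quantile edges (mass points, common in
sparse expression data) are collapsed so labels stay contiguous. MI is
the plug-in estimate over the empirical joint table, in nats, with the
convention `0·log 0 = 0`. Cell contributions are summed in sorted
order, which makes `MI(a,b)` and `MI(b,a)` bit-identical.

The log base is a global scale on both `I` and `R`, so it cannot change
the argmin of `E(x)` at fixed α; nats are reported throughout.

The plug-in estimator has a positive bias of roughly `(B−1)²/(2p)` nats
under independence (≈ 0.004 at `B = 10`, `p = 10⁴`); this floor is what
"near-zero" means for redundancy between unrelated genes.

`B = 10` was checked against the benchmark's hardest sub-task,
distinguishing a feature from a 0.995-correlated near-duplicate:
per-pair mis-ranking rates were ≈15% at `B = 5`, ≈6% at `B = 10–15`,
≈8% at `B = 20`, so deciles sit at the flat optimum.

## Choosing α

The two terms of `E(x)` live on different natural scales. Adding one
gene to a k-gene selection pays up to `(k−1)` pairwise redundancy
terms, each at least the estimator's bias floor δ, so a genuinely
informative gene with importance `I` survives only if
`α·I > (1−α)·(k−1)·δ̄`. Conversely a near-duplicate of an already
selected gene must stay excluded, which needs
`(1−α)·R_dup > α·I_dup`. Because duplicate redundancy (≈ the feature
entropy, order `log B` ≈ 2.3 nats) is two orders of magnitude above the
background level (≈ 0.01 nats), these constraints leave a wide feasible
window — empirically α ∈ [0.7, 0.95] on the synthetic benchmark — and
the package defaults to **α = 0.8**. At α = 0.5 the background
redundancy of a 5-gene selection (≈ 0.04 nats) already exceeds the
weakest real signals (≈ 0.03 nats), and even exact enumeration of all
C(50,5) subsets drops true sources; this was verified directly and is
why the default is importance-leaning. `alpha_sweep` exposes the
trade-off for new data.

## Cardinality

Two mechanisms select exactly `k` genes:

* **rank** (default): solve the unconstrained QUBO, then order features
  by greedy energy contribution — repeatedly add the feature whose
  inclusion lowers the energy most, exhausting the solver's mask before
  considering the rest — and take the first `k`. The per-feature deltas
  sum exactly to the mask energy, and the ordering is computed to full
  depth `n` so rankings beyond `k` (top-20 landscapes, top-500 energy
  paths) are always available. The unconstrained minimizer can hold
  fewer than `k` bits (it stops where marginal importance no longer
  beats accumulated redundancy), which is why the ranking must extend
  past it.
* **penalty**: add `M(Σxᵢ − k)²` in QUBO form (diagonal `+M(1−2k)`,
  upper off-diagonal `+2M`; the constant `−Mk²` is dropped, offsetting
  reported energies but not minimizers). Default
  `M = 2·n·max|Q|`, a sufficient scale in practice; the k-hot
  constraint is verified exactly by enumeration in the tests.

The mechanism used is recorded in every result's metadata.

## Solvers

All backends implement one interface (`solve(Q, seed, **params) →
SolverResult`), so a hardware annealer adapter would be a drop-in; only
classical backends ship.

* **exhaustive** — enumerates all 2ⁿ masks (guard: n ≤ 25),
  lexicographically smallest mask among ties. Serves as the ground
  truth oracle in tests.
* **sa** — single-flip Metropolis, geometric inverse-temperature
  schedule, default 1000 sweeps × 10 restarts, vectorized across
  restarts. The schedule endpoints default to an auto-scaled range
  derived from single-flip delta bounds (hot end accepts the worst
  uphill flip with probability ½, cold end rejects the smallest
  meaningful flip at 99%): MI-scale QUBOs have couplings of order 10⁻²
  nats, for which any fixed O(1) schedule is effectively always hot.
* **tabu** — steepest-descent single-flip search with a recency tabu
  list (tenure `max(7, n/10)`), aspiration on the incumbent, and random
  restarts (default 500 iterations × 10 restarts). This is the default
  backend.

All solvers are deterministic given their seed, and return the empty
mask whenever their best state has positive energy (selecting nothing
is always admissible).

No spin (±1) representation is implemented; for interoperability the
standard change of variables is `x_i = (1 + σ_i)/2`, which maps
`xᵀQx` to an Ising Hamiltonian with couplings `J_ij = Q_ij/4`, fields
`h_i = Q_ii/2 + Σ_j Q_ij/4`, and an additive constant. On 200 random 12-variable instances both
heuristics reach the exhaustive optimum in ≥ 95% of cases at default
budgets; on the benchmark QUBO they agree with each other to solver
tolerance.

## The synthetic benchmark

`make_benchmark` draws `p = 10,000` observations of `n = 50` features
from MVN(0, R) where R is the correlation matrix of a random Gram
matrix `BᵀB` (off-diagonals typically |r| ≈ 0.14 with occasional larger
values). Five *source* columns `s = [5, 11, 7, 1, 14]` drive the
target; five *decoy* columns `t = [16..20]` are overwritten with
`source + 0.1·ε` (population correlation 1/√1.01 ≈ 0.995). The target
is min-max normalized to [0,1] and X is z-scored.

The default target function is

    y = 0.5·cos(7)·X_s4 + sin(X_s3)·X_s2 + 0.1·exp(X_s5)·log2(10·|X_s1|) + 0.1·ε′

It mixes a linear term (s4), a product interaction (s3·s2 — neither
factor has a linear marginal), an exponential (s5) and an even,
heavy-tailed log factor (s1), so the five sources span strong-linear to
weak-nonlinear marginal signals; their binned-MI importances order
14/1 > 11 > 7 > 5, with the weakest source still above the background
floor. Two alternates are registered (`TARGET_FUNCTIONS`): an
oscillatory `cos(7·X_s4)` reading and a flat `log2(10+|X_s1|)` reading,
each of which leaves one source with almost no marginal signal of any
kind — useful for sensitivity analysis, not for recovery benchmarks.
The target-noise scale (0.1, matching ρ) and the target function are
both configurable.

What the generator does **not** emulate: count noise, dropout,
overdispersion, batch effects, or any mean–variance relation of real
scRNA-seq — its features are exactly Gaussian. Passing recovery tests
therefore demonstrates the selector's behaviour under controlled
nonlinearity and planted redundancy, not robustness to single-cell
technical noise (the preprocessing module addresses the count side
separately).

### Recovery is intrinsically stochastic at this design

A source and its decoy differ in binned MI by only 0.0015–0.0022 nats
at `p = 10⁴`, while the estimator's sampling sd is ≈ 0.001, so each of
the five pairs mis-ranks with probability 3–7.5% per draw. Across 20
generator seeds the default pipeline recovers 5/5 sources in ≈ 45% of
draws and 4/5 in ≈ 50% (the misses being decoy substitutions —
features correlated 0.995 with a true source). A single run reporting
perfect recovery is therefore an entirely plausible draw, but perfect
recovery is *not* the majority outcome under repeated sampling at these
exact design parameters; the benchmark harness reports replicate-level
raw accuracies for this reason.

## Stability analysis

`kfold_stability` partitions cells by a seeded shuffle + round-robin;
each fold's *local* cost function Q′ is built from the fold's training
complement (the usual (k−1)/k share — the natural reading of running
the selection "on a subset of the data"), solved, and the fold's top-k
is scored two ways: its energy under Q′ and under the global Q, plus
**fold accuracy** = overlap of the fold's top-k with the full-data
top-k as a fraction of k. Accuracy compares masks, not energies; this
definition is stated prominently because other readings (energy ratios,
rank correlations) are possible. Folds too small for the bin count are
binned coarser with a warning.

`compare_energy_paths` evaluates each method's feature ordering under
the *same* Q, as cumulative prefix energies; `landscape_enumeration`
evaluates every C(|candidates|, m) combination (guard: 10⁶).

## Preprocessing

Raw genes × cells counts pass a QC filter: cells first (library size ≥
1000, mitochondrial count fraction ≤ 15%, detected genes ≥ 500 —
minimums inclusive; mito genes matched by name prefix, default
`MT-`/`mt-`), then genes nonzero in < 15 of the *surviving* cells.
Cells-first ordering is fixed because gene detection counts depend on
which cells remain; a removed cell is attributed to the first criterion
it fails, so report counts are conserved. The filter is idempotent in
practice, with the documented caveat that removing rare genes could in
principle drag a borderline cell below the detected-genes threshold on
a second pass.

Filtered counts are transformed to analytic Pearson residuals
`(x − μ)/√(μ + μ²/θ)` with `μ` the outer product of margins over the
grand total, `θ = 100` (the `θ → ∞` limit is the classical Poisson
residual), clipped to ±√(n_cells). Embedding and pseudotime inference
are out of scope: the pipeline takes the per-cell target variable as an
input.

## Numerical choices and problem sizes

* Energies are exact quadratic forms; tests require agreement with the
  explicit double sum to 1e-10.
* Ties: exhaustive search and solver restarts break energy ties toward
  the lexicographically smallest mask; greedy ranking breaks delta ties
  toward the lowest feature index.
* Seeds: every stochastic routine takes one integer seed; derived seeds
  are reduced mod 2³¹−1.
* Indices: all public inputs/outputs are 1-based (matching gene-list
  conventions and the coordinate file format); masks are positional.
* Test problem sizes: unit tests run a 2,000-observation benchmark;
  end-to-end checks run the full 10,000 × 50 design, 20 replicates for
  the method comparison, and 200 random 12-variable instances for the
  solver-oracle study — sizes chosen so the full suite completes in
  minutes on one core.

## Known limitations

* The plug-in MI estimator is biased upward at small fold/bin ratios;
  fold-level analyses at a few hundred cells should reduce `B`.
* The redundancy matrix is built pairwise (O(n² p) time, O(n²) memory);
  n in the low thousands is the practical ceiling, matching the usual
  post-HVG gene counts.
* `α` is a genuine free parameter: the default suits MI-scale inputs,
  but data with much larger importance spread may warrant a sweep.
* Heuristic solvers carry no optimality certificate; for `n ≤ 25` the
  exhaustive backend provides one.
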