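# qubofs — QUBO feature selection for single-cell regression

`qubofs` selects genes whose expression jointly predicts a continuous
cell-state variable (pseudotime, treatment time, differentiation score)
from a cells × genes expression matrix. It is aimed at single-cell
analysts who want a small, interpretable, non-redundant gene panel for
a regression target — the setting where purely linear selectors (lasso)
miss nonlinear drivers and importance-only rankings return blocks of
co-regulated, mutually redundant genes.

## The model

Selection is cast as quadratic unconstrained binary optimization
(QUBO). With importance `I_i = MI(x_i; T)` (mutual information between
binned gene *i* and the binned target) and redundancy
`R_ij = MI(x_i; x_j)`, the selected mask `x ∈ {0,1}ⁿ` minimizes

```
E(x) = −α Σ_i I_i x_i + (1−α) Σ_{i≠j} R_ij x_i x_j = xᵀ Q x
```

`Q` is upper-triangular (diagonal `−α I_i`, upper couplings
`(1−α)(R_ij+R_ji)`); `α ∈ [0,1]` balances rewarding informative genes
against penalizing redundant pairs (default 0.8). The QUBO is minimized
by classical heuristics — iterated tabu search (default), simulated
annealing, or exact enumeration for small `n` — behind one backend
interface that a quantum-annealer adapter could also implement.
Features are then ranked by greedy energy contribution and the top *k*
reported. See `docs/methods.md` for estimation details, the α scale
analysis, and limitations.

## Worked example

`examples/01_select_features_synthetic.py` generates the built-in
synthetic benchmark — 10,000 observations of 50 correlated Gaussian
features, five of which (`[5, 11, 7, 1, 14]`) drive a highly nonlinear
target while five decoys (`[16..20]`) are 0.995-correlated near-copies
of the sources — and runs the full pipeline:

```
planted sources : [1, 5, 7, 11, 14]
selected top-5  : [1, 5, 7, 11, 14]
solver energy   : -0.2481 nats
recovery        : 100.0 %

contribution ranking (first 8):
  feature   1  delta -0.0936  (source)
  feature  14  delta -0.0766  (source)
  feature  11  delta -0.0557  (source)
  feature   7  delta -0.0195  (source)
  feature   5  delta -0.0027  (source)
  feature  28  delta +0.0076  (background)
```

Each delta is the energy change when that feature joins the selection:
the five planted sources all lower the energy (importance beyond the
redundancy they bring), the first background feature would raise it,
and none of the near-duplicate decoys appears — the redundancy term
blocks a decoy as soon as its source is selected. Recovery is the
percentage of the planted truth found in the top-5; because a source
and its decoy differ in estimated MI by only ~0.002 nats at this sample
size, individual draws occasionally swap one pair (see the methods
note).

Other examples cover QUBO anatomy and the α trade-off (`02`), the
method comparison harness (`03`), 10-fold stability and the
1,140-combination energy landscape (`04`), and count-matrix QC +
Pearson-residual preprocessing (`05`).

A thin CLI mirrors the library (`qubofs generate | select | solve |
preprocess | benchmark | stability`); every subcommand is a direct
wrapper of the corresponding function and reproduces library results
bit-for-bit at equal seeds.

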