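# trifuse

Sparse low-rank **collective matrix tri-factorization** for link prediction on
heterogeneous multi-type networks.

Given relation blocks `R_ij` between typed entity sets (plus optional
intra-type constraint matrices `Θ_i`), trifuse factorizes every block as
`G_i S_ij G_j^T` with shared nonnegative per-type factors `G_i`, a weighted
data-fit objective, and an element-level cardinality penalty expressed as a
difference of convex functions (`e^T G e − s^(k)(vec(G))`). The nonconvex
problem is solved by an accelerated proximal DC loop: Nesterov-style
extrapolation, secant (quasi-Newton) step constants, a non-monotone Armijo
line search against a decaying envelope, and a fallback anchored line search
with best-of-two selection. The reconstruction of a designated target block
ranks unobserved associations (e.g., protein–splicing-event links).

## Layout

| module | contents |
|---|---|
| `trifuse.network` | typed network model, YAML/TSV/Matrix-Market loader, validation |
| `trifuse.sparsity` | top-k sums, largest-k norm, subgradients, nonneg prox |
| `trifuse.objective` | smooth loss, DC penalty, closed-form gradients |
| `trifuse.optimizer` | the accelerated proximal DC solver and its bookkeeping |
| `trifuse.synthetic` | seeded planted-structure network generator (6 types, 7 relations, 2 constraints) |
| `trifuse.evaluation` | score reconstruction, k-fold CV, AUC/AUPR, ranked predictions |
| `trifuse.cli` | `trifuse simulate | fit | cv | predict` |

## CLI quick start

```bash
# write a seeded planted network (relations as TSV edge lists, constraints as .mtx)
trifuse simulate --outdir sim --seed 7

# fit the factor model and store factors + convergence trace
trifuse fit --config sim/network.yaml --outdir run --seed 7

# rank unobserved target-block pairs (optionally one source entity)
trifuse predict --config sim/network.yaml --fit-dir run --top-n 100
trifuse predict --config sim/network.yaml --fit-dir run --row rbp0 --top-n 10

# 5-fold cross-validation on the target block, with optional grid sweeps
trifuse cv --config sim/network.yaml --outdir cv --folds 5 --seed 7 \
    --grid "lambda=1,0.01" --grid "lambdaG=1,0.01"
```

Network configs are YAML (`types`, `relations`, optional `constraints`,
`target`); relation files are 2/3-column TSV edge lists keyed by string
entity IDs or Matrix Market files.

## Hyperparameters

`lam` (intra-relation regularization), `lambda_g` (sparsity penalty), `k`
(nonzero budget per factor matrix), plus solver controls (`delta`, `tau`,
`eta`, step bounds, `max_iter`, `tol`, `seed`). `init` selects the factor
initialization (`svd` default, `random`); `reweight` toggles the
per-iteration residual-based source reweighting; `--project-k` hard-zeroes
all but the top-k entries of each factor after fitting.

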