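# atvnetnmf

Joint non-negative matrix tri-factorization of paired omics co-expression
networks, with graph-Laplacian and adaptive total-variation (ATV)
regularization, for detecting co-expression modules that are coherent across
two molecular layers (for example DNA methylation and gene expression
measured on the same samples).

## The problem

Two omics layers profiled on the same cohort carry complementary views of
the same regulatory programs. Working on the correlation networks rather
than the raw matrices, the method takes three non-negative networks — the
within-layer co-expression networks `R11` (n1 × n1) and `R22` (n2 × n2),
and the cross-layer network `R12` (n1 × n2), built here from absolute
Pearson correlations — and factorizes them jointly:

```
min  ‖R11 − G1 S11 G1ᵀ‖²F + α‖R12 − G1 G2ᵀ‖²F + β‖R22 − G2 S22 G2ᵀ‖²F
         + Σᵢ [ λᵢ tr(Giᵀ Li Gi) + 2‖Gi‖_ATV ]
s.t. G1, G2, S11, S22 ≥ 0
```

`G1` (n1 × k) and `G2` (n2 × k) hold per-feature loadings on k shared
components; `S11`, `S22` capture component–component interactions; α = n1/n2
and β = (n1/n2)² balance the three residuals by default. `Li` is the
unnormalized Laplacian of a k-nearest-neighbor graph over each layer's
similarity matrix, and the graph terms reward loadings that vary smoothly
over that graph. The ATV term

```
‖G‖_ATV = Σᵢⱼ (1/pᵢⱼ) |∇G|ᵢⱼ^pᵢⱼ,     p = 1 + 1/(1 + |∇G|²) ∈ (1, 2]
```

denoises the factor matrices with an exponent that adapts to the local
gradient: quadratic smoothing in flat regions (p = 2), TV-like edge
preservation where loadings change sharply (p → 1). The problem is solved
by multiplicative updates that keep every factor non-negative; signed
contributions (the Laplacian and the TV divergence) are split by sign
between numerator and denominator, preserving fixed points.

Switching the two regularizers off individually yields the ablated
variants: plain `netnmf` (no graph, no TV), `nmfna` (graph only) and
`netnmf-atv` (TV only).

Modules are read off the factors by z-scoring each column of `Gi` and
keeping features with z ≥ 2; the largest module is the *core module*. The
regularization weight λ is chosen on a 0–0.1 grid by maximizing the
cross-layer module similarity `msim = Σₓ,ᵧ |Mx ∩ My| / min(|Mx|, |My|)`.

## Worked example

The built-in generator plants k partially overlapping co-expression modules
in two simulated layers, providing ground truth:

```python
from atvnetnmf import ATVNetNMF, generate_planted_multiomics, score_recovery
from atvnetnmf.networks import build_network_triple
from atvnetnmf.modules import extract_modules, zscore_columns

X1, X2, truth = generate_planted_multiomics(seed=7)   # 200 + 300 features, 60 samples
nets = build_network_triple(X1, X2)                    # |Pearson| networks
model = ATVNetNMF(n_components=4, lambda1=0.08, lambda2=0.08,
                  random_state=0).fit(nets)

print("objective:", f"{model.initial_objective_:.1f} -> {model.objective_trace_[-1]:.1f}")
print("reconstruction:", {k: round(v, 3)
                          for k, v in model.reconstruction_correlations(nets).items()})

mods1 = extract_modules(zscore_columns(model.G1_), nets.ids1, threshold=2.0)
print("layer-1 module sizes:", mods1.sizes(), "core:", mods1.core_index)
print("layer-1 recovery:", round(score_recovery(truth, mods1, 1, nets.ids1), 3))
```

prints

```
objective: 101435.7 -> 1069.8
reconstruction: {'R11': 0.935, 'R12': 0.959, 'R22': 0.944}
layer-1 module sizes: [25, 25, 25, 25] core: 0
layer-1 recovery: 1.0
```

The objective drops by over 99% across the 200 multiplicative sweeps; the
reconstructed networks correlate with the inputs at r ≈ 0.94–0.96; and the
four z-score modules recover the planted 25-feature modules exactly
(best-match Jaccard 1.0).

The same pipeline is available from the shell:

```
atvnetnmf simulate --n1 200 --n2 300 --samples 60 --k 4 --seed 7 --out sim/
atvnetnmf build-networks --layer1 sim/layer1.tsv --layer2 sim/layer2.tsv --out nets/
atvnetnmf factorize --networks nets/ --k 4 --variant atv-netnmf --seed 0 --out fac/
atvnetnmf modules --factors fac/ --threshold 2 --out mods/
atvnetnmf select-lambda --networks nets/ --grid 0:0.1:0.01 --k 4 --out lam/
atvnetnmf compare-variants --networks nets/ --seeds 0,1,2 --k 4 --out cmp/
```

Real data enter as delimited text (feature IDs in the first column, sample
IDs in the header); `build-networks --mean-filter 0.25` applies the usual
low-signal feature filter before the networks are built.

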