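# Methods

## Model

Given two non-negative feature-by-sample matrices over the same samples,
the package works on three derived networks: `R11` and `R22`, the absolute
Pearson correlation matrices within each layer, and `R12`, the absolute
correlations between layer-1 and layer-2 features. Absolute correlation is
used (rather than raw r) because the factorization requires non-negative
inputs and anticorrelation is biologically as informative as correlation; a
`signed="positive"` switch substitutes max(r, 0) for users who want signed
co-expression only. Diagonals of `R11`/`R22` are set to 1. Samples are
matched by identifier, never by position; a mismatch is an error rather
than a silent intersection, and zero-variance features are a hard error so
that preprocessing stays explicit. The customary low-signal filter
(dropping features with row mean below a threshold, 0.25 for methylation
beta-values) is available per layer.

The factorization approximates `R11 ≈ G1 S11 G1ᵀ`, `R12 ≈ G1 G2ᵀ`,
`R22 ≈ G2 S22 G2ᵀ` with all factors non-negative, minimizing the weighted
Frobenius residuals plus two optional regularizers per layer:

* **Graph smoothness** `λᵢ tr(Giᵀ Li Gi)`, with `Li` the unnormalized
  Laplacian `D − W` of the symmetrized binary k-nearest-neighbor graph of
  the layer's similarity matrix (default 5 neighbors, ties broken by
  index). The quadratic form penalizes loadings that differ across strongly
  similar feature pairs.
* **Adaptive total variation** `2‖Gi‖_ATV` with
  `‖G‖_ATV = Σ (1/p)|∇G|^p` and `p = 1 + 1/(1+|∇G|²)`. Gradients are
  periodic forward differences over the n × k factor treated as an image;
  the divergence used in the updates is the exact discrete negative adjoint
  of that gradient (backward differences with wrap), so the adjoint
  identity `⟨∇G, P⟩ = −⟨G, div P⟩` holds to rounding error. The row order
  of a factor matrix is arbitrary, so the "image" interpretation is a
  heuristic smoothing over the given ordering; this is inherent to the
  formulation and documented rather than repaired.

α and β default to n1/n2 and (n1/n2)², which equalizes the per-entry weight
of the three residual blocks (they contain n1², n1·n2 and n2² entries).

## Optimization

Multiplicative updates sweep S11, S22, G1, G2 in that order, each using the
freshest factors. Every update multiplies the factor elementwise by a
ratio of non-negative terms. Two contributions are signed and are split
elementwise by sign — the positive part joins the numerator, the magnitude
of the negative part the denominator — which preserves fixed points and
non-negativity:

* the TV diffusion term `div(∇G / |∇G|_ε^(2−p))`, and
* the Laplacian term, split structurally as `λWG` (numerator) and `λDG`
  (denominator).

Numerical choices: the gradient magnitude is smoothed as
`|∇G|_ε = sqrt(∇x² + ∇y² + ε²)` with ε = 1e-8 to guard the division in the
diffusion coefficient; the exponent map p is computed from the raw
magnitude so p = 2 exactly at zero gradient, and is refreshed from the
current factor at every sweep; all denominators are floored at 1e-12;
initialization draws G1, G2 i.i.d. uniform(0,1) and sets S11, S22 = AᵀA/k
for uniform A, so the S factors start symmetric — symmetry is then
preserved by the updates because R11/R22 are symmetric. Runs are
reproducible given `random_state`.

The default stopping rule is a fixed 200 sweeps; an optional relative
objective-change tolerance stops earlier. The plain-netNMF updates
(regularizers off) are monotone in practice and the test suite asserts a
non-increasing objective trace on random instances; the TV-modified update
is not provably monotone, so for the full model the suite asserts endpoint
improvement instead. Stationarity is assessed by the complementary-
slackness residual `max_F ‖min(F, ∂f/∂F)‖∞` over the four factors, with
analytic gradients validated against central differences (the TV gradient
under the convention that p is frozen at the evaluation point, matching
the update rules; the fully adaptive energy's dp/dG terms are deliberately
not part of the gradient).

## Module extraction and λ selection

Each factor column is z-scored with the (n−1)-denominator standard
deviation; constant columns map to zero (an empty module) rather than
erroring. Features with z ≥ 2 (signed; `abs_z` optional) form the column's
module, features may belong to several modules, and the largest module is
the core module (ties to the smallest index). Module similarity between
two module sets is the literal double sum `Σₓᵧ |Mx∩My|/min(|Mx|,|My|)`
over non-empty pairs. λ is selected on the grid 0–0.1 in steps of 0.01 by
factorizing at each λ (λ1 = λ2 = λ, fixed seed), extracting modules from G1
and G2, and maximizing the cross-layer msim computed over shared feature
identifiers; ties break toward the smallest λ. An alternative reading —
module stability across λ values instead of cross-layer agreement at each
λ — exists; the cross-layer form is implemented because it is the one the
selection curve supports directly.

## Synthetic benchmark

`generate_planted_multiomics` defines the package's study conditions:
defaults n1 = 200, n2 = 300 features, 60 samples, k_true = 4 modules,
signal strength 1.0, noise sd 0.3, shared fraction 0.5. Each module is
driven by a standard-normal latent sample profile; module features are
signal × profile + Gaussian noise, background features pure noise, and
every feature row is shifted by its minimum plus 0.1 (not clipped) so
correlations are untouched. Half of each layer's features carry signal
(module size = n/(2·k_true), minimum 5). Cross-layer coupling enters twice:
the layers share latent profiles (structure in R12) and a `shared_fraction`
of module features share identifiers across layers (signal in msim). These
sizes keep a full 10-seed recovery experiment under a minute on one CPU.

What the generator does *not* emulate: methylation beta-value marginals,
heavy-tailed expression distributions, batch effects, missing values, or
realistic background correlation structure (background features are
independent noise, so background |r| ≈ 0.1 at 60 samples). Passing tests
therefore demonstrate correctness of the algorithmic machinery and
recoverability of clean planted structure, not performance on real
cohorts.

On this generator the regularized variants reconstruct the (noisy) input
networks marginally *worse* than plain netNMF — the expected direction,
since plain netNMF optimizes exactly that residual while the regularizers
trade fit for smoothness; the differences are in the third decimal place.
Reported variant comparisons should be read with that in mind: the
regularizers are motivated by module quality and noise tolerance on real
data, not by reconstruction correlation on clean simulations.

## Limitations

* k must be chosen by the user (the one-tenth-of-min-dimension rule of
  thumb is documented, not enforced); no consensus clustering or automatic
  rank selection.
* The TV term's image interpretation depends on feature ordering (see
  above).
* Multiplicative updates find local minima; different seeds can yield
  different module decompositions. Determinism per seed is guaranteed,
  global optimality is not.
* Dense matrices throughout; intended for desk-scale networks (up to a few
  thousand features per layer).
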