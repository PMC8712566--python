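# Methods

## Problem and model

`eegfuse` implements decision-level fusion of binary classifiers with fuzzy
integrals, together with the EEG network-feature pipeline such fusion is
typically applied to: distinguishing two groups of subjects (e.g. patients
vs controls) from global graph descriptors of resting-state functional
connectivity.

### Sugeno λ-fuzzy measure

The ensemble `X = {x_1, …, x_n}` of base classifiers carries a capacity
(fuzzy measure) `g` with `g(∅) = 0`, `g(X) = 1`, monotone under inclusion.
The Sugeno λ-measure restricts `g` to the one-parameter family

    g(U ∪ W) = g(U) + g(W) + λ g(U) g(W)      (U ∩ W = ∅, λ > −1)

so the measure is determined by the singleton densities `g_i = g({x_i})` —
here each classifier's mean stratified 5-fold cross-validated accuracy on
the training split — and by normalization, which fixes λ as the unique
nonzero root of `1 + λ = ∏_i (1 + λ g_i)` (λ = 0 exactly when Σ g_i = 1;
Σ g_i < 1 ⇔ λ > 0; Σ g_i > 1 ⇔ λ ∈ (−1, 0)).

**Numerics.** We root-find on the *chain gap* `q(λ) = (∏(1+λg_i) − 1)/λ − 1`
rather than on `∏(1+λg_i) − (1+λ)` directly: the raw form has a trivial root
at λ = 0, so its residual is uninformative when Σ g_i ≈ 1 and the true root
sits near zero, whereas `q` equals exactly the terminal error of the
cumulative chain `g(U_n) − 1`. Brent's method on a sign-changing bracket
((−1, 0) or (0, ∞) by the sign law) with `xtol = 1e−15` keeps the terminal
value of every chain within 1e−9 of 1 and the normalization residual below
1e−10. Densities of exactly 0 are floored at 1e−6 (a never-correct
classifier would otherwise degenerate the chain), densities of 1 are pulled
to 1 − 1e−6 so that ensembles of several perfect classifiers stay solvable.

The chain for a score ordering is the recursion
`g(U_{i+1}) = g(U_i) + g_{i+1} + λ g_{i+1} g(U_i)`, the form consistent
with the defining identity on disjoint sets.

### Choquet integral and its generalizations

For scores `h(x_i) ∈ [0, 1]` sorted non-increasingly, `h_(n+1) = 0`, and the
chain `G_i = g(U_i)` aligned to that ordering:

    C       = Σ (h_(i) − h_(i+1)) · G_i
    C_M     = Σ M(h_(i) − h_(i+1), G_i)
    C_FM    = min(C_M, 1)
    C_CM    = Σ [M(h_(i), G_i) − M(h_(i+1), G_i)]
    C_MC    = Σ [M(h_(i), G_i) − M(h_(i+1), G_i) + M(h_(i) − h_(i+1), G_i)]
    C_MMin  = Σ M(min(h_(i), G_i) − min(h_(i+1), G_i), G_i)
    C_MMin2 = Σ M(min(h_(i), G_i), min(h_(i+1), G_i))
    C_MinM  = Σ min(M(h_(i), G_i), M(h_(i+1), G_i))
    C_D1    = Σ M(h_(i−1) − h_(i+1), G_i)
    C_D2    = Σ M(h_(i−1) + h_(i+1) − h_(i), G_i)
    C_D3    = Σ M((h_(i−1) + h_(i+1)) / h_(i), G_i)

with `M` any registered t-norm. `C_M` with the product recovers the classic
integral exactly. Design choices where the definitions are open:

* **Boundary score h_(0)** (first term of the D-variants): 1.0 by default —
  scores are probabilities bounded by 1 and the sorted sequence is
  non-increasing, so 1 is the natural upper boundary; `h_(0) = h_(1)` is
  available as an option.
* **Integrand clipping:** the D-variants (and nothing else) can produce
  arguments outside [0, 1]; they are clipped into [0, 1] before `M` is
  applied, the minimal extension that keeps the t-norm's domain.
* **C_D3 at h_(i) = 0:** the term is skipped (all later sorted scores are
  zero as well, so the tail contributes nothing in the limit).
* **C_D3 precedence:** the integrand is read as the ratio of the sum,
  `(h_(i−1) + h_(i+1)) / h_(i)`; the alternative reading
  `h_(i−1) + h_(i+1)/h_(i)` is selectable (`d3_ratio_of_sum=False`).

Only the classic integral is idempotent and bounded by `[min h, max h]`;
the pre-aggregation variants deliberately weaken those axioms, and the test
suite asserts exactly the properties that do hold (oracle equivalence,
`C_FM ≤ 1`, `C_M`(product) ≡ `C`).

OWA uses linearly decaying weights `ω_j = 1 − (j−1)/n` on the sorted
inputs, normalized to sum 1 by default. Baselines: min, max, median, mean,
majority vote (strict majority of scores thresholded at 0.5; exact ties
return 0.5).

### T-norm registry

Families are selectable by name or numeric id. Two parametric rational/
power families are registered under the ids 8 and 12 used in the fusion
literature this package reproduces:

* id 8: `M(x,y) = max(α²xy − (1−x)(1−y), 0) / (α² − (α−1)²(1−x)(1−y))`,
  α > 0. When the clipped numerator is 0 the value is 0 without evaluating
  the quotient (the denominator may vanish there).
* id 12 (Yager): `M(x,y) = max(1 − ((1−x)^α + (1−y)^α)^{1/α}, 0)`, α > 0;
  α = 1 is the Łukasiewicz t-norm.

Also registered: product, minimum, Łukasiewicz, Hamacher (α ≥ 0), Frank
(α > 0, α = 1 the product limit), Dombi (α > 0), Schweizer–Sklar (all real
α, α = 0 the product limit), Aczél–Alsina (α > 0). Further numeric ids can
be attached with `register_family_id` when reproducing catalogues that
index t-norms by number; we deliberately do not guess the identity of
catalogue families whose formulas we have no source for. The α sweep used
in grid searches is the arithmetic grid −10, −9.9, …, 10 intersected with
each family's admissible range (100 values for an α > 0 family).

## Fusion experiment harness

Each repetition: stratified 80:20 holdout; per-classifier densities from
stratified 5-fold CV accuracy on the training part; classifiers refit on
the full training part; per-class test probabilities fused independently
per class channel (the Sugeno chain is rebuilt for each channel's score
ordering; λ is shared, as it depends only on the densities); predicted
class = argmax of the fused values, ties broken by larger mean raw score
then lower class index. Accuracy per grid cell is pooled over repetitions
(micro average over `n_repetitions × test size` predictions — exactly
1,600 at the default 200 repetitions with 40 balanced subjects); a per-run
macro average is reported alongside. Per-repetition seeds are derived from
one master seed, making the whole harness reproducible bit for bit.
Splitting and cross-validation are stratified throughout: with 20 subjects
per class, unstratified splits too often produce single-class folds.

The default roster is decision tree, kNN, quadratic/cubic/linear SVM
(Platt-calibrated), logistic regression, random forest, and MLP, behind a
uniform fit/predict-probability interface; any subset is selectable. An
alternative fusion mode (`positive_channel_only`) aggregates only the
positive-class channel and thresholds at 0.5.

## EEG network features

Per band (delta 0.5–4, theta 4–8, low alpha 8–10, high alpha 10–12, beta
13–30, gamma 30–45 Hz): zero-phase Hamming-window FIR band-pass
(`filtfilt`; transition width min(lo/2, (Nyquist−hi)/2, 2 Hz), filter
length capped by the epoch length), then time-domain pairwise linear
Granger causality `F_{y→x} = ln(σ²_restricted/σ²_full)` from nested OLS
autoregressions at the AIC-selected VAR order of the epoch (default cap 20
lags). Band-resolved spectral GC is thus approximated by time-domain GC on
band-filtered signals — a deliberate simplification relative to
autocovariance-based spectral GC toolchains; the directionality recovery
this pipeline needs survives it (validated by simulation in the tests).

Per subject, GC matrices are averaged over epochs, symmetrized (mean of
the two directions by default, max by option), and reduced to the maximum
spanning tree by Kruskal's algorithm — edges sorted by descending weight,
added unless they close a cycle, ties broken lexicographically on the node
pair for determinism; strictly-zero weights count as absent edges. Five
global tree metrics per band (so 30 features over six bands):

* maximal degree;
* maximal betweenness centrality (normalized by (m−1)(m−2)/2 pairs; the
  raw count variant is available);
* leaf fraction L/m;
* diameter in edges;
* tree hierarchy Th = L / (2 · m_edges · BC_max), the leaf/betweenness
  balance index standard in the MST-EEG literature (no universal formula
  exists; this convention is flagged as a choice; Th := 0 for the 2-node
  tree where BC_max = 0).

## Synthetic data

* **Signal cohorts** (`gen_var_cohort`): per subject, a VAR(2) process with
  damped-oscillator diagonal dynamics (lag-1 coefficients 0.4–0.6, lag-2
  −0.35…−0.15) plus class-specific directed lag-1 couplings (default
  strength 0.35; 4 couplings in class 0 vs 12 in class 1, so only network
  topology separates the classes). Stability is enforced by checking the
  companion-matrix spectral radius (< 0.97) and shrinking couplings if
  needed. Defaults mirror a small resting-state study: 20 subjects per
  class, 19 channels, 512 Hz, 25 epochs of 4,096 samples.
* **Feature tables** (`gen_feature_table`): Gaussian features around
  plausible 19-node-tree baselines with user-specified standardized class
  shifts; metric constraints respected (integer degree/diameter ≥ 2, leaf
  fraction in (0, 1]).
* **Score ensembles** (`gen_classifier_scores`): Gaussian copula on latent
  correctness — classifier j is correct when its latent normal falls below
  the Φ⁻¹(acc_j) quantile, latents correlated as requested — so marginal
  accuracies are exact in expectation for any PSD correlation target.
  Winning-class confidence is 0.5 + 0.5·Beta(5, 2) when correct and
  0.5 + 0.5·Beta(2, 5) when wrong: informative but imperfect scores whose
  argmax reproduces the marginal accuracies. What this generator does *not*
  emulate: class-conditional difficulty (shared hard samples beyond the
  latent correlation), calibration drift, asymmetric class costs — so
  passing fusion tests show correctness of the operators and plausible
  lift under the stated error model, not clinical performance.

## Problem sizes and validation scales

The validation suite runs every mathematical contract at full stated scale
(1,000-instance oracle suites; exhaustive tree enumeration up to 8 nodes;
101×101 t-norm grids; 100 GC replicates at n = 4,096). The end-to-end
replica runs at a reduced scale chosen to keep the whole suite fast while
still exercising every stage: 40 subjects, 8 channels, 10 epochs × 1,024
samples, VAR order capped at 5, a 4-classifier roster, 2 operators × 2
t-norm families × 5 α values, 20 repetitions (160 pooled predictions).
At that scale the features carry a modest signal, so the meaningful check
is competitiveness — best fused accuracy within 2 points of the best
individual classifier — rather than a guaranteed positive lift; on the
1,600-sample score-ensemble benchmark, where the error model is controlled,
fusion clearly beats the best individual classifier.

## Known limitations

* Time-domain GC on band-filtered signals is not spectral GC; filtered
  signals violate strict VAR assumptions, and the absolute F values should
  be read as relative edge strengths, not calibrated test statistics.
* The λ-measure requires densities strictly inside (0, 1) for n ≥ 2; the
  flooring described above is a pragmatic regularization, not a model
  feature.
* Generalized operators are not aggregation functions in the strict
  axiomatic sense (no idempotence, no upper bound by max h); comparisons
  across operators should use the same densities and the same grid.
* The harness does not nest the density estimation inside an outer CV
  (single holdout per repetition), so grid-searched accuracies are mildly
  optimistic; the per-run macro average gives a feel for the spread.
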