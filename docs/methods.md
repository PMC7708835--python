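# Methods

## Model

A higher-order factorization machine (HOFM) of order *m* predicts a
response from a sparse feature vector **x** ∈ ℝ^d as a sum of a linear
term and interaction terms of every order t = 2..m. The order-t weight
of a feature tuple (i₁ < … < i_t) is the generalized inner product
⟨p⁽ᵗ⁾ᵢ₁, …, p⁽ᵗ⁾ᵢ_t⟩ = Σ_s Π_j p⁽ᵗ⁾ᵢⱼs of rows of a factor matrix
P⁽ᵗ⁾ ∈ ℝ^{d×k}. One rank k is shared by all orders, and one
regularization strength β by all parameter groups; the objective is

(1/n) Σᵢ (yᵢ − ŷ(xᵢ))² + (β/2)‖w‖² + Σ_t (β/2)‖P⁽ᵗ⁾‖².

There is no global intercept by default (an optional flag exists); the
constant level is absorbed by the one-hot weights, since every encoded
row activates the same number of blocks.

### Exact kernels and gradients

The degree-t interaction sum is the ANOVA kernel
A_t(z) = Σ_{i₁<…<i_t} z_{i₁}⋯z_{i_t} with z = P[:, s] ∘ x. The
public single-column routine uses the triangular dynamic program
a[t][i] = a[t][i−1] + zᵢ·a[t−1][i−1] in O(d·t). The batched training
path evaluates the same quantity through the Newton–Girard recurrence
over power sums S_r = Σᵢ zᵢʳ,

A_r = (1/r) Σ_{j=1..r} (−1)^{j+1} A_{r−j} S_j,

because every S_r is a single matrix product (Xʳ)(Pʳ) over the batch —
the two forms are algebraically identical (elementary symmetric
polynomials in z), and the test suite pins the fast path against an
exhaustive-enumeration oracle over 100 random models to 1e−8 relative.
Gradients differentiate the same recurrence (C_{t,r} = ∂A_t/∂S_r built
bottom-up), giving the exact gradient of the batch objective; it is
checked against central finite differences to 1e−5 relative. For the
degrees used here (t ≤ 5) and z of one-hot scale the alternating sum is
numerically benign.

### Training

Mini-batch SGD with Adam per-parameter step adaptation
(β₁ = 0.9, β₂ = 0.999, ε = 1e−8), factors initialized
Normal(0, 0.01²), linear weights zero. Training is bitwise reproducible
given the seed and aborts on a non-finite loss. Library defaults follow
the published full-scale budget — learning rate 0.001, 200 epochs,
batch 1024, order m = 5, rank k = 50, β selected from
{10², 10³, 10⁴, 10⁵} by nested CV. On the desk-scale synthetic screens
used throughout the tests those defaults undertrain and over-penalize:
with responses on the raw %-growth scale (≈0–100), weights must reach
magnitudes ~10–100, so β ≈ 1 already makes the ½β‖·‖² term dominate an
MSE of a few hundred. The benchmark configuration therefore uses
learning rate 0.05, 400 epochs, batch 256 and β = 1e−3, chosen from
training-loss convergence on the generator's default conditions.
Responses are not normalized or centered.

## Feature encoding

Five contiguous one-hot blocks (drug A, drug B, concentration A,
concentration B, cell line); drug and concentration blocks carry one
extra sentinel category so a monotherapy well is the same fifth-order
tensor entry with the absent slot pointing at the sentinel. The
concentration vocabulary is global (one shared list of distinct values
across both slots). Optional auxiliary blocks: per-slot binary
fingerprints (bits with zero variance across the drug panel removed),
a gene-expression block (top 0.5% of genes by variance across cell
lines, ties broken by gene identifier for determinism), and two scalar
log10-concentration features (0 for the sentinel). Descriptors are
consumed from user-provided tables as-is — bits binary, expression on
its z-score scale — and the filters are fit once on the full tables,
not per CV fold, mirroring the use of a single fixed descriptor set.

Unordered drug pairs are stored with identifiers in lexicographic
order; symmetry is handled at training time by duplicating every well
in both orientations (swapping the drug, concentration, and fingerprint
blocks), and at prediction time by averaging the two orientations.
Replicate wells are averaged at read time with a warning, since the
model maps one tensor entry to one response. Concentrations are
compared after rounding to 10 significant digits to absorb text-format
jitter.

## Synergy scores

The NCI ComboScore sums observed-minus-expected growth over the grid,
where the expectation is min(y_A, y_B) if either monotherapy growth is
≤ 0 and otherwise the product of the margins truncated at 150, divided
by 150. As printed, this makes synergistic growth *reduction* negative,
while synergy scores are conventionally read as positive; both sign
conventions are exposed (`as_printed` default, `alm_positive_synergy`
its negation) because the source definition is internally inconsistent
for growth data. The ComboScore of a predicted matrix is computed
against *measured* monotherapy margins by default (single-agent
responses are assumed known in all prediction scenarios); a predicted
grid can be passed explicitly.

The Bliss most-synergistic-area score converts growth to fractional
inhibition (1 − g/100, clamped to [0, 1]), subtracts the independence
surface e_A + e_B − e_A·e_B, and reports 100 × the maximal mean excess
over all 3 × 3 contiguous windows (window configurable, shrunk with a
warning on small grids). This windowed-mean definition is the prevailing
convention for "most synergistic area" and is declared as this package's
definition rather than claimed identical to any external tool.

Top-synergy labeling marks exactly ⌊fraction·N⌋ positives per group
(global or per tissue), ties at the cutoff broken by descending score
then ascending identifiers, so labels are deterministic.

## Cross-validation scenarios

Folds partition combination measurements at three levels — tensor
entries, (pair, cell line) matrices, or drug pairs — via shuffled
round-robin assignment over groups in dataset order (which makes
assignments equivariant under consistent relabeling). Monotherapies are
always in training. The pair-level scenario additionally requires every
drug of a held-out pair to appear in at least one training pair; draws
violating this are re-drawn with an incremented sub-seed (cap 100), and
a dataset containing a drug that occurs in only one pair is correctly
reported as infeasible. An audit routine re-checks partition,
disjointness, triplet/pair non-leakage and drug coverage and is run on
every fold construction inside nested CV; the test suite audits 1000
random draws per scenario.

Nested CV selects (k, β) by mean inner-fold RMSE, with inner folds
built by the same scenario's grouping restricted to the outer-training
measurements (hyperparameters should be selected under the same
generalization regime they will face). Per-fold outer metrics (RMSE,
Pearson, Spearman) are aggregated as unweighted means.

## Synthetic screens

The generator emulates the data regime of a large combination screen.
Per (drug, cell line) Hill monotherapies
g(c) = 100·(1 − Emax·cʰ/(cʰ + EC50ʰ)): reference EC50 per drug
log-uniform on [1e−8, 1e−5] M with 0.3-dex per-cell-line jitter, slope
uniform on [0.5, 3], Emax uniform on [0, 1]. Each drug gets its own
grid-size-point log-spaced dose grid spanning ±1.5 dex around its
reference EC50 (so dose grids bracket the active range, as designed
screens do). Combinations are Bliss-multiplicative
(g_A·g_B/100) minus a planted interaction
I(A, B, cell)·bump(p, q), with I a symmetric rank-r trilinear form in
Normal(0,1) drug/cell factors scaled by interaction_scale/√r and bump a
Gaussian weight in grid indices peaking mid-grid — positive I reduces
growth below independence (synergy), negative I produces antagonism.
I.i.d. Gaussian noise (sd in %-growth units) is added to every well.
Default conditions: 10 drugs, 20 of 45 pairs, 5 cell lines, 4 × 4
grids, interaction rank 2, interaction scale 10 %-growth units
(moderate: mid-grid Bliss excesses of ten-odd %-growth), noise sd 5.
Pair subsets are re-drawn until every screened drug sits in at least
two pairs, both because real screens pair each drug with many partners
and because pair-level hold-out is otherwise structurally infeasible.

What the generator does *not* emulate: growth stimulation beyond noise
(no responses systematically above 100), dose-response curve
mis-specification, plate/batch effects, replicate structure, or
realistic tissue stratification (tissues are a uniform categorical
assignment). Passing tests therefore demonstrate correct mechanics and
recoverability of multiplicative-plus-low-rank structure, not
performance on real screens. Note also that because the generator's
independence baseline is Bliss (product/100) while the ComboScore
expectation is the truncated product/150, noise-free non-interacting
matrices still have nonzero ComboScores; tests account for this offset.

## Benchmark problem sizes and observed behavior

The benchmark computations (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use the generator defaults: 1600 combination
wells + 200 monotherapies, encoded dimension 109. An order-3 rank-4
model trained on a 90/10 random-entry split reaches held-out RMSE ≈
6–8.5 %-growth (noise floor 5) and Pearson ≈ 0.96–0.98 across seeds;
the order-1 model is 2.5–3.5× worse in RMSE; with whole drug pairs held
out (5 folds) mean Pearson is ≈ 0.83–0.96. Variation across seeds
reflects the random interaction tensor and Hill parameters, not
training noise (doubling the epoch budget leaves the harder draws
unchanged). Fold-audit and labeling checks are exact.

## Known limitations

* Training is plain numpy; it is fast at desk scale but not tuned for
  the full screen-scale problem (no sparsity exploitation, no GPU).
* Rank is uniform across orders, matching the published choice;
  per-order ranks are not implemented.
* Only ComboScore and Bliss-MSA synergy models are provided; Loewe,
  HSA and ZIP require fitted dose-response curves and are out of scope.
* The brute-force predictor is an intentionally guarded test oracle
  (d ≤ 20); it is not a usable prediction path.
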